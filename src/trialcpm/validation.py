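"""Cross-validation, permutation nulls, and group-level inference.

The central design rule is train/test independence: ratings are normalized
within participant (so held-out participants never borrow training
statistics), every fold re-runs the full training procedure — edge selection
and the strength model — on the pooled training trials only, and the
permutation null repeats that *entire* procedure with rating-trial
assignments shuffled across the pooled training trials, then scores the same
held-out participant. Group-level significance compares each held-out
participant's predicted-vs-observed correlation against the mean of their
permutation-null correlations with a two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TrialCohort
from .errors import AtlasMismatchError, CollinearityError
from .model import (
    CpmModel,
    EdgeMask,
    fit_strength_model,
    network_strength,
    select_edges,
)

logger = logging.getLogger(__name__)


@dataclass
class PredictionReport:
    """Per-held-out-participant prediction outcomes plus group statistics."""

    per_participant: pd.DataFrame  # participant, n_trials, r_observed, mse, null_mean, degenerate
    group_p: float
    summary: dict
    null_distributions: dict[str, np.ndarray] = field(default_factory=dict)
    fold_masks: dict[str, EdgeMask] = field(default_factory=dict)
    fold_models: dict[str, CpmModel] = field(default_factory=dict)
    mask_overlap_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class TraitReport:
    """Spearman (and partial Spearman) prediction of a trait score."""

    rho: float
    p: float
    n: int
    partial: dict[str, tuple[float, float]] = field(default_factory=dict)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _column_correlations(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between a vector x and every column of Y."""
    x = np.asarray(x, float)
    xc = x - x.mean()
    sx = x.std()
    Yc = Y - Y.mean(axis=0)
    sy = Y.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / (len(x) * sx * sy)
    return r


def group_prediction_test(r_observed: np.ndarray, null_mean: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for observed r vs mean null r.

    Exact tail for small samples (no ties/zeros, n <= 50 via the standard
    enumeration), normal approximation with tie/zero handling otherwise.
    All-zero differences return p = 1.
    """
    obs = np.asarray(r_observed, float)
    nul = np.asarray(null_mean, float)
    if obs.shape != nul.shape or obs.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if obs.size < 5:
        raise ValueError("group test needs n >= 5 pairs")
    d = obs - nul
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(obs, nul, alternative="two-sided", zero_method="wilcox", method="auto")
    return float(res.pvalue)


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    n = len(y)
    X = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariate design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    # a variable fully explained by the covariates has nothing left to
    # correlate: snap numerically-zero residuals to exact zero
    if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(y), 1.0):
        resid = np.zeros_like(resid)
    return resid


def partial_prediction_correlation(
    predicted: np.ndarray, observed: np.ndarray, covariates: np.ndarray
) -> float:
    """Pearson correlation of predicted and observed after regressing both on
    the covariates (with intercept)."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    C = np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != len(predicted):
        C = C.T
    if len(predicted) < C.shape[1] + 3:
        raise ValueError("need at least n_covariates + 3 samples")
    rp = _residualize(predicted, C)
    ro = _residualize(observed, C)
    if not (rp.any() and ro.any()):
        return 0.0
    return _pearson(rp, ro)


def _permutation_null_fold(
    E_tr: np.ndarray,
    y_tr: np.ndarray,
    E_te: np.ndarray,
    y_te: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    allowed: np.ndarray,
) -> np.ndarray:
    """Null held-out correlations for one fold, fully vectorized.

    Re-runs the complete training procedure (edge selection at alpha, then
    the one-predictor OLS) under each of ``n_perm`` shuffles of the training
    ratings, and scores the held-out trials with each null model. Matches
    the naive per-permutation loop exactly (tested); permutations whose mask
    comes up empty or whose training strength is constant yield NaN.
    """
    n, m = E_tr.shape
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = y_tr[perm_idx].T  # (n, n_perm)

    mu = E_tr.mean(axis=0)
    sd = E_tr.std(axis=0, ddof=1)
    valid = allowed & (sd > 0)
    Ec = E_tr - mu
    sd_safe = np.where(sd > 0, sd, 1.0)
    yc = Y - Y.mean(axis=0)
    sy = Y.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Ec / sd_safe).T @ (yc / sy) / (n - 1)  # (m, n_perm)
        R = np.clip(R, -1.0, 1.0)
        T = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(T), df=n - 2)
    sel = (P < alpha) & valid[:, None]
    W = np.where(sel, np.sign(R), 0.0)  # (m, n_perm) mask weights

    S_tr = E_tr @ W  # (n, n_perm)
    S_te = E_te @ W
    s_mu = S_tr.mean(axis=0)
    s_var = S_tr.var(axis=0)
    cov = ((S_tr - s_mu) * yc).sum(axis=0) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = cov / S_tr.var(axis=0, ddof=1)
    # Pearson(beta*S_te + c, y_te) = sign(beta) * Pearson(S_te, y_te).
    r_te = _column_correlations(y_te, S_te)
    null_r = np.sign(beta) * r_te
    degenerate = (sel.sum(axis=0) == 0) | (s_var == 0) | ~np.isfinite(beta)
    null_r[degenerate] = np.nan
    return null_r


def _prepare_cohort(cohort: TrialCohort) -> tuple[TrialCohort, np.ndarray]:
    """Fill in rating_z if absent and drop edges with missing values from the
    candidate universe (cohort-wide, logged)."""
    if cohort.meta["rating_z"].isna().any():
        cohort, excluded = cohort.with_rating_z()
        if excluded:
            logger.warning("excluded zero-rating-variance participants: %s", excluded)
    good = ~np.isnan(cohort.edges).any(axis=0)
    if not good.all():
        logger.warning("excluding %d edges with missing values from the candidate universe", (~good).sum())
    return cohort, good


def lopo_cross_validate(
    cohort: TrialCohort,
    alpha: float = 0.01,
    seed: int = 0,
    n_perm: int = 1000,
    edge_subset: np.ndarray | None = None,
    covariates: list[str] | None = None,
) -> PredictionReport:
    """Leave-one-participant-out cross-validation with a permutation null.

    Per fold: edge selection and strength-model fit on all pooled training
    trials; per held-out participant: Pearson r between predicted and
    observed normalized ratings over their trials (plus MSE on the
    normalized scale). ``edge_subset`` restricts the edge universe before
    selection (restricted/lesioned variants). ``covariates`` names metadata
    columns for held-out partial correlations.
    """
    cohort, good = _prepare_cohort(cohort)
    allowed = good.copy()
    if edge_subset is not None:
        mask = np.zeros_like(allowed)
        mask[np.asarray(edge_subset, dtype=int)] = True
        allowed &= mask
    candidate = np.flatnonzero(allowed)

    participants = cohort.participants
    if len(participants) < 3:
        raise ValueError("LOPO needs >= 3 participants after exclusions")
    y_all = cohort.meta["rating_z"].to_numpy()

    rows = []
    null_dists: dict[str, np.ndarray] = {}
    fold_masks: dict[str, EdgeMask] = {}
    fold_models: dict[str, CpmModel] = {}
    for fold, part in enumerate(participants):
        te = cohort.participant_rows(part)
        tr = np.setdiff1d(np.arange(cohort.n_trials), te)
        E_tr, y_tr = cohort.edges[tr], y_all[tr]
        E_te, y_te = cohort.edges[te], y_all[te]

        emask = select_edges(E_tr, y_tr, cohort.n_nodes, alpha, candidate_edges=candidate)
        fold_masks[part] = emask
        row = {"participant": part, "n_trials": len(te), "n_training_trials": len(tr),
               "mask_pos": int(emask.positive.size), "mask_neg": int(emask.negative.size)}
        degenerate = emask.size == 0
        if not degenerate:
            s_tr = network_strength(E_tr, emask)
            if np.var(s_tr) == 0:
                degenerate = True
        if degenerate:
            warnings.warn(f"fold for {part} is degenerate (empty mask); excluded from group test",
                          RuntimeWarning, stacklevel=2)
            row.update(r_observed=np.nan, mse=np.nan, null_mean=np.nan, degenerate=True)
            rows.append(row)
            continue
        beta, c = fit_strength_model(s_tr, y_tr)
        model = CpmModel(mask=emask, beta=beta, intercept=c, training_n=len(tr), atlas=cohort.atlas)
        fold_models[part] = model
        pred = model.predict(E_te)
        row["r_observed"] = _pearson(pred, y_te)
        row["mse"] = float(np.mean((pred - y_te) ** 2))
        if covariates:
            for cov in covariates:
                cvals = cohort.meta[cov].to_numpy()[te]
                row[f"partial_r_{cov}"] = partial_prediction_correlation(pred, y_te, cvals)
        null_r = _permutation_null_fold(
            E_tr, y_tr, E_te, y_te, alpha, n_perm,
            np.random.default_rng([seed, 1000 + fold]), allowed,
        )
        null_dists[part] = null_r
        row["null_mean"] = float(np.nanmean(null_r)) if np.isfinite(null_r).any() else np.nan
        row["degenerate"] = False
        rows.append(row)

    per = pd.DataFrame(rows)
    ok = ~per["degenerate"].to_numpy()
    if ok.sum() >= 5:
        group_p = group_prediction_test(per.loc[ok, "r_observed"].to_numpy(),
                                        per.loc[ok, "null_mean"].to_numpy())
    else:
        group_p = np.nan
        warnings.warn("too few non-degenerate folds for a group test", RuntimeWarning, stacklevel=2)

    overlap = _mask_overlap_bookkeeping(cohort, alpha, candidate, fold_masks)
    summary = {
        "mean_r": float(np.nanmean(per["r_observed"])),
        "sd_r": float(np.nanstd(per["r_observed"], ddof=1)),
        "mean_mse": float(np.nanmean(per["mse"])),
        "sd_mse": float(np.nanstd(per["mse"], ddof=1)),
        "n_participants": len(participants),
        "n_degenerate": int((~ok).sum()),
        "alpha": alpha,
        "n_perm": n_perm,
    }
    return PredictionReport(
        per_participant=per, group_p=group_p, summary=summary,
        null_distributions=null_dists, fold_masks=fold_masks, fold_models=fold_models,
        mask_overlap_pct=overlap,
    )


def _mask_overlap_bookkeeping(cohort, alpha, candidate, fold_masks) -> dict[str, float]:
    """Mean percentage of each fold mask shared with the full-data mask, per sign."""
    full = select_edges(cohort.edges, cohort.meta["rating_z"].to_numpy(),
                        cohort.n_nodes, alpha, candidate_edges=candidate)
    out = {}
    for sign in ("positive", "negative"):
        fracs = []
        for emask in fold_masks.values():
            fm = getattr(emask, sign)
            if fm.size:
                fracs.append(100.0 * np.intersect1d(fm, getattr(full, sign)).size / fm.size)
        out[sign] = float(np.mean(fracs)) if fracs else np.nan
    return out


def train_full_model(cohort: TrialCohort, alpha: float = 0.01,
                     edge_subset: np.ndarray | None = None) -> CpmModel:
    """Train on every trial of a cohort (a single fold): the frozen model
    applied to external cohorts and resting data."""
    cohort, good = _prepare_cohort(cohort)
    candidate = np.flatnonzero(good) if edge_subset is None else np.intersect1d(
        np.flatnonzero(good), np.asarray(edge_subset, dtype=int))
    from .model import fit_cpm

    return fit_cpm(cohort.edges, cohort.meta["rating_z"].to_numpy(),
                   cohort.n_nodes, alpha, candidate_edges=candidate, atlas=cohort.atlas)


def apply_model_external(
    model: CpmModel,
    cohort: TrialCohort,
    n_perm: int = 1000,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> PredictionReport:
    """Apply a frozen model to an external cohort — no reselection, no refit.

    Each external participant is treated as held out; the null shuffles
    rating-trial assignments across the *whole* external cohort and rescoring
    uses the unchanged frozen predictions.
    """
    if model.mask.n_nodes != cohort.n_nodes:
        raise AtlasMismatchError(
            f"model expects {model.mask.n_nodes} nodes, cohort has {cohort.n_nodes}"
        )
    cohort, _ = _prepare_cohort(cohort)
    y_all = cohort.meta["rating_z"].to_numpy()
    pred_all = model.predict(cohort.edges)

    rng = np.random.default_rng([seed, 42])
    perm_idx = np.argsort(rng.random((n_perm, cohort.n_trials)), axis=1)

    rows = []
    null_dists = {}
    for part in cohort.participants:
        te = cohort.participant_rows(part)
        pred, obs = pred_all[te], y_all[te]
        row = {"participant": part, "n_trials": len(te),
               "r_observed": _pearson(pred, obs),
               "mse": float(np.mean((pred - obs) ** 2))}
        if covariates:
            for cov in covariates:
                cvals = cohort.meta[cov].to_numpy()[te]
                row[f"partial_r_{cov}"] = partial_prediction_correlation(pred, obs, cvals)
        Y_null = y_all[perm_idx[:, te]].T  # (n_trials_p, n_perm)
        null_r = _column_correlations(pred, Y_null)
        null_dists[part] = null_r
        row["null_mean"] = float(np.nanmean(null_r))
        row["degenerate"] = not np.isfinite(row["r_observed"])
        rows.append(row)

    per = pd.DataFrame(rows)
    ok = ~per["degenerate"].to_numpy()
    group_p = group_prediction_test(per.loc[ok, "r_observed"].to_numpy(),
                                    per.loc[ok, "null_mean"].to_numpy()) if ok.sum() >= 5 else np.nan
    summary = {
        "mean_r": float(np.nanmean(per["r_observed"])),
        "sd_r": float(np.nanstd(per["r_observed"], ddof=1)),
        "mean_mse": float(np.nanmean(per["mse"])),
        "sd_mse": float(np.nanstd(per["mse"], ddof=1)),
        "n_participants": len(per),
        "n_degenerate": int((~ok).sum()),
        "n_perm": n_perm,
    }
    return PredictionReport(per_participant=per, group_p=group_p, summary=summary,
                            null_distributions=null_dists)


def _partial_spearman(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> tuple[float, float]:
    """Partial Spearman = partial Pearson on average ranks; p via t-transform
    with df = n - 2 - n_covariates."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    C = np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != len(x):
        C = C.T
    rc = np.column_stack([stats.rankdata(c) for c in C.T])
    rho = _pearson(_residualize(rx, rc), _residualize(ry, rc))
    df = len(x) - 2 - rc.shape[1]
    t = rho * np.sqrt(df / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), df))


def trait_prediction(
    model: CpmModel,
    edge_vectors: np.ndarray,
    trait_scores: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
) -> TraitReport:
    """Spearman correlation between model-predicted and observed trait scores.

    Predicted score per participant is beta * S + c on the whole-run edge
    vector. Ties are handled by average ranks; partial Spearman residualizes
    the rank-transformed variables on each named covariate.
    """
    trait = np.asarray(trait_scores, float)
    n = len(trait)
    if n < 5:
        raise ValueError("trait prediction needs n >= 5 participants")
    predicted = np.asarray(model.predict(np.asarray(edge_vectors, float)))
    if np.std(trait) == 0:
        warnings.warn("constant trait vector; correlation undefined", RuntimeWarning, stacklevel=2)
        return TraitReport(rho=np.nan, p=np.nan, n=n)
    rho, p = stats.spearmanr(predicted, trait)
    report = TraitReport(rho=float(rho), p=float(p), n=n)
    for name, cov in (covariates or {}).items():
        report.partial[name] = _partial_spearman(predicted, trait, np.asarray(cov, float))
    return report


def group_strength_comparison(strengths_a: np.ndarray, strengths_b: np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of strengths
    between two groups, with tie correction; returns p and medians."""
    a = np.asarray(strengths_a, float)
    b = np.asarray(strengths_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need n >= 3")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {"p": float(res.pvalue), "statistic": float(res.statistic),
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "n_a": len(a), "n_b": len(b)}


def runwise_strength_trend(strengths: pd.DataFrame) -> pd.DataFrame:
    """Pairwise run comparisons of per-participant network strength.

    ``strengths`` is participants x runs (NaN for missing runs). Every run
    pair is tested with a two-sided Wilcoxon signed-rank on pairwise-complete
    participants; p-values are Benjamini-Hochberg adjusted across the tested
    pairs. Pairs with fewer than 3 complete participants are skipped with a
    warning.
    """
    runs = list(strengths.columns)
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    rows = []
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            a = strengths[runs[i]].to_numpy(float)
            b = strengths[runs[j]].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                warnings.warn(f"run pair ({runs[i]}, {runs[j]}) has < 3 complete participants; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            d = a[ok] - b[ok]
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(a[ok], b[ok], alternative="two-sided",
                                         zero_method="wilcox", method="auto").pvalue)
            rows.append({"run_a": runs[i], "run_b": runs[j], "n_complete": int(ok.sum()),
                         "median_diff": float(np.median(d)), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
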