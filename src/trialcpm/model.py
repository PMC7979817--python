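"""The CPM kernel: normalization, edge selection, network strength, linear model.

The modeling unit is the trial. Ratings are z-scored within participant
(training and held-out participants are normalized independently, so folds
never share statistics). Edges whose trial-wise Pearson correlation with the
normalized rating passes a two-tailed p < alpha threshold are split by sign
into positive and negative masks; each trial's network strength S is the sum
of its positive-mask edge values minus the sum of its negative-mask values;
the predictive model is ordinary least squares of rating on S alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AtlasMismatchError, DegenerateModelError, MissingEdgeError
from .features import EdgeVector, n_edges


@dataclass
class EdgeMask:
    """Positive and negative edge-index sets defining a CPM mask pair."""

    positive: np.ndarray
    negative: np.ndarray
    n_nodes: int
    selection_alpha: float = 0.01

    def __post_init__(self) -> None:
        self.positive = np.asarray(sorted(set(int(e) for e in np.atleast_1d(self.positive))), dtype=int)
        self.negative = np.asarray(sorted(set(int(e) for e in np.atleast_1d(self.negative))), dtype=int)
        m = n_edges(self.n_nodes)
        for name, idx in (("positive", self.positive), ("negative", self.negative)):
            if idx.size and (idx.min() < 0 or idx.max() >= m):
                raise ValueError(f"{name} mask indices out of range for {self.n_nodes} nodes")
        if np.intersect1d(self.positive, self.negative).size:
            raise ValueError("positive and negative masks must be disjoint")

    @property
    def size(self) -> int:
        return int(self.positive.size + self.negative.size)

    def sign_vector(self) -> np.ndarray:
        """Dense +1/-1/0 weight vector over the edge universe."""
        w = np.zeros(n_edges(self.n_nodes))
        w[self.positive] = 1.0
        w[self.negative] = -1.0
        return w


@dataclass
class CpmModel:
    """A frozen CPM: mask pair plus the linear coefficients fit on training trials."""

    mask: EdgeMask
    beta: float
    intercept: float
    training_n: int
    atlas: str = "synthetic"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and np.isfinite(self.intercept)):
            raise ValueError("CpmModel coefficients must be finite")
        if self.training_n < 3:
            raise ValueError("CpmModel.training_n must be >= 3")

    def predict(self, edges: EdgeVector | np.ndarray) -> float | np.ndarray:
        return predict(self, edges)


def zscore_within_participant(
    ratings: np.ndarray, participants: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Z-score ratings within each participant (sample SD, denominator n-1).

    Returns the z-scored vector and the list of participants flagged for
    exclusion because their ratings carry zero variance; their entries are
    NaN in the returned vector — callers drop them, they are never silently
    normalized.
    """
    ratings = np.asarray(ratings, dtype=float)
    participants = np.asarray(participants)
    z = np.full(ratings.shape, np.nan)
    excluded: list[str] = []
    for p in np.unique(participants):
        sel = participants == p
        vals = ratings[sel]
        if sel.sum() < 2:
            excluded.append(str(p))
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            excluded.append(str(p))
            continue
        z[sel] = (vals - vals.mean()) / sd
    return z, excluded


def edge_rating_correlations(
    edges: np.ndarray, rating_z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson r (and two-tailed p) across trials against rating_z.

    p-values use the exact t-transform t = r * sqrt((n-2)/(1-r^2)) against a
    t distribution with n-2 degrees of freedom. Edges with missing values or
    zero variance get r = NaN, p = 1 so they can never be selected.
    """
    E = np.asarray(edges, dtype=float)
    y = np.asarray(rating_z, dtype=float)
    n = E.shape[0]
    if n < 4:
        raise ValueError("edge-rating correlation needs >= 4 trials (df = n - 2 >= 2)")
    if y.shape != (n,):
        raise ValueError("rating_z length must equal trial count")
    valid = ~np.isnan(E).any(axis=0)
    Ec = E - np.nanmean(E, axis=0)
    sd_e = np.nanstd(E, axis=0, ddof=1)
    valid &= sd_e > 0
    yc = y - y.mean()
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise ValueError("rating_z is constant; correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec.T @ yc) / ((n - 1) * sd_e * sd_y)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    r[~valid] = np.nan
    p[~valid] = 1.0
    return r, p


def select_edges(
    edges: np.ndarray,
    rating_z: np.ndarray,
    n_nodes: int,
    alpha: float = 0.01,
    candidate_edges: np.ndarray | None = None,
) -> EdgeMask:
    """Sign-split edge selection at a two-tailed threshold (strict p < alpha).

    ``edges`` is a (n_trials, n_edges) matrix in canonical edge order.
    ``candidate_edges`` optionally restricts the universe considered (used by
    the restricted / lesioned model variants); edges outside it are never
    selected.
    """
    r, p = edge_rating_correlations(edges, rating_z)
    keep = p < alpha
    if candidate_edges is not None:
        allowed = np.zeros(r.shape[0], dtype=bool)
        allowed[np.asarray(candidate_edges, dtype=int)] = True
        keep &= allowed
    pos = np.flatnonzero(keep & (r > 0))
    neg = np.flatnonzero(keep & (r < 0))
    if pos.size == 0 and neg.size == 0:
        warnings.warn("edge selection returned an empty mask", RuntimeWarning, stacklevel=2)
    return EdgeMask(positive=pos, negative=neg, n_nodes=n_nodes, selection_alpha=alpha)


def network_strength(edges: EdgeVector | np.ndarray, mask: EdgeMask) -> float | np.ndarray:
    """S = sum of positive-mask edge values minus sum of negative-mask values.

    Accepts a single EdgeVector (or 1-D array) or a (n_trials, n_edges)
    matrix; returns a scalar or per-trial vector accordingly. A missing
    (NaN) value on a masked edge raises :class:`MissingEdgeError` so callers
    can drop the trial explicitly.
    """
    if isinstance(edges, EdgeVector):
        if edges.n_nodes != mask.n_nodes:
            raise AtlasMismatchError(
                f"edge vector has {edges.n_nodes} nodes, mask expects {mask.n_nodes}"
            )
        values = edges.values
    else:
        values = np.asarray(edges, dtype=float)
    single = values.ndim == 1
    V = np.atleast_2d(values)
    if V.shape[1] != n_edges(mask.n_nodes):
        raise AtlasMismatchError(
            f"edge dimension {V.shape[1]} does not match mask universe of {n_edges(mask.n_nodes)} edges"
        )
    masked = np.concatenate([mask.positive, mask.negative])
    if masked.size and np.isnan(V[:, masked]).any():
        raise MissingEdgeError("missing value on a masked edge")
    s = V[:, mask.positive].sum(axis=1) - V[:, mask.negative].sum(axis=1)
    return float(s[0]) if single else s


def fit_strength_model(strength: np.ndarray, rating_z: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares of rating_z on the single predictor S.

    Returns (beta, intercept). Raises :class:`DegenerateModelError` when S is
    constant (an empty mask or pathological data) or fewer than 3 trials are
    supplied.
    """
    s = np.asarray(strength, dtype=float)
    y = np.asarray(rating_z, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("strength and rating_z must be matching 1-D vectors")
    if s.size < 3:
        raise DegenerateModelError("fitting the strength model needs >= 3 trials")
    var = s.var()
    if var == 0 or not np.isfinite(var):
        raise DegenerateModelError("network strength is constant; model undefined")
    beta = float(np.cov(s, y, ddof=1)[0, 1] / s.var(ddof=1))
    intercept = float(y.mean() - beta * s.mean())
    return beta, intercept


def predict(model: CpmModel, edges: EdgeVector | np.ndarray) -> float | np.ndarray:
    """Predicted normalized rating: beta * S + c."""
    s = network_strength(edges, model.mask)
    return model.beta * s + model.intercept


def fit_cpm(
    edges: np.ndarray,
    rating_z: np.ndarray,
    n_nodes: int,
    alpha: float = 0.01,
    candidate_edges: np.ndarray | None = None,
    atlas: str = "synthetic",
) -> CpmModel:
    """Selection + strength + OLS in one step: the full training procedure on
    one pool of trials. Raises DegenerateModelError if the mask is empty."""
    mask = select_edges(edges, rating_z, n_nodes, alpha, candidate_edges)
    if mask.size == 0:
        raise DegenerateModelError("empty edge mask; no suprathreshold edges at this alpha")
    s = network_strength(edges, mask)
    beta, intercept = fit_strength_model(s, rating_z)
    return CpmModel(mask=mask, beta=beta, intercept=intercept, training_n=len(rating_z), atlas=atlas)
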