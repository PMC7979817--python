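"""File formats, run configuration and exclusion rules.

Everything on disk is plain text: trial tables and masks are TSV, edge
matrices are tab-delimited float text, run configuration is YAML, and model
metadata round-trips losslessly (floats are written at full precision).

Mask files use the edge-list convention (node_i, node_j, sign) with 0-based
node indices, one row per mask edge, so masks published against other
pipelines can be imported by relabeling nodes only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import META_COLUMNS, SyntheticCohort, TrialCohort
from .errors import ConfigurationError
from .features import (
    ParcellatedRun,
    connectivity,
    edge_index,
    edge_pair,
    extract_trial_window,
    n_edges,
)
from .model import CpmModel, EdgeMask
from .validation import PredictionReport

logger = logging.getLogger(__name__)

#: Participants whose mean overall frame-wise displacement exceeds this many
#: millimetres are excluded outright.
DEFAULT_FD_EXCLUDE_MM = 0.15


# ---------------------------------------------------------------- cohorts

def save_cohort(cohort: TrialCohort, out_dir: str | Path) -> Path:
    """Write a cohort as trials.tsv + edges.tsv (+ truth masks if synthetic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.meta[META_COLUMNS].to_csv(out / "trials.tsv", sep="\t", index=False)
    np.savetxt(out / "edges.tsv", cohort.edges, delimiter="\t", fmt="%.17g")
    meta = {"n_nodes": int(cohort.n_nodes), "atlas": cohort.atlas,
            "n_trials": int(cohort.n_trials)}
    if isinstance(cohort, SyntheticCohort):
        _write_edge_list(out / "truth_pos.tsv", cohort.truth_pos_edges, cohort.n_nodes, +1)
        _write_edge_list(out / "truth_neg.tsv", cohort.truth_neg_edges, cohort.n_nodes, -1)
        np.savetxt(out / "latent_states.tsv", cohort.latent_states, delimiter="\t", fmt="%.17g")
        meta["synthetic"] = True
    (out / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def load_cohort_dir(path: str | Path) -> TrialCohort:
    """Read a cohort written by :func:`save_cohort` (lossless round trip)."""
    p = Path(path)
    meta = yaml.safe_load((p / "cohort.yaml").read_text())
    trials = pd.read_csv(p / "trials.tsv", sep="\t")
    edges = np.loadtxt(p / "edges.tsv", delimiter="\t", ndmin=2)
    if meta.get("synthetic") and (p / "truth_pos.tsv").exists():
        pos = _read_edge_list(p / "truth_pos.tsv", meta["n_nodes"])[0]
        neg = _read_edge_list(p / "truth_neg.tsv", meta["n_nodes"])[1]
        latent = np.loadtxt(p / "latent_states.tsv", delimiter="\t", ndmin=1)
        return SyntheticCohort(edges=edges, meta=trials, n_nodes=meta["n_nodes"],
                               atlas=meta["atlas"], truth_pos_edges=pos,
                               truth_neg_edges=neg, latent_states=latent)
    return TrialCohort(edges=edges, meta=trials, n_nodes=meta["n_nodes"], atlas=meta["atlas"])


# ---------------------------------------------------------------- masks / models

def _write_edge_list(path: Path, edges: np.ndarray, n_nodes: int, sign: int) -> None:
    rows = [(*edge_pair(int(k), n_nodes), sign) for k in np.asarray(edges, int)]
    pd.DataFrame(rows, columns=["node_i", "node_j", "sign"]).to_csv(path, sep="\t", index=False)


def _read_edge_list(path: Path, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    pos, neg = [], []
    for _, row in df.iterrows():
        k = edge_index(int(row["node_i"]), int(row["node_j"]), n_nodes)
        (pos if int(row["sign"]) > 0 else neg).append(k)
    return np.asarray(sorted(pos), int), np.asarray(sorted(neg), int)


def save_mask(mask: EdgeMask, path: str | Path) -> None:
    """Edge-list TSV for a mask pair: node_i, node_j, sign (+1/-1)."""
    rows = [(*edge_pair(int(k), mask.n_nodes), 1) for k in mask.positive]
    rows += [(*edge_pair(int(k), mask.n_nodes), -1) for k in mask.negative]
    pd.DataFrame(rows, columns=["node_i", "node_j", "sign"]).to_csv(path, sep="\t", index=False)


def load_mask(path: str | Path, n_nodes: int, selection_alpha: float = 0.01) -> EdgeMask:
    pos, neg = _read_edge_list(Path(path), n_nodes)
    return EdgeMask(positive=pos, negative=neg, n_nodes=n_nodes, selection_alpha=selection_alpha)


def save_model(model: CpmModel, out_dir: str | Path) -> Path:
    """Serialize a frozen model: mask edge list + full-precision metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mask(model.mask, out / "mask.tsv")
    meta = {
        "beta": float(model.beta),
        "intercept": float(model.intercept),
        "selection_alpha": float(model.mask.selection_alpha),
        "n_nodes": int(model.mask.n_nodes),
        "training_n": int(model.training_n),
        "atlas": model.atlas,
    }
    (out / "model.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def load_model(path: str | Path) -> CpmModel:
    p = Path(path)
    meta = yaml.safe_load((p / "model.yaml").read_text())
    mask = load_mask(p / "mask.tsv", meta["n_nodes"], meta["selection_alpha"])
    return CpmModel(mask=mask, beta=meta["beta"], intercept=meta["intercept"],
                    training_n=meta["training_n"], atlas=meta.get("atlas", ""))


def write_prediction_report(report: PredictionReport, out_dir: str | Path,
                            dump_nulls: bool = False) -> Path:
    """Per-participant TSV + JSON summary (null distributions on request)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_participant.to_csv(out / "report.tsv", sep="\t", index=False)
    summary = dict(report.summary)
    summary["group_p"] = None if not np.isfinite(report.group_p) else float(report.group_p)
    summary["mask_overlap_pct"] = report.mask_overlap_pct
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if dump_nulls and report.null_distributions:
        null = pd.DataFrame(report.null_distributions)
        null.to_csv(out / "null_distributions.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------- raw series

def read_parcellated_series(path: str | Path, tr_seconds: float = 1.08) -> ParcellatedRun:
    """Frames x nodes TSV/CSV with a header naming the nodes; an optional
    ``framewise_displacement`` column is split off as the motion trace."""
    p = Path(path)
    sep = "," if p.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(p, sep=sep)
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ConfigurationError(f"{p}: could not parse series table ({exc})") from exc
    fd = None
    if "framewise_displacement" in df.columns:
        fd = df.pop("framewise_displacement").to_numpy(float)
    if df.shape[1] < 2:
        raise ConfigurationError(f"{p}: series needs >= 2 node columns")
    return ParcellatedRun(series=df.to_numpy(float).T, tr_seconds=tr_seconds,
                          node_ids=list(df.columns), framewise_displacement=fd, run_id=p.stem)


def read_events(path: str | Path, onset_unit: str = "frames",
                tr_seconds: float = 1.08, frames_one_based: bool = False) -> pd.DataFrame:
    """Probe/event table: columns ``onset`` and ``rating`` (plus covariates).

    The onset dialect is declared, never guessed: seconds are floored onto
    the frame grid; frame onsets must be integral and are shifted to the
    package's 0-based convention if declared 1-based.
    """
    p = Path(path)
    df = pd.read_csv(p, sep="\t")
    for col in ("onset", "rating"):
        if col not in df.columns:
            raise ConfigurationError(f"{p}: events table is missing the '{col}' column")
    onset = df["onset"].to_numpy(float)
    if onset_unit == "seconds":
        frames = np.floor(onset / tr_seconds).astype(int)
    elif onset_unit == "frames":
        if not np.allclose(onset, np.round(onset)):
            raise ConfigurationError(
                f"{p}: onset declared in frames but contains non-integer values — dialect mismatch"
            )
        frames = onset.astype(int) - (1 if frames_one_based else 0)
    else:
        raise ConfigurationError(f"unknown onset_unit {onset_unit!r} (use 'frames' or 'seconds')")
    out = df.copy()
    out["onset_frame"] = frames
    return out


# ---------------------------------------------------------------- exclusions

def iqr_run_exclusions(run_fd_means: np.ndarray) -> np.ndarray:
    """Boolean keep-mask over a participant's runs: a run is dropped when its
    mean FD exceeds the 75th percentile plus 1.5 times the interquartile
    range of that participant's runs."""
    fd = np.asarray(run_fd_means, float)
    q1, q3 = np.percentile(fd, [25, 75])
    return fd <= q3 + 1.5 * (q3 - q1)


@dataclass
class RunConfig:
    """Configuration of a cohort-loading run (paths resolved relative to the
    config file)."""

    participants: list[dict]  # each: id, series (path or list of paths), events, group
    n_nodes: int
    atlas: str = ""
    tr_seconds: float = 1.08
    window_len: int = 28
    selection_alpha: float = 0.01
    n_perm: int = 1000
    seed: int = 0
    fd_exclude_mm: float = DEFAULT_FD_EXCLUDE_MM
    onset_unit: str = "frames"
    frames_one_based: bool = False
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if self.fd_exclude_mm <= 0:
            raise ConfigurationError("fd_exclude_mm must be positive")
        if self.window_len < 3:
            raise ConfigurationError("window_len must be >= 3")
        for part in self.participants:
            for key in ("id", "series", "events"):
                if key not in part:
                    raise ConfigurationError(f"participant entry missing '{key}': {part}")
            series = part["series"] if isinstance(part["series"], list) else [part["series"]]
            for path in [*series, part["events"]]:
                if not (self.base_dir / path).exists():
                    raise ConfigurationError(f"path not resolvable: {self.base_dir / path}")


def load_run_config(path: str | Path) -> RunConfig:
    p = Path(path)
    raw = yaml.safe_load(p.read_text())
    raw.setdefault("base_dir", p.parent)
    raw["base_dir"] = Path(raw["base_dir"])
    return RunConfig(**raw)


def load_cohort(config: RunConfig) -> tuple[TrialCohort, list[dict]]:
    """Load, window and score a cohort from parcellated series + event tables.

    Applies, in order: participant-level mean-FD exclusion, run-level IQR
    exclusion (when a participant has several runs), window extraction and
    Fisher-z connectivity, then the zero-rating-variance exclusion. Every
    exclusion is logged with its reason and returned alongside the cohort.
    """
    exclusions: list[dict] = []
    records, edge_rows = [], []
    for part in config.participants:
        pid = str(part["id"])
        series_paths = part["series"] if isinstance(part["series"], list) else [part["series"]]
        runs = [read_parcellated_series(config.base_dir / sp, config.tr_seconds)
                for sp in series_paths]
        run_fd = np.array([np.nanmean(r.framewise_displacement)
                           if r.framewise_displacement is not None else np.nan for r in runs])
        overall_fd = np.nanmean(run_fd)
        if np.isfinite(overall_fd) and overall_fd > config.fd_exclude_mm:
            exclusions.append({"participant": pid, "level": "participant",
                               "reason": f"mean FD {overall_fd:.3f} mm > {config.fd_exclude_mm} mm"})
            logger.info("excluded %s: mean FD %.3f mm", pid, overall_fd)
            continue
        keep_runs = np.ones(len(runs), bool)
        if len(runs) > 1 and np.isfinite(run_fd).all():
            keep_runs = iqr_run_exclusions(run_fd)
            for i in np.flatnonzero(~keep_runs):
                exclusions.append({"participant": pid, "level": "run",
                                   "reason": f"run {runs[i].run_id} FD {run_fd[i]:.3f} mm beyond Q3 + 1.5*IQR"})
        events = read_events(config.base_dir / part["events"], config.onset_unit,
                             config.tr_seconds, config.frames_one_based)
        trial_counter = 0
        for run in (r for r, k in zip(runs, keep_runs) if k):
            for _, ev in events.iterrows():
                block, fd_mean = extract_trial_window(run, int(ev["onset_frame"]), config.window_len)
                edge_rows.append(connectivity(block).values)
                records.append({
                    "participant": pid, "trial_index": trial_counter,
                    "rating_raw": float(ev["rating"]), "rating_z": np.nan,
                    "fd_mean": fd_mean,
                    "rt_variability": float(ev.get("rt_variability", np.nan)),
                    "group": str(part.get("group", "healthy")),
                })
                trial_counter += 1
    if not records:
        raise ConfigurationError("no trials survived exclusion")
    cohort = TrialCohort(edges=np.vstack(edge_rows), meta=pd.DataFrame(records),
                         n_nodes=_nodes_from_edges(len(edge_rows[0])), atlas=config.atlas)
    cohort, zero_var = cohort.with_rating_z()
    for pid in zero_var:
        exclusions.append({"participant": pid, "level": "participant",
                           "reason": "no variation in ratings"})
    return cohort, exclusions


def _nodes_from_edges(m: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n_edges(n) != m:
        raise ValueError(f"{m} is not a triangular number of edges")
    return n
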