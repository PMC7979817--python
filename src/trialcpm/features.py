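"""Functional-connectivity feature extraction.

Turns parcellated BOLD time series and thought-probe onsets into per-trial
edge vectors: the Fisher-z transformed Pearson correlation of every unique
node pair, computed over the fixed-length window that precedes each probe.

Edge ordering is canonical throughout the package: row-major upper triangle,
i.e. the order produced by ``numpy.triu_indices(n_nodes, k=1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import WindowError

#: Pearson correlations are clipped to +/- (1 - R_CLIP) before the inverse
#: hyperbolic tangent so that degenerate perfect correlations stay finite
#: while preserving ordering.
R_CLIP = 1e-7


def n_edges(n_nodes: int) -> int:
    """Number of unique node pairs (edges) for an ``n_nodes`` parcellation."""
    return n_nodes * (n_nodes - 1) // 2


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Map an ordered node pair ``(i, j)`` with ``i < j`` to its edge position.

    The bijection follows row-major upper-triangle order: (0,1) -> 0,
    (0,2) -> 1, ..., (n-2, n-1) -> n_edges - 1.
    """
    if not (0 <= i < j < n_nodes):
        raise IndexError(f"edge_index requires 0 <= i < j < n_nodes, got ({i}, {j}) for {n_nodes} nodes")
    return i * n_nodes - i * (i + 1) // 2 + (j - i - 1)


def edge_pair(k: int, n_nodes: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: edge position -> node pair ``(i, j)``."""
    m = n_edges(n_nodes)
    if not (0 <= k < m):
        raise IndexError(f"edge position {k} out of range for {n_nodes} nodes ({m} edges)")
    # Row i holds (n_nodes - 1 - i) entries starting at offset i*n - i*(i+1)/2.
    i = int(n_nodes - 2 - np.floor((np.sqrt(8 * (m - k - 1) + 1) - 1) / 2))
    j = k - (i * n_nodes - i * (i + 1) // 2) + i + 1
    return i, int(j)


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays ``(rows, cols)`` of node indices in canonical edge order."""
    return np.triu_indices(n_nodes, k=1)


@dataclass
class EdgeVector:
    """Fisher-z connectivity values over all unique node pairs.

    ``values[k]`` is the edge between nodes ``edge_pair(k, n_nodes)``.
    Missing edges (from zero-variance nodes) are NaN, never silently zero.
    """

    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = n_edges(self.n_nodes)
        if self.values.shape != (expected,):
            raise ValueError(
                f"EdgeVector for {self.n_nodes} nodes needs {expected} values, got shape {self.values.shape}"
            )

    def as_matrix(self) -> np.ndarray:
        """Symmetric node x node matrix with zeros on the diagonal."""
        mat = np.zeros((self.n_nodes, self.n_nodes))
        iu = np.triu_indices(self.n_nodes, k=1)
        mat[iu] = self.values
        mat.T[iu] = self.values
        return mat


@dataclass
class ParcellatedRun:
    """A denoised node x frame time-series block from one fMRI run."""

    series: np.ndarray  # (n_nodes, n_frames)
    tr_seconds: float = 1.08
    node_ids: list[str] | None = None
    framewise_displacement: np.ndarray | None = None
    run_id: str = ""

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] < 2:
            raise ValueError("ParcellatedRun.series must be a (n_nodes >= 2) x n_frames matrix")
        if np.isnan(self.series).any():
            raise ValueError("ParcellatedRun.series contains missing frames")
        if self.node_ids is None:
            self.node_ids = [f"node{i:03d}" for i in range(self.series.shape[0])]
        if self.framewise_displacement is not None:
            self.framewise_displacement = np.asarray(self.framewise_displacement, dtype=float)
            if self.framewise_displacement.shape != (self.series.shape[1],):
                raise ValueError("framewise_displacement length must equal frame count")

    @property
    def n_nodes(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]


@dataclass
class TrialSample:
    """One thought-probe trial: its edge vector, ratings and covariates."""

    participant: str
    trial_index: int
    edges: EdgeVector
    rating_raw: float
    rating_z: float = np.nan
    fd_mean: float = np.nan
    rt_variability: float = np.nan
    group: str = "healthy"

    def __post_init__(self) -> None:
        if not (0 <= self.rating_raw <= 100):
            raise ValueError(f"rating_raw must lie in [0, 100], got {self.rating_raw}")


def extract_trial_window(
    run: ParcellatedRun, probe_onset_frame: int, window_len: int = 28
) -> tuple[np.ndarray, float]:
    """Slice the pre-probe window from a run.

    Returns the frames ``[probe_onset_frame - window_len, probe_onset_frame)``
    (half-open, 0-based — the probe-onset frame itself is excluded) together
    with the mean frame-wise displacement over exactly those frames (NaN when
    the run carries no displacement trace).
    """
    if window_len < 3:
        raise WindowError("window_len must be >= 3 frames for a defined correlation")
    if probe_onset_frame < window_len:
        raise WindowError(
            f"probe onset at frame {probe_onset_frame} leaves fewer than {window_len} preceding frames"
        )
    if probe_onset_frame > run.n_frames:
        raise WindowError(f"probe onset frame {probe_onset_frame} beyond run length {run.n_frames}")
    sl = slice(probe_onset_frame - window_len, probe_onset_frame)
    block = run.series[:, sl]
    if run.framewise_displacement is not None:
        fd_mean = float(run.framewise_displacement[sl].mean())
    else:
        fd_mean = float("nan")
    return block, fd_mean


def connectivity(block: np.ndarray) -> EdgeVector:
    """Fisher-z Pearson correlation of every unique node pair in a block.

    Correlations are clipped to ``+/- (1 - 1e-7)`` before ``arctanh``.
    Zero-variance nodes are flagged with a warning and every edge touching
    them is set to NaN so downstream code can exclude rather than mis-score
    those trials.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[0] < 2:
        raise ValueError("connectivity needs a (n_nodes >= 2) x n_frames block")
    nn, nf = block.shape
    if nf < 3:
        raise ValueError("connectivity needs at least 3 frames")
    sd = block.std(axis=1)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(block)
    iu = np.triu_indices(nn, k=1)
    r = np.clip(corr[iu], -1 + R_CLIP, 1 - R_CLIP)
    z = np.arctanh(r)
    bad = dead[iu[0]] | dead[iu[1]]
    if bad.any():
        z[bad] = np.nan
        warnings.warn(
            f"{int(dead.sum())} zero-variance node(s); {int(bad.sum())} edge(s) set to missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return EdgeVector(z, nn)


def whole_run_connectivity(runs: ParcellatedRun | list[ParcellatedRun]) -> EdgeVector:
    """Connectivity over the full duration of one run, or the edge-wise mean
    of per-run vectors when several runs from one participant are supplied."""
    if isinstance(runs, ParcellatedRun):
        runs = [runs]
    if not runs:
        raise ValueError("whole_run_connectivity needs at least one run")
    nn = runs[0].n_nodes
    vecs = []
    for run in runs:
        if run.n_nodes != nn:
            raise ValueError("all runs must share the same parcellation")
        vecs.append(connectivity(run.series).values)
    return EdgeVector(np.mean(vecs, axis=0), nn)
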