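"""In-memory cohort container: trial metadata plus the trial x edge matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import EdgeVector, TrialSample, n_edges
from .model import zscore_within_participant

#: Metadata columns every cohort frame carries.
META_COLUMNS = ["participant", "trial_index", "rating_raw", "rating_z", "fd_mean", "rt_variability", "group"]


@dataclass
class TrialCohort:
    """All thought-probe trials of a cohort.

    ``edges`` is a (n_trials, n_edges) matrix in canonical edge order and
    Fisher-z units; ``meta`` holds one row per trial with the columns in
    :data:`META_COLUMNS`, aligned with the edge rows.
    """

    edges: np.ndarray
    meta: pd.DataFrame
    n_nodes: int
    atlas: str = "synthetic"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 2 or self.edges.shape[1] != n_edges(self.n_nodes):
            raise ValueError(
                f"edges must be (n_trials, {n_edges(self.n_nodes)}) for {self.n_nodes} nodes"
            )
        if len(self.meta) != self.edges.shape[0]:
            raise ValueError("meta rows must align with edge rows")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns: {missing}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.edges.shape[0]

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.meta["participant"]))

    def with_rating_z(self) -> tuple["TrialCohort", list[str]]:
        """Return a copy with within-participant z-scored ratings filled in,
        dropping (and reporting) zero-variance participants."""
        z, excluded = zscore_within_participant(
            self.meta["rating_raw"].to_numpy(), self.meta["participant"].to_numpy()
        )
        meta = self.meta.copy()
        meta["rating_z"] = z
        keep = ~meta["participant"].isin(excluded)
        sub = TrialCohort(self.edges[keep.to_numpy()], meta[keep], self.n_nodes, self.atlas)
        return sub, excluded

    def participant_rows(self, participant: str) -> np.ndarray:
        return np.flatnonzero((self.meta["participant"] == participant).to_numpy())

    def subset(self, rows: np.ndarray) -> "TrialCohort":
        return TrialCohort(self.edges[rows], self.meta.iloc[rows], self.n_nodes, self.atlas)

    def trials(self):
        """Iterate trials as :class:`TrialSample` views (convenience surface)."""
        for i, row in self.meta.iterrows():
            yield TrialSample(
                participant=str(row["participant"]),
                trial_index=int(row["trial_index"]),
                edges=EdgeVector(self.edges[i], self.n_nodes),
                rating_raw=float(row["rating_raw"]),
                rating_z=float(row["rating_z"]),
                fd_mean=float(row["fd_mean"]),
                rt_variability=float(row["rt_variability"]),
                group=str(row["group"]),
            )


@dataclass
class SyntheticCohort(TrialCohort):
    """A generated cohort carrying its planted ground truth."""

    truth_pos_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    truth_neg_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    latent_states: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.truth_pos_edges = np.asarray(self.truth_pos_edges, dtype=int)
        self.truth_neg_edges = np.asarray(self.truth_neg_edges, dtype=int)
        if np.intersect1d(self.truth_pos_edges, self.truth_neg_edges).size:
            raise ValueError("planted positive and negative edge sets must be disjoint")
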