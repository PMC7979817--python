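"""Network-anatomical decomposition of CPM masks and edge universes.

Nodes carry canonical resting-state network labels (the 7- or 17-way
Yeo-Krienen taxonomy, or any user taxonomy); every edge then belongs to one
unordered within- or between-network pair bin (K labels give K*(K+1)/2
bins — 28 for the 7-network scheme). The module counts mask edges per bin,
summarizes trial FC per bin under a within-participant median split of
ratings, tests mask overlap with a hypergeometric tail, and runs restricted
("these pairs only") and lesioned ("these pairs deleted") variants of the
full cross-validated pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TrialCohort
from .errors import AtlasMismatchError, ConfigurationError
from .features import edge_pairs, n_edges
from .model import EdgeMask
from .validation import PredictionReport, lopo_cross_validate

#: Canonical 7-network labels of the Yeo-Krienen taxonomy.
YEO7_LABELS = ("VIS", "SMN", "DAN", "SAL", "LIM", "FPCN", "DMN")


@dataclass
class NetworkAssignment:
    """node -> network label map for one atlas and taxonomy scheme."""

    labels: np.ndarray  # one label string per node
    scheme: str = "7"
    atlas: str = "synthetic"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or len(self.labels) < 2:
            raise ValueError("labels must be a 1-D array with one entry per node (>= 2 nodes)")
        if any(lbl is None or str(lbl) == "" for lbl in self.labels):
            bad = [i for i, lbl in enumerate(self.labels) if lbl is None or str(lbl) == ""]
            raise ValueError(f"unlabeled node(s): {bad}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> list[str]:
        return sorted(set(str(x) for x in self.labels))

    def pair_bins(self) -> list[tuple[str, str]]:
        """All unordered network pairs, including within-network self-pairs."""
        return list(combinations_with_replacement(self.networks, 2))

    def edge_pair_labels(self) -> np.ndarray:
        """Canonical (sorted-label) pair key for every edge, in edge order."""
        iu, ju = edge_pairs(self.n_nodes)
        a = self.labels[iu].astype(str)
        b = self.labels[ju].astype(str)
        swap = a > b
        lo = np.where(swap, b, a)
        hi = np.where(swap, a, b)
        return np.char.add(np.char.add(lo.astype(str), "|"), hi.astype(str))

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: str = "7", atlas: str = "") -> "NetworkAssignment":
        """Two-column TSV (node_id, network_label), node order = file order."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (node_id, network_label)")
        return cls(labels=df.iloc[:, 1].to_numpy(), scheme=scheme, atlas=atlas or str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"node_id": np.arange(self.n_nodes), "network_label": self.labels}
        ).to_csv(path, sep="\t", index=False)


def _pair_key(a: str, b: str) -> str:
    lo, hi = sorted((str(a), str(b)))
    return f"{lo}|{hi}"


def count_edges_by_pair(edge_indices: np.ndarray, assignment: NetworkAssignment) -> pd.Series:
    """Count edges per unordered network-pair bin; zero bins are kept so the
    7-network scheme always yields its 28 rows. Counts sum to the number of
    edges given."""
    keys = assignment.edge_pair_labels()
    bins = [_pair_key(a, b) for a, b in assignment.pair_bins()]
    counts = pd.Series(0, index=pd.Index(bins, name="network_pair"), dtype=int)
    idx = np.asarray(edge_indices, dtype=int)
    if idx.size:
        if idx.max() >= n_edges(assignment.n_nodes):
            raise AtlasMismatchError("edge index beyond the assignment's edge universe")
        vals, n = np.unique(keys[idx], return_counts=True)
        counts.loc[vals] += n
    return counts


def count_mask_edges_by_pair(mask: EdgeMask, assignment: NetworkAssignment) -> dict[str, pd.Series]:
    """Per-sign network-pair counts for a CPM mask pair."""
    if mask.n_nodes != assignment.n_nodes:
        raise AtlasMismatchError(
            f"mask has {mask.n_nodes} nodes, assignment labels {assignment.n_nodes}"
        )
    return {
        "positive": count_edges_by_pair(mask.positive, assignment),
        "negative": count_edges_by_pair(mask.negative, assignment),
    }


def edges_for_pairs(
    assignment: NetworkAssignment, pairs: list[tuple[str, str]], n_nodes: int | None = None
) -> np.ndarray:
    """Edge indices whose two nodes' networks form one of the given pairs."""
    if n_nodes is not None and n_nodes != assignment.n_nodes:
        raise AtlasMismatchError("n_nodes does not match the assignment")
    wanted = {_pair_key(a, b) for a, b in pairs}
    unknown = wanted - {_pair_key(a, b) for a, b in assignment.pair_bins()}
    if unknown:
        raise ConfigurationError(f"unknown network pair(s): {sorted(unknown)}")
    keys = assignment.edge_pair_labels()
    return np.flatnonzero(np.isin(keys, list(wanted)))


def median_split_pair_summary(
    cohort: TrialCohort, pair: tuple[str, str], assignment: NetworkAssignment
) -> pd.DataFrame:
    """Mean pair FC for the low- and high-rating trial halves per participant.

    Trials are split at the within-participant median rating; trials exactly
    at the median fall in the low half (so an odd trial count makes the low
    half larger by one). The last rows hold the group mean and SEM across
    participants.
    """
    pair_edges = edges_for_pairs(assignment, [pair])
    if pair_edges.size == 0:
        raise ConfigurationError(f"network pair {pair} contains no edges")
    trial_means = cohort.edges[:, pair_edges].mean(axis=1)
    ratings = cohort.meta["rating_raw"].to_numpy(float)

    rows = []
    for part in cohort.participants:
        sel = cohort.participant_rows(part)
        if sel.size < 2:
            raise ValueError(f"participant {part} has < 2 trials")
        med = np.median(ratings[sel])
        low = sel[ratings[sel] <= med]
        high = sel[ratings[sel] > med]
        if high.size == 0:  # all ratings tied at the median
            high = low
        rows.append({"participant": part,
                     "low_mean": float(trial_means[low].mean()),
                     "high_mean": float(trial_means[high].mean()),
                     "n_low": int(low.size), "n_high": int(high.size)})
    out = pd.DataFrame(rows)
    n = len(out)
    grp = {"participant": "GROUP",
           "low_mean": float(out["low_mean"].mean()), "high_mean": float(out["high_mean"].mean()),
           "n_low": n, "n_high": n}
    sem = {"participant": "GROUP_SEM",
           "low_mean": float(out["low_mean"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
           "high_mean": float(out["high_mean"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
           "n_low": n, "n_high": n}
    return pd.concat([out, pd.DataFrame([grp, sem])], ignore_index=True)


@dataclass
class OverlapTest:
    """Hypergeometric edge-overlap test between two masks."""

    x: int  # overlapping edges
    M: int  # total edge universe
    K: int  # edges in mask 1
    n: int  # edges in mask 2
    p: float

    def __post_init__(self) -> None:
        if not (self.x <= min(self.K, self.n) and self.K <= self.M and self.n <= self.M):
            raise ValueError("inconsistent overlap counts (x <= min(K, n) <= M required)")


def mask_overlap_significance(
    mask1: np.ndarray, mask2: np.ndarray, M: int, inclusive: bool = False
) -> OverlapTest:
    """Tail probability of the edge overlap between two masks.

    Default is the strict tail P(X > x) under Hypergeometric(M, K, n) — the
    form conventionally written 1 - hygecdf(x, M, K, n); ``inclusive=True``
    gives the enrichment-style P(X >= x).
    """
    e1 = np.unique(np.asarray(mask1, dtype=int))
    e2 = np.unique(np.asarray(mask2, dtype=int))
    for e in (e1, e2):
        if e.size and (e.min() < 0 or e.max() >= M):
            raise AtlasMismatchError("mask edge index outside the M-edge universe")
    x = int(np.intersect1d(e1, e2).size)
    K, n = int(e1.size), int(e2.size)
    thresh = x - 1 if inclusive else x
    p = float(stats.hypergeom.sf(thresh, M, K, n))
    return OverlapTest(x=x, M=M, K=K, n=n, p=p)


def restrict_cpm(
    cohort: TrialCohort,
    pairs: list[tuple[str, str]],
    assignment: NetworkAssignment,
    alpha: float = 0.01,
    **lopo_kwargs,
) -> PredictionReport:
    """Full LOPO run with the edge universe restricted to the given network
    pairs before selection."""
    subset = edges_for_pairs(assignment, pairs)
    if subset.size == 0:
        raise ConfigurationError(f"pair filter {pairs} selects no edges")
    return lopo_cross_validate(cohort, alpha=alpha, edge_subset=subset, **lopo_kwargs)


def lesion_cpm(
    cohort: TrialCohort,
    pairs: list[tuple[str, str]],
    assignment: NetworkAssignment,
    alpha: float = 0.01,
    **lopo_kwargs,
) -> PredictionReport:
    """Full LOPO run with the given network pairs' edges deleted from
    training and testing data (virtual lesion)."""
    removed = edges_for_pairs(assignment, pairs)
    subset = np.setdiff1d(np.arange(n_edges(cohort.n_nodes)), removed)
    if subset.size == 0:
        raise ConfigurationError("lesion removes every edge")
    return lopo_cross_validate(cohort, alpha=alpha, edge_subset=subset, **lopo_kwargs)


def univariate_pair_association(
    cohort: TrialCohort, assignment: NetworkAssignment
) -> pd.DataFrame:
    """Trial-wise correlation of mean pair FC with normalized ratings, per
    participant, with a group-level signed-rank test per pair and BH-FDR
    across pairs. Empty pair bins are reported as missing rows and excluded
    from the FDR set.
    """
    if cohort.meta["rating_z"].isna().any():
        cohort, _ = cohort.with_rating_z()
    keys = assignment.edge_pair_labels()
    y = cohort.meta["rating_z"].to_numpy()
    rows = []
    for a, b in assignment.pair_bins():
        key = _pair_key(a, b)
        edges = np.flatnonzero(keys == key)
        row = {"network_pair": key, "n_edges": int(edges.size)}
        if edges.size == 0:
            row.update(mean_r=np.nan, p=np.nan)
            rows.append(row)
            continue
        pair_fc = cohort.edges[:, edges].mean(axis=1)
        rs = []
        for part in cohort.participants:
            sel = cohort.participant_rows(part)
            if sel.size >= 4 and np.std(pair_fc[sel]) > 0:
                rs.append(np.corrcoef(pair_fc[sel], y[sel])[0, 1])
        rs = np.asarray(rs, float)
        row["mean_r"] = float(np.mean(rs)) if rs.size else np.nan
        if rs.size >= 5 and not np.all(rs == 0):
            row["p"] = float(stats.wilcoxon(rs, alternative="two-sided", method="auto").pvalue)
        else:
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_fdr"] = np.nan
    if tested.any():
        out.loc[tested, "p_fdr"] = stats.false_discovery_control(
            out.loc[tested, "p"].to_numpy(), method="bh"
        )
    return out
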