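"""Synthetic cohorts with known edge-rating coupling.

Every downstream stage of the pipeline is exercised against data whose
ground truth is planted here: a latent per-trial state ``s`` drives both the
reported rating (an affine map of s onto the 0-100 probe scale plus noise)
and a chosen subset of edges (z_e = b_e + w_e * s + eps, with w_e = +effect
on planted positive edges, -effect on planted negative edges, 0 elsewhere).

The defaults mirror the study design this pipeline targets: 17 participants
with 36 probes each, 268-node parcellation, 28-frame pre-probe windows,
ratings on a 0-100 scale, and planted mask fractions giving a few hundred
informative edges. Direct-edge generation is the default; the time-series
mode exists to exercise the window-extraction path and plants shared
signals in node pairs whose amplitude tracks the latent state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import META_COLUMNS, SyntheticCohort
from .errors import ConfigurationError
from .features import ParcellatedRun, n_edges
from .model import CpmModel, EdgeMask, network_strength, zscore_within_participant

#: Edge baselines b_e are drawn once per cohort from N(0.3, 0.25) Fisher-z
#: units: a positive-skewed connectivity background typical of denoised data.
BASELINE_MEAN = 0.3
BASELINE_SD = 0.25


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for one synthetic cohort.

    ``effect`` is the dimensionless coupling weight w applied to the latent
    state on planted edges; ``group_state_shift`` moves the latent-state mean
    (modeling a cohort with elevated off-task thought as a mean shift only,
    not a different coupling).
    """

    n_participants: int = 17
    n_trials_per_participant: int = 36
    n_nodes: int = 268
    n_frames_per_window: int = 28
    frac_pos_informative: float = 0.007
    frac_neg_informative: float = 0.004
    effect: float = 0.05
    edge_noise_sd: float = 1.0
    rating_noise_sd: float = 10.0
    rating_scale: tuple[float, float] = (0.0, 100.0)
    group_state_shift: float = 0.0
    group_label: str = "healthy"
    seed: int = 0
    # Explicit planted sets override the random draw (used to confine the
    # signal to chosen network pairs in anatomy experiments).
    planted_pos_edges: tuple[int, ...] | None = None
    planted_neg_edges: tuple[int, ...] | None = None

    def validate(self) -> None:
        for name in ("n_participants", "n_trials_per_participant", "n_nodes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_nodes < 2:
            raise ConfigurationError("n_nodes must be >= 2 to define edges")
        if self.n_frames_per_window < 3:
            raise ConfigurationError("n_frames_per_window must be >= 3 (Pearson r needs >= 3 samples)")
        if self.frac_pos_informative < 0 or self.frac_neg_informative < 0:
            raise ConfigurationError("informative edge fractions must be non-negative")
        if self.frac_pos_informative + self.frac_neg_informative >= 1:
            raise ConfigurationError("frac_pos_informative + frac_neg_informative must be < 1")
        if self.edge_noise_sd < 0 or self.rating_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        if not self.rating_scale[0] < self.rating_scale[1]:
            raise ConfigurationError("rating_scale must be an increasing (min, max) pair")
        if self.planted_pos_edges is not None and self.planted_neg_edges is not None:
            if set(self.planted_pos_edges) & set(self.planted_neg_edges):
                raise ConfigurationError("planted positive and negative edge sets must be disjoint")


def _rating_from_state(s: np.ndarray, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Affine map of s in [-3, 3] onto the rating scale, plus noise, clipped,
    rounded to the integer grid the probe records."""
    lo, hi = config.rating_scale
    raw = lo + (np.clip(s, -3.0, 3.0) + 3.0) / 6.0 * (hi - lo)
    raw = raw + rng.normal(0.0, config.rating_noise_sd, size=s.shape)
    return np.round(np.clip(raw, lo, hi))


def _planted_sets(config: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    m = n_edges(config.n_nodes)
    if config.planted_pos_edges is not None or config.planted_neg_edges is not None:
        pos = np.asarray(sorted(config.planted_pos_edges or ()), dtype=int)
        neg = np.asarray(sorted(config.planted_neg_edges or ()), dtype=int)
        if (pos.size and pos.max() >= m) or (neg.size and neg.max() >= m):
            raise ConfigurationError(f"planted edge index out of range for {config.n_nodes} nodes")
        return pos, neg
    k_pos = int(round(config.frac_pos_informative * m))
    k_neg = int(round(config.frac_neg_informative * m))
    chosen = rng.choice(m, size=k_pos + k_neg, replace=False)
    return np.sort(chosen[:k_pos]), np.sort(chosen[k_pos:])


def generate_trial_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of trial-locked edge vectors with planted coupling.

    Deterministic under a fixed config (including its seed): identical
    configs produce bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = n_edges(config.n_nodes)
    pos, neg = _planted_sets(config, rng)

    w = np.zeros(m)
    w[pos] = config.effect
    w[neg] = -config.effect
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=m)

    n_total = config.n_participants * config.n_trials_per_participant
    s = rng.normal(0.0, 1.0, size=n_total) + config.group_state_shift
    rating_raw = _rating_from_state(s, config, rng)
    edges = baselines[None, :] + np.outer(s, w) + rng.normal(0.0, config.edge_noise_sd, size=(n_total, m))

    participants = np.repeat(
        [f"sub-{i + 1:03d}" for i in range(config.n_participants)], config.n_trials_per_participant
    )
    trial_index = np.tile(np.arange(config.n_trials_per_participant), config.n_participants)
    fd_mean = np.abs(rng.normal(0.08, 0.03, size=n_total))
    # RT variability rises with off-task state, as observed behaviorally.
    rt_var = 0.3 * s + rng.normal(0.0, 0.5, size=n_total)

    rating_z, _ = zscore_within_participant(rating_raw, participants)
    meta = pd.DataFrame(
        {
            "participant": participants,
            "trial_index": trial_index,
            "rating_raw": rating_raw,
            "rating_z": rating_z,
            "fd_mean": fd_mean,
            "rt_variability": rt_var,
            "group": config.group_label,
        },
        columns=META_COLUMNS,
    )
    return SyntheticCohort(
        edges=edges,
        meta=meta,
        n_nodes=config.n_nodes,
        atlas="synthetic",
        truth_pos_edges=pos,
        truth_neg_edges=neg,
        latent_states=s,
    )


def planted_node_pairs(config: CohortConfig) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Node pairs that carry shared signal in time-series mode.

    Pairs use disjoint nodes (consecutive node indices) so each planted
    correlation is controlled independently of the others.
    """
    k_pos = int(round(config.frac_pos_informative * config.n_nodes / 2))
    k_neg = int(round(config.frac_neg_informative * config.n_nodes / 2))
    if 2 * (k_pos + k_neg) > config.n_nodes:
        raise ConfigurationError("too many planted node pairs for the node count")
    nodes = iter(range(config.n_nodes))
    pos = [(next(nodes), next(nodes)) for _ in range(k_pos)]
    neg = [(next(nodes), next(nodes)) for _ in range(k_neg)]
    return pos, neg


def generate_timeseries_run(
    config: CohortConfig,
    participant: int = 0,
    inter_probe_frames: int | None = None,
) -> tuple[ParcellatedRun, pd.DataFrame]:
    """One participant's node x frame series plus its probe table.

    Within each pre-probe window, planted node pairs share a common signal
    whose amplitude exp(effect * s) tracks the trial's latent state, so the
    windowed Fisher-z of a planted pair correlates with the state in the
    planted direction. Probe onsets are spaced so every window has the full
    ``n_frames_per_window`` preceding frames.
    """
    config.validate()
    win = config.n_frames_per_window
    if inter_probe_frames is None:
        inter_probe_frames = win + 4
    if inter_probe_frames < win:
        raise ConfigurationError(
            f"inter_probe_frames ({inter_probe_frames}) shorter than the window ({win})"
        )
    rng = np.random.default_rng([config.seed, 7919, participant])
    pos_pairs, neg_pairs = planted_node_pairs(config)

    n_trials = config.n_trials_per_participant
    onsets = inter_probe_frames * np.arange(1, n_trials + 1)
    n_frames = int(onsets[-1]) + 4
    s = rng.normal(0.0, 1.0, size=n_trials) + config.group_state_shift
    rating_raw = _rating_from_state(s, config, rng)

    series = rng.normal(0.0, 1.0, size=(config.n_nodes, n_frames))
    for t, onset in enumerate(onsets):
        sl = slice(onset - win, onset)
        amp = float(np.exp(config.effect * s[t]))
        for i, j in pos_pairs:
            shared = rng.normal(0.0, 1.0, size=win)
            series[i, sl] += amp * shared
            series[j, sl] += amp * shared
        for i, j in neg_pairs:
            shared = rng.normal(0.0, 1.0, size=win)
            series[i, sl] += amp * shared
            series[j, sl] -= amp * shared

    fd = np.abs(rng.normal(0.08, 0.03, size=n_frames))
    run = ParcellatedRun(
        series=series,
        tr_seconds=1.08,
        framewise_displacement=fd,
        run_id=f"sub-{participant + 1:03d}_run-01",
    )
    probes = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "onset_frame": onsets,
            "rating": rating_raw,
            "latent_state": s,
        }
    )
    return run, probes


@dataclass
class RestCohort:
    """Per-participant whole-run edge vectors with a coupled trait score."""

    edge_vectors: np.ndarray  # (n_participants, n_edges)
    traits: np.ndarray
    n_nodes: int
    participants: list[str] = field(default_factory=list)
    strengths: np.ndarray = field(default_factory=lambda: np.array([]))


def generate_rest_cohort(
    n_participants: int,
    coupling: float,
    seed: int,
    mask: EdgeMask | CpmModel,
    edge_noise_sd: float = 0.3,
    trait_noise_sd: float = 0.0,
) -> RestCohort:
    """Resting-state cohort whose trait score tracks network strength.

    trait = coupling * S + noise, where S is the strength of the supplied
    mask (or a frozen model's mask) on that participant's whole-run edge
    vector — so rank-correlation recovery of the coupling is testable.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if edge_noise_sd < 0 or trait_noise_sd < 0:
        raise ConfigurationError("noise standard deviations must be non-negative")
    emask = mask.mask if isinstance(mask, CpmModel) else mask
    rng = np.random.default_rng(seed)
    m = n_edges(emask.n_nodes)
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=m)
    vectors = baselines[None, :] + rng.normal(0.0, edge_noise_sd, size=(n_participants, m))
    strengths = network_strength(vectors, emask)
    traits = coupling * strengths + rng.normal(0.0, trait_noise_sd, size=n_participants)
    return RestCohort(
        edge_vectors=vectors,
        traits=np.asarray(traits),
        n_nodes=emask.n_nodes,
        participants=[f"sub-{i + 1:03d}" for i in range(n_participants)],
        strengths=np.asarray(strengths),
    )


def shifted_config(config: CohortConfig, shift: float, seed: int, label: str = "shifted") -> CohortConfig:
    """A copy of a config with a latent-state mean shift (clinical analogue)."""
    return replace(config, group_state_shift=shift, seed=seed, group_label=label)
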