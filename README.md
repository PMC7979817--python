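# trialcpm

Trial-wise connectome-based predictive modeling (CPM) of
stimulus-independent, task-unrelated thought (SITUT) — the "mind
wandering" facet rated 0–100 at in-task thought probes — from windowed
functional connectivity.

The package is for researchers who have parcellated, denoised BOLD time
series with trial-locked experience-sampling ratings (or resting-state
runs with trait questionnaires) and want a tested, reproducible pipeline
from node × frame tables to cross-validated predictions, permutation-based
significance, confound controls, external-cohort application, and
network-anatomical decomposition. A synthetic-data generator with planted
ground truth stands in for restricted human data, so every stage is
testable end to end.

## The model

For each thought probe, connectivity is the Fisher-z Pearson correlation
of every unique node pair over the 28 frames (~30 s) preceding probe
onset. Within each leave-one-participant-out (LOPO) fold:

- edges whose trial-wise correlation with within-participant z-scored
  ratings passes *P* < 0.01 (two-tailed, exact t-transform) form positive
  and negative masks;
- each trial's network strength is
  *S* = Σ<sub>pos</sub> z<sub>e</sub> − Σ<sub>neg</sub> z<sub>e</sub>;
- a linear model *rating* = *β·S* + *c* is fit on the pooled training
  trials and applied to the held-out participant;
- the observed predicted-vs-observed Pearson *r* is compared with a null
  distribution from re-running the entire training under shuffled rating
  assignments, and group significance is a Wilcoxon signed-rank of
  observed *r* against the per-participant mean null *r*.

Frozen models (no reselection, no refit) transfer to external cohorts and
resting-state data; masks decompose into canonical network-pair bins with
hypergeometric overlap tests; restricted ("these pairs only") and
virtually lesioned ("these pairs deleted") variants probe sufficiency and
necessity of a network pair. See `docs/methods.md` for assumptions,
numerical choices, and known limitations.

## Worked example

```sh
python examples/simulate_and_validate.py
```

builds a 10-participant × 30-trial cohort (40 nodes) in which a latent
per-trial state with planted per-edge correlation ≈ 0.4 drives both the
ratings and 78 positive / 78 negative edges, then cross-validates:

```
cohort: 300 trials, 780 edges, 78+/78- planted edges
participant  r_observed      mse  null_mean  mask_pos  mask_neg
    sub-001    0.939488 0.177617  -0.026666        80        79
    sub-002    0.932102 0.182963   0.003582        80        79
    ...
held-out r = 0.932 +/- 0.016 (mean +/- SD across 10 held-out participants)
group p (signed-rank, observed vs null mean) = 0.002
cross-fold mask overlap with the full-data mask: 98.3% (positive), 98.7% (negative)
```

Each `r_observed` is the correlation between predicted and observed
normalized ratings over one held-out participant's 30 trials; `null_mean`
is the same quantity after full re-training on permuted ratings (here
≈ 0, as it should be); `mask_pos`/`mask_neg` are per-fold mask sizes
(close to the 78 planted edges per sign plus the ~1% selection noise
floor). The other scripts in `examples/` each demonstrate one capability:
external frozen-model application with a state-shifted (clinical
analogue) cohort, network-pair anatomy with restriction/lesioning, trait
prediction from resting data with run-wise strength trends, and raw
time-series window extraction.

A thin CLI mirrors the pipeline stages:

```sh
trialcpm simulate --config cohort.yaml --seed 7 --out cohort/
trialcpm train    --cohort cohort/ --out model/
trialcpm validate --cohort cohort/ --n-perm 1000 --seed 1 --out report/
trialcpm apply    --model model/ --cohort external/ --out external_report/
trialcpm anatomy  --model model/ --assignment labels.tsv --out anatomy/
```

Every command writes a manifest (arguments, config hash, seed, version)
beside its outputs; all formats are plain text (TSV tables, edge-list
masks, YAML/JSON metadata) and round-trip losslessly.

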