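# Methods

## The model

`trialcpm` implements trial-wise connectome-based predictive modeling (CPM)
of stimulus-independent, task-unrelated thought (SITUT) — the "mind
wandering" facet rated 0–100 at in-task thought probes. The unit of
analysis is the trial: for each probe, functional connectivity is computed
over a fixed-length window of parcellated BOLD frames preceding probe onset
(default 28 frames, ~30 s at a ~1 s TR), as the Fisher-z transformed
Pearson correlation of every unique node pair.

The predictive kernel is deliberately simple:

1. **Normalization.** Ratings are z-scored *within participant* (sample
   SD). A participant with zero rating variance is excluded, never
   normalized. Because normalization never crosses participants, training
   and held-out data share no statistics.
2. **Edge selection.** For each edge, the Pearson correlation across the
   pooled training trials with the normalized rating is converted to a
   two-tailed p-value through the exact t-transform
   t = r·√((n−2)/(1−r²)), df = n−2. Edges with p strictly below α
   (default 0.01) are split by the sign of r into positive and negative
   masks.
3. **Network strength.** Each trial's summary score is
   S = Σ_{e∈pos} z_e − Σ_{e∈neg} z_e over the *unique* edges (upper
   triangle, counted once). Externally published masks expressed over full
   symmetric matrices must be converted on import.
4. **Linear model.** Ordinary least squares of the normalized rating on
   the single predictor S: rating = β·S + c.

Cross-validation is leave-one-participant-out (LOPO): all of a
participant's trials are held out together; selection and fit use only the
pooled training trials. Per held-out participant the report carries the
Pearson r between predicted and observed normalized ratings, the MSE on
the normalized scale (consistent with the training target), and optional
partial correlations (residualizing both predicted and observed on named
covariates such as window-mean frame-wise displacement or RT variability).

## Permutation null and group inference

Each fold's null re-runs the *entire* training procedure — selection and
fit — under shuffles of the training ratings across the pooled training
trials (default 1000 permutations; tests use 100–200), then scores the
unchanged held-out participant. The implementation vectorizes all
permutations of a fold into matrix operations; a test verifies it is
numerically identical to literally re-training per permutation.
Permutations whose mask comes up empty yield an undefined null draw and
are dropped from the null mean (logged). Group-level significance is a
two-sided Wilcoxon signed-rank of the per-participant observed r against
the per-participant mean null r (exact tail for small untied samples,
normal approximation with tie handling otherwise).

Frozen-model application (`apply_model_external`) never reselects or
refits; its null shuffles rating–trial assignments across the whole
external cohort while the frozen predictions stay fixed. Trait prediction
on resting data computes β·S + c per participant on whole-run (or
mean-across-runs) connectivity and uses Spearman rank correlation
(average-rank ties); partial Spearman is partial Pearson on ranks with
df = n − 2 − k. Group strength contrasts use the two-sided Wilcoxon
rank-sum with tie correction. Run-wise strength trends test every run pair
with a signed-rank on pairwise-complete participants (runs are paired
within participants, so the paired test is the appropriate one even where
rank-sum language is sometimes used for this analysis) and adjust with
Benjamini–Hochberg across the tested pairs; pairs with fewer than three
complete participants are skipped with a warning.

## Network anatomy

Nodes carry canonical network labels (e.g., the 7- or 17-way Yeo-Krienen
taxonomy; for 17-network Schaefer labels, note that the FPCN_A/FPCN_B
subnetwork names are conventionally swapped relative to the distributed
files so that FPCN_A denotes the rostrolateral-prefrontal subsystem — the
package consumes whatever label file it is given). Every edge belongs to
one unordered within- or between-network pair bin; K labels give
K(K+1)/2 bins (28 for 7 networks). Provided operations: mask-edge counts
per bin (conserving mask size); mean pair connectivity for the low- and
high-rating trial halves of a within-participant median split (trials at
the median fall in the low half, so odd counts make the low half larger by
one — any fixed deterministic rule is acceptable, this one is documented);
hypergeometric mask-overlap significance using the strict tail
P(X > x) = 1 − hygecdf(x, M, K, n) (the inclusive enrichment-style
P(X ≥ x) is available behind the `inclusive` flag, default strict);
pair-restricted and virtually lesioned CPM variants, which restrict or
delete an edge set from the universe *before* selection and then run the
identical LOPO pipeline (restrict(F) and lesion(¬F) provably share the
same universe); and a univariate per-pair analysis correlating mean pair
connectivity with ratings per participant, with a group signed-rank per
pair and BH-FDR across the 28 bins. The univariate group test is a
nonparametric stand-in for a mixed-effects formulation; we keep the module
self-contained and distribution-free.

## The synthetic generator

The generator provides recoverable ground truth for every downstream
stage. A latent per-trial state s ~ N(group_shift, 1) drives both the
rating — an affine map of s∈[−3,3] onto the 0–100 probe scale plus
Gaussian noise, clipped and rounded to the integer grid — and a planted
edge subset: z_e = b_e + w_e·s + ε with w_e = +effect on planted positive
edges, −effect on planted negative edges, 0 elsewhere, ε ~ N(0,
edge_noise_sd). Baselines b_e ~ N(0.3, 0.25) Fisher-z units are drawn once
per cohort (a positive-skewed connectivity background; configurable). The
planted per-edge correlation with the state is therefore
effect/√(effect² + edge_noise_sd²) in closed form, which the tests verify
by brute-force sampling. A group-state shift models a clinical analogue as
a mean shift of the latent state only (higher ratings and higher strength,
unchanged coupling). Generation is bit-reproducible under a fixed config.

Defaults mirror the targeted study design: 17 participants × 36 probes,
268 nodes, 28-frame windows, planted fractions 0.007/0.004 (≈250/≈140
informative edges at 268 nodes), effect 0.05 with unit edge noise and
rating noise SD 10 — weak per-edge coupling chosen so that held-out
prediction lands at the r ~ 0.1 order of magnitude typical of trial-wise
self-report prediction, rather than at an unrealistically clean value.
Tests and the acceptance script use smaller cohorts (10–11 participants ×
30 trials, 20–40 nodes) with a stronger planted correlation (~0.4) where
the point is signal recovery, and effect 0 where the point is null
calibration; these problem sizes are the package's chosen desk scale.

Direct-edge generation is the default: it gives exact control of the
planted coupling and separates model tests from feature-extraction tests.
The time-series mode exists to exercise window extraction: planted node
pairs (disjoint consecutive nodes) share a per-window signal whose
amplitude exp(effect·s) tracks the trial state, so windowed Fisher-z on a
planted pair follows the state in the planted direction. The resting-state
generator couples a trait score to the network strength of a supplied mask
(trait = coupling·S + noise), making rank-correlation recovery testable.

What the generator does *not* emulate: hemodynamics, spatial structure,
autocorrelated noise (white noise within window suffices for the
contracts tested), heavy-tailed motion artifacts, or realistic rating
response styles. Passing tests therefore demonstrate the correctness and
statistical behavior of the pipeline, not the effect sizes to be expected
on real fMRI data.

## Numerical choices and degenerate inputs

- Pearson correlations are clipped to |r| ≤ 1 − 1e−7 before `arctanh`, so
  degenerate perfect correlations stay finite while ordering is preserved.
- Window convention is 0-based and half-open: frames
  [onset − window, onset); the probe-onset frame itself is excluded, and
  the window-mean FD covers exactly those frames.
- Zero-variance nodes flag their edges as missing (NaN) with a warning
  rather than erroring at cohort level; edges missing in any trial are
  excluded from the cross-validation candidate universe (logged), while
  direct `network_strength` calls on a missing masked edge raise.
- Ties at p = α are excluded (strict inequality), matching the stated
  threshold "< α".
- Empty-mask folds are recorded as degenerate and excluded from the group
  test with a warning (a correlation with a constant prediction is
  undefined); they are never scored as zero.
- Edge order is canonical row-major upper triangle
  (`numpy.triu_indices(n, 1)`), with a closed-form index↔pair bijection.
- Exact signed-rank/rank-sum distributions are used for small untied
  samples and the normal approximation with tie/zero corrections beyond,
  matching the group sizes this design produces (≈17–20).
- Events-table onset units are declared (seconds or frames, 0- or
  1-based), never guessed; mismatched declarations raise.
- Exclusion rules: participants with mean overall FD > 0.15 mm; runs whose
  FD exceeds Q3 + 1.5·IQR of the participant's runs (when several runs
  exist); participants with zero rating variance. Every exclusion is
  logged with its reason.

## Known limitations

- **Group-test calibration.** The per-edge selection rate is calibrated
  (≈1% of edges at α = 0.01 under the null — measured by the acceptance
  suite) and, within a fold, the observed held-out r is exchangeable with
  its permutation null (a KS check on null-quantiles passes at desk
  scale). However, the group-level signed-rank of observed r against mean
  null r is anti-conservative under a global null at desk scale: the
  acceptance suite measures a ~0.2–0.35 rejection rate at nominal 0.05
  (100 null cohorts of 10 × 30 trials). The cause is intrinsic to the
  procedure, and reproduces in an independent from-scratch simulation:
  LOPO fold masks are selected on overlapping training sets, so each
  fold's mask and β sign align with the *other* participants' spurious
  edge–rating alignments, making held-out correlations positively
  dependent across folds (the variance of the cohort-mean r is ~3× the
  independence prediction). The per-fold permutation null keeps held-out
  data fixed and cannot express this cross-fold dependence, and the
  signed-rank then treats folds as independent. Users should treat the
  group p-value as a descriptive summary rather than a calibrated
  error rate; per-fold null quantiles are calibrated and are exposed via
  the stored null distributions.
- MSE is reported on the normalized rating scale; Pearson r is invariant
  to the within-participant affine normalization, MSE is not.
- The RT-variability covariate is consumed as a supplied column; its
  construction from task behavior is upstream of this package, as is all
  voxel-level preprocessing, nuisance regression, and atlas parcellation.
- Cross-fold mask overlap is reported as the mean over folds of
  |fold ∩ full-data mask| / |fold mask| per sign; the denominator is a
  package choice since "overlap" admits several normalizations.
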