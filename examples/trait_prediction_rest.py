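"""Apply a frozen CPM to resting-state data: trait scores and run dynamics.

A resting cohort is generated whose trait questionnaire score is coupled
to the model's network strength on whole-run connectivity; the frozen
model's predictions are then rank-correlated with the trait, with and
without covariate control. A second block synthesizes per-run strengths
that drift upward and tests every run pair with signed-rank + BH-FDR.
"""

import numpy as np
import pandas as pd

from trialcpm import (
    CohortConfig,
    generate_rest_cohort,
    generate_trial_cohort,
    runwise_strength_trend,
    train_full_model,
    trait_prediction,
)

training = generate_trial_cohort(CohortConfig(
    n_participants=10, n_trials_per_participant=30, n_nodes=40,
    frac_pos_informative=0.1, frac_neg_informative=0.1,
    effect=0.436, rating_noise_sd=5.0, seed=11))
model = train_full_model(training, alpha=0.01)

rest = generate_rest_cohort(n_participants=80, coupling=1.0, seed=3, mask=model,
                            edge_noise_sd=0.3, trait_noise_sd=2.0)
rng = np.random.default_rng(3)
covariates = {"fd": rng.normal(0.08, 0.02, size=80), "age": rng.integers(20, 40, size=80)}
report = trait_prediction(model, rest.edge_vectors, rest.traits, covariates=covariates)
print(f"trait prediction over {report.n} participants: Spearman rho = {report.rho:.3f} "
      f"(p = {report.p:.2g})")
for name, (rho, p) in report.partial.items():
    print(f"  partial rho controlling for {name}: {rho:.3f} (p = {p:.2g})")
print("rho is the rank correlation between model-predicted and observed trait scores.")

# per-run strength dynamics: strengths drift upward after run 1
n, runs = 40, 4
drift = np.array([0.0, 1.0, 1.4, 1.5])
strengths = pd.DataFrame(
    rng.normal(size=(n, runs)) + drift, columns=[f"run{r + 1}" for r in range(runs)])
trend = runwise_strength_trend(strengths)
print("\npairwise run comparisons (Wilcoxon signed-rank, BH-FDR over the 6 pairs):")
print(trend.to_string(index=False))
print("Adjusted p < 0.05 marks run pairs whose strengths reliably differ; here "
      "the drift after run 1 is detected while runs 2-4 plateau.")
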