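"""Cross-validation, permutation nulls, and group-level inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialcpm import (
    AtlasMismatchError,
    CohortConfig,
    CollinearityError,
    apply_model_external,
    fit_strength_model,
    generate_trial_cohort,
    group_prediction_test,
    group_strength_comparison,
    lopo_cross_validate,
    network_strength,
    partial_prediction_correlation,
    predict,
    runwise_strength_trend,
    select_edges,
    train_full_model,
    trait_prediction,
)
from trialcpm.validation import _permutation_null_fold
from _oracles import (
    bh_adjust_loop,
    partial_corr_formula,
    pearson_loop,
    ranksum_exact,
    signed_rank_exact,
    spearman_loop,
)


class TestLopo:
    def test_fold_bookkeeping(self, strong_cohort):
        rep = lopo_cross_validate(strong_cohort, seed=0, n_perm=20)
        per = rep.per_participant
        assert len(per) == 8
        assert (per["n_training_trials"] == 7 * 30).all()
        assert (per["n_trials"] == 30).all()

    def test_strong_signal_high_r_significant(self, strong_cohort):
        rep = lopo_cross_validate(strong_cohort, seed=0, n_perm=100)
        assert (rep.per_participant["r_observed"] > 0.8).all()
        assert rep.group_p < 0.05

    def test_train_test_independence(self, strong_cohort):
        """Perturbing a held-out trial's rating never changes that fold's model."""
        rep1 = lopo_cross_validate(strong_cohort, seed=0, n_perm=5)
        cohort2 = strong_cohort.subset(np.arange(strong_cohort.n_trials))
        held = cohort2.participant_rows("sub-001")
        cohort2.meta.loc[held[0], "rating_raw"] = 100 - cohort2.meta.loc[held[0], "rating_raw"]
        cohort2.meta["rating_z"] = np.nan
        rep2 = lopo_cross_validate(cohort2, seed=0, n_perm=5)
        m1, m2 = rep1.fold_models["sub-001"], rep2.fold_models["sub-001"]
        np.testing.assert_array_equal(m1.mask.positive, m2.mask.positive)
        np.testing.assert_array_equal(m1.mask.negative, m2.mask.negative)
        assert m1.beta == m2.beta and m1.intercept == m2.intercept

    def test_permutation_determinism(self, strong_cohort):
        r1 = lopo_cross_validate(strong_cohort, seed=5, n_perm=30)
        r2 = lopo_cross_validate(strong_cohort, seed=5, n_perm=30)
        for p in r1.null_distributions:
            np.testing.assert_array_equal(r1.null_distributions[p], r2.null_distributions[p])

    def test_mask_overlap_reported(self, strong_cohort):
        rep = lopo_cross_validate(strong_cohort, seed=0, n_perm=5)
        assert 0 <= rep.mask_overlap_pct["positive"] <= 100
        assert 0 <= rep.mask_overlap_pct["negative"] <= 100


class TestPermutationEngine:
    def test_vectorized_engine_matches_naive_retraining(self, rng):
        """The vectorized null equals literally re-running selection + fit +
        prediction under each permutation."""
        n_tr, n_te, nn = 40, 12, 8
        m = nn * (nn - 1) // 2
        E_tr = rng.normal(size=(n_tr, m))
        y_tr = rng.normal(size=n_tr)
        E_tr[:, 5] += 0.8 * y_tr  # one informative edge so masks are non-trivial
        E_te = rng.normal(size=(n_te, m))
        y_te = rng.normal(size=n_te)
        alpha, n_perm, seed = 0.1, 25, 77

        fast = _permutation_null_fold(E_tr, y_tr, E_te, y_te, alpha, n_perm,
                                      np.random.default_rng(seed), np.ones(m, bool))
        # replay the same permutations through the modular path
        perm_idx = np.argsort(np.random.default_rng(seed).random((n_perm, n_tr)), axis=1)
        for k in range(n_perm):
            y_perm = y_tr[perm_idx[k]]
            mask = select_edges(E_tr, y_perm, nn, alpha)
            if mask.size == 0:
                assert np.isnan(fast[k])
                continue
            s_tr = network_strength(E_tr, mask)
            beta, c = fit_strength_model(s_tr, y_perm)
            pred = beta * network_strength(E_te, mask) + c
            expected = pearson_loop(list(pred), list(y_te))
            assert fast[k] == pytest.approx(expected, abs=1e-10)


class TestGroupPredictionTest:
    def test_identical_pairs_p_one(self):
        x = np.linspace(0, 1, 8)
        assert group_prediction_test(x, x) == 1.0

    def test_all_greater_n17_exact(self):
        """All 17 observed above null: two-sided exact p = 2 / 2^17."""
        obs = np.linspace(0.1, 0.9, 17)
        nul = obs - np.linspace(0.01, 0.2, 17)
        assert group_prediction_test(obs, nul) == pytest.approx(2 / 2**17, rel=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        """Exact signed-rank tail vs brute enumeration of sign assignments."""
        for _ in range(100):
            n = int(rng.integers(6, 11))
            d = rng.normal(size=n)
            while len(set(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(size=n)
            obs = rng.normal(size=n)
            p = group_prediction_test(obs, obs - d)
            assert p == pytest.approx(signed_rank_exact(list(d)), abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            group_prediction_test(np.ones(3), np.zeros(3))


class TestPartialCorrelation:
    def test_orthogonal_covariate_no_change(self, rng):
        n = 200
        x, y = rng.normal(size=n), rng.normal(size=n)
        y += 0.5 * x
        # residualizing on a covariate independent of both barely moves r
        z = rng.normal(size=n)
        plain = np.corrcoef(x, y)[0, 1]
        part = partial_prediction_correlation(x, y, z)
        assert part == pytest.approx(plain, abs=0.05)

    def test_observed_equals_covariate(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert partial_prediction_correlation(x, y, y) == pytest.approx(0.0, abs=1e-10)

    def test_matches_recursive_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.3 * z + rng.normal(size=n)
            got = partial_prediction_correlation(x, y, z)
            want = partial_corr_formula(list(x), list(y), list(z))
            assert got == pytest.approx(want, abs=1e-10)

    def test_collinear_covariates_rejected(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(CollinearityError):
            partial_prediction_correlation(x, y, np.column_stack([z, 2 * z]))


class TestExternalApplication:
    def test_training_cohort_consistency(self, strong_cohort):
        """Applied to its own training cohort, the frozen model reproduces the
        in-sample fitted correlations."""
        model = train_full_model(strong_cohort)
        rep = apply_model_external(model, strong_cohort, n_perm=10, seed=0)
        for part in strong_cohort.participants:
            rows = strong_cohort.participant_rows(part)
            pred = predict(model, strong_cohort.edges[rows])
            expected = np.corrcoef(pred, strong_cohort.meta["rating_z"].to_numpy()[rows])[0, 1]
            got = rep.per_participant.set_index("participant").loc[part, "r_observed"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_same_planted_masks_generalize(self, strong_cohort):
        model = train_full_model(strong_cohort)
        cfg = CohortConfig(n_participants=6, n_trials_per_participant=30, n_nodes=30,
                           frac_pos_informative=0.1, frac_neg_informative=0.1,
                           effect=0.436, rating_noise_sd=0.0, seed=555,
                           planted_pos_edges=tuple(strong_cohort.truth_pos_edges),
                           planted_neg_edges=tuple(strong_cohort.truth_neg_edges))
        external = generate_trial_cohort(cfg)
        rep = apply_model_external(model, external, n_perm=100, seed=1)
        assert rep.summary["mean_r"] > 0.5
        assert rep.group_p < 0.05

    def test_zero_coupling_external_null(self, strong_cohort, null_cohort):
        model = train_full_model(strong_cohort)
        cfg = CohortConfig(n_participants=6, n_trials_per_participant=30, n_nodes=30,
                           effect=0.0, rating_noise_sd=15.0, seed=321)
        rep = apply_model_external(model, generate_trial_cohort(cfg), n_perm=100, seed=2)
        assert abs(rep.summary["mean_r"]) < 0.25

    def test_atlas_mismatch_hard_error(self, strong_cohort, null_cohort):
        model = train_full_model(strong_cohort)  # 30 nodes
        with pytest.raises(AtlasMismatchError):
            apply_model_external(model, null_cohort)  # 20 nodes


class TestTraitPrediction:
    def test_monotone_trait_rho_one(self, strong_cohort, rng):
        model = train_full_model(strong_cohort)
        vectors = rng.normal(0.3, 0.3, size=(12, strong_cohort.edges.shape[1]))
        s = network_strength(vectors, model.mask)
        trait = np.exp(s / max(1.0, np.abs(s).max()))  # strictly increasing in S
        rep = trait_prediction(model, vectors, trait)
        assert rep.rho * np.sign(model.beta) == pytest.approx(1.0)

    def test_tied_ranks_match_rank_pearson_oracle(self, strong_cohort, rng):
        model = train_full_model(strong_cohort)
        vectors = rng.normal(0.3, 0.3, size=(15, strong_cohort.edges.shape[1]))
        trait = rng.integers(1, 5, size=15).astype(float)  # heavy ties
        rep = trait_prediction(model, vectors, trait)
        pred = np.asarray(predict(model, vectors))
        assert rep.rho == pytest.approx(spearman_loop(list(pred), list(trait)), abs=1e-10)

    def test_partial_spearman_reported(self, strong_cohort, rng):
        model = train_full_model(strong_cohort)
        vectors = rng.normal(0.3, 0.3, size=(20, strong_cohort.edges.shape[1]))
        trait = rng.normal(size=20)
        rep = trait_prediction(model, vectors, trait, covariates={"fd": rng.normal(size=20)})
        rho, p = rep.partial["fd"]
        assert -1 <= rho <= 1 and 0 <= p <= 1

    def test_constant_trait_undefined(self, strong_cohort, rng):
        model = train_full_model(strong_cohort)
        vectors = rng.normal(0.3, 0.3, size=(8, strong_cohort.edges.shape[1]))
        with pytest.warns(RuntimeWarning, match="constant trait"):
            rep = trait_prediction(model, vectors, np.full(8, 3.0))
        assert np.isnan(rep.rho)


class TestGroupStrengthComparison:
    def test_identical_groups_p_one(self):
        res = group_strength_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] == pytest.approx(1.0)

    def test_separated_3v3_exact(self):
        res = group_strength_comparison([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res["p"] == pytest.approx(0.1)  # 2 / C(6,3)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            na, nb = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + rng.normal()
            res = group_strength_comparison(a, b)
            assert res["p"] == pytest.approx(ranksum_exact(list(a), list(b)), abs=1e-10)


class TestRunwiseTrend:
    def test_four_runs_six_pairs(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)), columns=["run1", "run2", "run3", "run4"])
        out = runwise_strength_trend(df)
        assert len(out) == 6

    def test_identical_runs_all_p_one(self):
        col = np.arange(10.0)
        df = pd.DataFrame({"run1": col, "run2": col, "run3": col})
        out = runwise_strength_trend(df)
        assert (out["p"] == 1.0).all()
        assert (out["p_fdr"] == 1.0).all()

    def test_bh_adjustment_matches_step_up_oracle(self):
        ps = [0.01, 0.02, 0.03, 0.04]
        adj = stats.false_discovery_control(ps, method="bh")
        np.testing.assert_allclose(adj, bh_adjust_loop(ps), atol=1e-12)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_random_bh_matches_oracle(self, rng):
        for _ in range(50):
            ps = rng.uniform(size=int(rng.integers(2, 12)))
            np.testing.assert_allclose(
                stats.false_discovery_control(ps, method="bh"), bh_adjust_loop(list(ps)),
                atol=1e-12)

    def test_incomplete_pair_skipped(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        df.loc[0:3, "c"] = np.nan  # only 2 complete pairs with c
        with pytest.warns(RuntimeWarning, match="skipped"):
            out = runwise_strength_trend(df)
        assert len(out) == 1  # only (a, b) tested
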