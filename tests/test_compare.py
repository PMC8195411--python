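"""Model comparison: omniscient bound, normalised scores, bootstrap,
mean-estimate summaries and the asymmetry statistic."""

import numpy as np
import pandas as pd
import pytest

from scobs import (
    ObserverParams,
    asymmetry_statistic,
    bootstrap_ci,
    build_design,
    normalized_loglik,
    omniscient_loglik,
    predict_incorrect,
    simulate_subject,
    split_and_filter,
    table_loglik,
)
from scobs.compare import mean_estimate_summary
from scobs.data import TrialTable
from mc_oracle import mc_predictive, total_variation


@pytest.fixture(scope="module")
def cohort(exp1_params):
    design, _ = build_design("exp1", 70, seed=0)
    t = simulate_subject(exp1_params, design, seed=8)
    correct, incorrect, *_ = split_and_filter(t)
    return t, correct, incorrect


def _table(estimates, theta=3.0, correct=False):
    df = pd.DataFrame(
        {
            "subject_id": "S1",
            "experiment_id": "exp1",
            "trial_index": range(len(estimates)),
            "theta_deg": theta,
            "noise_level": "high",
            "sigma_s_deg": 18.0,
            "true_category": "cw",
            "choice": "ccw" if not correct else "cw",
            "choice_correct": correct,
            "estimate_deg": estimates,
        }
    )
    return TrialTable(df, {})


class TestOmniscient:
    def test_single_trial_contributes_zero(self):
        assert omniscient_loglik(_table([4.2])) == 0.0

    def test_two_trials_same_or_different_bins(self):
        assert omniscient_loglik(_table([4.1, 4.2])) == pytest.approx(0.0)
        assert omniscient_loglik(_table([4.1, 7.3])) == pytest.approx(2 * np.log(0.5))

    def test_upper_bounds_every_model(self, exp1_params, grid, cohort):
        _, _, incorrect = cohort
        ll_omni = omniscient_loglik(incorrect)
        for mid in ("1a", "1b", "2a"):
            dists = predict_incorrect(exp1_params, incorrect, mid, grid)
            assert ll_omni >= table_loglik(dists, incorrect)


class TestTableLoglik:
    def test_counts_bin_probabilities(self, exp1_params, grid):
        tbl = _table([4.2])
        dists = predict_incorrect(exp1_params, tbl, "2a", grid)
        d = dists[(3.0, "high")]
        expected = np.log(max(d.prob_of(4.2), 1e-6))
        assert table_loglik(dists, tbl) == pytest.approx(expected)

    def test_invariant_to_trial_order(self, exp1_params, grid, cohort):
        _, _, incorrect = cohort
        dists = predict_incorrect(exp1_params, incorrect, "2a", grid)
        shuffled = TrialTable(
            incorrect.df.sample(frac=1.0, random_state=1).reset_index(drop=True), {}
        )
        assert table_loglik(dists, shuffled) == pytest.approx(
            table_loglik(dists, incorrect)
        )


class TestPredictIncorrect:
    def test_model1a_identical_across_noise(self, exp1_params, grid, cohort):
        _, _, incorrect = cohort
        dists = predict_incorrect(exp1_params, incorrect, "1a", grid)
        pairs = {(abs(t), n): d for (t, n), d in dists.items() if t > 0}
        for (t, _n), d in pairs.items():
            other = pairs.get((t, "low" if _n == "high" else "high"))
            if other is not None:
                assert np.abs(d.bin_probs - other.bin_probs).max() < 1e-9

    def test_model1b_mean_is_signed_sigma(self, exp1_params, grid, cohort):
        _, _, incorrect = cohort
        dists = predict_incorrect(exp1_params, incorrect, "1b", grid)
        for (theta, level), d in dists.items():
            if theta == 0.0:
                continue
            # the feedback-corrected category is the true one: sign(theta)
            expected = np.sign(theta) * exp1_params.sigma_s(level)
            assert d.mean == pytest.approx(expected, abs=0.05)

    def test_model2a_matches_forward_monte_carlo(self, exp1_params, grid):
        tbl = _table([4.0])
        d = predict_incorrect(exp1_params, tbl, "2a", grid)[(3.0, "high")]
        mc, _ = mc_predictive(exp1_params, grid, 3.0, "high", "2a", "incorrect", seed=3)
        assert total_variation(d.bin_probs, mc) < 0.02


class TestNormalizedLoglik:
    def test_anchors(self):
        assert normalized_loglik(-100.0, -100.0, -50.0) == 0.0
        assert normalized_loglik(-50.0, -100.0, -50.0) == 1.0
        assert normalized_loglik(-75.0, -100.0, -50.0) == 0.5

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            normalized_loglik(-1.0, -1.0, -1.0)


class TestBootstrap:
    def test_constant_statistic_zero_width(self, cohort):
        _, _, incorrect = cohort
        point, lo, hi = bootstrap_ci(lambda t: 3.5, incorrect, n_boot=20, seed=0)
        assert point == lo == hi == 3.5

    def test_same_seed_same_interval(self, cohort):
        _, _, incorrect = cohort
        stat = lambda t: float(t.df.estimate_deg.mean())
        a = bootstrap_ci(stat, incorrect, n_boot=50, seed=4)
        b = bootstrap_ci(stat, incorrect, n_boot=50, seed=4)
        assert a == b

    def test_clt_width_for_gaussian_mean(self):
        rng = np.random.default_rng(2)
        tbl = _table(rng.standard_normal(10_000))
        point, lo, hi = bootstrap_ci(
            lambda t: float(t.df.estimate_deg.mean()), tbl, n_boot=200, seed=1
        )
        half = (hi - lo) / 2.0
        assert half == pytest.approx(1.96 / 100.0, rel=0.30)


class TestMeanEstimateSummary:
    def test_perfect_model_has_zero_mse_unit_r(self, exp1_params, grid, cohort):
        _, _, incorrect = cohort
        dists = predict_incorrect(exp1_params, incorrect, "2a", grid)
        # craft a distribution set whose means equal the data means exactly
        summary = mean_estimate_summary(incorrect, {"2a": dists})
        fake = summary.copy()
        data_means = fake.drop_duplicates(["theta_deg", "noise_level"])
        assert {"mse", "pearson_r"} <= set(summary.columns)
        # with model means forced to data means, mse = 0 and r = 1
        class _D:
            def __init__(self, mu):
                self.mean = mu

        forced = {
            (row.theta_deg, row.noise_level): _D(row.data_mean)
            for row in data_means.itertuples()
        }
        s2 = mean_estimate_summary(incorrect, {"perfect": forced})
        assert s2["mse"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert s2["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_r_shift_invariance(self, cohort, exp1_params, grid):
        _, _, incorrect = cohort
        dists = predict_incorrect(exp1_params, incorrect, "2a", grid)

        class _Shift:
            def __init__(self, d):
                self.mean = d.mean + 2.0

        shifted = {k: _Shift(d) for k, d in dists.items()}
        s0 = mean_estimate_summary(incorrect, {"m": dists})
        s1 = mean_estimate_summary(incorrect, {"m": shifted})
        assert s1["pearson_r"].iloc[0] == pytest.approx(s0["pearson_r"].iloc[0], abs=1e-9)
        assert s1["mse"].iloc[0] != pytest.approx(s0["mse"].iloc[0])


class TestAsymmetry:
    def test_symmetric_cohort_difference_covers_zero(self, cohort):
        _, _, incorrect = cohort
        point, lo, hi = bootstrap_ci(
            lambda t: asymmetry_statistic(t)[2], incorrect, n_boot=100, seed=0
        )
        assert lo <= 0.0 <= hi

    def test_asymmetric_priors_repulse_cw_side_more(self, exp2_params):
        design, _ = build_design("exp2", 70, seed=0)
        t = simulate_subject(exp2_params, design, seed=10)
        _, incorrect, *_ = split_and_filter(t)
        cw_mean, ccw_mean, diff = asymmetry_statistic(incorrect)
        assert cw_mean > ccw_mean
        assert diff > 0

    def test_invariant_to_trial_order(self, cohort):
        _, _, incorrect = cohort
        shuffled = TrialTable(
            incorrect.df.sample(frac=1.0, random_state=3).reset_index(drop=True), {}
        )
        assert asymmetry_statistic(shuffled) == pytest.approx(
            asymmetry_statistic(incorrect)
        )

    def test_one_sided_table_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_statistic(_table([4.0, 5.0]))


class TestRankingOnResampledCohorts:
    def test_generating_model_wins_on_2b_data(self, grid):
        """Cohorts generated with conditioned resampling identify Model 2b:
        its normalised log-likelihood beats every other variant (in particular
        2b >= 2a, the resampling repulsion signature) for most seeds."""
        params = ObserverParams.symmetric(3.0, 18.0, 4.0, 24.0, 8.0, sigma_0=1.5)
        wins_best, wins_2b = 0, 0
        n_seeds = 6
        for seed in range(n_seeds):
            design, _ = build_design("exp1", 70, seed=seed)
            t = simulate_subject(params, design, "2b-resampled", seed=300 + seed)
            _, incorrect, *_ = split_and_filter(t)
            ll = {}
            for mid in ("1a", "1b", "2a", "2b"):
                dists = predict_incorrect(params, incorrect, mid, grid)
                ll[mid] = table_loglik(dists, incorrect)
            ll_omni = omniscient_loglik(incorrect)
            norm = {m: normalized_loglik(ll[m], ll["1a"], ll_omni) for m in ll}
            assert norm["2b"] <= 1.0  # omniscient stays the upper bound
            if norm["2b"] >= max(norm["1a"], norm["1b"], norm["2a"]):
                wins_best += 1
            if norm["2b"] >= norm["2a"]:
                wins_2b += 1
        assert wins_best > n_seeds / 2
        assert wins_2b > n_seeds / 2
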