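"""Designs, synthetic subjects, trial-table I/O and the consistency filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chi2

from scobs import (
    ObserverEngine,
    ObserverParams,
    build_design,
    read_trials,
    simulate_subject,
    split_and_filter,
    write_trials,
)
from scobs.data import SchemaError, TrialTable


class TestBuildDesign:
    @pytest.mark.parametrize(
        "exp,n_trials,n_orients", [("exp1", 2100, 15), ("exp2", 1820, 13)]
    )
    def test_design_sizes(self, exp, n_trials, n_orients):
        design, trials = build_design(exp, 70, seed=0)
        assert design.n_trials == n_trials == len(trials)
        assert len(design.orientations) == n_orients
        assert trials["theta_deg"].nunique() == n_orients

    def test_noise_widths(self):
        assert build_design("exp1", 1)[0].noise_sigmas == (3.0, 18.0)
        assert build_design("exp2", 1)[0].noise_sigmas == (6.0, 18.0)

    def test_condition_balance(self):
        _, trials = build_design("exp1", 70, seed=3)
        counts = trials.groupby(["theta_deg", "noise_level"]).size()
        assert (counts == 70).all()

    def test_unknown_experiment(self):
        with pytest.raises(ValueError):
            build_design("exp3", 70)


@pytest.fixture(scope="module")
def sim_table(exp1_params):
    design, _ = build_design("exp1", 70, seed=0)
    return simulate_subject(exp1_params, design, seed=42, subject_id="S1")


class TestSimulateSubject:
    def test_deterministic_given_seed(self, exp1_params):
        design, _ = build_design("exp1", 10, seed=0)
        a = simulate_subject(exp1_params, design, seed=9)
        b = simulate_subject(exp1_params, design, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_reference_trials_correct_half_the_time(self, exp1_params):
        """Random a-priori category at theta = 0 under a symmetric generator."""
        design, _ = build_design("exp1", 40, seed=1)
        rows = []
        for seed in range(13):
            t = simulate_subject(exp1_params, design, seed=seed)
            rows.append(t.df[t.df.theta_deg == 0.0])
        d0 = pd.concat(rows)
        assert len(d0) >= 1000
        assert d0["choice_correct"].mean() == pytest.approx(0.5, abs=0.03)

    def test_noise_free_chain_reproduces_posterior_mean(self, grid):
        """With sigma_m = sigma_0 = 0, the estimate is exactly the mapped measurement."""
        from scobs import CategoryLabel, estimate_posterior_mean

        params = ObserverParams.symmetric(3.0, 18.0, 0.0, 24.0, 8.0, sigma_0=0.0)
        design, _ = build_design("exp1", 2, seed=0)
        t = simulate_subject(params, design, seed=5, grid=grid)
        correct = t.df[t.df.choice_correct]
        eng = ObserverEngine(params, grid)
        for _, row in correct.head(20).iterrows():
            cat = CategoryLabel.parse(row["choice"])
            sig = params.sigma_like_for(row["noise_level"])
            expected = estimate_posterior_mean(row["m"], cat, sig, eng.prior(cat), grid)
            assert row["estimate_deg"] == pytest.approx(expected, abs=1e-9)

    def test_incorrect_rate_matches_psychometric(self, exp1_params, sim_table, grid):
        """Per-condition error rates stay inside binomial 95% bounds."""
        eng = ObserverEngine(exp1_params, grid)
        df = sim_table.df[sim_table.df.theta_deg != 0.0]
        n_outside = 0
        cells = 0
        for (theta, level), g in df.groupby(["theta_deg", "noise_level"]):
            p_corr = eng.p_choice(theta, level, _true_cat(theta))
            lo, hi = binom.ppf([0.025, 0.975], len(g), 1.0 - p_corr)
            cells += 1
            k = int((~g.choice_correct).sum())
            if not lo <= k <= hi:
                n_outside += 1
        assert n_outside <= max(3, int(0.15 * cells))

    def test_choice_frequencies_match_psychometric_chi2(self, exp1_params, grid):
        """Goodness of fit of simulated choices to the psychometric op, 20 seeds."""
        design, _ = build_design("exp1", 70, seed=0)
        eng = ObserverEngine(exp1_params, grid)
        for seed in range(20):
            t = simulate_subject(exp1_params, design, seed=100 + seed)
            g2 = 0.0
            dof = 0
            for (theta, level), g in t.df.groupby(["theta_deg", "noise_level"]):
                p = float(np.clip(eng.psychometric(theta, level), 1e-9, 1 - 1e-9))
                k, n = int((g.choice == "cw").sum()), len(g)
                exp_counts = np.array([n * p, n * (1 - p)])
                obs = np.array([k, n - k])
                mask = exp_counts > 1e-9
                g2 += float(np.sum((obs[mask] - exp_counts[mask]) ** 2 / exp_counts[mask]))
                dof += 1
            assert chi2.sf(g2, dof) > 0.001


def _true_cat(theta):
    from scobs import CategoryLabel

    return CategoryLabel.of_orientation(theta)


class TestTrialIO:
    def test_round_trip(self, sim_table, tmp_path):
        path = tmp_path / "trials.csv"
        write_trials(sim_table, path)
        back = read_trials(path)
        assert back.metadata["seed"] == sim_table.metadata["seed"]
        pd.testing.assert_frame_equal(back.df, sim_table.df, check_exact=False, atol=1e-8)

    def test_missing_column_raises_schema_error(self, sim_table, tmp_path):
        path = tmp_path / "broken.csv"
        df = sim_table.df.drop(columns=["estimate_deg"])
        write_trials(TrialTable(df, {}), path)
        with pytest.raises(SchemaError, match="estimate_deg"):
            read_trials(path)

    def test_non_numeric_theta_raises(self, sim_table, tmp_path):
        path = tmp_path / "bad.csv"
        df = sim_table.df.head(5).copy()
        df["theta_deg"] = df["theta_deg"].astype(object)
        df.loc[2, "theta_deg"] = "oops"
        write_trials(TrialTable(df, {}), path)
        with pytest.raises(SchemaError, match="theta_deg"):
            read_trials(path)

    def test_real_data_without_generator_fields(self, sim_table, tmp_path):
        path = tmp_path / "real.csv"
        df = sim_table.df.drop(columns=["m", "m_m", "n_draws", "consistent"]).head(50)
        write_trials(TrialTable(df, {}), path)
        back = read_trials(path)
        assert back.df["m"].isna().all()
        assert len(back.df) == 50


class TestSplitAndFilter:
    def test_partition_and_counts(self, sim_table):
        correct, incorrect, excluded, report = split_and_filter(sim_table)
        assert report["n_correct"] + report["n_incorrect"] + report["n_excluded"] == len(
            sim_table
        )
        assert correct.df.choice_correct.all()
        assert not incorrect.df.choice_correct.any()

    def test_exclusion_rule_on_handmade_trials(self):
        df = pd.DataFrame(
            {
                "subject_id": "S1",
                "experiment_id": "exp1",
                "trial_index": range(4),
                "theta_deg": [6.0, 6.0, 6.0, 6.0],
                "noise_level": "low",
                "sigma_s_deg": 3.0,
                "true_category": ["cw", "cw", "cw", "cw"],
                "choice": ["cw", "ccw", "ccw", "cw"],
                "choice_correct": [True, False, False, True],
                "estimate_deg": [4.0, -6.0, 3.0, 0.0],
            }
        )
        correct, incorrect, excluded, report = split_and_filter(TrialTable(df, {}))
        # correct cw trial, estimate +4 kept; feedback-corrected cw with -6 excluded;
        # incorrect trial re-estimated at +3 kept; estimate exactly 0 never flagged
        assert list(correct.df.trial_index) == [0, 3]
        assert list(incorrect.df.trial_index) == [2]
        assert list(excluded.df.trial_index) == [1]
        assert report["excluded_fraction"] == 0.25

    def test_injected_lapses_are_counted(self, exp1_params):
        params = exp1_params.replace(lapse=0.05)
        design, _ = build_design("exp1", 70, seed=0)
        t = simulate_subject(params, design, seed=77)
        *_, report = split_and_filter(t)
        # an injected lapse is inconsistent roughly half the time
        assert 0.01 < report["excluded_fraction"] < 0.05

    def test_no_motor_noise_means_no_exclusions(self):
        params = ObserverParams.symmetric(3.0, 18.0, 4.0, 24.0, 8.0, sigma_0=0.0)
        design, _ = build_design("exp1", 20, seed=0)
        t = simulate_subject(params, design, seed=3)
        *_, report = split_and_filter(t)
        assert report["excluded_fraction"] == 0.0

    def test_realistic_motor_noise_rarely_excludes(self, sim_table):
        *_, report = split_and_filter(sim_table)
        assert report["excluded_fraction"] < 0.02
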