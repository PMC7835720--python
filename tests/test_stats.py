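"""Percent-correct analysis: t-tests, bootstrap, Bayesian estimation, procedures."""

import numpy as np
import pandas as pd
import pytest

from polygrasp.observer import ObserverModel, records_to_frame, simulate_experiment
from polygrasp.stats import (
    CHANCE,
    DegenerateTestError,
    bayes_estimate,
    bayes_estimate_paired,
    bootstrap_ci,
    effect_size,
    effect_size_paired,
    hdi,
    learning_trend,
    one_sample_t,
    paired_t,
    percent_correct,
    rope_fraction,
    select_replication_subset,
    session_values,
    summarize_group,
    unpaired_t,
)


def trial_frame(correct_flags, session="vision", participant=0):
    n = len(correct_flags)
    return pd.DataFrame(
        {
            "participant": [participant] * n,
            "session": [session] * n,
            "object": [f"o{i}" for i in range(n)],
            "criterion": ["aperture"] * n,
            "trial": range(n),
            "order": ["near_first"] * n,
            "chose_near_optimal": correct_flags,
        }
    )


class TestPercentCorrect:
    @pytest.mark.parametrize("n_correct,expected", [(12, 75.0), (16, 100.0), (8, 50.0)])
    def test_simple_proportions(self, n_correct, expected):
        frame = trial_frame([1] * n_correct + [0] * (16 - n_correct))
        pc = percent_correct(frame)
        assert pc["percent_correct"].iloc[0] == pytest.approx(expected)

    def test_grouping_by_participant_and_session(self):
        frame = pd.concat(
            [
                trial_frame([1, 1, 0, 0], participant=0),
                trial_frame([1, 1, 1, 1], participant=1),
            ]
        )
        pc = percent_correct(frame)
        assert len(pc) == 2
        assert sorted(pc["percent_correct"]) == [50.0, 100.0]

    def test_nan_responses_dropped_and_counted(self):
        frame = trial_frame([1, 0, 1, 1]).astype({"chose_near_optimal": float})
        frame.loc[2, "chose_near_optimal"] = np.nan
        pc = percent_correct(frame)
        assert pc.attrs["n_dropped"] == 1
        assert pc["n_trials"].iloc[0] == 3


class TestTTests:
    def test_one_sample_closed_form(self):
        res = one_sample_t([60, 70, 80], 50)
        assert res.t == pytest.approx(20 / (10 / np.sqrt(3)))
        assert res.df == 2
        assert res.mean_diff == pytest.approx(20.0)

    def test_all_at_chance_gives_zero_t(self):
        res = one_sample_t([50, 50, 50], 50)
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_off_chance_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            one_sample_t([60, 60, 60], 50)

    def test_single_observation_rejected(self):
        with pytest.raises(DegenerateTestError):
            one_sample_t([60], 50)

    def test_paired_identical_gives_zero(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_paired_constant_shift_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_paired_matches_one_sample_on_differences(self):
        rng = np.random.default_rng(0)
        a = rng.normal(60, 8, 20)
        b = rng.normal(55, 8, 20)
        res = paired_t(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(t_manual)
        assert res.df == 19

    def test_length_mismatch_rejected(self):
        with pytest.raises(DegenerateTestError):
            paired_t([1, 2, 3], [1, 2])

    def test_unpaired_welch_and_pooled_variants(self):
        rng = np.random.default_rng(1)
        a = rng.normal(70, 5, 25)
        b = rng.normal(65, 12, 25)
        welch = unpaired_t(a, b, welch=True)
        pooled = unpaired_t(a, b, welch=False)
        assert pooled.df == 48
        assert welch.df <= 48
        assert welch.mean_diff == pytest.approx(a.mean() - b.mean())


class TestBootstrap:
    def test_constant_values_degenerate_interval(self):
        assert bootstrap_ci([5.0, 5.0, 5.0]) == (5.0, 5.0)

    def test_matches_analytic_ci_for_large_normal_sample(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(1000)
        lo, hi = bootstrap_ci(v, reps=10000, seed=3)
        se = v.std(ddof=1) / np.sqrt(v.size)
        assert lo == pytest.approx(v.mean() - 1.96 * se, abs=0.012)
        assert hi == pytest.approx(v.mean() + 1.96 * se, abs=0.012)

    def test_contains_sample_mean_and_is_seeded(self):
        rng = np.random.default_rng(4)
        v = rng.normal(60, 10, 21)
        a = bootstrap_ci(v, seed=5)
        b = bootstrap_ci(v, seed=5)
        assert a == b
        assert a[0] <= v.mean() <= a[1]

    def test_summarize_group_invariants(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(40, 90, 21)
        summ = summarize_group(v, reps=2000, seed=0)
        assert summ.ci_low <= summ.mean <= summ.ci_high


class TestEffectSize:
    def test_direct_arithmetic(self):
        # mean 70, sd 10 around chance 50 -> effect 2.0
        v = np.array([60.0, 70.0, 80.0])
        assert effect_size(v, 50) == pytest.approx(20 / 10)

    def test_zero_at_chance(self):
        assert effect_size([40.0, 50.0, 60.0], 50) == 0.0

    def test_paired_antisymmetry(self):
        a = np.array([60.0, 65.0, 72.0])
        b = np.array([55.0, 58.0, 70.0])
        assert effect_size_paired(a, b) == pytest.approx(-effect_size_paired(b, a))

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateTestError):
            effect_size([50.0, 50.0], 50)


class TestHdiRope:
    def test_gaussian_quantile_oracle(self):
        rng = np.random.default_rng(7)
        s = rng.standard_normal(200_000)
        lo, hi = hdi(s, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)
        # Phi(0.4) - Phi(-0.4) = 0.3108
        assert rope_fraction(s, (-0.4, 0.4)) == pytest.approx(0.3108, abs=0.01)

    def test_degenerate_samples(self):
        assert hdi(np.zeros(100)) == (0.0, 0.0)
        assert rope_fraction(np.zeros(100)) == 1.0

    def test_hdi_matches_central_interval_for_symmetric_samples(self):
        rng = np.random.default_rng(8)
        s = rng.normal(3.0, 2.0, 100_000)
        lo, hi = hdi(s, 0.95)
        clo, chi = np.quantile(s, [0.025, 0.975])
        assert lo == pytest.approx(clo, abs=0.1)
        assert hi == pytest.approx(chi, abs=0.1)

    def test_rope_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(9)
        s = rng.normal(0.2, 0.5, 5000)
        f1 = rope_fraction(s)
        f2 = rope_fraction(rng.permutation(s))
        assert f1 == f2
        assert 0.0 <= f1 <= 1.0

    def test_unordered_rope_bounds_rejected(self):
        with pytest.raises(ValueError):
            rope_fraction([0.0], (0.4, -0.4))


class TestBayesEstimate:
    def test_posterior_mean_tracks_sample_mean(self):
        rng = np.random.default_rng(10)
        v = rng.normal(62.0, 8.0, 100)
        res = bayes_estimate(v, CHANCE, seed=1)
        se = v.std(ddof=1) / np.sqrt(v.size)
        assert res.mu.mean() == pytest.approx(v.mean(), abs=2 * se)
        assert res.hdi95[0] < v.mean() - CHANCE < res.hdi95[1]
        assert max(res.rhat.values()) <= 1.1

    def test_agrees_with_frequentist_for_large_n(self):
        rng = np.random.default_rng(11)
        v = rng.normal(58.0, 6.0, 200)
        res = bayes_estimate(v, CHANCE, seed=2)
        freq = one_sample_t(v, CHANCE)
        se = v.std(ddof=1) / np.sqrt(v.size)
        assert (res.mu.mean() - CHANCE) == pytest.approx(freq.mean_diff, abs=2 * se)

    def test_clear_effect_empties_rope(self):
        rng = np.random.default_rng(12)
        v = rng.normal(75.0, 5.0, 30)  # ~5 sd above chance
        res = bayes_estimate(v, CHANCE, seed=3)
        assert res.rope_fraction < 0.01

    def test_null_data_fills_rope(self):
        rng = np.random.default_rng(13)
        v = rng.normal(50.0, 8.0, 25)
        res = bayes_estimate(v, CHANCE, seed=4)
        assert res.rope_fraction > 0.5
        assert res.hdi95[0] < 0 < res.hdi95[1]

    def test_paired_variant_is_one_group_on_differences(self):
        rng = np.random.default_rng(14)
        a = rng.normal(70, 6, 40)
        b = rng.normal(64, 6, 40)
        res = bayes_estimate_paired(a, b, seed=5)
        d = a - b
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert res.mu.mean() == pytest.approx(d.mean(), abs=2 * se)

    def test_too_few_observations_rejected(self):
        with pytest.raises(DegenerateTestError):
            bayes_estimate([60.0], CHANCE)


class TestReplicationSubset:
    def test_closed_loop_selection(self):
        """Objects built to satisfy the rule are selected; others are not."""
        strong = [(f"strong{i}", "torque", 1.5) for i in range(3)]
        null = [(f"null{i}", "torque", 0.0) for i in range(3)]
        obs = ObserverModel(
            sensitivity_k={"vision": 0.0, "grasping": 6.0}, seed=21
        )
        records = simulate_experiment(
            strong + null, obs, 40, sessions=["vision", "grasping"]
        )
        frame = records_to_frame(records)
        selected = select_replication_subset(frame, seed=0)
        assert set(selected) == {f"strong{i}" for i in range(3)}

    def test_above_chance_vision_objects_excluded(self):
        pairs = [(f"o{i}", "nga", 2.0) for i in range(3)]
        obs = ObserverModel(sensitivity_k={"vision": 6.0, "grasping": 6.0}, seed=3)
        records = simulate_experiment(pairs, obs, 40, sessions=["vision", "grasping"])
        frame = records_to_frame(records)
        assert select_replication_subset(frame, seed=0) == []


class TestLearningTrend:
    def test_stationary_observer_rarely_significant(self):
        design = [(f"o{i}", "aperture", 0.5) for i in range(16)]
        n_reject = 0
        runs = 30
        for seed in range(runs):
            obs = ObserverModel(sensitivity_k={"vision": 1.0}, seed=seed)
            frame = records_to_frame(
                simulate_experiment(design, obs, 15, sessions=["vision"])
            )
            res = learning_trend(frame)["vision"]
            n_reject += res.p < 0.05
        assert n_reject <= 4  # ~alpha-level false positives only

    def test_drifting_observer_shows_positive_slope(self):
        design = [(f"o{i}", "aperture", 0.5) for i in range(16)]
        obs = ObserverModel(
            sensitivity_k={"vision": 0.0}, seed=0, drift_per_trial=0.8
        )
        frame = records_to_frame(
            simulate_experiment(design, obs, 40, sessions=["vision"])
        )
        res = learning_trend(frame)["vision"]
        assert res.mean_diff > 0
        assert res.p < 0.05

    def test_alternating_responses_have_zero_slope(self):
        # palindromic alternation: contributions at mirrored trial indices cancel
        frame = trial_frame([1, 0, 1, 0, 1, 0, 1])
        res = learning_trend(frame)["vision"]
        assert res.mean_diff == pytest.approx(0.0, abs=1e-12)

    def test_single_trial_sessions_rejected(self):
        frame = trial_frame([1])
        with pytest.raises(DegenerateTestError):
            learning_trend(frame)


class TestSessionValues:
    def test_participant_ordering(self):
        frame = pd.concat(
            [
                trial_frame([1, 1, 1, 1], participant=1),
                trial_frame([1, 0, 0, 0], participant=0),
            ]
        )
        v = session_values(percent_correct(frame), "vision")
        assert v == pytest.approx([25.0, 100.0])
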