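"""Risk states, transitions, scenario engine and robustness protocols."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twinforge as tf
from twinforge.twin import (
    Perturbation,
    ScenarioError,
    ScenarioSpec,
    _builtin_scenario,
    _kmeans_1d_exact,
    apply_scenario,
    assign_states,
    fit_outcome,
    fit_states,
    fit_transition,
    high_risk_union,
    jaccard_overlap,
    load_scenario,
    monotonicity_sweep,
    simulate_scenario,
    stability_analysis,
)


def _three_clump_risks(n=2000, seed=2):
    rng = np.random.default_rng(seed)
    sizes = (int(n * 0.791), int(n * 0.101))
    return np.concatenate(
        [
            np.clip(rng.normal(0.0303, 0.02, sizes[0]), 0, 1),
            np.clip(rng.normal(0.278, 0.05, sizes[1]), 0, 1),
            np.clip(rng.normal(0.935, 0.04, n - sum(sizes)), 0, 1),
        ]
    )


class TestFitStates:
    def test_three_clump_centroids_recovered(self):
        risks = _three_clump_risks()
        model = fit_states(risks, K=3)
        assert np.all(np.abs(model.centroids - [0.0303, 0.278, 0.935]) < 0.02)
        assert model.labels == ("low", "medium", "high")

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="K must be >= 2"):
            fit_states(np.linspace(0, 1, 10), K=1)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_states(np.array([0.1, 0.1, 0.9, 0.9]), K=3)

    def test_fitting_is_deterministic(self):
        risks = _three_clump_risks(seed=4)
        m1, m2 = fit_states(risks, K=4, seed=0), fit_states(risks, K=4, seed=0)
        assert np.array_equal(m1.centroids, m2.centroids)

    def test_dp_solution_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(7)
        for n, K in [(30, 2), (40, 3), (25, 4)]:
            x = rng.random(n)
            _, sse = _kmeans_1d_exact(x, K)
            xs = np.sort(x)
            best = min(
                sum(((seg - seg.mean()) ** 2).sum() for seg in np.split(xs, bnd))
                for bnd in itertools.combinations(range(1, n), K - 1)
            )
            assert sse == pytest.approx(best, abs=1e-9)


@pytest.fixture(scope="module")
def model():
    return fit_states(_three_clump_risks(), K=3)


class TestAssignStates:
    def test_zero_risk_is_low(self, model):
        assert assign_states(np.array([0.0]), model)[0] == 0

    def test_midpoint_tie_goes_to_lower_state(self):
        from twinforge.twin import RiskStateModel

        # exact binary fractions so the midpoint is exactly equidistant
        m = RiskStateModel(
            K=2, centroids=np.array([0.25, 0.75]), labels=("state_0", "state_1"),
            fit_seed=0, cluster_sizes=np.array([1, 1]),
            high_risk_clusters=frozenset({1}), reference_high_size=1,
        )
        assert assign_states(np.array([0.5]), m)[0] == 0

    def test_matches_argmin_scan_oracle(self, model):
        rng = np.random.default_rng(11)
        risks = rng.random(1000)
        got = assign_states(risks, model)
        expected = np.array(
            [int(np.argmin(np.abs(model.centroids - r))) for r in risks]
        )
        assert np.array_equal(got, expected)

    def test_out_of_range_risk_rejected(self, model):
        with pytest.raises(ValueError, match="\\[0,1\\]"):
            assign_states(np.array([1.2]), model)


class TestHighRiskUnion:
    def test_k3_reference_returns_top_cluster_only(self):
        model = fit_states(_three_clump_risks(), K=3)
        union = high_risk_union(model, model.reference_high_size)
        assert union == frozenset({2})

    def test_accumulates_until_reference_size_met(self):
        model = fit_states(_three_clump_risks(), K=4)
        model.cluster_sizes = np.array([2000, 800, 130, 100])
        assert high_risk_union(model, 220) == frozenset({3, 2})

    def test_zero_reference_still_returns_top_cluster(self):
        model = fit_states(_three_clump_risks(), K=3)
        assert high_risk_union(model, 0) == frozenset({2})

    def test_reference_beyond_population_rejected(self):
        model = fit_states(_three_clump_risks(n=100), K=3)
        with pytest.raises(ValueError, match="exceeds population"):
            high_risk_union(model, 10_000)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({1, 2}, {2, 3}, 1 / 3), ({1, 2}, {1, 2}, 1.0), ({1}, {2}, 0.0), (set(), set(), 1.0)],
    )
    def test_closed_forms(self, a, b, expected):
        assert jaccard_overlap(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.frozensets(st.integers(0, 20)),
        b=st.frozensets(st.integers(0, 20)),
    )
    def test_bounded_and_symmetric(self, a, b):
        j = jaccard_overlap(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard_overlap(b, a)
        if a == b:
            assert j == 1.0


class TestTransition:
    def test_copy_dynamics_learned_perfectly(self):
        rng = np.random.default_rng(5)
        n = 3000
        x = rng.normal(size=(n, 4))
        s = rng.integers(0, 3, n)
        tm = fit_transition(x, s, s, folds=5, seed=5, models=("random_forest",))
        m = tm.metrics["random_forest"]
        assert m["accuracy"] == 1.0
        assert m["avg_log_likelihood"] >= -0.01

    def test_label_independent_states_hit_uniform_baseline(self):
        rng = np.random.default_rng(6)
        n = 10_000
        x = rng.normal(size=(n, 5))
        s2 = rng.integers(0, 3, n)
        s3 = rng.integers(0, 3, n)
        tm = fit_transition(x, s2, s3, folds=5, seed=6, models=("logistic",))
        m = tm.metrics["logistic"]
        assert m["accuracy"] == pytest.approx(1 / 3, abs=0.03)
        assert m["avg_log_likelihood"] == pytest.approx(-np.log(3), abs=0.05)

    def test_soft_outputs_sum_to_one(self, small_twin):
        soft = small_twin.transition.oof_proba
        assert np.allclose(soft.sum(axis=1), 1.0, atol=1e-9)

    def test_markov_dynamics_beat_marginal_majority_baseline(self):
        """State+covariate dynamics must be learnable well above the
        majority-class floor."""
        rng = np.random.default_rng(8)
        n = 10_000
        x = rng.normal(size=(n, 1))
        s2 = rng.integers(0, 3, n)
        # next state deterministic in (state, sign of covariate), with noise
        s3 = np.where(x[:, 0] > 0, np.minimum(s2 + 1, 2), s2)
        flip = rng.random(n) < 0.05
        s3 = np.where(flip, rng.integers(0, 3, n), s3)
        tm = fit_transition(x, s2, s3, folds=5, seed=8)
        majority = np.bincount(s3).max() / n
        acc = tm.metrics["gradient_boosted_trees"]["accuracy"]
        assert acc >= majority + 0.20


class TestOutcome:
    def test_outcome_determined_by_state_is_separable(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.normal(size=(n, 3))
        s2 = rng.integers(0, 3, n)
        s3 = rng.integers(0, 3, n)
        soft = np.zeros((n, 3))
        soft[np.arange(n), s3] = 1.0  # perfect soft inputs
        y = (s3 == 2).astype(int)
        om = fit_outcome(x, s2, soft, y, folds=5, seed=9, models=("logistic",))
        assert om.metrics["logistic"]["auc"] == pytest.approx(1.0, abs=1e-6)

    def test_permuted_outcome_gives_chance_auc(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.normal(size=(n, 3))
        s2 = rng.integers(0, 3, n)
        soft = rng.dirichlet(np.ones(3), n)
        y = rng.integers(0, 2, n)
        om = fit_outcome(x, s2, soft, y, folds=5, seed=10, models=("logistic",))
        assert om.metrics["logistic"]["auc"] == pytest.approx(0.5, abs=0.05)

    def test_in_sample_soft_states_refused(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError, match="cross-fitted"):
            fit_outcome(
                x, np.zeros(10, dtype=int), np.ones((10, 3)) / 3,
                np.arange(10) % 2, soft_is_crossfitted=False,
            )


class TestScenarios:
    def test_weight_reduction_propagates_to_bmi(self, small_panel):
        scenario = load_scenario(_builtin_scenario("scenario_weight10"))
        out = apply_scenario(small_panel, scenario)
        w2 = small_panel.data["wave"] == "W2"
        base_w = small_panel.data.loc[w2, "weight_lbs"].to_numpy()
        base_b = small_panel.data.loc[w2, "bmi"].to_numpy()
        assert np.allclose(out.data.loc[w2, "weight_lbs"], base_w * 0.9)
        assert np.allclose(out.data.loc[w2, "bmi"], base_b * 0.9)
        # e.g. weight 200 -> 180; BMI 29.6 -> 26.64
        assert 200.0 * 0.9 == 180.0 and round(29.6 * 0.9, 2) == 26.64

    def test_wave3_rows_untouched(self, small_panel):
        scenario = load_scenario(_builtin_scenario("scenario_weight10"))
        out = apply_scenario(small_panel, scenario)
        w3 = small_panel.data["wave"] == "W3"
        pd.testing.assert_frame_equal(
            out.data.loc[w3], small_panel.data.loc[w3], check_dtype=False
        )

    def test_ordinal_shift_clamps_at_scale_maximum(self, small_panel):
        scenario = ScenarioSpec(
            "activity+1", [Perturbation("physical_activity", "ordinal_shift", 1)]
        )
        out = apply_scenario(small_panel, scenario)
        w2 = small_panel.data["wave"] == "W2"
        before = small_panel.data.loc[w2, "physical_activity"].to_numpy()
        after = out.data.loc[w2, "physical_activity"].to_numpy()
        assert after.max() <= 6
        assert np.all(after[before == 6] == 6)
        assert np.all(after[before < 6] == before[before < 6] + 1)

    def test_additive_reduction_floors_at_zero(self, small_panel):
        scenario = ScenarioSpec(
            "alcohol-2", [Perturbation("alcohol_drinks_week", "additive", -2.0)]
        )
        out = apply_scenario(small_panel, scenario)
        w2 = small_panel.data["wave"] == "W2"
        assert out.data.loc[w2, "alcohol_drinks_week"].min() >= 0.0

    def test_zero_magnitude_change_is_identity(self, small_panel):
        scenario = ScenarioSpec(
            "null", [Perturbation("weight_lbs", "multiplicative", 0.0)]
        )
        out = apply_scenario(small_panel, scenario)
        pd.testing.assert_frame_equal(out.data, small_panel.data, check_dtype=False)

    def test_non_modifiable_variable_rejected(self, small_panel):
        scenario = ScenarioSpec(
            "cheat", [Perturbation("prescription_meds", "categorical_set", 0)]
        )
        with pytest.raises(ScenarioError, match="prescription_meds"):
            apply_scenario(small_panel, scenario)


class TestSimulate:
    def test_placebo_changes_nothing_at_all(self, small_panel, small_twin):
        scenario = load_scenario(_builtin_scenario("scenario_placebo"))
        res = simulate_scenario(small_panel, scenario, small_twin)
        assert np.all(res.risk_delta == 0.0)
        assert np.array_equal(
            res.baseline_state_fractions, res.perturbed_state_fractions
        )
        assert res.baseline_cases == res.perturbed_cases
        assert res.n_state_changes == 0 and res.n_high_to_low == 0

    def test_state_fractions_sum_to_one_and_population_conserved(
        self, small_panel, small_twin
    ):
        scenario = load_scenario(_builtin_scenario("scenario_weight10"))
        res = simulate_scenario(small_panel, scenario, small_twin)
        assert res.baseline_state_fractions.sum() == pytest.approx(1.0)
        assert res.perturbed_state_fractions.sum() == pytest.approx(1.0)
        assert res.n == small_panel.n_participants == len(res.risk_delta)

    def test_weight_loss_reduces_mean_risk(self, small_panel, small_twin):
        scenario = load_scenario(_builtin_scenario("scenario_weight10"))
        res = simulate_scenario(small_panel, scenario, small_twin)
        assert res.perturbed_mean_risk < res.baseline_mean_risk
        assert res.n_reduced_risk > res.n // 2

    def test_lifestyle_scenario_runs_and_logs(self, small_panel, small_twin):
        scenario = load_scenario(_builtin_scenario("scenario_lifestyle"))
        run_log = []
        res = simulate_scenario(small_panel, scenario, small_twin, run_log=run_log)
        assert len(run_log) == 1
        assert run_log[0]["scenario"] == "composite_lifestyle"
        assert res.perturbed_mean_risk <= res.baseline_mean_risk

    def test_simulation_is_deterministic(self, small_panel, small_twin):
        scenario = load_scenario(_builtin_scenario("scenario_weight10"))
        r1 = simulate_scenario(small_panel, scenario, small_twin)
        r2 = simulate_scenario(small_panel, scenario, small_twin)
        assert np.array_equal(r1.risk_delta, r2.risk_delta)
        assert r1.summary() == r2.summary()


class TestMonotonicity:
    def test_increasing_weight_reduction_is_non_increasing_in_risk(
        self, small_panel, small_twin
    ):
        sweep = monotonicity_sweep(
            small_panel, small_twin, magnitudes=(0.05, 0.10, 0.15)
        )
        assert sweep["monotone_non_increasing"]

    def test_zero_magnitude_equals_baseline(self, small_panel, small_twin):
        sweep = monotonicity_sweep(small_panel, small_twin, magnitudes=(0.0,))
        scenario = load_scenario(_builtin_scenario("scenario_placebo"))
        res = simulate_scenario(small_panel, scenario, small_twin)
        assert sweep["mean_risk"][0] == pytest.approx(res.baseline_mean_risk)

    def test_duplicate_magnitudes_reproduce_identical_values(
        self, small_panel, small_twin
    ):
        sweep = monotonicity_sweep(small_panel, small_twin, magnitudes=(0.1, 0.1))
        assert sweep["mean_risk"][0] == sweep["mean_risk"][1]

    def test_empty_magnitudes_rejected(self, small_panel, small_twin):
        with pytest.raises(ValueError, match="non-empty"):
            monotonicity_sweep(small_panel, small_twin, magnitudes=())


class TestStability:
    def test_single_k_gives_trivial_matrix(self):
        risks = _three_clump_risks()
        rep = stability_analysis(risks, risks, K_range=(3,))
        assert rep.jaccard.shape == (1, 1)
        assert rep.jaccard.iloc[0, 0] == 1.0

    def test_three_clump_design_keeps_high_risk_membership_stable(self):
        risks = _three_clump_risks(n=4174)
        rep = stability_analysis(risks, risks, K_range=(3, 4, 5))
        assert rep.jaccard.to_numpy().min() >= 0.9

    def test_k_below_two_rejected(self):
        risks = _three_clump_risks()
        with pytest.raises(ValueError, match=">= 2"):
            stability_analysis(risks, risks, K_range=(1, 3))


class TestFrozenCentroids:
    def test_wave3_assignment_never_refits(self, small_twin):
        before = small_twin.states.centroid_digest()
        assign_states(np.clip(small_twin.risk_w3, 0, 1), small_twin.states)
        assert small_twin.states.centroid_digest() == before
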