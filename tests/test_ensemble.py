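import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from easigp import ensemble as ens
from easigp.attribution import MarkerEffectProfile

from conftest import make_dataset


class TestBuildScenarios:
    def test_full_grid_count(self):
        out = ens.build_scenarios([f"P{i}" for i in range(5)], [0.8, 0.65, 0.5], 500)
        assert len(out) == 7500

    def test_single_cell(self):
        out = ens.build_scenarios(["P"], [0.5], 1)
        assert len(out) == 1

    def test_deterministic_seeds(self):
        a = ens.build_scenarios(["A", "B"], [0.8, 0.5], 3, base_seed=42)
        b = ens.build_scenarios(["A", "B"], [0.8, 0.5], 3, base_seed=42)
        assert [s.seed for s in a] == [s.seed for s in b]

    def test_seeds_distinct(self):
        out = ens.build_scenarios(["A", "B"], [0.8, 0.5], 50, base_seed=0)
        seeds = [s.seed for s in out]
        assert len(set(seeds)) == len(seeds)

    def test_bad_ratio_errors(self):
        with pytest.raises(ValueError):
            ens.build_scenarios(["P"], [1.2], 1)


class TestSplit:
    def test_worked_example_444(self):
        d = make_dataset(np.zeros((444, 1), int), np.arange(444))
        train, test = ens.split_train_test(d, 0.8, seed=0)
        assert (train.n_records, test.n_records) == (355, 89)

    def test_even_split(self):
        d = make_dataset(np.zeros((10, 1), int), np.arange(10))
        train, test = ens.split_train_test(d, 0.5, seed=1)
        assert (train.n_records, test.n_records) == (5, 5)

    def test_deterministic_membership(self):
        d = make_dataset(np.zeros((30, 1), int), np.arange(30))
        t1, _ = ens.split_train_test(d, 0.7, seed=9)
        t2, _ = ens.split_train_test(d, 0.7, seed=9)
        assert t1.ids == t2.ids

    def test_disjoint_and_exhaustive(self):
        d = make_dataset(np.zeros((23, 1), int), np.arange(23))
        train, test = ens.split_train_test(d, 0.6, seed=3)
        assert set(train.ids) | set(test.ids) == set(d.ids)
        assert not set(train.ids) & set(test.ids)

    def test_empty_side_errors(self):
        d = make_dataset(np.zeros((3, 1), int), np.arange(3))
        with pytest.raises(ValueError):
            ens.split_train_test(d, 0.1, seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert ens.pearson_r(obs, obs) == pytest.approx(1.0)
        assert ens.mse(obs, obs) == 0.0

    def test_anticorrelated(self):
        obs = np.array([-1.0, 0.0, 1.0])
        assert ens.pearson_r(-obs, obs) == pytest.approx(-1.0)

    def test_hand_computed_mse(self):
        assert ens.mse([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 3)

    def test_constant_obs_errors(self):
        with pytest.raises(ValueError):
            ens.pearson_r([1.0, 2.0], [5.0, 5.0])


class TestEnsemblePredict:
    def test_two_models(self):
        np.testing.assert_array_equal(ens.ensemble_predict([[2.0], [4.0]]), [3.0])

    def test_single_model_identity(self):
        np.testing.assert_array_equal(ens.ensemble_predict([[1.0, 2.0]]), [1.0, 2.0])

    def test_oracle_mean(self):
        rng = np.random.default_rng(0)
        preds = [rng.normal(0, 1, 20) for _ in range(6)]
        out = ens.ensemble_predict(preds)
        brute = np.array([np.mean([p[i] for p in preds]) for i in range(20)])
        np.testing.assert_allclose(out, brute)

    def test_misaligned_errors(self):
        with pytest.raises(ValueError):
            ens.ensemble_predict([[1.0, 2.0], [1.0]])


class TestDiversityDecomposition:
    def test_hand_computed(self):
        e, i, v = ens.diversity_decomposition([[2.0], [4.0]], [3.0])
        assert (e, i, v) == (0.0, 1.0, 1.0)

    def test_identical_models(self):
        p = np.array([1.0, 2.0])
        e, i, v = ens.diversity_decomposition([p, p, p], [0.0, 0.0])
        assert v == 0.0 and e == i

    def test_identity_random_instance(self):
        rng = np.random.default_rng(1)
        preds = [rng.normal(0, 1, 50) for _ in range(6)]
        obs = rng.normal(0, 1, 50)
        e, i, v = ens.diversity_decomposition(preds, obs)
        assert abs(e - (i - v)) < 1e-10
        assert e <= i

    @given(hnp.arrays(np.float64, (4, 9), elements=st.floats(-50, 50)),
           hnp.arrays(np.float64, (9,), elements=st.floats(-50, 50)))
    @settings(max_examples=40, deadline=None)
    def test_identity_property(self, preds, obs):
        e, i, v = ens.diversity_decomposition(list(preds), obs)
        assert abs(e - (i - v)) < 1e-9 * max(1.0, i)
        assert e <= i + 1e-12


class TestNormalization:
    def test_minmax(self):
        p = MarkerEffectProfile("m", ["a", "b", "c"], [1.0, 3.0, 5.0])
        np.testing.assert_allclose(ens.normalize_effects(p).scores, [0, 0.5, 1])

    def test_constant_maps_to_zero(self):
        p = MarkerEffectProfile("m", ["a", "b"], [2.0, 2.0])
        np.testing.assert_array_equal(ens.normalize_effects(p).scores, [0.0, 0.0])

    def test_magnitude_rule(self):
        p = MarkerEffectProfile("m", ["a", "b", "c"], [-5.0, 0.0, 5.0])
        np.testing.assert_allclose(ens.normalize_effects(p).scores, [1, 0, 1])

    @given(hnp.arrays(np.float64, (7,), elements=st.floats(-100, 100)))
    @settings(max_examples=40, deadline=None)
    def test_range_property(self, scores):
        p = MarkerEffectProfile("m", [f"x{i}" for i in range(7)], scores)
        out = ens.normalize_effects(p).scores
        assert out.min() >= 0 and out.max() <= 1


class TestEnsembleEffects:
    def test_two_profiles(self):
        a = MarkerEffectProfile("A", ["x", "y"], [0.0, 1.0])
        b = MarkerEffectProfile("B", ["x", "y"], [1.0, 0.0])
        out = ens.ensemble_effects([a, b])
        np.testing.assert_allclose(out.scores, [0.5, 0.5])
        assert out.model == "Ensemble"

    def test_identical_profiles_identity(self):
        a = MarkerEffectProfile("A", ["x"], [0.4])
        out = ens.ensemble_effects([a, a])
        np.testing.assert_allclose(out.scores, [0.4])

    def test_oracle_mean(self):
        rng = np.random.default_rng(2)
        profs = [MarkerEffectProfile(f"M{i}", ["a", "b", "c"], rng.random(3))
                 for i in range(6)]
        out = ens.ensemble_effects(profs)
        brute = np.mean([p.scores for p in profs], axis=0)
        np.testing.assert_allclose(out.scores, brute)

    def test_marker_mismatch_errors(self):
        a = MarkerEffectProfile("A", ["x"], [1.0])
        b = MarkerEffectProfile("B", ["y"], [1.0])
        with pytest.raises(ValueError):
            ens.ensemble_effects([a, b])


def _mk_result(scenario, effects_by_model, ens_scores, markers):
    profs = {m: MarkerEffectProfile(m, markers, s, scenario.id)
             for m, s in effects_by_model.items()}
    return ens.ScenarioResult(
        scenario=scenario, marker_names=markers,
        predictions={}, metrics={m: {"pearson_r": 0.5, "mse": 1.0}
                                 for m in effects_by_model},
        effects=profs,
        ensemble_effects=MarkerEffectProfile("Ensemble", markers, ens_scores,
                                             scenario.id))


class TestAggregation:
    def test_single_scenario_identity(self):
        sc = ens.PredictionScenario("P", 0.8, 0, 1)
        agg = ens.aggregate_scenarios([_mk_result(sc, {"A": [0.2, 0.4]},
                                                  [0.1, 0.3], ["x", "y"])])
        assert agg.per_model_effects.loc["x", "A"] == pytest.approx(0.2)
        assert agg.ensemble_effects["y"] == pytest.approx(0.3)

    def test_two_scenario_mean(self):
        s1 = ens.PredictionScenario("P", 0.8, 0, 1)
        s2 = ens.PredictionScenario("P", 0.8, 1, 2)
        agg = ens.aggregate_scenarios([
            _mk_result(s1, {"A": [0.2]}, [0.2], ["x"]),
            _mk_result(s2, {"A": [0.4]}, [0.4], ["x"])])
        assert agg.per_model_effects.loc["x", "A"] == pytest.approx(0.3)

    def test_na_skipping_oracle(self):
        rng = np.random.default_rng(3)
        markers_all = ["x", "y", "z"]
        results, raw = [], {m: [] for m in markers_all}
        for k in range(10):
            sc = ens.PredictionScenario("P", 0.8, k, k + 1)
            present = markers_all if k % 2 == 0 else ["x", "z"]  # y pruned away
            scores = rng.random(len(present))
            for m, s in zip(present, scores):
                raw[m].append(s)
            results.append(_mk_result(sc, {"A": scores}, scores, list(present)))
        agg = ens.aggregate_scenarios(results)
        for m in markers_all:
            assert agg.per_model_effects.loc[m, "A"] == pytest.approx(np.mean(raw[m]))
        assert agg.presence["y"] == 5 and agg.presence["x"] == 10

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ens.aggregate_scenarios([])


class TestRunScenario:
    def test_smoke_and_jensen(self, epistatic_sim):
        d, truth, gmap = epistatic_sim
        sc = ens.PredictionScenario("SIM1", 0.8, 0, 77)
        res = ens.run_scenario(
            d, sc, models=("rrBLUP", "RF"),
            model_params={"RF": {"n_trees": 50}},
            attribution_params={"shapley_n_samples": 5, "shapley_max_test": 8,
                                "max_background": 8, "interaction_n_samples": 4,
                                "interaction_screen_top": 8},
            compute_interactions=True)
        assert set(res.metrics) == {"rrBLUP", "RF", "Ensemble"}
        for m, vals in res.metrics.items():
            assert np.isfinite(vals["pearson_r"]) and np.isfinite(vals["mse"])
        ens_mse = res.metrics["Ensemble"]["mse"]
        mean_ind = np.mean([res.metrics[m]["mse"] for m in ("rrBLUP", "RF")])
        assert ens_mse <= mean_ind + 1e-12
        assert res.interactions is not None

    def test_scenario_count_invariant(self):
        scens = ens.build_scenarios(["A", "B", "C"], [0.8, 0.5], 4)
        assert len(scens) == 3 * 2 * 4
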