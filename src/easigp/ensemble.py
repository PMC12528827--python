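"""Scenario grid driver, metrics, naive ensemble-average and aggregation.

A run covers |populations| x |ratios| x |repeats| prediction scenarios.
Each scenario draws a seeded train/test split, optionally re-runs LD
pruning on its training set, fits the configured models, computes Pearson
r and MSE, estimates per-marker effects per model and (from the forest)
pairwise interactions. Effects are min-max normalized on magnitude within
each scenario x model, averaged across models for the ensemble profile,
and averaged across scenarios for the final architecture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import attribution as attr
from .data_io import Dataset, GeneticMap, ld_prune
from .predictors import MODEL_FITTERS
from .predictors.gat import GATFit
from .predictors.linear import LinearModelFit


@dataclass(frozen=True)
class PredictionScenario:
    population: str
    train_fraction: float
    repeat: int
    seed: int

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train fraction {self.train_fraction} outside (0,1)")

    @property
    def id(self) -> str:
        return f"{self.population}|{self.train_fraction:g}|{self.repeat}"


@dataclass
class ScenarioResult:
    scenario: PredictionScenario
    marker_names: list
    predictions: dict            # model -> {"train": ..., "test": ...}
    metrics: dict                # model -> {"pearson_r": float, "mse": float}
    effects: dict                # model -> MarkerEffectProfile (raw)
    ensemble_effects: "attr.MarkerEffectProfile"
    interactions: "attr.InteractionMatrix | None" = None


@dataclass
class AggregateResult:
    per_model_effects: pd.DataFrame       # index marker, column per model (raw means)
    ensemble_effects: pd.Series           # mean normalized-ensemble effect per marker
    presence: pd.Series                   # scenarios in which each marker was present
    mean_interactions: "attr.InteractionMatrix | None"
    metrics: pd.DataFrame                 # one row per scenario x model


# ---------------------------------------------------------------------------
# scenario grid
# ---------------------------------------------------------------------------

def derive_seed(base_seed: int, population: str, ratio_index: int, repeat: int) -> int:
    key = f"{base_seed}|{population}|{ratio_index}|{repeat}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


def build_scenarios(populations, ratios, n_repeats: int, base_seed: int = 0):
    """Full factorial grid of |populations| x |ratios| x n_repeats scenarios,
    each with a deterministic derived seed."""
    if not populations or not ratios or n_repeats < 1:
        raise ValueError("need non-empty populations/ratios and n_repeats >= 1")
    for r in ratios:
        if not 0 < r < 1:
            raise ValueError(f"train ratio {r} outside (0,1)")
    out = [
        PredictionScenario(pop, float(ratio), rep,
                           derive_seed(base_seed, str(pop), ri, rep))
        for pop in populations
        for ri, ratio in enumerate(ratios)
        for rep in range(n_repeats)
    ]
    assert len(out) == len(populations) * len(ratios) * n_repeats
    return out


def split_train_test(d: Dataset, train_fraction: float, seed: int):
    """Seeded record-level split: floor(train_fraction * N) training records,
    the rest test; disjoint and exhaustive."""
    if not 0 < train_fraction < 1:
        raise ValueError("train fraction outside (0,1)")
    n = d.n_records
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split of {n} records at {train_fraction} leaves an empty side")
    perm = np.random.default_rng(seed).permutation(n)
    return d.subset_records(np.sort(perm[:n_train])), d.subset_records(np.sort(perm[n_train:]))


# ---------------------------------------------------------------------------
# metrics / ensemble algebra
# ---------------------------------------------------------------------------

def pearson_r(pred, obs) -> float:
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(pred, obs)[0, 1])


def mse(pred, obs) -> float:
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("length mismatch")
    return float(np.mean((pred - obs) ** 2))


def ensemble_predict(per_model_predictions) -> np.ndarray:
    """Equal-weight element-wise mean of the individual model predictions."""
    preds = [np.asarray(p, float) for p in per_model_predictions]
    if not preds:
        raise ValueError("need at least one model")
    if len({p.shape for p in preds}) != 1:
        raise ValueError("misaligned prediction vectors")
    return np.mean(preds, axis=0)


def diversity_decomposition(per_model_predictions, obs):
    """(ensemble squared error, mean individual squared error, diversity);
    the first equals the second minus the third, exactly."""
    preds = [np.asarray(p, float) for p in per_model_predictions]
    if len(preds) < 2:
        raise ValueError("need at least two models")
    obs = np.asarray(obs, float)
    ens = ensemble_predict(preds)
    ens_err = float(np.mean((ens - obs) ** 2))
    ind_err = float(np.mean([(p - obs) ** 2 for p in preds]))
    diversity = float(np.mean([(p - ens) ** 2 for p in preds]))
    return ens_err, ind_err, diversity


def normalize_effects(profile: attr.MarkerEffectProfile) -> attr.MarkerEffectProfile:
    """Magnitude min-max normalization to [0, 1] within one scenario x model;
    a constant profile maps to all zeros."""
    a = np.abs(profile.scores)
    lo, hi = a.min(), a.max()
    scaled = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    return attr.MarkerEffectProfile(profile.model, list(profile.marker_names), scaled,
                                    profile.scenario, {**profile.metadata, "normalized": True})


def ensemble_effects(per_model_normalized_profiles) -> attr.MarkerEffectProfile:
    """Arithmetic mean of the normalized per-model profiles, tagged Ensemble."""
    profiles = list(per_model_normalized_profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    names = profiles[0].marker_names
    for p in profiles[1:]:
        if list(p.marker_names) != list(names):
            raise ValueError("marker sets differ between profiles")
    scores = np.mean([p.scores for p in profiles], axis=0)
    return attr.MarkerEffectProfile("Ensemble", list(names), scores,
                                    profiles[0].scenario, {"n_models": len(profiles)})


# ---------------------------------------------------------------------------
# per-scenario execution
# ---------------------------------------------------------------------------

DEFAULT_MODELS = ("rrBLUP", "BayesB", "RKHS", "RF", "SVR", "GAT")


def run_scenario(d: Dataset, scenario: PredictionScenario, models=DEFAULT_MODELS,
                 model_params: dict | None = None, attribution_params: dict | None = None,
                 ld_params: dict | None = None, gmap: GeneticMap | None = None,
                 compute_interactions: bool = True) -> ScenarioResult:
    """Fit every configured model on one seeded split and collect
    predictions, metrics, marker effects and forest interactions."""
    model_params = dict(model_params or {})
    ap = {"shapley_n_samples": 30, "shapley_max_test": 20, "max_background": 20,
          "ig_m": 64, "ig_baseline": "mean", "interaction_n_samples": 8,
          "interaction_screen_top": 15, **(attribution_params or {})}

    train, test = split_train_test(d, scenario.train_fraction, scenario.seed)
    if ld_params is not None:
        pruned = ld_prune(train, gmap=gmap, **ld_params)
        train = pruned
        test = test.select_markers(pruned.marker_names)

    rng = np.random.default_rng(scenario.seed)
    test_sub = test
    if test.n_records > ap["shapley_max_test"]:
        idx = np.sort(rng.choice(test.n_records, size=ap["shapley_max_test"], replace=False))
        test_sub = test.subset_records(idx)

    predictions, metrics, effects = {}, {}, {}
    interactions = None
    for name in models:
        if name not in MODEL_FITTERS:
            raise ValueError(f"unknown model {name!r}")
        params = dict(model_params.get(name, {}))
        if name in ("BayesB", "RF", "GAT"):
            params.setdefault("seed", scenario.seed)
        fit = MODEL_FITTERS[name](train, **params)
        pred_train, pred_test = fit.predict(train), fit.predict(test)
        predictions[name] = {"train": pred_train, "test": pred_test}
        metrics[name] = {"pearson_r": pearson_r(pred_test, test.y),
                         "mse": mse(pred_test, test.y)}

        if isinstance(fit, LinearModelFit):
            prof = attr.coef_effects(fit, scenario.id)
        elif name == "RF":
            prof = attr.impurity_importance(fit, scenario.id)
            if compute_interactions:
                interactions = attr.pairwise_interactions(
                    fit, test_sub, train=train, mode="sampled",
                    n_samples=ap["interaction_n_samples"], seed=scenario.seed,
                    max_background=ap["max_background"],
                    screen_top=ap["interaction_screen_top"])
        elif isinstance(fit, GATFit):
            spec = attr.make_ig_spec(train, fit, baseline=ap["ig_baseline"], m=ap["ig_m"])
            prof = attr.integrated_gradients(fit, test_sub, spec, scenario.id)
        else:  # RKHS, SVR: sampled Shapley
            prof = attr.shapley_effects(fit, test_sub, train=train, mode="sampled",
                                        n_samples=ap["shapley_n_samples"],
                                        seed=scenario.seed,
                                        max_background=ap["max_background"],
                                        scenario=scenario.id)
        prof.model = name
        effects[name] = prof

    ens_prof = ensemble_effects([normalize_effects(p) for p in effects.values()])
    ens_prof.scenario = scenario.id

    ens_test = ensemble_predict([predictions[m]["test"] for m in models])
    ens_train = ensemble_predict([predictions[m]["train"] for m in models])
    predictions["Ensemble"] = {"train": ens_train, "test": ens_test}
    metrics["Ensemble"] = {"pearson_r": pearson_r(ens_test, test.y),
                           "mse": mse(ens_test, test.y)}
    if len(models) >= 2:
        e, i, v = diversity_decomposition([predictions[m]["test"] for m in models], test.y)
        assert abs(e - (i - v)) < 1e-8 * max(1.0, abs(i))
        metrics["Ensemble"]["diversity"] = v
        metrics["Ensemble"]["mean_individual_mse"] = i

    return ScenarioResult(scenario, list(train.marker_names), predictions, metrics,
                          effects, ens_prof, interactions)


def aggregate_scenarios(results) -> AggregateResult:
    """Average effects (raw per model, normalized for the ensemble ring) and
    interactions across scenarios, skipping markers absent from a scenario."""
    results = list(results)
    if not results:
        raise ValueError("no scenario results to aggregate")

    rows = []
    for r in results:
        for model, prof in r.effects.items():
            for mk, sc in zip(prof.marker_names, prof.scores):
                rows.append((mk, model, r.scenario.id, sc))
        for mk, sc in zip(r.ensemble_effects.marker_names, r.ensemble_effects.scores):
            rows.append((mk, "Ensemble", r.scenario.id, sc))
    df = pd.DataFrame(rows, columns=["marker", "model", "scenario", "score"])
    wide = df.pivot_table(index="marker", columns="model", values="score", aggfunc="mean")
    presence = df[df.model == "Ensemble"].groupby("marker").size()

    ints = [r.interactions for r in results if r.interactions is not None]
    mean_int = None
    if ints:
        frames = []
        for im in ints:
            n = len(im.marker_names)
            iu = np.triu_indices(n, 1)
            frames.append(pd.DataFrame({
                "a": [im.marker_names[i] for i in iu[0]],
                "b": [im.marker_names[j] for j in iu[1]],
                "score": im.M[iu]}))
        pool = pd.concat(frames).groupby(["a", "b"], as_index=False)["score"].mean()
        names = sorted(set(pool.a) | set(pool.b))
        pos = {m: i for i, m in enumerate(names)}
        M = np.zeros((len(names), len(names)))
        for rec in pool.itertuples():
            M[pos[rec.a], pos[rec.b]] = M[pos[rec.b], pos[rec.a]] = rec.score
        mean_int = attr.InteractionMatrix(names, M, {"n_scenarios": len(ints)})

    metric_rows = [
        {"scenario": r.scenario.id, "population": r.scenario.population,
         "train_fraction": r.scenario.train_fraction, "repeat": r.scenario.repeat,
         "model": model, **vals}
        for r in results for model, vals in r.metrics.items()
    ]
    ens = wide["Ensemble"] if "Ensemble" in wide else wide.mean(axis=1)
    per_model = wide.drop(columns=["Ensemble"], errors="ignore")
    return AggregateResult(per_model, ens, presence, mean_int,
                           pd.DataFrame(metric_rows))


def run_pipeline(d: Dataset, scenarios, models=DEFAULT_MODELS, **kwargs) -> AggregateResult:
    """Run every scenario (subsetting the dataset to each scenario's
    population) and aggregate."""
    results = []
    for sc in scenarios:
        rows = np.where(d.population == sc.population)[0]
        sub = d.subset_records(rows) if rows.size else d
        results.append(run_scenario(sub, sc, models=models, **kwargs))
    return aggregate_scenarios(results)
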