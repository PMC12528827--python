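"""Per-marker effect estimation and pairwise interaction scores.

Four routes, matched to the model family they explain:

* ``coef_effects`` — allele-substitution effects read directly off a
  linear fit (rrBLUP, BayesB);
* ``shapley_effects`` — game-theoretic attributions for black-box models
  (RKHS, SVR), exact by subset enumeration for small marker counts or by
  seeded (antithetic) permutation sampling otherwise;
* ``impurity_importance`` — normalized split-criterion importance of the
  random forest;
* ``integrated_gradients`` — path-integral attributions for the graph
  attention network, using its analytic input gradients.

Pairwise marker-by-marker interactions use the Shapley interaction index
(pair-coalition contribution minus the two singleton contributions) on the
forest, exact for small marker counts and subset-sampled otherwise.

"Absent" features are marginalized interventionally: predictions are
averaged over a background sample of training genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset
from .predictors.gat import GATFit
from .predictors.linear import LinearModelFit

EXACT_SHAPLEY_MAX_P = 12
EXACT_INTERACTION_MAX_P = 10
DEFAULT_BACKGROUND = 100


@dataclass
class MarkerEffectProfile:
    """Per-marker scores from one model in one prediction scenario."""

    model: str
    marker_names: list
    scores: np.ndarray
    scenario: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.marker_names):
            raise ValueError("one score per marker required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite effect score")


@dataclass
class InteractionMatrix:
    """Symmetric marker x marker pairwise interaction scores (diagonal zero)."""

    marker_names: list
    M: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.marker_names),) * 2:
            raise ValueError("matrix shape does not match marker count")
        if not np.allclose(self.M, self.M.T, atol=1e-10):
            raise ValueError("interaction matrix must be symmetric")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("non-finite interaction score")


@dataclass
class IGSpec:
    """Baseline and step count for integrated gradients."""

    baseline: np.ndarray
    m: int = 64

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.m < 1:
            raise ValueError("need at least one interpolation step")


# ---------------------------------------------------------------------------
# coalition machinery
# ---------------------------------------------------------------------------

class CoalitionGame:
    """Value function v(S) = E_background f(x with features outside S replaced),
    evaluated per test record, with caching and batched prediction."""

    def __init__(self, predict, X_test, background, chunk_masks: int = 64):
        self.predict = predict
        self.X = np.atleast_2d(np.asarray(X_test, dtype=float))
        self.bg = np.atleast_2d(np.asarray(background, dtype=float))
        if self.X.shape[1] != self.bg.shape[1]:
            raise ValueError("test and background feature dimensions differ")
        self.p = self.X.shape[1]
        self._cache: dict[int, np.ndarray] = {}
        self.chunk = chunk_masks

    def values(self, masks) -> np.ndarray:
        """Return v(S) for each bitmask, shape (len(masks), n_test)."""
        todo = sorted({m for m in masks if m not in self._cache})
        nt, nb, p = self.X.shape[0], self.bg.shape[0], self.p
        for start in range(0, len(todo), self.chunk):
            batch = todo[start:start + self.chunk]
            block = np.broadcast_to(self.bg[None, None, :, :],
                                    (len(batch), nt, nb, p)).copy()
            for k, mask in enumerate(batch):
                cols = [j for j in range(p) if mask >> j & 1]
                block[k, :, :, cols] = self.X[:, cols].T[:, :, None]
            preds = self.predict(block.reshape(-1, p)).reshape(len(batch), nt, nb)
            for k, mask in enumerate(batch):
                self._cache[mask] = preds[k].mean(axis=1)
        return np.stack([self._cache[m] for m in masks])

    def value(self, mask: int) -> np.ndarray:
        return self.values([mask])[0]


def _background_from(train: Dataset | np.ndarray, model, max_rows: int, seed: int) -> np.ndarray:
    if isinstance(train, Dataset):
        B = train.features(use_replicate=getattr(model, "use_replicate", False))
    else:
        B = np.atleast_2d(np.asarray(train, dtype=float))
    if B.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        B = B[rng.choice(B.shape[0], size=max_rows, replace=False)]
    return B


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

def exact_shapley(predict, X_test, background) -> np.ndarray:
    """Per-record Shapley values by full subset enumeration (p <= 12).

    Returns an (n_test, p) array satisfying the efficiency axiom:
    each row sums to f(x) - mean background prediction.
    """
    game = CoalitionGame(predict, X_test, background)
    p = game.p
    if p > EXACT_SHAPLEY_MAX_P:
        raise ValueError(
            f"exact Shapley limited to {EXACT_SHAPLEY_MAX_P} features (got {p}); "
            "use mode='sampled'")
    all_masks = list(range(1 << p))
    V = game.values(all_masks)                     # (2^p, n_test)
    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros((game.X.shape[0], p))
    for mask in all_masks:
        s = bin(mask).count("1")
        for i in range(p):
            if mask >> i & 1:
                continue
            w = fact[s] * fact[p - s - 1] / fact[p]
            phi[:, i] += w * (V[mask | (1 << i)] - V[mask])
    return phi


def sampled_shapley(predict, X_test, background, n_samples: int = 2000,
                    seed: int = 0, antithetic: bool = True):
    """Permutation-sampling Shapley estimate.

    Each draw walks one random feature ordering (and, antithetically, its
    reverse), crediting every feature its marginal contribution. Returns
    (per-record values (n_test, p), Monte-Carlo SEs of the per-feature
    test-set means).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    game = CoalitionGame(predict, X_test, background)
    p, nt = game.p, game.X.shape[0]
    rng = np.random.default_rng(seed)
    contribs = []                                   # per permutation: (nt, p)
    n_perms = n_samples
    for _ in range(n_perms):
        perm = rng.permutation(p)
        orders = [perm, perm[::-1]] if antithetic else [perm]
        draw = np.zeros((nt, p))
        for order in orders:
            masks = [0]
            m = 0
            for j in order:
                m |= 1 << int(j)
                masks.append(m)
            V = game.values(masks)
            deltas = V[1:] - V[:-1]                 # (p, nt)
            for k, j in enumerate(order):
                draw[:, int(j)] += deltas[k] / len(orders)
        contribs.append(draw)
    arr = np.stack(contribs)                        # (n_perms, nt, p)
    phi = arr.mean(axis=0)
    per_perm_mean = arr.mean(axis=1)                # (n_perms, p): test-set mean per draw
    se = per_perm_mean.std(axis=0, ddof=1) / np.sqrt(n_perms) if n_perms > 1 else \
        np.full(p, np.inf)
    return phi, se


def shapley_effects(model, test: Dataset, train: Dataset | np.ndarray | None = None,
                    mode: str = "sampled", n_samples: int = 2000, seed: int = 0,
                    max_background: int = DEFAULT_BACKGROUND,
                    scenario: str = "") -> MarkerEffectProfile:
    """Mean Shapley value over test records for every marker.

    ``train`` supplies the background for interventional marginalization
    (defaults to the test genotypes when omitted).
    """
    X_test = test.features(use_replicate=getattr(model, "use_replicate", False))
    bg = _background_from(train if train is not None else test, model, max_background, seed)
    if mode == "exact":
        phi = exact_shapley(model.predict_matrix, X_test, bg)
        se = None
    elif mode == "sampled":
        phi, se = sampled_shapley(model.predict_matrix, X_test, bg,
                                  n_samples=n_samples, seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nm = len(test.marker_names)
    meta = {"mode": mode, "n_samples": n_samples if mode == "sampled" else None,
            "seed": seed, "n_background": bg.shape[0]}
    if se is not None:
        meta["mc_se"] = se[:nm]
    return MarkerEffectProfile(getattr(model, "tag", "model"), list(test.marker_names),
                               phi.mean(axis=0)[:nm], scenario, meta)


# ---------------------------------------------------------------------------
# direct / impurity / integrated gradients
# ---------------------------------------------------------------------------

def coef_effects(fit, scenario: str = "") -> MarkerEffectProfile:
    """Allele-substitution effects of a linear fit, used verbatim as scores."""
    if not isinstance(fit, LinearModelFit):
        raise TypeError(f"coef_effects requires a linear fit, got {type(fit).__name__}")
    return MarkerEffectProfile(fit.tag, list(fit.marker_names), fit.beta.copy(),
                               scenario, {"mode": "exact"})


def impurity_importance(fit, scenario: str = "") -> MarkerEffectProfile:
    """Forest impurity importance over markers, renormalized to sum to one."""
    if getattr(fit, "tag", None) != "RF":
        raise TypeError("impurity_importance requires a random-forest fit")
    imp = np.asarray(fit.estimator.feature_importances_, dtype=float)
    nm = len(fit.marker_names)
    imp = imp[:nm]                      # drop the replicate feature if present
    total = imp.sum()
    if total > 0:
        imp = imp / total
    else:
        imp = np.full(nm, 1.0 / nm)
    return MarkerEffectProfile("RF", list(fit.marker_names), imp, scenario,
                               {"mode": "exact"})


def make_ig_spec(reference: Dataset, model, baseline: str = "mean", m: int = 64) -> IGSpec:
    """Build an IG baseline from a reference dataset: the population-mean
    feature vector (default) or all-zeros."""
    X = reference.features(use_replicate=getattr(model, "use_replicate", False))
    if baseline == "mean":
        b = X.mean(axis=0)
    elif baseline == "zero":
        b = np.zeros(X.shape[1])
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    return IGSpec(baseline=b, m=m)


def integrated_gradients_matrix(grad_fn, X, baseline, m: int) -> np.ndarray:
    """Riemann-sum IG along the straight path baseline -> x:
    (x - x') * mean_{k=1..m} grad(x' + (k/m)(x - x'))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (X.shape[1],):
        raise ValueError("baseline dimension does not match features")
    diff = X - baseline[None, :]
    acc = np.zeros_like(X)
    for k in range(1, m + 1):
        acc += grad_fn(baseline[None, :] + (k / m) * diff)
    return diff * acc / m


def integrated_gradients(fit: GATFit, test: Dataset, spec: IGSpec,
                         scenario: str = "") -> MarkerEffectProfile:
    """Mean integrated-gradients attribution over test records per marker."""
    X = test.features(use_replicate=fit.use_replicate)
    attr = integrated_gradients_matrix(fit.input_gradients, X, spec.baseline, spec.m)
    nm = len(test.marker_names)
    return MarkerEffectProfile(fit.tag, list(test.marker_names), attr.mean(axis=0)[:nm],
                               scenario, {"mode": "exact", "m": spec.m})


# ---------------------------------------------------------------------------
# pairwise interactions
# ---------------------------------------------------------------------------

def _pair_weight(s: int, p: int) -> float:
    return (math.factorial(s) * math.factorial(p - s - 2)) / math.factorial(p - 1)


def exact_pairwise_interactions(predict, X_test, background) -> np.ndarray:
    """Shapley interaction index by full enumeration (p <= 10): for pair
    (i, j), the weighted sum over S of f(S+ij) - f(S+i) - f(S+j) + f(S)."""
    game = CoalitionGame(predict, X_test, background)
    p = game.p
    if p > EXACT_INTERACTION_MAX_P:
        raise ValueError(
            f"exact interactions limited to {EXACT_INTERACTION_MAX_P} features "
            f"(got {p}); use mode='sampled'")
    V = game.values(list(range(1 << p)))
    nt = game.X.shape[0]
    M = np.zeros((nt, p, p))
    for i in range(p):
        for j in range(i + 1, p):
            bi, bj = 1 << i, 1 << j
            acc = np.zeros(nt)
            for mask in range(1 << p):
                if mask & (bi | bj):
                    continue
                s = bin(mask).count("1")
                acc += _pair_weight(s, p) * (V[mask | bi | bj] - V[mask | bi]
                                             - V[mask | bj] + V[mask])
            M[:, i, j] = M[:, j, i] = acc
    return M.mean(axis=0)


def sampled_pairwise_interactions(predict, X_test, background, pairs=None,
                                  n_samples: int = 30, seed: int = 0) -> np.ndarray:
    """Subset-sampling estimate of the Shapley interaction index.

    The index equals the expectation of the second difference under a
    uniformly random coalition size s in {0..p-2} and a uniform size-s
    subset, so sampling is a draw of (s, S) per replicate. ``pairs``
    restricts estimation to candidate pairs (others stay zero).
    """
    game = CoalitionGame(predict, X_test, background)
    p = game.p
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    M = np.zeros((p, p))
    others_cache = {}
    for (i, j) in pairs:
        key = (i, j)
        others = others_cache.setdefault(key, np.array(
            [k for k in range(p) if k not in (i, j)], dtype=int))
        bi, bj = 1 << i, 1 << j
        masks = []
        for _ in range(n_samples):
            s = int(rng.integers(0, p - 1))        # uniform on 0..p-2
            S = rng.choice(others, size=s, replace=False) if s else []
            base = 0
            for k in S:
                base |= 1 << int(k)
            masks.extend([base, base | bi, base | bj, base | bi | bj])
        V = game.values(masks)
        delta = np.zeros(game.X.shape[0])
        for t in range(n_samples):
            b0, vi, vj, vij = V[4 * t: 4 * t + 4]
            delta += vij - vi - vj + b0
        M[i, j] = M[j, i] = float((delta / n_samples).mean())
    return M


def pairwise_interactions(fit, test: Dataset, train: Dataset | np.ndarray | None = None,
                          mode: str = "sampled", n_samples: int = 30, seed: int = 0,
                          max_background: int = DEFAULT_BACKGROUND,
                          screen_top: int | None = None) -> InteractionMatrix:
    """Pairwise marker-by-marker interaction scores from the forest.

    ``screen_top`` optionally restricts the sampled estimator to pairs among
    the top-k markers by impurity importance (the rest are exact zeros);
    the full symmetric matrix over markers is always returned.
    """
    if getattr(fit, "tag", None) != "RF":
        raise TypeError("pairwise_interactions requires a random-forest fit")
    X_test = test.features(use_replicate=fit.use_replicate)
    bg = _background_from(train if train is not None else test, fit, max_background, seed)
    nm = len(test.marker_names)
    if mode == "exact":
        M = exact_pairwise_interactions(fit.predict_matrix, X_test, bg)
    elif mode == "sampled":
        pairs = None
        if screen_top is not None and screen_top < nm:
            imp = np.asarray(fit.estimator.feature_importances_)[:nm]
            top = np.sort(np.argsort(imp)[::-1][:screen_top])
            pairs = [(int(a), int(b)) for ai, a in enumerate(top) for b in top[ai + 1:]]
        M = sampled_pairwise_interactions(fit.predict_matrix, X_test, bg, pairs=pairs,
                                          n_samples=n_samples, seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    M = M[:nm, :nm]
    np.fill_diagonal(M, 0.0)
    return InteractionMatrix(list(test.marker_names), M,
                             {"mode": mode, "seed": seed, "n_samples": n_samples})


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_effects_tsv(profiles, path) -> None:
    import pandas as pd
    rows = [(m, p.model, p.scenario, s)
            for p in profiles for m, s in zip(p.marker_names, p.scores)]
    pd.DataFrame(rows, columns=["marker", "model", "scenario", "score"]).to_csv(
        path, sep="\t", index=False)


def write_interactions_tsv(im: InteractionMatrix, path) -> None:
    import pandas as pd
    names = im.marker_names
    rows = [(names[i], names[j], im.M[i, j])
            for i in range(len(names)) for j in range(i + 1, len(names))]
    pd.DataFrame(rows, columns=["marker_a", "marker_b", "score"]).to_csv(
        path, sep="\t", index=False)
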