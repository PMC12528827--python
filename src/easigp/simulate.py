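"""Synthetic BC1S4 RIL populations with a known genetic architecture.

The cross design mirrors a biparental RIL panel: F1 = recurrent x donor,
one backcross to the recurrent parent, then four selfing generations by
single-seed descent. Crossovers follow map distances under the Haldane
function (no interference). Dosage codes count donor alleles (0/1/2).

The simulated trait is a sum of additive QTL effects, additive-by-additive
epistatic products of centered dosages, a replicate shift and Gaussian
noise scaled so the realized narrow-plus-epistatic heritability matches
the target. Each RIL appears twice, once per replicate (factor 0/1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import AnnotationTrack, Dataset, GeneticMap


@dataclass
class TruthArchitecture:
    """Known causal structure of a simulated trait."""

    additive_idx: list
    additive_effects: list
    epistatic_pairs: list = field(default_factory=list)      # [(i, j), ...]
    epistatic_effects: list = field(default_factory=list)
    h2: float = 0.7
    replicate_effect_sd: float = 0.25    # shift in units of phenotypic SD
    # filled by the simulator:
    genetic_values: np.ndarray | None = None
    noise_sd: float | None = None
    marker_names: list | None = None

    def __post_init__(self):
        if not 0 < self.h2 <= 1:
            raise ValueError("target h2 must be in (0, 1]")
        if len(self.additive_idx) != len(self.additive_effects):
            raise ValueError("additive effect list misaligned")
        if len(self.epistatic_pairs) != len(self.epistatic_effects):
            raise ValueError("epistatic effect list misaligned")

    def causal_markers(self) -> list:
        idx = set(self.additive_idx)
        for i, j in self.epistatic_pairs:
            idx.update((i, j))
        return sorted(idx)

    def to_json(self) -> str:
        d = asdict(self)
        d["genetic_values"] = None if self.genetic_values is None else list(self.genetic_values)
        return json.dumps(d, indent=2)


@dataclass
class SimConfig:
    n_ril: int = 200
    p: int = 100
    chromosomes: int = 10
    length_cM: float = 150.0
    seed: int = 0
    population: str = "SIM1"

    def __post_init__(self):
        if self.n_ril < 2 or self.p < 1:
            raise ValueError("need n_ril >= 2 and p >= 1")
        if self.p < self.chromosomes:
            raise ValueError("need at least one marker per chromosome")


def simulate_map(chromosomes: int, length_cM: float, p: int, seed: int = 0) -> GeneticMap:
    """Place ``p`` markers uniformly at random over equal-length chromosomes,
    sorted within each chromosome; names follow map order."""
    if p < chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = np.random.default_rng(seed)
    per = np.full(chromosomes, p // chromosomes)
    per[: p % chromosomes] += 1
    positions, lengths = {}, {}
    k = 0
    for c in range(1, chromosomes + 1):
        pos = np.sort(rng.uniform(0, length_cM, size=per[c - 1]))
        for x in pos:
            k += 1
            positions[f"M{k:04d}"] = (c, float(x))
        lengths[c] = float(length_cM)
    return GeneticMap(positions=positions, chromosome_lengths=lengths)


def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def _chrom_blocks(gmap: GeneticMap, markers: list):
    """Per chromosome: (marker index array, adjacent recombination fractions)."""
    blocks = []
    by_chrom = {}
    for j, m in enumerate(markers):
        by_chrom.setdefault(gmap.chrom(m), []).append(j)
    for c in sorted(by_chrom):
        idx = np.array(by_chrom[c])
        pos = np.array([gmap.pos(markers[j]) for j in idx])
        order = np.argsort(pos, kind="stable")
        idx = idx[order]
        r = _haldane_r(np.diff(pos[order]))
        blocks.append((idx, r))
    return blocks


def _gametes(h1: np.ndarray, h2: np.ndarray, blocks, rng, n: int) -> np.ndarray:
    """Draw ``n`` gametes per row of the (n, p) parental haplotype pair."""
    p = h1.shape[1]
    out = np.empty((n, p), dtype=np.int8)
    for idx, r in blocks:
        start = rng.integers(0, 2, size=n)
        if len(idx) > 1:
            switch = rng.random((n, len(idx) - 1)) < r[None, :]
            phase = (start[:, None] + np.concatenate(
                [np.zeros((n, 1), dtype=int), np.cumsum(switch, axis=1)], axis=1)) % 2
        else:
            phase = start[:, None]
        rows = np.arange(n)[:, None]
        out[:, idx] = np.where(phase == 0, h1[rows, idx[None, :]], h2[rows, idx[None, :]])
    return out


def simulate_genotypes(cfg: SimConfig, gmap: GeneticMap, rng=None) -> tuple[np.ndarray, list]:
    """BC1S4 dosage matrix (n_ril x p, donor-allele count) and marker order."""
    rng = rng or np.random.default_rng(cfg.seed)
    markers = sorted(gmap.positions, key=lambda m: (gmap.chrom(m), gmap.pos(m)))
    blocks = _chrom_blocks(gmap, markers)
    n, p = cfg.n_ril, len(markers)

    donor = np.ones((n, p), dtype=np.int8)
    recurrent = np.zeros((n, p), dtype=np.int8)
    # F1: one donor + one recurrent haplotype; BC1: F1 gamete x recurrent
    h1 = _gametes(donor, recurrent, blocks, rng, n)
    h2 = np.zeros((n, p), dtype=np.int8)
    for _ in range(4):  # selfing by single-seed descent
        g1 = _gametes(h1, h2, blocks, rng, n)
        g2 = _gametes(h1, h2, blocks, rng, n)
        h1, h2 = g1, g2
    return (h1 + h2).astype(np.int8), markers


def genetic_values(G: np.ndarray, truth: TruthArchitecture) -> np.ndarray:
    g = np.zeros(G.shape[0])
    for j, a in zip(truth.additive_idx, truth.additive_effects):
        g = g + a * G[:, j]
    center = G.mean(axis=0)
    for (i, j), w in zip(truth.epistatic_pairs, truth.epistatic_effects):
        g = g + w * (G[:, i] - center[i]) * (G[:, j] - center[j])
    return g


def simulate_ril_population(cfg: SimConfig, truth: TruthArchitecture,
                            gmap: GeneticMap | None = None):
    """Simulate genotypes and a two-replicate phenotype with the target
    heritability; returns (Dataset, truth with realized components filled)."""
    rng = np.random.default_rng(cfg.seed)
    if gmap is None:
        gmap = simulate_map(cfg.chromosomes, cfg.length_cM, cfg.p, seed=cfg.seed)
    G, markers = simulate_genotypes(cfg, gmap, rng)
    for j in truth.causal_markers():
        if not 0 <= j < G.shape[1]:
            raise ValueError(f"causal index {j} out of range")

    g = genetic_values(G, truth)
    var_g = float(np.var(g))
    if truth.h2 < 1 and var_g == 0:
        raise ValueError("zero genetic variance: target h2 unreachable")
    noise_sd = 0.0 if truth.h2 >= 1 else float(np.sqrt(var_g * (1 - truth.h2) / truth.h2))
    pheno_sd = float(np.sqrt(var_g + noise_sd ** 2)) or 1.0
    rep_shift = truth.replicate_effect_sd * pheno_sd

    n = cfg.n_ril
    y0 = g + rng.normal(0, noise_sd, size=n)
    y1 = g + rep_shift + rng.normal(0, noise_sd, size=n)
    ids = [f"RIL{k + 1:04d}" for k in range(n)]
    d = Dataset(
        ids=ids + ids,
        population=np.array([cfg.population] * 2 * n, dtype=object),
        G=np.vstack([G, G]),
        marker_names=markers,
        y=np.concatenate([y0, y1]),
        replicate=np.array([0] * n + [1] * n),
    )
    truth.genetic_values = np.concatenate([g, g])
    truth.noise_sd = noise_sd
    truth.marker_names = [markers[j] for j in truth.causal_markers()]
    return d, truth


def realized_h2(d: Dataset, truth: TruthArchitecture) -> float:
    """Share of phenotypic variance explained by the simulated genetic values."""
    if truth.genetic_values is None:
        raise ValueError("truth has no realized genetic values; run the simulator first")
    var_y = float(np.var(d.y))
    if var_y == 0:
        return 0.0
    return float(np.var(truth.genetic_values) / var_y)


def truth_annotations(truth: TruthArchitecture, gmap: GeneticMap,
                      pad_cM: float = 1.0) -> AnnotationTrack:
    """Truth regions as a pseudo-QTL annotation track."""
    regions = []
    names = truth.marker_names or []
    for k, m in enumerate(names):
        c, pos = gmap.positions[m]
        L = gmap.chromosome_lengths[c]
        regions.append((c, max(0.0, pos - pad_cM), min(L, pos + pad_cM),
                        f"Q{k + 1}", "simulated"))
    return AnnotationTrack(name="QTL", regions=regions)
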