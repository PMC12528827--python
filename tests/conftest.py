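import numpy as np
import pytest

from easigp import simulate
from easigp.data_io import Dataset


def make_dataset(G, y, population="P", replicate=None, ids=None, marker_names=None):
    G = np.asarray(G)
    n, p = G.shape
    return Dataset(
        ids=ids or [f"R{i + 1}" for i in range(n)],
        population=np.array([population] * n, dtype=object),
        G=G,
        marker_names=marker_names or [f"m{j + 1}" for j in range(p)],
        y=np.asarray(y, dtype=float),
        replicate=np.zeros(n, dtype=int) if replicate is None else np.asarray(replicate, int),
    )


@pytest.fixture(scope="session")
def ril_genotypes():
    """400 BC1S4 RILs, 100 loosely linked markers (20 chromosomes)."""
    cfg = simulate.SimConfig(n_ril=400, p=100, chromosomes=20, length_cM=300.0, seed=7)
    gmap = simulate.simulate_map(20, 300.0, 100, seed=7)
    G, markers = simulate.simulate_genotypes(cfg, gmap)
    return G, markers, gmap


@pytest.fixture(scope="session")
def additive_dataset(ril_genotypes):
    """Dense additive trait at h2 = 0.9 with known effects."""
    G, markers, _ = ril_genotypes
    rng = np.random.default_rng(7)
    beta = rng.normal(0, 1, G.shape[1])
    g = G @ beta
    y = g + rng.normal(0, np.sqrt(np.var(g) * (1 - 0.9) / 0.9), G.shape[0])
    return make_dataset(G, y, marker_names=markers), beta


@pytest.fixture(scope="session")
def qtl1_dataset(ril_genotypes):
    """One causal marker (index 3 of the first 10 markers), h2 = 0.9."""
    G, markers, _ = ril_genotypes
    G10 = G[:200, :10]
    rng = np.random.default_rng(11)
    g = 2.0 * G10[:, 3]
    y = g + rng.normal(0, np.sqrt(np.var(g) * (1 - 0.9) / 0.9), 200)
    return make_dataset(G10, y, marker_names=markers[:10]), 3


@pytest.fixture(scope="session")
def epistatic_sim():
    """150-RIL, 60-marker, 2-QTL + 1-epistatic-pair simulation with map."""
    cfg = simulate.SimConfig(n_ril=150, p=60, chromosomes=10, length_cM=150.0, seed=3)
    gmap = simulate.simulate_map(10, 150.0, 60, seed=3)
    truth = simulate.TruthArchitecture(
        additive_idx=[10, 40], additive_effects=[1.2, 1.0],
        epistatic_pairs=[(20, 50)], epistatic_effects=[3.0], h2=0.8)
    d, truth = simulate.simulate_ril_population(cfg, truth, gmap=gmap)
    return d, truth, gmap
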