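"""Tabular I/O and genotype preprocessing.

Reads the dataset CSV (``id,population,replicate,<markers...>,<phenotype>``),
genetic-map and annotation TSVs, and implements the three preprocessing
steps applied before model fitting: per-population modal imputation with
high-missingness marker exclusion, removal of records lacking a phenotype,
and greedy windowed LD pruning on squared dosage correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype call. Never a valid dosage.
MISSING = -1

RESERVED_COLUMNS = ("id", "population", "replicate")


@dataclass
class Dataset:
    """Aligned genotypes, phenotypes and record metadata.

    Attributes
    ----------
    ids : list of str
        Record identifiers; ``(id, replicate)`` pairs are unique.
    population : ndarray of str
        Population label per record.
    G : ndarray, shape (n_records, n_markers)
        Allele dosages in {0, 1, 2}; :data:`MISSING` marks absent calls.
    marker_names : list of str
        Column labels of ``G`` (unique, order preserved).
    y : ndarray of float
        Phenotype per record; NaN marks a missing value.
    replicate : ndarray of int
        Evaluation factor, 0 or 1.
    """

    ids: list
    population: np.ndarray
    G: np.ndarray
    marker_names: list
    y: np.ndarray
    replicate: np.ndarray

    def __post_init__(self):
        self.G = np.asarray(self.G)
        self.y = np.asarray(self.y, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        self.replicate = np.asarray(self.replicate, dtype=int)
        n = self.G.shape[0]
        if not (len(self.ids) == len(self.y) == len(self.population) == len(self.replicate) == n):
            raise ValueError("record-aligned fields have inconsistent lengths")
        if self.G.shape[1] != len(self.marker_names):
            raise ValueError("marker_names length does not match G columns")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("duplicate marker names")

    @property
    def n_records(self) -> int:
        return self.G.shape[0]

    @property
    def n_markers(self) -> int:
        return self.G.shape[1]

    def subset_records(self, index) -> "Dataset":
        index = np.asarray(index)
        return Dataset(
            ids=[self.ids[i] for i in index],
            population=self.population[index],
            G=self.G[index],
            marker_names=list(self.marker_names),
            y=self.y[index],
            replicate=self.replicate[index],
        )

    def select_markers(self, names) -> "Dataset":
        pos = {m: j for j, m in enumerate(self.marker_names)}
        cols = [pos[m] for m in names]
        return replace(self, G=self.G[:, cols], marker_names=list(names))

    def features(self, use_replicate: bool = False) -> np.ndarray:
        """Model feature matrix: dosages, optionally with the replicate factor appended."""
        X = self.G.astype(float)
        if use_replicate:
            X = np.column_stack([X, self.replicate.astype(float)])
        return X


@dataclass
class GeneticMap:
    """Marker -> (chromosome, position cM) lookup plus chromosome lengths."""

    positions: dict  # marker -> (chrom:int, pos_cM:float)
    chromosome_lengths: dict  # chrom -> length cM

    def __post_init__(self):
        for m, (c, p) in self.positions.items():
            if p < 0:
                raise ValueError(f"negative map position for {m}")
            if c not in self.chromosome_lengths:
                raise ValueError(f"marker {m} on chromosome {c} absent from lengths")
            if p > self.chromosome_lengths[c] + 1e-9:
                raise ValueError(f"marker {m} at {p} cM beyond chromosome {c} length")

    @property
    def chromosomes(self) -> list:
        return sorted(self.chromosome_lengths)

    def __contains__(self, marker) -> bool:
        return marker in self.positions

    def chrom(self, marker) -> int:
        return self.positions[marker][0]

    def pos(self, marker) -> float:
        return self.positions[marker][1]


@dataclass
class AnnotationTrack:
    """Labelled genomic regions for one ring (e.g. QTL, leaf, SAM)."""

    name: str
    regions: list = field(default_factory=list)  # (chrom, start_cM, end_cM, label, pathway)

    def validate(self, gmap: GeneticMap) -> None:
        for chrom, start, end, label, _ in self.regions:
            if start > end:
                raise ValueError(f"region {label}: start {start} > end {end}")
            if chrom not in gmap.chromosome_lengths:
                raise ValueError(f"region {label}: unknown chromosome {chrom}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dataset(path, phenotype=None, gmap=None, marker_prefix=None) -> Dataset:
    """Read a dataset CSV into a :class:`Dataset`.

    Marker columns are identified by membership in ``gmap`` or by
    ``marker_prefix``; with neither, every non-reserved column except the
    last is taken as a marker and the last as the phenotype. Empty genotype
    cells become :data:`MISSING`; empty phenotype cells become NaN.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "population" not in df.columns:
        raise ValueError("dataset CSV must contain 'id' and 'population' columns")
    replicate = df["replicate"].to_numpy(dtype=int) if "replicate" in df.columns else np.zeros(len(df), dtype=int)

    key = list(zip(df["id"], replicate))
    if len(set(key)) != len(key):
        dups = df["id"][pd.Series(key).duplicated()].tolist()
        raise ValueError(f"duplicated record id(s): {sorted(set(dups))}")

    candidates = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if marker_prefix is not None:
        markers = [c for c in candidates if c.startswith(marker_prefix)]
        rest = [c for c in candidates if not c.startswith(marker_prefix)]
    elif gmap is not None:
        markers = [c for c in candidates if c in gmap]
        rest = [c for c in candidates if c not in gmap]
    else:
        markers, rest = candidates[:-1], candidates[-1:]
    if phenotype is None:
        if not rest:
            raise ValueError("no phenotype column identified")
        phenotype = rest[-1]
    elif phenotype in markers:
        markers = [m for m in markers if m != phenotype]

    if gmap is not None:
        orphan = [m for m in markers if m not in gmap]
        if orphan:
            warnings.warn(f"{len(orphan)} marker column(s) not in the genetic map: kept, "
                          "but they cannot be placed on circos rings", stacklevel=2)

    G = df[markers].to_numpy(dtype=float)
    G = np.where(np.isnan(G), MISSING, G).astype(np.int16)
    return Dataset(
        ids=df["id"].tolist(),
        population=df["population"].to_numpy(dtype=object),
        G=G,
        marker_names=markers,
        y=df[phenotype].to_numpy(dtype=float),
        replicate=replicate,
    )


def write_dataset(d: Dataset, path, phenotype="y") -> None:
    df = pd.DataFrame({"id": d.ids, "population": d.population, "replicate": d.replicate})
    gdf = pd.DataFrame(d.G, columns=d.marker_names).astype(object)
    gdf = gdf.mask(pd.DataFrame(d.G == MISSING, columns=d.marker_names))
    df = pd.concat([df, gdf], axis=1)
    df[phenotype] = d.y
    df.to_csv(path, index=False)


def read_genetic_map(path) -> GeneticMap:
    """Read a ``marker<TAB>chrom<TAB>pos_cM`` TSV; chromosome lengths default
    to the maximum observed position per chromosome."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    positions = {str(r.marker): (int(r.chrom), float(r.pos_cm)) for r in df.itertuples()}
    lengths = {}
    for c, p in positions.values():
        lengths[c] = max(lengths.get(c, 0.0), p)
    return GeneticMap(positions=positions, chromosome_lengths=lengths)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = [(m, c, p) for m, (c, p) in gmap.positions.items()]
    pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list:
    """Read annotation TSV (``track chrom start_cM end_cM label pathway``) into tracks."""
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for r in df.itertuples():
        t = tracks.setdefault(str(r.track), AnnotationTrack(name=str(r.track)))
        t.regions.append((int(r.chrom), float(r.start_cM), float(r.end_cM), str(r.label), str(r.pathway)))
    return list(tracks.values())


def write_annotations(tracks, path) -> None:
    rows = [(t.name, c, s, e, l, pw) for t in tracks for (c, s, e, l, pw) in t.regions]
    pd.DataFrame(rows, columns=["track", "chrom", "start_cM", "end_cM", "label", "pathway"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_markers(d: Dataset, max_missing_frac: float = 0.10) -> Dataset:
    """Drop markers with a missing fraction strictly above ``max_missing_frac``,
    then fill remaining missing calls with the modal dosage of the record's
    population at that marker (mode ties broken toward the smaller dosage).
    """
    miss = d.G == MISSING
    frac = miss.mean(axis=0)
    keep = frac <= max_missing_frac
    G = d.G[:, keep].copy()
    names = [m for m, k in zip(d.marker_names, keep) if k]

    for pop in np.unique(d.population):
        rows = np.where(d.population == pop)[0]
        sub = G[rows]
        mj, mi = np.where(sub == MISSING)
        for j in np.unique(mi):
            col = sub[:, j]
            observed = col[col != MISSING]
            if observed.size == 0:
                raise ValueError(f"marker {names[j]} missing for the entire population {pop!r}")
            vals, counts = np.unique(observed, return_counts=True)
            mode = vals[np.argmax(counts)]  # np.unique sorts ascending: ties -> smaller dosage
            col[col == MISSING] = mode
        G[rows] = sub

    dropped = int((~keep).sum())
    if dropped:
        log.info("impute_markers: dropped %d marker(s) above %.0f%% missing", dropped, 100 * max_missing_frac)
    return replace(d, G=G, marker_names=names)


def drop_missing_phenotypes(d: Dataset) -> Dataset:
    keep = np.where(~np.isnan(d.y))[0]
    if keep.size == 0:
        raise ValueError("every record has a missing phenotype")
    return d.subset_records(keep)


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns; monomorphic
    columns get r^2 = 0 against everything."""
    X = G.astype(float)
    sd = X.std(axis=0)
    poly = sd > 0
    r2 = np.zeros((X.shape[1], X.shape[1]))
    if poly.sum() >= 2:
        c = np.corrcoef(X[:, poly], rowvar=False)
        r2[np.ix_(poly, poly)] = np.square(c)
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(d: Dataset, window: int = 30000, step: int = 5,
             r2_threshold: float = 0.8, gmap: GeneticMap | None = None) -> Dataset:
    """Greedy windowed LD pruning on squared dosage correlation.

    Within each window of ``window`` consecutive markers, the later-indexed
    marker of every pair with r^2 > ``r2_threshold`` is removed; the window
    slides forward by ``step`` markers. Windows never span chromosomes when
    a map is supplied. Markers must already be imputed and map-ordered.
    """
    if np.any(d.G == MISSING):
        raise ValueError("ld_prune requires imputed genotypes")
    p = d.n_markers
    if gmap is not None:
        groups = {}
        for j, m in enumerate(d.marker_names):
            groups.setdefault(gmap.chrom(m) if m in gmap else None, []).append(j)
        blocks = [np.array(v) for _, v in sorted(groups.items(), key=lambda kv: (kv[0] is None, kv[0]))]
    else:
        blocks = [np.arange(p)]

    monomorphic = d.G.std(axis=0) == 0
    if monomorphic.any():
        log.info("ld_prune: %d monomorphic marker(s) retained (r^2 defined as 0)",
                 int(monomorphic.sum()))

    alive = np.ones(p, dtype=bool)
    for block in blocks:
        r2 = _r2_matrix(d.G[:, block])
        nb = len(block)
        for start in range(0, max(nb - 1, 1), step):
            idx = [k for k in range(start, min(start + window, nb)) if alive[block[k]]]
            for a_i, ka in enumerate(idx):
                if not alive[block[ka]]:
                    continue
                for kb in idx[a_i + 1:]:
                    if alive[block[kb]] and r2[ka, kb] > r2_threshold:
                        alive[block[kb]] = False
    names = [m for m, a in zip(d.marker_names, alive) if a]
    return d.select_markers(names)


def concat_replicates(d1: Dataset, d2: Dataset) -> Dataset:
    """Stack two evaluations of the same material; rows of ``d1`` get
    replicate 0 and rows of ``d2`` replicate 1."""
    if list(d1.marker_names) != list(d2.marker_names):
        raise ValueError("replicate datasets have different marker sets")
    return Dataset(
        ids=list(d1.ids) + list(d2.ids),
        population=np.concatenate([d1.population, d2.population]),
        G=np.vstack([d1.G, d2.G]) if d2.n_records else d1.G.copy(),
        marker_names=list(d1.marker_names),
        y=np.concatenate([d1.y, d2.y]),
        replicate=np.concatenate([np.zeros(d1.n_records, dtype=int),
                                  np.ones(d2.n_records, dtype=int)]),
    )
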