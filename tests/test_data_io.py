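import numpy as np
import pytest

from easigp import data_io as dio
from easigp.data_io import MISSING, Dataset, GeneticMap

from conftest import make_dataset


def write_csv(tmp_path, text, name="d.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDataset:
    def test_toy_shape(self, tmp_path):
        p = write_csv(tmp_path,
                      "id,population,replicate,m1,m2,m3,y\n"
                      "R1,P,0,0,1,2,5.0\nR2,P,0,1,1,0,6.0\n"
                      "R3,P,0,2,0,1,7.0\nR4,P,0,0,0,0,4.0\n")
        d = dio.read_dataset(p)
        assert d.G.shape == (4, 3)
        assert d.marker_names == ["m1", "m2", "m3"]
        assert list(d.y) == [5.0, 6.0, 7.0, 4.0]

    def test_missing_cell_becomes_sentinel(self, tmp_path):
        p = write_csv(tmp_path,
                      "id,population,replicate,m1,m2,y\nR1,P,0,,1,5.0\nR2,P,0,1,2,6.0\n")
        d = dio.read_dataset(p)
        assert int((d.G == MISSING).sum()) == 1
        assert d.G[0, 0] == MISSING

    def test_duplicate_id_errors(self, tmp_path):
        p = write_csv(tmp_path,
                      "id,population,replicate,m1,y\nR1,P,0,0,5.0\nR1,P,0,1,6.0\n")
        with pytest.raises(ValueError, match="R1"):
            dio.read_dataset(p)

    def test_same_id_different_replicate_ok(self, tmp_path):
        p = write_csv(tmp_path,
                      "id,population,replicate,m1,y\nR1,P,0,0,5.0\nR1,P,1,1,6.0\n")
        d = dio.read_dataset(p)
        assert d.n_records == 2

    def test_marker_not_in_map_warns_but_kept(self, tmp_path):
        p = write_csv(tmp_path,
                      "id,population,replicate,m1,mX,y\nR1,P,0,0,1,5.0\nR2,P,0,1,2,6.0\n")
        gmap = GeneticMap({"m1": (1, 10.0), "mX_other": (1, 20.0)}, {1: 50.0})
        with pytest.warns(UserWarning, match="not in the genetic map"):
            d = dio.read_dataset(p, gmap=gmap, phenotype="y", marker_prefix="m")
        assert "mX" in d.marker_names

    def test_round_trip(self, tmp_path):
        d = make_dataset([[0, 1], [2, MISSING]], [1.0, np.nan])
        out = tmp_path / "rt.csv"
        dio.write_dataset(d, out)
        d2 = dio.read_dataset(out)
        np.testing.assert_array_equal(d.G, d2.G)
        np.testing.assert_array_equal(np.isnan(d.y), np.isnan(d2.y))


class TestImputeMarkers:
    def test_drops_marker_above_threshold(self):
        G = np.zeros((20, 2), dtype=int)
        G[:3, 0] = MISSING  # 15% missing
        d = make_dataset(G, np.ones(20))
        out = dio.impute_markers(d)
        assert out.marker_names == ["m2"]

    def test_mode_imputation(self):
        col = np.array([2] * 12 + [0] * 7 + [MISSING])
        d = make_dataset(col[:, None], np.ones(20))
        out = dio.impute_markers(d)
        assert out.G[19, 0] == 2

    def test_exactly_ten_percent_retained(self):
        G = np.ones((20, 1), dtype=int)
        G[:2, 0] = MISSING  # exactly 10%
        d = make_dataset(G, np.ones(20))
        out = dio.impute_markers(d)
        assert out.n_markers == 1
        assert not (out.G == MISSING).any()

    def test_mode_tie_breaks_to_smaller_dosage(self):
        col = np.array([0] * 5 + [2] * 5 + [MISSING])
        d = make_dataset(col[:, None], np.ones(11))
        out = dio.impute_markers(d, max_missing_frac=0.2)
        assert out.G[10, 0] == 0

    def test_per_population_mode(self):
        G = np.array([[0]] * 5 + [[2]] * 5 + [[MISSING]] + [[2]] * 2)
        pops = np.array(["A"] * 5 + ["B"] * 8, dtype=object)
        d = Dataset(ids=[f"R{i}" for i in range(13)], population=pops, G=G,
                    marker_names=["m1"], y=np.ones(13), replicate=np.zeros(13, int))
        out = dio.impute_markers(d, max_missing_frac=0.2)
        assert out.G[10, 0] == 2  # mode of population B, not pooled

    def test_fully_missing_population_errors(self):
        G = np.array([[0], [MISSING], [MISSING]])
        pops = np.array(["A", "B", "B"], dtype=object)
        d = Dataset(ids=["R1", "R2", "R3"], population=pops, G=G,
                    marker_names=["m1"], y=np.ones(3), replicate=np.zeros(3, int))
        with pytest.raises(ValueError, match="m1"):
            dio.impute_markers(d, max_missing_frac=0.9)

    def test_never_changes_observed_cells(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, (30, 8))
        mask = rng.random((30, 8)) < 0.05
        Gm = np.where(mask, MISSING, G)
        d = make_dataset(Gm, np.ones(30))
        out = dio.impute_markers(d, max_missing_frac=1.0)
        observed = Gm != MISSING
        np.testing.assert_array_equal(out.G[observed], Gm[observed])
        n_dropped = d.n_markers - out.n_markers
        assert n_dropped == int(((Gm == MISSING).mean(axis=0) > 1.0).sum())


class TestDropMissingPhenotypes:
    def test_removes_missing(self):
        d = make_dataset(np.zeros((5, 1), int), [1, 2, np.nan, 4, 5])
        out = dio.drop_missing_phenotypes(d)
        assert out.n_records == 4
        assert out.ids == ["R1", "R2", "R4", "R5"]

    def test_identity_when_complete(self):
        d = make_dataset(np.zeros((3, 1), int), [1, 2, 3])
        out = dio.drop_missing_phenotypes(d)
        assert out.n_records == 3
        np.testing.assert_array_equal(out.y, d.y)

    def test_all_missing_errors(self):
        d = make_dataset(np.zeros((3, 1), int), [np.nan] * 3)
        with pytest.raises(ValueError):
            dio.drop_missing_phenotypes(d)


def brute_force_no_high_ld_pairs(d, window, threshold):
    """Oracle: no surviving within-window pair exceeds the r^2 threshold."""
    X = d.G.astype(float)
    for a in range(d.n_markers):
        for b in range(a + 1, min(a + window, d.n_markers)):
            if X[:, a].std() == 0 or X[:, b].std() == 0:
                continue
            r2 = np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
            assert r2 <= threshold + 1e-12, (a, b, r2)


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(1)
        c1 = rng.integers(0, 3, 30)
        c3 = rng.permutation(c1)  # decorrelated by shuffling
        d = make_dataset(np.column_stack([c1, c1, c3]), np.ones(30))
        out = dio.ld_prune(d, window=10, step=1, r2_threshold=0.8)
        assert out.marker_names == ["m1", "m3"]
        brute_force_no_high_ld_pairs(out, 10, 0.8)

    def test_low_ld_identity(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, (200, 6))
        d = make_dataset(G, np.ones(200))
        out = dio.ld_prune(d, window=10, step=1)
        assert out.marker_names == d.marker_names

    def test_identical_trio_keeps_first(self):
        rng = np.random.default_rng(3)
        c = rng.integers(0, 3, 40)
        d = make_dataset(np.column_stack([c, c, c]), np.ones(40))
        out = dio.ld_prune(d, window=10, step=1)
        assert out.marker_names == ["m1"]

    def test_posthoc_scan_on_random_ril_data(self, ril_genotypes):
        G, markers, gmap = ril_genotypes
        window, step, thr = 15, 3, 0.5
        d = make_dataset(G[:120, :40], np.ones(120), marker_names=markers[:40])
        out = dio.ld_prune(d, window=window, step=step, r2_threshold=thr)
        # every surviving pair close enough in original index to be
        # guaranteed co-windowed must satisfy the threshold
        orig = {m: j for j, m in enumerate(d.marker_names)}
        X = out.G.astype(float)
        for a in range(out.n_markers):
            for b in range(a + 1, out.n_markers):
                if orig[out.marker_names[b]] - orig[out.marker_names[a]] > window - step:
                    continue
                if X[:, a].std() == 0 or X[:, b].std() == 0:
                    continue
                r2 = np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
                assert r2 <= thr + 1e-12

    def test_monomorphic_retained(self):
        rng = np.random.default_rng(4)
        G = np.column_stack([np.ones(30, int), rng.integers(0, 3, 30)])
        d = make_dataset(G, np.ones(30))
        out = dio.ld_prune(d, window=5, step=1)
        assert "m1" in out.marker_names

    def test_requires_imputed(self):
        d = make_dataset([[MISSING, 0], [1, 2]], [1, 2])
        with pytest.raises(ValueError, match="imputed"):
            dio.ld_prune(d)


class TestConcatReplicates:
    def test_stacks_with_replicate_factor(self):
        d1 = make_dataset(np.zeros((10, 2), int), np.arange(10))
        d2 = make_dataset(np.ones((10, 2), int), np.arange(10) + 1)
        out = dio.concat_replicates(d1, d2)
        assert out.n_records == 20
        assert out.replicate.sum() == 10
        assert out.n_records == d1.n_records + d2.n_records

    def test_empty_second_dataset(self):
        d1 = make_dataset(np.zeros((4, 2), int), np.arange(4))
        d2 = d1.subset_records(np.array([], dtype=int))
        out = dio.concat_replicates(d1, d2)
        assert out.n_records == 4
        assert (out.replicate == 0).all()

    def test_marker_mismatch_errors(self):
        d1 = make_dataset(np.zeros((3, 2), int), np.arange(3))
        d2 = make_dataset(np.zeros((3, 2), int), np.arange(3),
                          marker_names=["x1", "x2"])
        with pytest.raises(ValueError):
            dio.concat_replicates(d1, d2)


class TestMapsAndAnnotations:
    def test_map_round_trip(self, tmp_path):
        gmap = GeneticMap({"m1": (1, 5.0), "m2": (2, 7.5)}, {1: 10.0, 2: 20.0})
        path = tmp_path / "map.tsv"
        dio.write_genetic_map(gmap, path)
        g2 = dio.read_genetic_map(path)
        assert g2.positions == gmap.positions

    def test_map_position_beyond_length_errors(self):
        with pytest.raises(ValueError):
            GeneticMap({"m1": (1, 99.0)}, {1: 10.0})

    def test_annotation_round_trip(self, tmp_path):
        tr = dio.AnnotationTrack("QTL", [(1, 2.0, 4.0, "q1", "photoperiod")])
        path = tmp_path / "ann.tsv"
        dio.write_annotations([tr], path)
        tracks = dio.read_annotations(path)
        assert tracks[0].name == "QTL"
        assert tracks[0].regions[0][:3] == (1, 2.0, 4.0)
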