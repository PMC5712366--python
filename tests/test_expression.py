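import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diurnet import (CountMatrix, DesignGrid, ExpressionTensor, SeriesMatrix,
                     compute_rpm, filter_expressed, replicate_mean,
                     zscore_genes)


def make_counts(counts, library_sizes, hours=(2, 6), n_reps=2):
    """Small CountMatrix with samples laid out (timepoint-major, replicate)."""
    counts = np.asarray(counts)
    n_genes = counts.shape[0]
    samples, day, hour, rep = [], [], [], []
    for h in hours:
        for r in range(1, n_reps + 1):
            samples.append(f"d1_h{h}_r{r}")
            day.append(1)
            hour.append(h)
            rep.append(r)
    meta = pd.DataFrame({"day": day, "hour": hour, "replicate": rep},
                        index=pd.Index(samples, name="sample_id"))
    return CountMatrix([f"g{i}" for i in range(n_genes)], samples, counts,
                       meta, np.asarray(library_sizes, dtype=float))


class TestComputeRpm:
    @pytest.mark.parametrize("count,lib,expected", [
        (50, 1e6, 50.0),          # definition
        (0, 1e6, 0.0),
        (123, 2.5e6, 49.2),       # 123 / 2.5
    ])
    def test_definition(self, count, lib, expected):
        cm = make_counts([[count, 0, 0, 0]], [lib, lib, lib, lib])
        tensor = compute_rpm(cm)
        assert tensor.values[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_grid_arrangement_shuffled_samples(self):
        cm = make_counts([[1, 2, 3, 4]], [1e6] * 4)
        # shuffle sample order: values must still land on the right cells
        perm = [2, 0, 3, 1]
        cm2 = CountMatrix(cm.genes, [cm.samples[i] for i in perm],
                          cm.counts[:, perm], cm.metadata.iloc[perm],
                          cm.library_size[perm])
        t1, t2 = compute_rpm(cm), compute_rpm(cm2)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_duplicate_cell_rejected(self):
        cm = make_counts([[1, 2, 3, 4]], [1e6] * 4)
        meta = cm.metadata.copy()
        meta.iloc[1] = meta.iloc[0]
        cm_bad = CountMatrix(cm.genes, cm.samples, cm.counts, meta,
                             cm.library_size)
        with pytest.raises(ValueError, match="duplicate"):
            compute_rpm(cm_bad)

    def test_missing_cell_rejected(self):
        cm = make_counts([[1, 2, 3, 4]], [1e6] * 4)
        # drop one sample: 2 hours × 2 reps grid now has a hole
        cm_bad = CountMatrix(cm.genes, cm.samples[:3],
                             cm.counts[:, :3], cm.metadata.iloc[:3],
                             cm.library_size[:3])
        with pytest.raises(ValueError, match="incomplete"):
            compute_rpm(cm_bad)

    def test_linearity_in_counts(self):
        cm1 = make_counts([[10, 20, 30, 40]], [1e6] * 4)
        cm3 = make_counts([[30, 60, 90, 120]], [1e6] * 4)
        np.testing.assert_allclose(compute_rpm(cm3).values,
                                   3 * compute_rpm(cm1).values)


class TestFilterExpressed:
    def make_tensor(self, values):
        values = np.asarray(values, dtype=float)
        g, t, r = values.shape
        grid = DesignGrid(hours=np.arange(t) * 4.0 + 2.0, n_reps=r)
        return ExpressionTensor([f"g{i}" for i in range(g)], grid, values)

    def test_boundary_inclusive(self):
        # exactly 1.0 in every replicate at one timepoint counts as expressed
        t = self.make_tensor([[[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]]])
        assert filter_expressed(t, 1.0) == ["g0"]

    def test_all_replicates_required(self):
        # one failing replicate at every timepoint drops the gene
        t = self.make_tensor([[[5, 5, 0.9], [5, 5, 0.9]]])
        assert filter_expressed(t, 1.0) == []

    def test_hand_enumerated_four_genes(self):
        t = self.make_tensor([
            [[2, 2, 2], [0, 0, 0]],    # kept: all reps pass at t0
            [[2, 0.5, 2], [2, 2, 0]],  # dropped: no timepoint with all reps
            [[0, 0, 0], [1, 1, 9]],    # kept at t1
            [[0.9, 0.9, 0.9], [0, 0, 0]],  # dropped: below threshold
        ])
        assert filter_expressed(t, 1.0) == ["g0", "g2"]

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_monotone_in_threshold(self, lo, delta):
        rng = np.random.default_rng(0)
        t = self.make_tensor(rng.uniform(0, 5, size=(20, 3, 3)))
        assert set(filter_expressed(t, lo + delta)) <= set(filter_expressed(t, lo))


class TestReplicateMean:
    def test_mean_and_identity(self, grid):
        rng = np.random.default_rng(1)
        t = ExpressionTensor(["g0"], grid, rng.uniform(size=(1, 12, 3)))
        np.testing.assert_allclose(replicate_mean(t).values,
                                   t.values.mean(axis=2))
        g1 = DesignGrid(n_reps=1)
        t1 = ExpressionTensor(["g0"], g1, rng.uniform(size=(1, 12, 1)))
        np.testing.assert_array_equal(replicate_mean(t1).values,
                                      t1.values[:, :, 0])

    def test_examples(self):
        g = DesignGrid(hours=np.array([2.0, 6.0]), n_reps=3)
        t = ExpressionTensor(["g0"], g, np.array([[[1, 2, 3], [7, 7, 7]]], float))
        np.testing.assert_allclose(replicate_mean(t).values, [[2.0, 7.0]])


class TestZscore:
    def test_two_point_standardization(self):
        s = SeriesMatrix(["g0"], np.array([0.0, 4.0]), np.array([[0.0, 2.0]]))
        z, excluded = zscore_genes(s)
        np.testing.assert_allclose(z.values, [[-1.0, 1.0]])
        assert excluded == []

    def test_constant_gene_excluded_with_record(self):
        s = SeriesMatrix(["flat", "ok"], np.array([0.0, 4.0, 8.0]),
                         np.array([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]]))
        z, excluded = zscore_genes(s)
        assert excluded == ["flat"]
        assert z.genes == ["ok"]

    def test_postconditions_and_idempotence(self):
        rng = np.random.default_rng(2)
        s = SeriesMatrix([f"g{i}" for i in range(10)], np.arange(12.0),
                         rng.normal(2, 5, size=(10, 12)))
        z, _ = zscore_genes(s)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=0), 1, atol=1e-12)
        z2, _ = zscore_genes(z)
        np.testing.assert_allclose(z2.values, z.values, atol=1e-12)

    def test_log2_pretransform(self):
        s = SeriesMatrix(["g0"], np.arange(3.0), np.array([[0.0, 1.0, 3.0]]))
        z, _ = zscore_genes(s, log2_transform=True)
        expect = np.log2(np.array([1.0, 2.0, 4.0]))
        expect = (expect - expect.mean()) / expect.std()
        np.testing.assert_allclose(z.values[0], expect)


class TestTsvRoundTrips:
    def test_count_matrix(self, tmp_path):
        cm = make_counts([[1, 2, 3, 4], [5, 6, 7, 8]], [1e6, 2e6, 3e6, 4e6])
        cm.to_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        np.testing.assert_array_equal(back.counts, cm.counts)
        np.testing.assert_array_equal(back.library_size, cm.library_size)
        assert back.genes == cm.genes

    def test_library_from_column_sums(self, tmp_path):
        cm = make_counts([[10, 0, 2, 4], [30, 8, 6, 4]], [1e6] * 4)
        cm.to_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv",
                                    library_from_column_sums=True)
        np.testing.assert_array_equal(back.library_size, [40, 8, 8, 8])

    def test_expression_tensor(self, tmp_path, grid):
        rng = np.random.default_rng(3)
        t = ExpressionTensor(["a", "b"], grid, rng.uniform(size=(2, 12, 3)))
        t.to_tsv(tmp_path / "e.tsv")
        back = ExpressionTensor.from_tsv(tmp_path / "e.tsv", grid)
        np.testing.assert_allclose(back.values, t.values)

    def test_series_matrix(self, tmp_path):
        s = SeriesMatrix(["a", "b"], np.arange(5.0) * 4,
                         np.arange(10.0).reshape(2, 5))
        s.to_tsv(tmp_path / "s.tsv")
        back = SeriesMatrix.from_tsv(tmp_path / "s.tsv")
        np.testing.assert_allclose(back.values, s.values)
        np.testing.assert_allclose(back.hours, s.hours)
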