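"""Readers, QC filters, size factors, log transform and catalog subsetting."""

import numpy as np
import pandas as pd
import pytest

import recat
from recat.matrix import (
    ExpressionMatrix,
    ValidationError,
    read_catalog,
    read_expression,
    write_catalog,
    write_expression_mtx,
    write_expression_tsv,
)
from recat.preprocess import (
    deseq_size_factors,
    log_transform,
    normalize,
    qc_filter_cells,
    qc_filter_genes,
    subset_to_catalog,
)


class TestReadExpression:
    def test_tsv_round_trip(self, tmp_path):
        mat = ExpressionMatrix([[1.0, 2.0], [3.0, 4.0]], ["gA", "gB"], ["c1", "c2"])
        write_expression_tsv(mat, tmp_path / "m.tsv")
        back = read_expression(tmp_path / "m.tsv", unit="TPM")
        np.testing.assert_array_equal(back.values, mat.values)
        assert back.gene_ids == ["gA", "gB"] and back.cell_ids == ["c1", "c2"]
        assert back.layer == "raw"

    def test_mtx_equals_tsv(self, tmp_path):
        mat = ExpressionMatrix([[1.0, 2.0], [3.0, 4.0]], ["gA", "gB"], ["c1", "c2"])
        write_expression_tsv(mat, tmp_path / "m.tsv")
        write_expression_mtx(mat, tmp_path / "m.mtx")
        a = read_expression(tmp_path / "m.tsv")
        b = read_expression(tmp_path / "m.mtx")
        np.testing.assert_array_equal(a.values, b.values)
        assert a.gene_ids == b.gene_ids and a.cell_ids == b.cell_ids

    def test_duplicate_gene_id_rejected(self, tmp_path):
        (tmp_path / "dup.tsv").write_text("gene\tc1\tc2\ngA\t1\t2\ngA\t3\t4\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            read_expression(tmp_path / "dup.tsv")

    def test_transpose_flag(self, tmp_path):
        # on disk: cells x genes
        pd.DataFrame([[1.0, 3.0], [2.0, 4.0]], index=["c1", "c2"], columns=["gA", "gB"]).to_csv(
            tmp_path / "t.tsv", sep="\t"
        )
        mat = read_expression(tmp_path / "t.tsv", transpose=True)
        assert mat.gene_ids == ["gA", "gB"]
        np.testing.assert_array_equal(mat.values, [[1.0, 2.0], [3.0, 4.0]])

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            ExpressionMatrix([[-1.0]], ["g"], ["c"])


class TestCellQc:
    def test_strict_boundary(self):
        # a cell with exactly min_genes genes above threshold is removed
        values = np.zeros((5000, 2))
        values[:4000, 0] = 3.0   # exactly 4000 genes above 2 -> out
        values[:4001, 1] = 3.0   # 4001 -> kept
        mat = ExpressionMatrix(values, [f"g{i}" for i in range(5000)], ["drop", "keep"])
        kept, report = qc_filter_cells(mat)
        assert kept.cell_ids == ["keep"]
        assert report.cells_in == 2 and report.cells_kept == 1

    def test_nonzero_count_toy(self):
        values = np.zeros((10, 2))
        values[:4, 0] = 1.0  # 4 nonzero genes -> kept with min_genes=3
        values[:3, 1] = 1.0  # 3 nonzero genes -> removed (strictly more than)
        mat = ExpressionMatrix(values, [f"g{i}" for i in range(10)], ["a", "b"])
        kept, _ = qc_filter_cells(mat, min_genes=3, min_expr=0)
        assert kept.cell_ids == ["a"]

    def test_vacuous_filter_and_idempotence(self, toy_matrix):
        kept, _ = qc_filter_cells(toy_matrix, min_genes=0, min_expr=0)
        assert kept.cell_ids == toy_matrix.cell_ids
        twice, _ = qc_filter_cells(kept, min_genes=0, min_expr=0)
        np.testing.assert_array_equal(twice.values, kept.values)

    def test_all_removed_raises(self, toy_matrix):
        with pytest.raises(ValidationError, match="no eligible cells"):
            qc_filter_cells(toy_matrix, min_genes=100)


class TestGeneQc:
    @pytest.mark.parametrize(
        "row, min_mean, kept",
        [((2.0, 2.0, 2.0), 2.0, True),   # boundary inclusive
         ((0.0, 0.0, 3.0), 2.0, False),  # mean 1 < 2
         ((0.0, 0.0, 0.0), 0.0, True)],  # min_mean=0 keeps everything
    )
    def test_mean_boundary(self, row, min_mean, kept):
        mat = ExpressionMatrix(
            np.vstack([row, [9.0, 9.0, 9.0]]), ["g", "anchor"], ["c1", "c2", "c3"]
        )
        out = qc_filter_genes(mat, min_mean=min_mean)
        assert ("g" in out.gene_ids) == kept


class TestSizeFactors:
    def test_identical_cells_give_unit_factors(self):
        mat = ExpressionMatrix(np.tile([[2.0], [8.0]], (1, 3)), ["a", "b"], ["c1", "c2", "c3"])
        np.testing.assert_allclose(deseq_size_factors(mat), [1.0, 1.0, 1.0])

    def test_doubled_cell_doubles_factor(self):
        a = np.array([3.0, 7.0, 1.0])
        mat = ExpressionMatrix(np.column_stack([a, 2 * a]), ["g1", "g2", "g3"], ["A", "B"])
        f = deseq_size_factors(mat)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_one_gene_hand_case(self):
        # single gene (4, 9): geometric mean 6, factors (4/6, 9/6)
        mat = ExpressionMatrix([[4.0, 9.0]], ["g"], ["A", "B"])
        np.testing.assert_allclose(deseq_size_factors(mat), [4 / 6, 9 / 6])

    def test_scale_equivariance_of_normalized_matrix(self, small_sim):
        # scaling one cell by c shifts every factor by the shared geometric-mean
        # renormalization c^(1/n); relative to that, the scaled cell's factor
        # grows by c and the others are unchanged, so the normalized matrices
        # agree up to one global constant
        mat, _ = small_sim
        n = mat.n_cells
        f = deseq_size_factors(mat)
        scaled_values = mat.values.copy()
        scaled_values[:, 0] *= 5.0
        scaled = ExpressionMatrix(scaled_values, mat.gene_ids, mat.cell_ids, mat.unit)
        f2 = deseq_size_factors(scaled)
        shared = 5.0 ** (-1.0 / n)
        assert f2[0] / f[0] == pytest.approx(5.0 * shared)
        np.testing.assert_allclose(f2[1:] / f[1:], shared)
        a, b = normalize(scaled).values, normalize(mat).values
        nz = b > 0
        np.testing.assert_allclose(a[nz] / b[nz], (a[nz] / b[nz]).flat[0])

    def test_no_reference_gene_raises(self):
        mat = ExpressionMatrix([[1.0, 0.0], [0.0, 1.0]], ["a", "b"], ["c1", "c2"])
        with pytest.raises(ValidationError, match="relax gene QC"):
            deseq_size_factors(mat)


class TestLogTransform:
    def test_fixed_points(self, toy_matrix):
        out = log_transform(toy_matrix)
        assert out.layer == "log2"
        # 0 -> 0, 1 -> 1, 3 -> 2
        assert out.values[2, 0] == 0.0
        assert out.values[0, 0] == 1.0
        assert out.values[0, 2] == 2.0

    def test_monotone(self, small_sim):
        mat, _ = small_sim
        out = log_transform(mat)
        order_in = np.argsort(mat.values[0])
        order_out = np.argsort(out.values[0])
        np.testing.assert_array_equal(order_in, order_out)

    def test_no_double_transform(self, toy_matrix):
        once = log_transform(toy_matrix)
        with pytest.raises(ValidationError):
            log_transform(once)


class TestCatalog:
    def _catalog(self, genes):
        return recat.GeneCatalog(
            pd.DataFrame({"gene": genes, "peak_stage": ["G1"] * len(genes),
                          "rank": range(1, len(genes) + 1)})
        )

    def test_subset_identity_and_intersection(self, toy_matrix):
        full = subset_to_catalog(toy_matrix, self._catalog(["g1", "g2", "g3"]))
        assert full.gene_ids == toy_matrix.gene_ids
        two = subset_to_catalog(toy_matrix, self._catalog(["g3", "g1"]))
        assert two.gene_ids == ["g1", "g3"]  # matrix order preserved

    def test_disjoint_catalog_raises(self, toy_matrix):
        with pytest.raises(ValidationError, match="no overlap"):
            subset_to_catalog(toy_matrix, self._catalog(["x", "y"]))

    def test_case_insensitive_fallback(self, toy_matrix):
        out = subset_to_catalog(toy_matrix, self._catalog(["G1"]), case_insensitive=True)
        assert out.gene_ids == ["g1"]

    def test_catalog_round_trip(self, tmp_path, small_sim):
        _, truth = small_sim
        catalog = recat.make_catalog(truth)
        write_catalog(catalog, tmp_path / "cat.tsv")
        back = read_catalog(tmp_path / "cat.tsv")
        pd.testing.assert_frame_equal(back.table, catalog.table)
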