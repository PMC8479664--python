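"""Container invariants and file-format round trips."""

import subprocess

import numpy as np
import pytest

from prism import (
    CellLabels,
    CountMatrix,
    FormatError,
    ModelParams,
    ValidationError,
    align_genes,
    align_labels,
    read_counts_mtx,
    read_counts_tsv,
    read_labels,
    write_counts_mtx,
    write_counts_tsv,
    write_decomposition,
)
from conftest import make_counts


class TestCountMatrix:
    def test_rejects_negative_and_nan_at_construction(self):
        with pytest.raises(ValidationError, match="negative"):
            make_counts([[1.0, -1.0]])
        with pytest.raises(ValidationError, match="NaN|finite"):
            make_counts([[np.nan, 1.0]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate gene"):
            CountMatrix(np.ones((2, 1)), ["g", "g"], ["u"])
        with pytest.raises(ValidationError, match="duplicate unit"):
            CountMatrix(np.ones((1, 2)), ["g"], ["u", "u"])

    def test_accepts_real_valued_effective_counts(self):
        cm = make_counts([[1.5, 0.0], [2.25, 3.75]])
        assert cm.values.dtype == float


class TestCellLabels:
    def test_type_names_ordered_by_first_appearance(self):
        lab = CellLabels(
            ["a", "b", "c", "d"], ["EOC", "EOC", "Fibroblast", "Immune"]
        )
        assert lab.type_names == ["EOC", "Fibroblast", "Immune"]
        assert lab.n_types == 3

    def test_onehot_matches_index(self):
        lab = CellLabels(["a", "b", "c"], ["x", "y", "x"])
        W = lab.onehot()
        np.testing.assert_array_equal(W, [[1, 0, 1], [0, 1, 0]])


class TestModelParams:
    def test_simplex_and_bounds_enforced(self):
        ok = ModelParams(
            np.ones((2, 2)), np.ones((2, 2)),
            np.array([[0.5, 0.2], [0.5, 0.8]]), np.ones(2),
        )
        assert ok.n_types == 2
        with pytest.raises(ValidationError, match="sum to 1"):
            ModelParams(np.ones((2, 2)), np.ones((2, 2)),
                        np.array([[0.6], [0.6]]), np.ones(1))
        with pytest.raises(ValidationError, match="T outside"):
            ModelParams(np.ones((2, 2)), np.full((2, 2), 1e9),
                        np.array([[0.5], [0.5]]), np.ones(1))


class TestTsvRoundTrip:
    def test_values_and_ids_survive(self, tmp_path):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.uniform(0, 1000, (5, 3)))
        p = tmp_path / "c.tsv"
        write_counts_tsv(cm, p)
        back = read_counts_tsv(p, kind="bulk")
        assert back.gene_ids == cm.gene_ids
        assert back.unit_ids == cm.unit_ids
        np.testing.assert_allclose(back.values, cm.values, rtol=1e-9)

    def test_nine_significant_digits(self, tmp_path):
        cm = make_counts([[123456789.123456, 0.000123456789]])
        p = tmp_path / "c.tsv"
        write_counts_tsv(cm, p)
        back = read_counts_tsv(p)
        np.testing.assert_allclose(back.values, cm.values, rtol=1e-9)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\ts1\ng0\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            read_counts_tsv(p)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\ts1\ts2\ng0\t1\t2\ng1\t3\tNA\n")
        with pytest.raises(FormatError, match="'NA'.*g1.*s2"):
            read_counts_tsv(p)

    def test_empty_body_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_id\ts1\n")
        with pytest.raises(ValidationError, match="no genes"):
            read_counts_tsv(p)

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene_id\ts1\ng0\t1\ng0\t2\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            read_counts_tsv(p)


class TestMtx:
    def _write_triplet(self, tmp_path, header, entries, feats, bcs):
        mtx = tmp_path / "matrix.mtx"
        body = "".join(f"{i} {j} {v}\n" for i, j, v in entries)
        mtx.write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            f"{header}\n{body}"
        )
        f = tmp_path / "features.tsv"
        f.write_text("".join(x + "\n" for x in feats))
        b = tmp_path / "barcodes.tsv"
        b.write_text("".join(x + "\n" for x in bcs))
        return mtx, f, b

    def test_triplet_expansion(self, tmp_path):
        mtx, f, b = self._write_triplet(
            tmp_path, "2 2 2", [(1, 1, 5), (2, 2, 3)],
            ["gA", "gB"], ["c1", "c2"],
        )
        cm = read_counts_mtx(mtx, f, b)
        np.testing.assert_array_equal(cm.values, [[5, 0], [0, 3]])
        assert cm.gene_ids == ["gA", "gB"]
        assert cm.kind == "single_cell"

    def test_dimension_mismatch_names_offending_file(self, tmp_path):
        mtx, f, b = self._write_triplet(
            tmp_path, "2 2 1", [(1, 1, 5)],
            ["gA", "gB", "gC"], ["c1", "c2"],
        )
        with pytest.raises(FormatError, match="features.tsv"):
            read_counts_mtx(mtx, f, b)

    def test_negative_entry_rejected(self, tmp_path):
        mtx, f, b = self._write_triplet(
            tmp_path, "2 2 1", [(1, 1, -5)], ["gA", "gB"], ["c1", "c2"]
        )
        with pytest.raises(ValidationError, match="negative"):
            read_counts_mtx(mtx, f, b)

    def test_transpose_detected_from_id_lengths(self, tmp_path):
        mtx, f, b = self._write_triplet(
            tmp_path, "2 3 2", [(1, 1, 5), (2, 3, 2)],
            ["gA", "gB", "gC"], ["c1", "c2"],
        )
        cm = read_counts_mtx(mtx, f, b)
        assert cm.values.shape == (3, 2)
        assert cm.values[0, 0] == 5 and cm.values[2, 1] == 2

    def test_mtx_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        cm = make_counts(
            rng.poisson(3, (4, 3)).astype(float), kind="single_cell"
        )
        write_counts_mtx(cm, tmp_path / "mtx")
        back = read_counts_mtx(
            tmp_path / "mtx" / "matrix.mtx",
            tmp_path / "mtx" / "features.tsv",
            tmp_path / "mtx" / "barcodes.tsv",
        )
        write_counts_tsv(back, tmp_path / "c.tsv")
        back2 = read_counts_tsv(tmp_path / "c.tsv", kind="single_cell")
        np.testing.assert_array_equal(back2.values, cm.values)
        assert back2.gene_ids == cm.gene_ids
        assert back2.unit_ids == cm.unit_ids


class TestLabels:
    def test_read_orders_types_by_first_appearance(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("c1\tEOC\nc2\tEOC\nc3\tFibroblast\nc4\tImmune\n")
        lab = read_labels(p)
        assert lab.type_names == ["EOC", "Fibroblast", "Immune"]

    def test_optional_header_skipped(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("unit_id\tlabel\nc1\tA\n")
        assert read_labels(p).unit_ids == ["c1"]

    def test_duplicate_unit_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("c1\tA\nc1\tB\n")
        with pytest.raises(ValidationError, match="more than once"):
            read_labels(p)

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("")
        with pytest.raises(ValidationError, match="no labels"):
            read_labels(p)


class TestAlign:
    def test_identity_when_ids_match(self):
        cm = make_counts(np.ones((2, 3)), kind="single_cell")
        lab = CellLabels(list(cm.unit_ids), ["A", "B", "A"])
        c2, l2 = align_labels(cm, lab)
        assert c2 is cm and l2 is lab

    def test_partial_overlap_drops_and_orders(self, caplog):
        cm = make_counts(np.arange(12.0).reshape(2, 6), "single_cell")
        lab = CellLabels(
            ["u4", "u0", "u2", "u1", "zz"], ["A", "B", "A", "B", "C"]
        )
        c2, l2 = align_labels(cm, lab)
        assert c2.unit_ids == ["u0", "u1", "u2", "u4"]
        assert l2.labels == ["B", "B", "A", "A"]
        # idempotent
        c3, l3 = align_labels(c2, l2)
        assert c3 is c2 and l3 is l2

    def test_disjoint_ids_error(self):
        cm = make_counts(np.ones((1, 2)), "single_cell")
        lab = CellLabels(["x1", "x2"], ["A", "B"])
        with pytest.raises(ValidationError, match="no units shared"):
            align_labels(cm, lab)

    def test_align_genes_keeps_reference_order(self):
        ref = make_counts(np.arange(8.0).reshape(4, 2), "single_cell")
        bulk = CountMatrix(
            np.array([[9.0], [7.0], [5.0]]), ["g3", "g1", "gX"], ["b0"]
        )
        r2, b2 = align_genes(ref, bulk)
        assert r2.gene_ids == ["g1", "g3"]
        assert b2.gene_ids == ["g1", "g3"]
        np.testing.assert_array_equal(b2.values[:, 0], [7.0, 9.0])


class TestWriteDecomposition:
    def test_file_set_and_readback(self, tmp_path, baseline_fit):
        files = write_decomposition(baseline_fit, tmp_path / "out")
        names = sorted(f.name for f in files)
        k = len(baseline_fit.type_names)
        assert sum(n.startswith("allocations_") for n in names) == k
        assert {"composition.tsv", "scale.tsv", "X.tsv", "T.tsv",
                "metadata.json"} <= set(names)
        comp = read_counts_tsv(tmp_path / "out" / "composition.tsv")
        np.testing.assert_allclose(comp.values.sum(axis=0), 1.0, atol=1e-6)

    def test_rewrite_is_byte_identical(self, tmp_path, baseline_fit):
        write_decomposition(baseline_fit, tmp_path / "a")
        write_decomposition(baseline_fit, tmp_path / "b")
        for name in ("composition.tsv", "scale.tsv", "X.tsv", "T.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
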