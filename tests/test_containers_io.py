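"""Container invariants, file parsing, alignment and archive round-trips."""

import numpy as np
import pytest

from xferdrp.containers import (AlignmentError, DataError, DrugScreenDataset,
                                ExpressionMatrix, InputLayerWeights,
                                ResponseTable, align_dataset, intersect_genes)
from xferdrp.io import (ParseError, archive_manifest, load_weights,
                        read_expression, read_response, save_weights,
                        write_expression, write_response)
from xferdrp.nn import NetworkConfig, build_model, predict


def _expr(genes, samples, values, **meta):
    return ExpressionMatrix(genes, samples, np.asarray(values, float), meta)


class TestExpressionParsing:
    def test_toy_file_parses_to_expected_shape(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tA\tB\nG1\t1\t2\nG2\t3\t4\nG3\t5\t6\n")
        m = read_expression(p)
        assert (m.n_genes, m.n_samples) == (3, 2)
        assert m.gene_ids == ["G1", "G2", "G3"]
        assert m.values[2, 1] == 6

    def test_duplicate_gene_keeps_first_with_warning(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tA\nG1\t1\nG1\t9\nG2\t2\n")
        with pytest.warns(UserWarning, match="duplicate gene"):
            m = read_expression(p)
        assert m.gene_ids == ["G1", "G2"]
        assert m.values[0, 0] == 1

    def test_na_cell_raises_parse_error_naming_location(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tA\tB\nG1\t1\t2\nG2\tNA\t4\n")
        with pytest.raises(ParseError, match="G2.*A"):
            read_expression(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            read_expression(p)

    def test_round_trip_preserves_values_exactly(self, tmp_path):
        rng = np.random.default_rng(0)
        m = _expr([f"G{i}" for i in range(5)], ["A", "B", "C"],
                  rng.standard_normal((5, 3)))
        write_expression(m, tmp_path / "rt.tsv")
        back = read_expression(tmp_path / "rt.tsv")
        assert back.gene_ids == m.gene_ids
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.values, m.values)


class TestResponseParsing:
    def test_22_row_csv(self, tmp_path):
        p = tmp_path / "r.csv"
        rows = "\n".join(f"S{i},{0.5 + i/100}" for i in range(22))
        p.write_text("sample_id,auc\n" + rows + "\n")
        r = read_response(p)
        assert r.n_samples == 22
        assert r.drug == "unknown"
        assert not r.normalized

    def test_duplicate_sample_raises(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("sample_id,auc\nS1,0.5\nS1,0.7\n")
        with pytest.raises(ParseError, match="S1"):
            read_response(p)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("sample_id,value\nS1,0.5\n")
        with pytest.raises(ParseError, match="auc"):
            read_response(p)

    def test_drug_column_round_trip(self, tmp_path):
        r = ResponseTable(["A", "B"], [0.1, 0.9], drug="OXA")
        write_response(r, tmp_path / "r.csv")
        back = read_response(tmp_path / "r.csv")
        assert back.drug == "OXA"
        np.testing.assert_array_equal(back.auc, r.auc)


class TestAlignment:
    def test_reorders_columns_to_response_order(self):
        m = _expr(["G1"], ["A", "B", "C"], [[1.0, 2.0, 3.0]])
        r = ResponseTable(["B", "A"], [0.2, 0.8])
        ds = align_dataset(m, r, "c")
        assert ds.expression.sample_ids == ["B", "A"]
        np.testing.assert_array_equal(ds.expression.values, [[2.0, 1.0]])

    def test_missing_sample_lists_it(self):
        m = _expr(["G1"], ["A", "B"], [[1.0, 2.0]])
        r = ResponseTable(["B", "D"], [0.2, 0.8])
        with pytest.raises(AlignmentError, match="D"):
            align_dataset(m, r, "c")

    def test_identity_alignment(self):
        m = _expr(["G1"], ["A", "B"], [[1.0, 2.0]])
        r = ResponseTable(["A", "B"], [0.2, 0.8])
        ds = align_dataset(m, r, "c")
        np.testing.assert_array_equal(ds.expression.values, m.values)


class TestIntersectGenes:
    def test_pairwise_intersection_sorted(self):
        a = _expr(["G1", "G2", "G3"], ["A"], [[1.], [2.], [3.]])
        b = _expr(["G3", "G2", "G4"], ["B"], [[30.], [20.], [40.]])
        ra, rb = intersect_genes([a, b])
        assert ra.gene_ids == rb.gene_ids == ["G2", "G3"]
        np.testing.assert_array_equal(ra.values[:, 0], [2.0, 3.0])
        np.testing.assert_array_equal(rb.values[:, 0], [20.0, 30.0])

    def test_three_way_single_gene(self):
        ms = [_expr(["G5", f"X{i}"], ["S"], [[1.0], [2.0]]) for i in range(3)]
        out = intersect_genes(ms)
        assert all(m.gene_ids == ["G5"] for m in out)

    def test_disjoint_raises(self):
        a = _expr(["G1"], ["A"], [[1.0]])
        b = _expr(["G2"], ["B"], [[2.0]])
        with pytest.raises(DataError, match="empty"):
            intersect_genes([a, b])

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        a = _expr(["G3", "G1", "G2"], ["A"], rng.standard_normal((3, 1)))
        b = _expr(["G2", "G3", "G9"], ["B"], rng.standard_normal((3, 1)))
        once = intersect_genes([a, b])
        twice = intersect_genes(once)
        swapped = intersect_genes([b, a])
        for x, y in zip(once, twice):
            assert x.gene_ids == y.gene_ids
            np.testing.assert_array_equal(x.values, y.values)
        assert swapped[0].gene_ids == once[1].gene_ids
        np.testing.assert_array_equal(swapped[0].values, once[1].values)


class TestInvariantEnforcement:
    def test_non_finite_expression_rejected(self):
        with pytest.raises(DataError):
            _expr(["G1"], ["A"], [[np.nan]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            _expr(["G1", "G2"], ["A"], [[1.0]])

    def test_dataset_requires_matching_sample_order(self):
        m = _expr(["G1"], ["A", "B"], [[1.0, 2.0]])
        r = ResponseTable(["B", "A"], [0.2, 0.8])
        with pytest.raises(AlignmentError):
            DrugScreenDataset(m, r, "c")


class TestWeightArchive:
    def test_input_layer_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        w = InputLayerWeights(["G1", "G2"], rng.standard_normal((2, 4)),
                              rng.standard_normal(4))
        save_weights(w, tmp_path / "w.npz")
        back = load_weights(tmp_path / "w.npz")
        assert back.gene_ids == w.gene_ids
        np.testing.assert_array_equal(back.W, w.W)
        np.testing.assert_array_equal(back.b, w.b)

    def test_missing_array_raises(self, tmp_path):
        np.savez(tmp_path / "bad.npz",
                 _meta=np.frombuffer(
                     b'{"version": 1, "kind": "input_layer", "gene_ids": ["G1"]}',
                     dtype=np.uint8),
                 W=np.zeros((1, 3)))
        with pytest.raises(DataError, match="'b'"):
            load_weights(tmp_path / "bad.npz")

    def test_model_state_round_trip_predicts_identically(self, tmp_path):
        cfg = NetworkConfig(n_genes=6, hidden_sizes=(5, 3), seed=7)
        model = build_model(cfg, [f"G{i}" for i in range(6)])
        save_weights(model, tmp_path / "m.npz")
        back = load_weights(tmp_path / "m.npz")
        expr = _expr([f"G{i}" for i in range(6)], ["A", "B"],
                     np.random.default_rng(0).standard_normal((6, 2)))
        np.testing.assert_array_equal(predict(back, expr), predict(model, expr))
        assert back.config == model.config

    def test_version_mismatch_raises(self, tmp_path):
        np.savez(tmp_path / "v.npz",
                 _meta=np.frombuffer(b'{"version": 99, "kind": "input_layer"}',
                                     dtype=np.uint8))
        with pytest.raises(DataError, match="version"):
            load_weights(tmp_path / "v.npz")

    def test_truncated_file_raises(self, tmp_path):
        p = tmp_path / "t.npz"
        p.write_bytes(b"PK\x03\x04broken")
        with pytest.raises(DataError, match="corrupt|truncated"):
            load_weights(p)

    def test_manifest_reports_arrays_and_genes(self, tmp_path):
        w = InputLayerWeights(["G1"], np.zeros((1, 2)), np.zeros(2))
        save_weights(w, tmp_path / "w.npz")
        meta = archive_manifest(tmp_path / "w.npz")
        assert meta["kind"] == "input_layer"
        assert meta["arrays"]["W"] == [1, 2]
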