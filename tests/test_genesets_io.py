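import math

import numpy as np
import pytest

from pygsva import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    apply_size_filter,
    iqr_filter,
    read_expression,
    read_gmt,
    read_scores,
    write_expression,
    write_gmt,
    write_scores,
)
from pygsva.containers import EnrichmentMatrix

from conftest import make_expr


def write_lines(tmp_path, lines, name="sets.gmt"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadGmt:
    def test_basic_line(self, tmp_path):
        gsc = read_gmt(write_lines(tmp_path, ["S1\tdesc\tA\tB\tC"]))
        assert gsc["S1"].members == ("A", "B", "C")
        assert gsc["S1"].description == "desc"

    def test_duplicate_members_dropped_in_order(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            gsc = read_gmt(write_lines(tmp_path, ["S1\tdesc\tA\tA\tB"]))
        assert gsc["S1"].members == ("A", "B")
        assert "duplicate" in caplog.text

    def test_too_few_fields_reports_line_number(self, tmp_path):
        path = write_lines(tmp_path, ["S1\tdesc\tA", "S2\tonlydesc"])
        with pytest.raises(ValueError, match=":2"):
            read_gmt(path)

    def test_duplicate_set_name_is_error(self, tmp_path):
        path = write_lines(tmp_path, ["S1\td\tA\tB\tC", "S1\td\tD\tE\tF"])
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)

    def test_trailing_empty_fields_ignored(self, tmp_path):
        gsc = read_gmt(write_lines(tmp_path, ["S1\tdesc\tA\tB\t\t"]))
        assert gsc["S1"].members == ("A", "B")

    def test_roundtrip_preserves_member_order(self, tmp_path, rng):
        members = tuple(f"G{i}" for i in rng.permutation(30))
        gsc = GeneSetCollection([GeneSet("S", "d", members)])
        out = tmp_path / "rt.gmt"
        write_gmt(gsc, out)
        assert read_gmt(out)["S"].members == members


class TestSizeFilter:
    def expr(self, n_genes):
        return make_expr(np.random.default_rng(0), p=n_genes, n=3)

    def test_small_and_large_sets_removed_bounds_inclusive(self):
        expr = self.expr(600)
        ids = expr.gene_ids
        gsc = GeneSetCollection(
            [
                GeneSet("tiny", "", tuple(ids[:5])),
                GeneSet("at_min", "", tuple(ids[:10])),
                GeneSet("at_max", "", tuple(ids[:500])),
                GeneSet("huge", "", tuple(ids[:501])),
            ]
        )
        out = apply_size_filter(gsc, expr)
        assert out.names == ["at_min", "at_max"]

    def test_members_intersected_with_matrix(self):
        expr = self.expr(50)
        members = tuple(expr.gene_ids[:20]) + tuple(f"missing{i}" for i in range(10))
        gsc = GeneSetCollection([GeneSet("S", "", members)])
        out = apply_size_filter(gsc, expr, min_size=10)
        assert out["S"].members == tuple(expr.gene_ids[:20])

    def test_idempotent(self):
        expr = self.expr(100)
        gsc = GeneSetCollection([GeneSet("S", "", tuple(expr.gene_ids[:30]))])
        once = apply_size_filter(gsc, expr)
        twice = apply_size_filter(once, expr)
        assert [s.members for s in once] == [s.members for s in twice]

    def test_empty_result_is_error(self):
        expr = self.expr(50)
        gsc = GeneSetCollection([GeneSet("S", "", tuple(expr.gene_ids[:5]))])
        with pytest.raises(ValueError, match="no gene sets survive"):
            apply_size_filter(gsc, expr)


class TestIqrFilter:
    def test_lowest_iqr_genes_dropped(self):
        # four genes with IQRs 0, 3, 6, 9: dropping half keeps the top two
        values = np.array(
            [[5.0, 5, 5, 5], [1, 2, 3, 4], [1, 3, 5, 7], [0, 3, 6, 9]]
        )
        expr = ExpressionMatrix(values, list("abcd"), ["s1", "s2", "s3", "s4"])
        out = iqr_filter(expr, 0.5)
        assert out.gene_ids == ["c", "d"]

    def test_zero_fraction_is_identity(self, small_expr):
        out = iqr_filter(small_expr, 0.0)
        assert out.gene_ids == small_expr.gene_ids

    def test_tie_at_boundary_keeps_earlier_rows(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], (4, 1))  # all IQRs equal
        expr = ExpressionMatrix(values, list("abcd"), ["s1", "s2", "s3", "s4"])
        out = iqr_filter(expr, 0.5)
        assert out.gene_ids == ["a", "b"]

    @pytest.mark.parametrize("p,frac", [(10, 0.5), (11, 0.5), (7, 0.3), (20, 0.9)])
    def test_survivor_count(self, p, frac):
        expr = make_expr(np.random.default_rng(p), p=p, n=5)
        assert iqr_filter(expr, frac).n_genes == p - math.floor(p * frac)

    def test_invalid_fraction(self, small_expr):
        with pytest.raises(ValueError):
            iqr_filter(small_expr, 1.0)

    def test_counts_rejected(self, rng):
        expr = make_expr(rng, p=10, n=4, value_kind="counts")
        with pytest.raises(ValueError):
            iqr_filter(expr)


class TestMatrixIO:
    def test_expression_roundtrip(self, tmp_path, small_expr):
        path = tmp_path / "expr.tsv"
        write_expression(small_expr, path)
        back = read_expression(path)
        np.testing.assert_allclose(back.values, small_expr.values, rtol=1e-11)
        assert back.gene_ids == small_expr.gene_ids
        assert back.sample_ids == small_expr.sample_ids

    def test_fractional_counts_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t2.5\t3\n")
        with pytest.raises(ValueError, match="fractional"):
            read_expression(path, value_kind="counts")

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("g1\t1.0\t2.0\ng2\t3.0\t4.0\n")
        with pytest.raises(ValueError, match="header"):
            read_expression(path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1.0\toops\ng2\t3.0\t4.0\n")
        with pytest.raises(ValueError, match="g1.*s2"):
            read_expression(path)

    def test_scores_roundtrip_with_metadata(self, tmp_path, rng):
        em = EnrichmentMatrix(
            scores=rng.normal(size=(3, 4)),
            set_names=["a", "b", "c"],
            sample_ids=[f"s{j}" for j in range(4)],
            method="gsva",
            params={"tau": 1.0, "es_mode": "diff"},
        )
        path = tmp_path / "scores.tsv"
        write_scores(em, path)
        back = read_scores(path)
        np.testing.assert_allclose(back.scores, em.scores, rtol=1e-11)
        assert back.method == "gsva"
        assert back.params["es_mode"] == "diff"
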