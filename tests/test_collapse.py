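import numpy as np
import pytest

from goclique import (
    FDRMatrix,
    ValidationError,
    apply_clusters,
    build_meta_cim,
    collapse_fdr,
    collapse_membership,
    compression_ratio,
    multiclust,
    name_groups,
)

from conftest import cluster_set, graph_from_edges, membership_from_rows


class TestNameGroups:
    def test_lexicographic_without_fdr(self):
        groups = name_groups(cluster_set([{"B", "A"}]))
        assert groups[0].representative == "A"
        assert groups[0].display_name == "A:1"

    def test_most_significant_member_wins_with_fdr(self):
        f = FDRMatrix(("X", "Y"), ("e1", "e2"), np.array([[0.2, 0.9], [0.5, 0.001]]))
        groups = name_groups(cluster_set([{"X", "Y"}]), f)
        assert groups[0].representative == "Y"  # min FDR 0.001 beats 0.2

    def test_singleton_keeps_bare_name(self):
        groups = name_groups(cluster_set([{"Z"}]))
        assert groups[0].display_name == "Z"

    def test_fdr_tie_breaks_lexicographically(self):
        f = FDRMatrix(("P", "Q"), ("e1",), np.array([[0.05], [0.05]]))
        assert name_groups(cluster_set([{"Q", "P"}]), f)[0].representative == "P"

    def test_sidecar_concatenation_lists_all_members(self):
        g = name_groups(cluster_set([{"B", "A", "C"}]))[0]
        assert g.concatenated_name == "A;B;C"


class TestCollapseMembership:
    def test_cells_average_over_members(self):
        m = membership_from_rows({"a": "101", "b": "111"})
        red = collapse_membership(m, cluster_set([{"a", "b"}]))
        np.testing.assert_allclose(red.values, [[1.0, 0.5, 1.0]])
        assert red.row_labels == ("a:1",)

    def test_singleton_row_passes_through(self):
        m = membership_from_rows({"a": "101", "b": "111"})
        red = collapse_membership(m, cluster_set([{"a"}, {"b"}]))
        np.testing.assert_allclose(red.values, m.values.astype(float))
        assert red.row_labels == ("a", "b")

    def test_merging_identical_rows_is_idempotent(self):
        m = membership_from_rows({"a": "0110", "b": "0110", "c": "0110"})
        red = collapse_membership(m, cluster_set([{"a", "b", "c"}]))
        np.testing.assert_allclose(red.values, [[0, 1, 1, 0]])

    def test_values_bounded_by_member_rows(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, size=(4, 7))
        vals[vals.sum(axis=1) == 0, 0] = 1
        m = membership_from_rows(
            {f"c{i}": "".join(map(str, vals[i])) for i in range(4)}
        )
        red = collapse_membership(m, cluster_set([{"c0", "c1", "c2", "c3"}]))
        assert (red.values >= vals.min(axis=0)).all()
        assert (red.values <= vals.max(axis=0)).all()

    def test_unknown_member_rejected(self):
        m = membership_from_rows({"a": "10", "b": "01"})
        with pytest.raises(ValidationError, match="unknown"):
            collapse_membership(m, cluster_set([{"a", "ghost"}]))


class TestCollapseFDR:
    def test_cells_take_the_minimum(self):
        f = FDRMatrix(("a", "b"), ("e1", "e2"), np.array([[0.05, 0.2], [0.1, 0.01]]))
        red = collapse_fdr(f, cluster_set([{"a", "b"}]))
        np.testing.assert_allclose(red.values, [[0.05, 0.01]])
        assert red.kind == "fdr"

    def test_singleton_unchanged(self):
        f = FDRMatrix(("a",), ("e1",), np.array([[0.3]]))
        red = collapse_fdr(f, cluster_set([{"a"}]))
        np.testing.assert_allclose(red.values, [[0.3]])

    def test_never_exceeds_any_member_row(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(3, 4))
        f = FDRMatrix(("a", "b", "c"), tuple("wxyz"), vals)
        red = collapse_fdr(f, cluster_set([{"a", "b", "c"}]))
        assert (red.values <= vals).all()


class TestApplyClusters:
    def test_consistent_with_direct_collapse(self):
        m = membership_from_rows({"a": "110", "b": "110", "c": "001"})
        cs = multiclust(graph_from_edges("abc", [("a", "b")]))
        direct = collapse_membership(m, cs)
        applied = apply_clusters(m, cs)
        assert applied.row_labels == direct.row_labels
        np.testing.assert_allclose(applied.values, direct.values)

    def test_missing_member_degrades_the_group(self, caplog):
        m = membership_from_rows({"a": "110"})
        with caplog.at_level("WARNING", logger="goclique"):
            red = apply_clusters(m, cluster_set([{"a", "b"}]))
        assert red.row_labels == ("a",)  # singleton now, bare name
        np.testing.assert_allclose(red.values, [[1, 1, 0]])
        assert any("dropping absent" in r.message for r in caplog.records)

    def test_fully_absent_group_is_omitted(self):
        m = membership_from_rows({"a": "10"})
        red = apply_clusters(m, cluster_set([{"a"}, {"x", "y"}]))
        assert red.row_labels == ("a",)


class TestMetaCIM:
    def test_shared_category_has_two_ones(self):
        meta = build_meta_cim(cluster_set([{"A", "B"}, {"B", "C"}, {"D"}]))
        assert meta.row_labels == ("A", "B", "C")
        assert meta.column_labels == ("group_1", "group_2")
        np.testing.assert_array_equal(meta.values, [[1, 0], [1, 1], [0, 1]])

    def test_all_singletons_give_empty_meta(self):
        meta = build_meta_cim(cluster_set([{"A"}, {"B"}]))
        assert meta.is_empty
        assert meta.shape == (0, 0)

    def test_single_all_category_cluster(self):
        meta = build_meta_cim(cluster_set([{"A", "B", "C"}]))
        assert meta.shape == (3, 1)
        assert meta.values.sum() == 3

    def test_column_sums_at_least_two(self):
        meta = build_meta_cim(
            cluster_set([{"A", "B"}, {"B", "C", "D"}, {"E"}, {"A", "D"}])
        )
        assert (meta.values.sum(axis=0) >= 2).all()
        assert (meta.values.sum(axis=1) >= 1).all()


class TestCompressionRatio:
    @pytest.mark.parametrize(
        "n_in, n_out, expected",
        [(73, 38, 1.92), (66, 27, 2.44), (66, 20, 3.30), (10, 10, 1.00)],
    )
    def test_reported_to_two_decimals(self, n_in, n_out, expected):
        assert compression_ratio(n_in, n_out) == expected

    def test_zero_rows_rejected(self):
        with pytest.raises(ValidationError):
            compression_ratio(5, 0)
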