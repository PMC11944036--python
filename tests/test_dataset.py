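import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathcolor.chem_io import AnnotationTable, PathwayHierarchy
from pathcolor.coloring import FeatureMatrix, featurize_compounds
from pathcolor.dataset import (
    aggregate_pathway_features,
    assign_levels,
    build_dataset,
    cross_join,
    deduplicate,
    normalize,
    pathway_size,
    subset_by_level,
)
from pathcolor.errors import EmptyInputError, HierarchyError


def random_matrix(rng, n, width, prefix="E"):
    return FeatureMatrix(
        [f"{prefix}{i}" for i in range(n)],
        [f"c{j}" for j in range(width)],
        rng.integers(0, 4, size=(n, width)),
    )


class TestAggregate:
    def test_single_member_pathway_equals_compound_row(self, methane, water):
        fm = featurize_compounds([methane, water], "auto")
        table = AnnotationTable({("methane", "P1")})
        pm = aggregate_pathway_features(fm, table)
        assert pm.entity_ids == ["P1"]
        assert np.array_equal(pm.values[0], fm.row("methane"))

    def test_methane_plus_water_sums(self, methane, water):
        fm = featurize_compounds([methane, water], "auto")
        table = AnnotationTable({("methane", "P1"), ("water", "P1")})
        pm = aggregate_pathway_features(fm, table)
        assert pm.values[0].tolist() == [1, 1]

    def test_additivity_against_summation_oracle(self, rng):
        fm = random_matrix(rng, 12, 8)
        pairs = {
            (f"E{rng.integers(0, 12)}", f"P{rng.integers(0, 4)}") for _ in range(30)
        }
        table = AnnotationTable(pairs)
        pm = aggregate_pathway_features(fm, table)
        members = table.pathway_members()
        for pid in pm.entity_ids:
            expected = sum(fm.row(c) for c in members[pid])
            assert np.array_equal(pm.row(pid), expected)

    def test_pathway_without_featured_members_excluded(self, rng):
        fm = random_matrix(rng, 3, 4)
        table = AnnotationTable({("E0", "P1"), ("ghost", "P2")})
        pm = aggregate_pathway_features(fm, table)
        assert pm.entity_ids == ["P1"]
        with pytest.raises(EmptyInputError):
            aggregate_pathway_features(fm, AnnotationTable({("ghost", "P2")}))


class TestPathwaySize:
    def test_examples(self):
        table = AnnotationTable({("a", "P1"), ("a", "P2"), ("b", "P2"), ("x", "P3")})
        sizes = pathway_size(table, {"a": 5, "b": 12, "z": 1})
        assert sizes["P1"] == 5
        assert sizes["P2"] == 17
        assert "P3" not in sizes  # no sized member -> excluded, not 0


class TestDeduplicate:
    def test_identical_rows_merge_annotations(self):
        fm = FeatureMatrix(["B", "A"], ["c"], np.array([[2], [2]]))
        table = AnnotationTable({("A", "P1"), ("B", "P2")})
        out, merged, rep = deduplicate(fm, table, "compound")
        assert out.entity_ids == ["A"]  # lexicographically smallest kept
        assert merged.pairs == {("A", "P1"), ("A", "P2")}
        assert rep == {"B": "A"}

    def test_distinct_rows_identity(self, rng):
        fm = random_matrix(rng, 5, 3)
        fm.values[:, 0] = np.arange(5)  # force distinct
        table = AnnotationTable({("E0", "P0")})
        out, merged, rep = deduplicate(fm, table)
        assert out.entity_ids == fm.entity_ids and rep == {}

    def test_idempotence_on_random_matrices(self, rng):
        for _ in range(10):
            fm = random_matrix(rng, 8, 2)
            table = AnnotationTable({("E0", "P0"), ("E3", "P1")})
            once_m, once_t, _ = deduplicate(fm, table)
            twice_m, twice_t, rep2 = deduplicate(once_m, once_t)
            assert twice_m.equals(once_m)
            assert twice_t.pairs == once_t.pairs and rep2 == {}


class TestNormalize:
    def test_column_max_scaling(self):
        fm = FeatureMatrix(["a", "b", "c"], ["x"], np.array([[0], [2], [4]]))
        assert normalize(fm).values[:, 0].tolist() == [0, 0.5, 1.0]

    def test_binary_matrix_unchanged(self, rng):
        fm = FeatureMatrix(["a", "b"], ["x", "y"], np.array([[0, 1], [1, 1]]))
        assert np.array_equal(normalize(fm).values, fm.values)

    def test_range_and_max_attained(self, rng):
        fm = random_matrix(rng, 20, 10)
        out = normalize(fm)
        assert out.values.min() >= 0 and out.values.max() <= 1
        nonzero = fm.values.max(axis=0) > 0
        assert np.allclose(out.values.max(axis=0)[nonzero], 1.0)

    def test_zero_column_stays_zero(self):
        fm = FeatureMatrix(["a"], ["x", "y"], np.array([[0, 3]]))
        assert normalize(fm).values.tolist() == [[0.0, 1.0]]


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    arrays(
        np.int64,
        st.tuples(st.integers(1, 8), st.integers(1, 6)),
        elements=st.integers(0, 50),
    )
)
def test_normalize_property(values):
    """Column-max scaling always lands in [0,1], attains 1 on nonzero columns,
    and is idempotent."""
    fm = FeatureMatrix(
        [f"E{i}" for i in range(values.shape[0])],
        [f"c{j}" for j in range(values.shape[1])],
        values,
    )
    out = normalize(fm)
    assert out.values.min() >= 0.0 and out.values.max() <= 1.0
    nonzero = values.max(axis=0) > 0
    assert np.allclose(out.values.max(axis=0)[nonzero], 1.0)
    assert np.allclose(normalize(out).values, out.values)


class TestCrossJoin:
    def test_single_annotated_pair(self, rng):
        cm = random_matrix(rng, 1, 2, "C")
        pm = random_matrix(rng, 1, 2, "P")
        ds = cross_join(cm, pm, AnnotationTable({("C0", "P0")}))
        assert ds.n_entries == 1 and ds.labels.tolist() == [True]

    def test_against_nested_loop_oracle(self, rng):
        cm = random_matrix(rng, 2, 3, "C")
        pm = random_matrix(rng, 3, 3, "P")
        table = AnnotationTable({("C0", "P1"), ("C1", "P2")})
        ds = cross_join(cm, pm, table)
        assert ds.n_entries == 6 and ds.n_positive == 2
        k = 0
        for ci, cid in enumerate(cm.entity_ids):
            for pi, pid in enumerate(pm.entity_ids):
                assert ds.labels[k] == ((cid, pid) in table.pairs)
                feats = ds.entry_features(np.array([k]))[0]
                assert np.allclose(feats[:3], cm.values[ci])
                assert np.allclose(feats[3:], pm.values[pi])
                k += 1

    def test_empty_matrix_errors(self, rng):
        cm = random_matrix(rng, 1, 2, "C")
        empty = FeatureMatrix([], ["c0", "c1"], np.zeros((0, 2)))
        with pytest.raises(EmptyInputError):
            cross_join(cm, empty, AnnotationTable({("C0", "P0")}))

    def test_positive_count_restricted_to_retained_ids(self, rng):
        cm = random_matrix(rng, 2, 2, "C")
        pm = random_matrix(rng, 2, 2, "P")
        table = AnnotationTable({("C0", "P0"), ("C9", "P0"), ("C1", "P9")})
        ds = cross_join(cm, pm, table)
        assert ds.n_positive == 1


class TestAssignLevels:
    def test_root_is_level_one(self):
        lm = assign_levels(PathwayHierarchy({("A", "B")}))
        assert lm.level["A"] == 1 and lm.level["B"] == 2

    def test_chain_of_nine_display_grouping(self):
        edges = {(f"N{i}", f"N{i + 1}") for i in range(8)}
        lm = assign_levels(PathwayHierarchy(edges))
        assert lm.level["N8"] == 9
        assert lm.display_level("N8") == "L6+"
        assert lm.display_level("N4") == "L5"

    def test_diamond_min_depth_bfs_oracle(self):
        import networkx as nx

        edges = {("A", "B"), ("A", "C"), ("C", "D"), ("B", "D")}
        lm = assign_levels(PathwayHierarchy(edges))
        assert lm.level["D"] == 3
        # independent oracle: BFS shortest path from any root
        g = nx.DiGraph(list(edges))
        for node in g.nodes:
            expected = 1 + min(
                nx.shortest_path_length(g, root, node)
                for root in [n for n in g.nodes if g.in_degree(n) == 0]
                if nx.has_path(g, root, node)
            )
            assert lm.level[node] == expected

    def test_annotated_pathway_missing_from_hierarchy_gets_level1(self):
        lm = assign_levels(PathwayHierarchy({("A", "B")}), extra_pathways={"Z"})
        assert lm.level["Z"] == 1

    def test_cycle_raises(self):
        with pytest.raises(HierarchyError):
            assign_levels(PathwayHierarchy({("A", "B"), ("B", "A")}))


class TestSubsetByLevel:
    def build(self, rng, level_of):
        pm = random_matrix(rng, len(level_of), 2, "P")
        pm.entity_ids = list(level_of)
        cm = random_matrix(rng, 4, 2, "C")
        table = AnnotationTable({("C0", pm.entity_ids[0])})
        from pathcolor.dataset import LevelMap

        return cross_join(cm, pm, table), LevelMap(dict(level_of))

    def test_min_level_one_is_identity(self, rng):
        ds, lm = self.build(rng, {"P0": 1, "P1": 2})
        assert subset_by_level(ds, lm, 1) is ds

    def test_level_subset_counts(self, rng):
        ds, lm = self.build(rng, {"P0": 1, "P1": 1, "P2": 2, "P3": 2, "P4": 2})
        l2 = subset_by_level(ds, lm, 2)
        assert l2.n_entries == 4 * 3
        assert l2.n_compounds == 4

    def test_nested_pathway_sets(self, rng):
        ds, lm = self.build(rng, {"P0": 1, "P1": 2, "P2": 3})
        l2 = subset_by_level(ds, lm, 2)
        l3 = subset_by_level(ds, lm, 3)
        assert set(l3.pathway_matrix.entity_ids) <= set(l2.pathway_matrix.entity_ids)

    def test_labels_follow_pathways(self, rng):
        ds, lm = self.build(rng, {"P0": 1, "P1": 2})
        l2 = subset_by_level(ds, lm, 2)
        grid = ds.labels.reshape(4, 2)
        assert np.array_equal(l2.labels, grid[:, 1])

    def test_all_removed_errors(self, rng):
        ds, lm = self.build(rng, {"P0": 1, "P1": 1})
        with pytest.raises(EmptyInputError):
            subset_by_level(ds, lm, 2)


class TestBuildDataset:
    def test_end_to_end_on_synthetic_study(self, small_study):
        ds, levels = build_dataset(
            small_study.graphs,
            small_study.annotations,
            small_study.hierarchy,
            max_radius=1,
        )
        assert ds.n_entries == ds.n_compounds * ds.n_pathways
        assert 0 < ds.n_positive < ds.n_entries
        assert ds.compound_matrix.values.max() <= 1.0
        # dedup can only merge annotation pairs, never invent them
        assert 0 < ds.n_positive <= len(small_study.annotations.pairs)
        assert all(
            levels.get(p) is not None for p in ds.pathway_matrix.entity_ids
        )
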