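"""Tour segmentation, GO-similarity merging, and density filtering."""

from __future__ import annotations

import pytest

from ppintour import (
    GOAnnotationMap,
    ModuleSet,
    PostprocessParams,
    PPINGraph,
    Tour,
    filter_by_density,
    merge_by_function,
    module_density,
    module_similarity,
    protein_similarity,
    segment_tour,
    tour_length,
)


@pytest.fixture()
def nn_tour(example_dist) -> Tour:
    order = ("A", "D", "E", "C", "B", "F")
    return Tour(order=order, length=tour_length(order, example_dist))


class TestSegmentTour:
    def test_cut_at_long_edges_on_worked_example(self, nn_tour, example_dist):
        # only the D-E edge (0.4286) exceeds delta = 0.40
        ms = segment_tour(nn_tour, example_dist, cut_threshold=0.40)
        assert set(ms.modules) == {frozenset("AD"), frozenset("BCEF")}
        assert ms.unassigned == frozenset()

    def test_threshold_one_keeps_everything_together(self, nn_tour, example_dist):
        ms = segment_tour(nn_tour, example_dist, cut_threshold=1.0)
        assert ms.modules == (frozenset("ABCDEF"),)

    def test_threshold_zero_with_positive_distances_gives_singletons(
        self, nn_tour, example_dist
    ):
        ms = segment_tour(nn_tour, example_dist, cut_threshold=0.0)
        assert all(len(m) == 1 for m in ms.modules)
        assert len(ms.modules) == 6

    def test_default_threshold_is_75th_percentile_of_tour_edges(
        self, nn_tour, example_dist
    ):
        # tour edges: 1/3, 3/7, 1/3, 1/3, 1/3 -> 75th percentile 1/3,
        # so exactly the one edge above 1/3 is cut
        ms = segment_tour(nn_tour, example_dist, cut_threshold=None)
        assert set(ms.modules) == {frozenset("AD"), frozenset("BCEF")}

    def test_module_count_non_increasing_in_threshold(self, nn_tour, example_dist):
        counts = [
            len(segment_tour(nn_tour, example_dist, cut_threshold=d).modules)
            for d in (0.0, 0.2, 0.35, 0.45, 0.7, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestProteinSimilarity:
    def test_same_protein_is_one(self):
        assert protein_similarity(set(), {"x"}, same_protein=True) == 1.0

    def test_jaccard_of_term_sets(self):
        assert protein_similarity({"t1", "t2"}, {"t2", "t3"}) == pytest.approx(1 / 3)

    def test_disjoint_nonempty_sets_are_zero(self):
        assert protein_similarity({"t1"}, {"t2"}) == 0.0

    def test_two_unannotated_proteins_are_zero(self):
        assert protein_similarity(set(), set()) == 0.0


class TestModuleSimilarity:
    def test_singletons_reduce_to_protein_similarity(self):
        go = GOAnnotationMap({"i": {"a", "b"}, "j": {"b", "c"}})
        # s(i,j) = 1/3, min size 1
        assert module_similarity(
            frozenset({"i"}), frozenset({"j"}), go
        ) == pytest.approx(1 / 3)

    def test_cross_pair_sum_normalised_by_smaller_module(self):
        # s(i1,j1) = |{a}| / |{a..e}| = 0.2, s(i2,j1) = |{a,b}| / |{a..e}| = 0.4
        go = GOAnnotationMap(
            {"i1": {"a"}, "i2": {"a", "b"}, "j1": {"a", "b", "c", "d", "e"}}
        )
        s = module_similarity(frozenset({"i1", "i2"}), frozenset({"j1"}), go)
        assert s == pytest.approx(0.6)

    def test_mutually_disjoint_annotations_give_zero(self):
        go = GOAnnotationMap({"i": {"a"}, "j": {"b"}, "k": {"c"}})
        assert module_similarity(frozenset({"i", "j"}), frozenset({"k"}), go) == 0.0

    def test_overlapping_modules_rejected(self):
        go = GOAnnotationMap()
        with pytest.raises(ValueError, match="overlap"):
            module_similarity(frozenset({"i", "j"}), frozenset({"j"}), go)

    def test_symmetry(self):
        go = GOAnnotationMap({"i": {"a", "b"}, "j": {"b"}, "k": {"a"}})
        a, b = frozenset({"i"}), frozenset({"j", "k"})
        assert module_similarity(a, b, go) == pytest.approx(module_similarity(b, a, go))


class TestMergeByFunction:
    def test_similar_pair_merges(self):
        go = GOAnnotationMap({"i": {"a", "b"}, "j": {"a", "b"}})  # s = 1 > theta
        ms = ModuleSet(modules=(frozenset({"i"}), frozenset({"j"})))
        out = merge_by_function(ms, go, merge_threshold=0.05)
        assert out.modules == (frozenset({"i", "j"}),)

    def test_all_pairs_below_threshold_is_a_fixed_point(self):
        go = GOAnnotationMap({"i": {"a"}, "j": {"b"}, "k": {"c"}})
        ms = ModuleSet(
            modules=(frozenset({"i"}), frozenset({"j"}), frozenset({"k"}))
        )
        out = merge_by_function(ms, go, merge_threshold=0.05)
        assert set(out.modules) == set(ms.modules)

    def test_cascade_merge_after_top_pair_union(self):
        # s(a*,b1) = 1/2, s(a*,c1) = s(b1,c1) = 1/3; theta = 0.75:
        # initially only S({a1,a2},{b1}) = 1.0 exceeds theta, but the union
        # {a1,a2,b1} then reaches S = 1.0 with {c1}, so everything merges
        go = GOAnnotationMap(
            {
                "a1": {"p"},
                "a2": {"p"},
                "b1": {"p", "q"},
                "c1": {"p", "q", "r"},
            }
        )
        m1, m2, m3 = frozenset({"a1", "a2"}), frozenset({"b1"}), frozenset({"c1"})
        assert module_similarity(m1, m2, go) == pytest.approx(1.0)
        assert module_similarity(m1, m3, go) == pytest.approx(2 / 3)
        assert module_similarity(m2, m3, go) == pytest.approx(2 / 3)
        out = merge_by_function(
            ModuleSet(modules=(m1, m2, m3)), go, merge_threshold=0.75
        )
        assert out.modules == (frozenset({"a1", "a2", "b1", "c1"}),)
        # exhaustive recomputation confirms the cascade: after the first
        # merge S({a1,a2,b1},{c1}) = (1/3 + 1/3 + 2/3) / 1 = 4/3 > theta
        assert module_similarity(m1 | m2, m3, go) == pytest.approx(4 / 3)

    def test_merge_count_bounded_and_unassigned_preserved(self):
        go = GOAnnotationMap({p: {"shared"} for p in "abcdef"})
        ms = ModuleSet(
            modules=tuple(frozenset({p}) for p in "abcdef"),
            unassigned=frozenset({"z"}),
        )
        out = merge_by_function(ms, go, merge_threshold=0.5)
        assert len(ms.modules) - len(out.modules) <= len(ms.modules) - 1
        assert out.modules == (frozenset("abcdef"),)
        assert out.unassigned == frozenset({"z"})


class TestDensity:
    def test_triangle_module_on_worked_example(self, example_graph):
        # B-D, B-E, D-E are all edges of the example network
        assert module_density(frozenset("BDE"), example_graph) == 1.0

    def test_partial_density(self):
        g = PPINGraph([("a", "b"), ("c", "d")])
        assert module_density(frozenset({"a", "b", "c"}), g) == pytest.approx(1 / 3)

    def test_singleton_density_is_zero_by_convention(self, example_graph):
        assert module_density(frozenset({"A"}), example_graph) == 0.0


class TestFilterByDensity:
    def test_zero_bound_keeps_all_non_singletons(self, example_graph):
        ms = ModuleSet(modules=(frozenset("AD"), frozenset("BCEF")))
        out = filter_by_density(ms, example_graph, density_min=0.0)
        assert set(out.modules) == set(ms.modules)

    def test_bound_one_keeps_only_cliques(self, example_graph):
        # {B,D,E} is a triangle; {A,C,F} has only A-C and C-F (density 2/3)
        ms = ModuleSet(modules=(frozenset("BDE"), frozenset("ACF")))
        out = filter_by_density(ms, example_graph, density_min=1.0)
        assert out.modules == (frozenset("BDE"),)
        assert out.unassigned == frozenset("ACF")

    def test_sparse_module_moves_to_unassigned_as_a_whole(self):
        g = PPINGraph([("B", "D"), ("B", "E"), ("D", "E"), ("A", "Y"), ("X", "Y")])
        ms = ModuleSet(modules=(frozenset("BDE"), frozenset("AX")))
        out = filter_by_density(ms, g, density_min=0.5)
        assert out.modules == (frozenset("BDE"),)
        assert out.unassigned == frozenset("AX")

    def test_singletons_follow_the_flag(self, example_graph):
        ms = ModuleSet(modules=(frozenset({"A"}), frozenset("BDE")))
        kept = filter_by_density(ms, example_graph, 0.5, keep_singletons=True)
        dropped = filter_by_density(ms, example_graph, 0.5, keep_singletons=False)
        assert frozenset({"A"}) in kept.modules
        assert frozenset({"A"}) not in dropped.modules
        assert "A" in dropped.unassigned


class TestModuleSetAndParams:
    def test_partition_conservation_through_all_stages(self, nn_tour, example_dist, example_graph):
        universe = frozenset(example_dist.labels)
        go = GOAnnotationMap({"A": {"x"}, "D": {"x"}})
        ms = segment_tour(nn_tour, example_dist, cut_threshold=0.40)
        assert ms.all_proteins == universe
        merged = merge_by_function(ms, go, merge_threshold=0.05)
        assert merged.all_proteins == universe
        final = filter_by_density(merged, example_graph, density_min=0.9)
        assert final.all_proteins == universe

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ModuleSet(modules=(frozenset("AB"), frozenset("BC")))

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ModuleSet(modules=(frozenset(),))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cut_threshold": 1.5},
            {"merge_threshold": -0.1},
            {"density_min": 2.0},
        ],
    )
    def test_invalid_postprocess_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PostprocessParams(**kwargs)
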