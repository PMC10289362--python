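import math

import dendropy
import numpy as np
import pytest

from pathscape.distances import (
    LeafSetError,
    bhv_distance,
    bhv_distance_bruteforce,
    cone_path_length,
    distance_matrix,
    geodesic,
    incompatibility_graph,
    rf_distance,
    splits_compatible,
    wrf_distance,
)
from pathscape.simulate import SimSpec, random_tree
from pathscape.treeio import parse_newick, splits_of, write_newick

from conftest import random_pair


class TestRF:
    def test_identical_topologies_give_zero(self, rng):
        t = random_tree(SimSpec(n_leaves=7), rng)
        scaled = t.copy()
        for node in scaled.edges():
            node.length *= 2.0
        assert rf_distance(t, scaled) == 0

    def test_quartet_nni_gives_two(self, quartet_pair):
        assert rf_distance(*quartet_pair) == 2

    def test_six_leaf_single_nni_gives_two(self):
        # one NNI swaps B and C across the AB|rest edge: only that split
        # changes ({A,B} -> {A,C}), so the symmetric difference has size 2
        t1 = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,(E:1,F:1):1):1);")
        t2 = parse_newick("(((A:1,C:1):1,B:1):1,(D:1,(E:1,F:1):1):1);")
        assert rf_distance(t1, t2) == 2

    def test_differing_leaf_sets_name_the_taxa(self):
        t1 = parse_newick("((A:1,B:1):1,C:1);")
        t2 = parse_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(LeafSetError, match="C"):
            rf_distance(t1, t2)

    def test_matches_dendropy_on_random_pairs(self, rng):
        """Independent cross-check against dendropy's RF implementation."""
        for _ in range(50):
            t1, t2 = random_pair(int(rng.integers(5, 10)), rng)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                                   taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                                   taxon_namespace=ns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expected


class TestWRF:
    def test_self_distance_zero(self, rng):
        t = random_tree(SimSpec(n_leaves=6), rng)
        assert wrf_distance(t, t) == 0.0

    def test_single_edge_difference(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,B:1):1.3,(C:1,D:1):1);")
        assert wrf_distance(t1, t2) == pytest.approx(0.3)

    def test_disjoint_internal_splits_sum(self):
        t1 = parse_newick("((A:1,B:1):0.4,(C:1,D:1):0);")
        t2 = parse_newick("((A:1,C:1):0.7,(B:1,D:1):0);")
        # AB|CD carries 0.4, AC|BD carries 0.7, pendants identical
        assert wrf_distance(t1, t2) == pytest.approx(0.4 + 0.7)


class TestCompatibility:
    @pytest.mark.parametrize(
        "m1, m2, n, expected",
        [
            (0b1100, 0b1010, 4, False),  # AB|CD vs AC|BD
            (0b00110, 0b11000, 5, True),  # AB|CDE-ish disjoint clades
            (0b0010, 0b1100, 4, True),  # pendant vs anything
        ],
    )
    def test_pairs(self, m1, m2, n, expected):
        assert splits_compatible(m1, m2, n) is expected

    def test_incompatibility_graph_edges(self):
        g = incompatibility_graph([0b1100], [0b1010, 0b0010], 4)
        assert g.has_edge(("a", 0b1100), ("b", 0b1010))
        assert not g.has_edge(("a", 0b1100), ("b", 0b0010))


class TestGeodesic:
    def test_identical_trees(self, rng):
        t = random_tree(SimSpec(n_leaves=7), rng)
        g = geodesic(t, t.copy())
        assert g.length == 0.0
        assert len(g.support.legs) == 0

    def test_same_topology_reduces_to_euclidean(self, rng):
        t1 = random_tree(SimSpec(n_leaves=7), rng)
        t2 = t1.copy()
        for node in t2.edges():
            node.length *= 1.0 + 0.5 * rng.random()
        g = geodesic(t1, t2)
        assert len(g.support.legs) == 0
        s1, s2 = splits_of(t1), splits_of(t2)
        euclid = math.sqrt(sum((s1[m] - s2[m]) ** 2 for m in s1))
        assert g.length == pytest.approx(euclid, abs=1e-12)

    def test_single_incompatible_pair_is_cone_path(self):
        a, b = 0.8, 1.7
        t1 = parse_newick(f"((A:1,B:1):{a/2},(C:1,D:1):{a/2});")
        t2 = parse_newick(f"((A:1,C:1):{b/2},(B:1,D:1):{b/2});")
        assert bhv_distance(t1, t2) == pytest.approx(a + b, abs=1e-12)
        assert bhv_distance_bruteforce(t1, t2) == pytest.approx(a + b, abs=1e-12)

    def test_support_invariants_hold(self, rng):
        for _ in range(40):
            t1, t2 = random_pair(8, rng)
            g = geodesic(t1, t2)
            s1 = {m for m, v in splits_of(t1).items() if m not in splits_of(t2)}
            s2 = {m for m, v in splits_of(t2).items() if m not in splits_of(t1)}
            a_union = set().union(*(leg.a_splits for leg in g.support.legs), set())
            b_union = set().union(*(leg.b_splits for leg in g.support.legs), set())
            assert a_union == s1 and b_union == s2
            # nondecreasing ratios
            ratios = [leg.ratio for leg in g.support.legs]
            assert all(r1 <= r2 + 1e-12 for r1, r2 in zip(ratios, ratios[1:]))
            # every intermediate orthant's split set is pairwise compatible
            n = t1.n_leaves
            k = len(g.support.legs)
            for i in range(k + 1):
                masks = list(g.support.common)
                for leg in g.support.legs[:i]:
                    masks.extend(leg.b_splits)
                for leg in g.support.legs[i:]:
                    masks.extend(leg.a_splits)
                assert all(
                    splits_compatible(x, y, n)
                    for xi, x in enumerate(masks)
                    for y in masks[xi + 1:]
                )

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(60):
            a, b = random_pair(8, rng)
            c = random_tree(SimSpec(n_leaves=8), rng)
            for dist in (bhv_distance, wrf_distance):
                dab, dba = dist(a, b), dist(b, a)
                assert dab == pytest.approx(dba, abs=1e-14)
                assert dist(a, c) <= dab + dist(b, c) + 1e-9

    def test_bounded_by_cone_path_and_wrf(self, rng):
        for _ in range(40):
            t1, t2 = random_pair(8, rng)
            g = geodesic(t1, t2)
            cone = cone_path_length(t1, t2)
            assert g.length <= cone + 1e-12
            assert g.length <= wrf_distance(t1, t2) + 1e-12
            if len(g.support.legs) == 1:
                assert g.length == pytest.approx(cone, abs=1e-12)


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        trees = [random_tree(SimSpec(n_leaves=6), rng) for _ in range(5)]
        for metric in ("bhv", "wrf", "rf"):
            mat = distance_matrix(trees, metric=metric)
            assert np.allclose(mat, mat.T)
            assert np.all(np.diag(mat) == 0)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            distance_matrix([], metric="kendall")
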