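"""Tree distances: Robinson-Foulds, weighted RF, and the BHV geodesic.

BHV treespace is piecewise Euclidean: each orthant collects the trees sharing
one topology, with coordinates given by that topology's split lengths, and
orthants are glued along shared-split boundaries.  Between any two trees
there is a unique shortest path (geodesic) whose length is the BHV distance.

The geodesic is computed with the successive-refinement (GTP) algorithm:
start from the cone path, whose support is the single leg
``(A_1, B_1) = (splits only in T1, splits only in T2)``, and repeatedly try
to split a leg ``(A_i, B_i)`` by solving a minimum-weight vertex cover on the
bipartite incompatibility graph between its two sides, with node weights
``|e|^2 / ||A_i||^2`` (resp. ``/ ||B_i||^2``).  A cover of weight < 1 yields
a strictly shorter path; the geodesic is reached when no leg can be split.
The cover is found exactly via max-flow/min-cut (Koenig duality).

Splits common to both trees -- always including all pendant splits -- behave
as shared Euclidean coordinates and contribute squared length differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .treeio import (
    DEFAULT_CONTRACT_TOL,
    Tree,
    canonical_split,
    is_pendant,
    split_leaves,
    splits_of,
)

__all__ = [
    "Leg",
    "GeodesicSupport",
    "Geodesic",
    "LeafSetError",
    "rf_distance",
    "wrf_distance",
    "splits_compatible",
    "incompatibility_graph",
    "geodesic",
    "bhv_distance",
    "bhv_distance_bruteforce",
    "cone_path_length",
    "distance_matrix",
]

_RATIO_TOL = 1e-12


class LeafSetError(ValueError):
    """The two trees are not over the same leaf set."""


def _check_taxa(t1: Tree, t2: Tree) -> None:
    if t1.taxa == t2.taxa:
        return
    only1 = sorted(set(t1.taxa) - set(t2.taxa))
    only2 = sorted(set(t2.taxa) - set(t1.taxa))
    parts = []
    if only1:
        parts.append(f"only in first tree: {', '.join(only1)}")
    if only2:
        parts.append(f"only in second tree: {', '.join(only2)}")
    raise LeafSetError("leaf sets differ; " + "; ".join(parts))


def _norm(lengths) -> float:
    return math.sqrt(sum(v * v for v in lengths))


# ---------------------------------------------------------------------------
# RF family
# ---------------------------------------------------------------------------


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Unweighted Robinson-Foulds: |symmetric difference| of nontrivial splits."""
    _check_taxa(t1, t2)
    n = t1.n_leaves
    s1 = {m for m in splits_of(t1) if not is_pendant(m, n)}
    s2 = {m for m in splits_of(t2) if not is_pendant(m, n)}
    return len(s1 ^ s2)


def wrf_distance(t1: Tree, t2: Tree) -> float:
    """Weighted Robinson-Foulds: L1 distance over the union of all splits.

    Pendant splits are included; a split present in only one tree contributes
    its full length.  This is the L1 analogue of the BHV (L2) distance and is
    at most twice the BHV distance.
    """
    _check_taxa(t1, t2)
    s1 = splits_of(t1)
    s2 = splits_of(t2)
    # sorted so the floating-point sum is exactly symmetric in (t1, t2)
    return sum(
        abs(s1.get(m, 0.0) - s2.get(m, 0.0)) for m in sorted(s1.keys() | s2.keys())
    )


# ---------------------------------------------------------------------------
# Split compatibility
# ---------------------------------------------------------------------------


def splits_compatible(m1: int, m2: int, n_leaves: int) -> bool:
    """Two bipartitions are compatible iff some intersection cell is empty."""
    full = (1 << n_leaves) - 1
    return (
        m1 & m2 == 0
        or m1 & ~m2 & full == 0
        or ~m1 & m2 & full == 0
        or ~m1 & ~m2 & full == 0
    )


def incompatibility_graph(a_masks, b_masks, n_leaves: int) -> nx.Graph:
    """Bipartite graph with an edge for each incompatible (a, b) split pair.

    Nodes are ``("a", mask)`` / ``("b", mask)``; weights are attached by the
    caller (the geodesic refinement uses normalized squared lengths).
    """
    g = nx.Graph()
    g.add_nodes_from((("a", m) for m in a_masks), bipartite=0)
    g.add_nodes_from((("b", m) for m in b_masks), bipartite=1)
    for ma in a_masks:
        for mb in b_masks:
            if not splits_compatible(ma, mb, n_leaves):
                g.add_edge(("a", ma), ("b", mb))
    return g


# ---------------------------------------------------------------------------
# Geodesic support
# ---------------------------------------------------------------------------


@dataclass
class Leg:
    """One support pair (A_i, B_i): A_i drops to zero, B_i grows from zero."""

    a_splits: dict[int, float]  # mask -> length in T1
    b_splits: dict[int, float]  # mask -> length in T2

    @property
    def norm_a(self) -> float:
        return _norm(self.a_splits.values())

    @property
    def norm_b(self) -> float:
        return _norm(self.b_splits.values())

    @property
    def ratio(self) -> float:
        na, nb = self.norm_a, self.norm_b
        if na == 0.0:
            return 0.0
        if nb == 0.0:
            return math.inf
        return na / nb

    @property
    def boundary(self) -> float:
        """Position lambda at which A_i has shrunk to zero length."""
        na, nb = self.norm_a, self.norm_b
        if na == 0.0 and nb == 0.0:
            return 0.0
        return na / (na + nb)


@dataclass
class GeodesicSupport:
    """Ordered legs plus common splits defining a geodesic's orthant sequence."""

    legs: list[Leg]
    common: dict[int, tuple[float, float]]  # mask -> (length in T1, length in T2)


@dataclass
class Geodesic:
    t1: Tree
    t2: Tree
    support: GeodesicSupport
    length: float

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.t1.taxa


def _min_vertex_cover(a: dict[int, float], b: dict[int, float], n_leaves: int):
    """Min-weight vertex cover of the incompatibility graph via max-flow.

    Weights are normalized squared lengths so the whole of either side has
    weight exactly 1.  Returns ``(weight, cover_a, cover_b)``.
    """
    graph = incompatibility_graph(sorted(a), sorted(b), n_leaves)
    if graph.number_of_edges() == 0:
        return 0.0, set(), set()
    na2 = sum(v * v for v in a.values())
    nb2 = sum(v * v for v in b.values())
    flow = nx.DiGraph()
    for m in sorted(a):
        flow.add_edge("s", ("a", m), capacity=a[m] * a[m] / na2)
    for m in sorted(b):
        flow.add_edge(("b", m), "t", capacity=b[m] * b[m] / nb2)
    for u, v in sorted(graph.edges()):
        an, bn = (u, v) if u[0] == "a" else (v, u)
        flow.add_edge(an, bn)  # no capacity attribute = infinite
    _, flow_dict = nx.maximum_flow(
        flow, "s", "t", flow_func=nx.algorithms.flow.shortest_augmenting_path
    )
    # Derive the min cut ourselves: float flows leave ~1e-15 residuals on
    # saturated edges, which confuses networkx's exact-saturation partition.
    eps = 1e-10
    reachable = {"s"}
    frontier = ["s"]
    while frontier:
        u = frontier.pop()
        for v in flow.successors(u):
            cap = flow[u][v].get("capacity", math.inf)
            if v not in reachable and cap - flow_dict[u][v] > eps:
                reachable.add(v)
                frontier.append(v)
        for v in flow.predecessors(u):
            if v not in reachable and flow_dict[v][u] > eps:
                reachable.add(v)
                frontier.append(v)
    cover_a = {m for m in a if ("a", m) not in reachable}
    cover_b = {m for m in b if ("b", m) in reachable}
    weight = (
        sum(a[m] * a[m] for m in cover_a) / na2
        + sum(b[m] * b[m] for m in cover_b) / nb2
    )
    return weight, cover_a, cover_b


def _refine(a: dict[int, float], b: dict[int, float], n_leaves: int) -> list[Leg]:
    """Recursively split a leg while a vertex cover of weight < 1 exists."""
    if not a or not b:
        return [Leg(dict(a), dict(b))]
    weight, cover_a, cover_b = _min_vertex_cover(a, b, n_leaves)
    if weight >= 1.0 - _RATIO_TOL:
        return [Leg(dict(a), dict(b))]
    if (cover_a == set(a) and not cover_b) or (cover_b == set(b) and not cover_a):
        # Whole-side covers have weight exactly 1; reaching here means pure
        # floating-point noise, and splitting would not terminate.
        return [Leg(dict(a), dict(b))]
    # Split (A, B) into (C_A, B \ C_B) followed by (A \ C_A, C_B): the
    # cover guarantees A \ C_A is compatible with B \ C_B, so the combined
    # split sets of adjacent orthants remain valid trees.
    left_a = {m: v for m, v in a.items() if m in cover_a}
    left_b = {m: v for m, v in b.items() if m not in cover_b}
    right_a = {m: v for m, v in a.items() if m not in cover_a}
    right_b = {m: v for m, v in b.items() if m in cover_b}
    return _refine(left_a, left_b, n_leaves) + _refine(right_a, right_b, n_leaves)


def geodesic(t1: Tree, t2: Tree, tol: float = DEFAULT_CONTRACT_TOL) -> Geodesic:
    """Compute the BHV geodesic between two trees on the same leaf set.

    Splits exclusive to one tree with length <= ``tol`` are contracted before
    the support computation (they would otherwise produce degenerate
    0-norm ratio comparisons).  The returned support's legs are sorted by
    nondecreasing ``||A_i|| / ||B_i||`` with lexicographic tie-breaking.
    """
    _check_taxa(t1, t2)
    n = t1.n_leaves
    s1 = splits_of(t1)
    s2 = splits_of(t2)
    common = {m: (s1[m], s2[m]) for m in s1.keys() & s2.keys()}
    a_only = {m: v for m, v in s1.items() if m not in s2 and v > tol}
    b_only = {m: v for m, v in s2.items() if m not in s1 and v > tol}

    if not a_only and not b_only:
        legs: list[Leg] = []
    else:
        legs = _refine(a_only, b_only, n)
        legs = [leg for leg in legs if leg.a_splits or leg.b_splits]
        legs.sort(
            key=lambda leg: (
                leg.ratio,
                tuple(sorted(leg.a_splits)),
                tuple(sorted(leg.b_splits)),
            )
        )

    sq = sum((leg.norm_a + leg.norm_b) ** 2 for leg in legs)
    sq += sum((l1 - l2) ** 2 for l1, l2 in common.values())
    return Geodesic(t1, t2, GeodesicSupport(legs, common), math.sqrt(sq))


def bhv_distance(t1: Tree, t2: Tree, tol: float = DEFAULT_CONTRACT_TOL) -> float:
    """Length of the BHV geodesic between two trees."""
    return geodesic(t1, t2, tol=tol).length


def cone_path_length(t1: Tree, t2: Tree, tol: float = DEFAULT_CONTRACT_TOL) -> float:
    """Length of the cone path (through the shared-splits-only boundary).

    Always an upper bound on the BHV distance; equal to it when the geodesic
    support has a single leg.
    """
    _check_taxa(t1, t2)
    s1 = splits_of(t1)
    s2 = splits_of(t2)
    common = s1.keys() & s2.keys()
    na = _norm(v for m, v in s1.items() if m not in common and v > tol)
    nb = _norm(v for m, v in s2.items() if m not in common and v > tol)
    sq = (na + nb) ** 2 + sum((s1[m] - s2[m]) ** 2 for m in common)
    return math.sqrt(sq)


# ---------------------------------------------------------------------------
# Exhaustive reference for small trees
# ---------------------------------------------------------------------------


def _ordered_partitions(items: list, k: int):
    """All assignments of items to k ordered (possibly empty) blocks."""
    if not items:
        yield [[] for _ in range(k)]
        return
    head, tail = items[0], items[1:]
    for rest in _ordered_partitions(tail, k):
        for i in range(k):
            blocks = [list(block) for block in rest]
            blocks[i].append(head)
            yield blocks


def bhv_distance_bruteforce(
    t1: Tree, t2: Tree, tol: float = DEFAULT_CONTRACT_TOL
) -> float:
    """BHV distance by exhaustive enumeration of valid ordered supports.

    Enumerates every pair of ordered partitions ``(A_1..A_k), (B_1..B_k)``
    of the tree-exclusive splits such that (a) for every i, the split set
    ``C u B_1..B_i u A_{i+1}..A_k`` is pairwise compatible, and (b) the
    ratios ``||A_i|| / ||B_i||`` are nondecreasing (a support violating the
    ratio ordering does not describe a traversable path, so its formula
    value is not a path length).  Scores each valid support with the
    path-length formula and returns the minimum.  Exponential; intended as
    an independent reference for trees with few leaves.
    """
    _check_taxa(t1, t2)
    n = t1.n_leaves
    s1 = splits_of(t1)
    s2 = splits_of(t2)
    common = {m: (s1[m], s2[m]) for m in s1.keys() & s2.keys()}
    a_only = {m: v for m, v in s1.items() if m not in s2 and v > tol}
    b_only = {m: v for m, v in s2.items() if m not in s1 and v > tol}
    common_sq = sum((l1 - l2) ** 2 for l1, l2 in common.values())

    if not a_only and not b_only:
        return math.sqrt(common_sq)

    common_masks = list(common)
    a_masks = sorted(a_only)
    b_masks = sorted(b_only)

    def valid(a_blocks, b_blocks) -> bool:
        k = len(a_blocks)
        for i in range(k + 1):
            current = common_masks + [
                m for block in b_blocks[:i] for m in block
            ] + [m for block in a_blocks[i:] for m in block]
            for x in range(len(current)):
                for y in range(x + 1, len(current)):
                    if not splits_compatible(current[x], current[y], n):
                        return False
        return True

    def ratios_ordered(na, nb) -> bool:
        previous = -math.inf
        for x, y in zip(na, nb):
            if x == 0.0 and y == 0.0:
                continue  # empty leg: no constraint, no length
            ratio = math.inf if y == 0.0 else x / y
            if ratio < previous - _RATIO_TOL:
                return False
            previous = ratio
        return True

    best = math.inf
    kmax = max(1, len(a_masks) + len(b_masks))
    for k in range(1, kmax + 1):
        for a_blocks in _ordered_partitions(a_masks, k):
            na = [_norm(a_only[m] for m in block) for block in a_blocks]
            for b_blocks in _ordered_partitions(b_masks, k):
                nb = [_norm(b_only[m] for m in block) for block in b_blocks]
                if not ratios_ordered(na, nb):
                    continue
                if not valid(a_blocks, b_blocks):
                    continue
                sq = sum((x + y) ** 2 for x, y in zip(na, nb)) + common_sq
                best = min(best, math.sqrt(sq))
    return best


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

_METRICS = {
    "bhv": bhv_distance,
    "wrf": wrf_distance,
    "rf": lambda a, b: float(rf_distance(a, b)),
}


def distance_matrix(trees, metric: str = "bhv") -> np.ndarray:
    """Symmetric zero-diagonal pairwise distance matrix for a list of trees."""
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    n = len(trees)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(trees[i], trees[j])
    return mat
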