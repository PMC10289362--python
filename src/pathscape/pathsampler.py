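"""Trees along BHV geodesics ("pathtrees").

A geodesic between trees T1 and T2 is parameterized by 0 <= lambda <= 1,
proportional to distance traveled.  With support legs (A_1, B_1)..(A_k, B_k)
and common splits C, the tree at position lambda in the i-th orthant contains
exactly the splits  C u B_1..B_i u A_{i+1}..A_k,  with lengths

    e in A_j:  ((1 - lam) ||A_j|| - lam ||B_j||) / ||A_j|| * |e|_T1
    e in B_j:  (lam ||B_j|| - (1 - lam) ||A_j||) / ||B_j|| * |e|_T2
    e in C:    (1 - lam) |e|_T1 + lam |e|_T2

The leg boundary sits at lambda = ||A_i|| / (||A_i|| + ||B_i||); a boundary
tree keeps the vanishing splits at length exactly 0, so pathtrees may be
multifurcating.
"""

from __future__ import annotations

from dataclasses import dataclass

from .distances import Geodesic, geodesic
from .treeio import Tree, tree_from_splits

__all__ = ["PathPoint", "PathTreeRecord", "tree_at", "sample_path", "all_pairs_pathtrees"]


@dataclass
class PathPoint:
    """A tree at position ``lam`` on a geodesic, in orthant ``orthant_index``."""

    lam: float
    orthant_index: int
    tree: Tree


@dataclass
class PathTreeRecord:
    """A pathtree annotated with its source pair and position."""

    pair: tuple[int, int]
    lam: float
    tree: Tree


def tree_at(g: Geodesic, lam: float) -> PathPoint:
    """Evaluate the geodesic at position ``lam`` in [0, 1].

    The endpoints reproduce T1 and T2 exactly.  A boundary lambda equal to
    ``||A_i|| / (||A_i|| + ||B_i||)`` is assigned to orthant i: the vanished
    A_i splits are dropped and the B_i splits enter at length 0 (retained).
    Lengths within -1e-12 of zero are clamped to 0.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    legs = g.support.legs
    if lam == 0.0:
        return PathPoint(0.0, 0, g.t1.copy())
    if lam == 1.0:
        return PathPoint(1.0, len(legs), g.t2.copy())

    index = sum(1 for leg in legs if leg.boundary <= lam)
    splits: dict[int, float] = {}
    for mask, (l1, l2) in g.support.common.items():
        splits[mask] = (1.0 - lam) * l1 + lam * l2
    for j, leg in enumerate(legs, start=1):
        na, nb = leg.norm_a, leg.norm_b
        if j <= index:
            factor = (lam * nb - (1.0 - lam) * na) / nb
            items = leg.b_splits
        else:
            factor = ((1.0 - lam) * na - lam * nb) / na
            items = leg.a_splits
        for mask, length in items.items():
            value = factor * length
            if value < 0.0:
                if value < -1e-9:
                    raise AssertionError(
                        f"negative pathtree length {value} at lambda={lam}"
                    )
                value = 0.0
            splits[mask] = value
    return PathPoint(lam, index, tree_from_splits(g.taxa, splits))


def sample_path(t1: Tree, t2: Tree, m: int) -> list[Tree]:
    """``m`` equally spaced trees strictly between T1 and T2.

    Positions are lambda_j = j / (m + 1) for j = 1..m; the endpoints are
    excluded.  Spacing uniform in lambda is uniform in arc length.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    g = geodesic(t1, t2)
    return [tree_at(g, j / (m + 1)).tree for j in range(1, m + 1)]


def all_pairs_pathtrees(starting: list[Tree], m: int) -> list[PathTreeRecord]:
    """Pathtrees between every unordered pair of starting trees.

    Produces ``m * s * (s - 1) / 2`` records for ``s`` starting trees, each
    annotated with its source pair indices and lambda.
    """
    if len(starting) < 2:
        raise ValueError("need at least 2 starting trees")
    records: list[PathTreeRecord] = []
    for i in range(len(starting)):
        for j in range(i + 1, len(starting)):
            g = geodesic(starting[i], starting[j])
            for step in range(1, m + 1):
                lam = step / (m + 1)
                records.append(PathTreeRecord((i, j), lam, tree_at(g, lam).tree))
    return records
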