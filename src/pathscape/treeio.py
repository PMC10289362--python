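"""Tree and alignment I/O, split decomposition, and topology canonicalization.

Trees are rooted phylogenies with non-negative branch lengths in expected
substitutions per site.  Distance and geodesic computations operate on the
*unrooted* split decomposition of a tree: every edge induces a bipartition
(split) of the leaf set, and the two edges incident to a degree-2 root induce
the same bipartition, so their lengths are summed into a single split weight.
Rooting is preserved in :class:`Tree` for serialization.

Splits are encoded as bitmasks over the indices of the lexicographically
sorted taxon list; the canonical orientation stores the side that does *not*
contain taxon index 0.  Pendant (single-leaf) splits are "trivial": they carry
branch-length information but never distinguish topologies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "Node",
    "Alignment",
    "NewickError",
    "PhylipError",
    "DEFAULT_CONTRACT_TOL",
    "parse_newick",
    "write_newick",
    "read_newicks",
    "write_newicks",
    "splits_of",
    "is_pendant",
    "canonical_split",
    "split_leaves",
    "topology_key",
    "tree_from_splits",
    "parse_phylip",
    "write_phylip",
]

#: Internal edges not longer than this are treated as absent when comparing
#: topologies or preparing geodesic supports (zero-length contraction).
DEFAULT_CONTRACT_TOL = 1e-9


class NewickError(ValueError):
    """Malformed Newick input (syntax, duplicate labels, negative lengths)."""


class PhylipError(ValueError):
    """Malformed PHYLIP input (header/body mismatch, unequal lengths)."""


@dataclass
class Node:
    """A node of a rooted tree; ``length`` is the edge to its parent."""

    label: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length, [c.copy() for c in self.children])


class Tree:
    """Rooted phylogeny over a fixed, sorted taxon list.

    Multifurcations are permitted (trees on orthant boundaries of treespace
    are legitimately non-binary).  Leaf labels must be unique and branch
    lengths non-negative.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in self.leaf_nodes()]
        if any(l is None or l == "" for l in labels):
            raise NewickError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {', '.join(dupes)}")
        self.taxa: tuple[str, ...] = tuple(sorted(labels))
        self._index = {name: i for i, name in enumerate(self.taxa)}
        for node in self.iter_nodes():
            if node.length < 0:
                raise NewickError(
                    f"negative branch length {node.length!r} on edge above "
                    f"{node.label or 'an internal node'!r}"
                )

    # -- traversal -----------------------------------------------------

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaf_nodes(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def edges(self) -> list[Node]:
        """Non-root nodes; each stands for the edge to its parent."""
        return [n for n in self.iter_nodes() if n is not self.root]

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def taxon_index(self, label: str) -> int:
        return self._index[label]

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)!r})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.is_leaf():
        label = dnode.label
    length = dnode.edge.length if dnode.edge.length is not None else 0.0
    return Node(
        label=label,
        length=float(length),
        children=[_from_dendropy(c) for c in dnode.child_nodes()],
    )


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string into a rooted :class:`Tree`.

    Missing branch lengths default to 0.  Unbalanced parentheses, duplicate
    leaf labels, and negative lengths raise :class:`NewickError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"could not parse Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = 0.0
    return Tree(root)


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_rec(node: Node, root: Node) -> str:
    if node.is_leaf:
        body = _quote(node.label)
    else:
        body = "(" + ",".join(_newick_rec(c, root) for c in node.children) + ")"
    if node is root:
        return body + ";"
    return f"{body}:{float(node.length)!r}"


def write_newick(t: Tree) -> str:
    """Serialize with full-precision branch lengths (exact round-trip)."""
    return _newick_rec(t.root, t.root)


def read_newicks(text: str) -> list[Tree]:
    """Parse a multi-tree file, one Newick string per line."""
    return [parse_newick(line) for line in text.splitlines() if line.strip()]


def write_newicks(trees) -> str:
    return "".join(write_newick(t) + "\n" for t in trees)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def canonical_split(mask: int, n_leaves: int) -> int:
    """Orient a split bitmask so the side without taxon index 0 is stored."""
    full = (1 << n_leaves) - 1
    return (full ^ mask) if (mask & 1) else mask


def is_pendant(mask: int, n_leaves: int) -> bool:
    """True for trivial splits separating a single leaf from the rest."""
    pc = mask.bit_count()
    return pc == 1 or pc == n_leaves - 1


def split_leaves(mask: int, taxa) -> tuple[str, ...]:
    """Taxon names on the stored side of a split (for error messages)."""
    return tuple(name for i, name in enumerate(taxa) if mask >> i & 1)


def splits_of(t: Tree) -> dict[int, float]:
    """Decompose a tree into its weighted splits.

    Returns a map from canonical split bitmask to branch length.  The two
    root-incident edges of a degree-2 root induce the same bipartition and
    their lengths are summed; the same merging applies to any chain of
    degree-2 nodes, so the result depends only on the underlying unrooted
    weighted tree.
    """
    n = t.n_leaves
    result: dict[int, float] = {}

    def rec(node: Node) -> int:
        if node.is_leaf:
            mask = 1 << t.taxon_index(node.label)
        else:
            mask = 0
            for child in node.children:
                mask |= rec(child)
        if node is not t.root:
            cm = canonical_split(mask, n)
            result[cm] = result.get(cm, 0.0) + node.length
        return mask

    rec(t.root)
    return result


def topology_key(t: Tree, tol: float = DEFAULT_CONTRACT_TOL) -> str:
    """Canonical topology identifier.

    Two trees receive the same key iff their sets of nontrivial splits with
    length > ``tol`` coincide, i.e. iff their unweighted Robinson-Foulds
    distance is 0 after contracting edges not longer than ``tol``.
    """
    n = t.n_leaves
    masks = sorted(
        m
        for m, length in splits_of(t).items()
        if not is_pendant(m, n) and length > tol
    )
    return f"{n}|" + ",".join(format(m, "x") for m in masks)


def tree_from_splits(taxa, split_lengths: dict[int, float]) -> Tree:
    """Reconstruct a rooted tree from a compatible set of weighted splits.

    ``split_lengths`` maps canonical bitmasks (over the sorted ``taxa``) to
    branch lengths; pendant splits supply the leaf edge lengths.  The tree is
    rooted at the attachment point of the first taxon.  Raises ``ValueError``
    if the nontrivial splits are not pairwise compatible (not laminar).
    """
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    full = (1 << n) - 1
    if n == 2:
        leaf0 = Node(label=taxa[0], length=0.0)
        leaf1 = Node(label=taxa[1], length=split_lengths.get(2, 0.0))
        return Tree(Node(children=[leaf0, leaf1]))

    pendant0 = full & ~1
    active: dict[int, Node] = {
        (1 << i): Node(label=taxa[i], length=split_lengths.get(1 << i, 0.0))
        for i in range(1, n)
    }
    internal = sorted(
        (m for m in split_lengths if 2 <= m.bit_count() <= n - 2),
        key=lambda m: (m.bit_count(), m),
    )
    for mask in internal:
        kid_masks = [am for am in active if am & mask == am]
        union = 0
        for am in kid_masks:
            union |= am
        if union != mask:
            raise ValueError(
                f"splits are not compatible: clade {split_leaves(mask, taxa)} "
                "is not a union of nested clades"
            )
        node = Node(length=split_lengths[mask],
                    children=[active.pop(am) for am in sorted(kid_masks)])
        active[mask] = node
    leaf0 = Node(label=taxa[0], length=split_lengths.get(pendant0, 0.0))
    root = Node(children=[leaf0] + [active[m] for m in sorted(active)])
    return Tree(root)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class Alignment:
    """A DNA multiple sequence alignment with site-pattern compression.

    Characters outside ``{A, C, G, T}`` (gaps, N, ambiguity codes) are
    treated as fully missing data.
    """

    def __init__(self, taxa, sequences):
        self.taxa: tuple[str, ...] = tuple(taxa)
        self.sequences: tuple[str, ...] = tuple(s.upper() for s in sequences)
        if len(self.taxa) != len(self.sequences):
            raise PhylipError("taxon count does not match sequence count")
        if len(set(self.taxa)) != len(self.taxa):
            raise PhylipError("duplicate taxon names in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise PhylipError(f"sequences of unequal length: {sorted(lengths)}")
        self._by_name = dict(zip(self.taxa, self.sequences))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, name: str) -> str:
        return self._by_name[name]

    def encoded(self, taxa_subset=None) -> np.ndarray:
        """Integer matrix (taxa x sites): A,C,G,T -> 0..3, missing -> 4."""
        names = self.taxa if taxa_subset is None else tuple(taxa_subset)
        missing = [nm for nm in names if nm not in self._by_name]
        if missing:
            raise KeyError(f"taxa absent from alignment: {', '.join(missing)}")
        mat = np.full((len(names), self.n_sites), 4, dtype=np.int8)
        for i, nm in enumerate(names):
            seq = self._by_name[nm]
            mat[i] = [_CODE.get(ch, 4) for ch in seq]
        return mat

    def site_patterns(self, taxa_subset=None) -> tuple[np.ndarray, np.ndarray]:
        """Distinct alignment columns and their multiplicities.

        Returns ``(patterns, counts)`` with ``patterns`` of shape
        ``(n_patterns, n_taxa)``; multiplicities sum to ``n_sites``.
        """
        mat = self.encoded(taxa_subset)
        patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
        return patterns, counts


def parse_phylip(text: str) -> Alignment:
    """Parse relaxed PHYLIP (sequential or interleaved, autodetected)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PhylipError("empty PHYLIP input")
    header = lines[0].split()
    try:
        ntax, nchar = int(header[0]), int(header[1])
    except (IndexError, ValueError) as exc:
        raise PhylipError(f"bad PHYLIP header: {lines[0]!r}") from exc

    errors = []
    for interleaved in (False, True):
        try:
            matrix = dendropy.DnaCharacterMatrix.get(
                data=text,
                schema="phylip",
                strict=False,
                interleaved=interleaved,
                underscores_to_spaces=False,
            )
            taxa = [tx.label for tx in matrix.taxon_namespace]
            seqs = [matrix[tx].symbols_as_string() for tx in matrix.taxon_namespace]
        except Exception as exc:
            errors.append(str(exc))
            continue
        if len(taxa) == ntax and all(len(s) == nchar for s in seqs):
            return Alignment(taxa, seqs)
        errors.append(
            f"{'interleaved' if interleaved else 'sequential'} read gave "
            f"{len(taxa)} taxa x {sorted({len(s) for s in seqs})} sites, "
            f"header promised {ntax} x {nchar}"
        )
    raise PhylipError("; ".join(errors))


def write_phylip(aln: Alignment) -> str:
    """Relaxed sequential PHYLIP with whitespace-delimited names."""
    width = max(len(nm) for nm in aln.taxa) + 2
    out = io.StringIO()
    out.write(f"{aln.n_taxa} {aln.n_sites}\n")
    for nm in aln.taxa:
        out.write(f"{nm:<{width}}{aln.sequence(nm)}\n")
    return out.getvalue()
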