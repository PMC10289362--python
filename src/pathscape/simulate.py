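"""Synthetic fixtures: random trees, perturbed tree clouds, JC69 alignments.

The generator stands in for the inputs a user would bring from a Bayesian
MCMC run: a cloud of topologically similar trees with jittered branch
lengths, plus the sequence alignment they were sampled against.  Random
topologies come from uniform sequential attachment (each new leaf attaches
to a uniformly chosen edge or above the root), which draws uniformly from
the (2n-3)!! rooted binary leaf-labeled topologies.  Branch lengths are
i.i.d. exponential or uniform.  Sequences evolve site-independently under
JC69 from uniform root states.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass

import numpy as np

from .treeio import (
    Alignment,
    Node,
    Tree,
    write_newick,
    write_newicks,
    write_phylip,
)

__all__ = ["SimSpec", "random_tree", "perturb_cloud", "simulate_alignment", "write_fixture"]

_BASES = "ACGT"


@dataclass
class SimSpec:
    """Study conditions for fixture generation.

    Defaults emulate a modest MCMC sample: 8 taxa, 1000 sites, exponential
    branch lengths with mean 0.1 substitutions/site, 50 cloud trees one NNI
    move away from the base tree with mild (sigma = 0.1) log-normal
    branch-length jitter.
    """

    n_leaves: int = 8
    n_sites: int = 1000
    branch_dist: tuple = ("exponential", 0.1)
    n_trees: int = 50
    perturb_moves: int = 1
    jitter_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        kind = self.branch_dist[0]
        if kind == "exponential":
            if self.branch_dist[1] <= 0:
                raise ValueError("exponential mean must be positive")
        elif kind == "uniform":
            lo, hi = self.branch_dist[1], self.branch_dist[2]
            if not 0 < lo < hi:
                raise ValueError("uniform bounds must satisfy 0 < lo < hi")
        else:
            raise ValueError(f"unknown branch distribution {kind!r}")

    def taxa(self) -> list[str]:
        width = len(str(self.n_leaves))
        return [f"t{i:0{width}d}" for i in range(1, self.n_leaves + 1)]


def _draw_length(spec: SimSpec, rng: np.random.Generator) -> float:
    kind = spec.branch_dist[0]
    if kind == "exponential":
        return float(rng.exponential(spec.branch_dist[1]))
    lo, hi = spec.branch_dist[1], spec.branch_dist[2]
    return float(rng.uniform(lo, hi))


def random_tree(spec: SimSpec, rng: np.random.Generator | None = None) -> Tree:
    """Uniform random rooted binary topology with i.i.d. branch lengths."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa()
    root = Node(children=[Node(label=taxa[0]), Node(label=taxa[1])])
    for label in taxa[2:]:
        # Attachment positions: any existing edge, or above the root.
        positions: list[tuple[Node | None, Node]] = [(root, None)]

        def collect(parent: Node):
            for child in parent.children:
                positions.append((parent, child))
                collect(child)

        collect(root)
        parent, child = positions[rng.integers(len(positions))]
        leaf = Node(label=label)
        if child is None:
            root = Node(children=[parent, leaf])
        else:
            parent.children[parent.children.index(child)] = Node(
                children=[child, leaf]
            )
    tree = Tree(root)
    for node in tree.edges():
        node.length = _draw_length(spec, rng)
    return tree


def _nni(tree: Tree, rng: np.random.Generator) -> None:
    """One random nearest-neighbor interchange, in place.

    Picks an edge that is internal in the *unrooted* sense and swaps a
    subtree from one side with a subtree from the other.  Around a degree-2
    root the two root-incident edges form a single unrooted edge, so the
    swap must cross from one root child into the other; swapping a child of
    one root child with its sibling would only rotate the rooted shape.
    """
    root = tree.root
    degree2_root = len(root.children) == 2

    candidates = []
    for parent in tree.iter_nodes():
        for child in parent.children:
            if child.is_leaf:
                continue
            if parent is root and degree2_root:
                others = [c for c in root.children if c is not child]
                if all(c.is_leaf for c in others):
                    continue  # the merged root edge is pendant: no NNI
            candidates.append((parent, child))
    if not candidates:
        return
    parent, lower = candidates[rng.integers(len(candidates))]

    if parent is root and degree2_root:
        sib = next(c for c in root.children if c is not lower and not c.is_leaf)
        kid = lower.children[rng.integers(len(lower.children))]
        skid = sib.children[rng.integers(len(sib.children))]
        lower.children[lower.children.index(kid)] = skid
        sib.children[sib.children.index(skid)] = kid
    else:
        siblings = [c for c in parent.children if c is not lower]
        sib = siblings[rng.integers(len(siblings))]
        kid = lower.children[rng.integers(len(lower.children))]
        parent.children[parent.children.index(sib)] = kid
        lower.children[lower.children.index(kid)] = sib


def perturb_cloud(
    base: Tree, spec: SimSpec, rng: np.random.Generator | None = None
) -> list[Tree]:
    """A cloud of ``spec.n_trees`` trees around ``base``.

    The first element is the base tree itself; each other tree receives
    ``spec.perturb_moves`` random NNI moves and multiplicative log-normal
    branch-length jitter with sigma ``spec.jitter_sigma``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cloud = [base.copy()]
    for _ in range(spec.n_trees - 1):
        tree = base.copy()
        for _ in range(spec.perturb_moves):
            _nni(tree, rng)
        if spec.jitter_sigma > 0:
            for node in tree.edges():
                node.length *= float(
                    math.exp(rng.normal(0.0, spec.jitter_sigma))
                )
        cloud.append(tree)
    return cloud


def simulate_alignment(
    tree: Tree, n_sites: int, seed: int | np.random.Generator = 0
) -> Alignment:
    """Evolve a DNA alignment along ``tree`` under JC69.

    Root states are i.i.d. uniform over {A, C, G, T}; along each edge of
    length t a site keeps its state with probability 1/4 + 3/4 exp(-4t/3)
    and otherwise switches to one of the other three states uniformly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states: dict[str, np.ndarray] = {}

    def evolve(node: Node, parent_states: np.ndarray) -> None:
        if node.length > 0:
            stay = 0.25 + 0.75 * math.exp(-4.0 * node.length / 3.0)
            switch = rng.random(n_sites) >= stay
            jump = rng.integers(1, 4, size=n_sites)
            node_states = np.where(
                switch, (parent_states + jump) % 4, parent_states
            )
        else:
            node_states = parent_states
        if node.is_leaf:
            states[node.label] = node_states
        for child in node.children:
            evolve(child, node_states)

    root_states = rng.integers(0, 4, size=n_sites)
    for child in tree.root.children:
        evolve(child, root_states)
    taxa = sorted(states)
    seqs = ["".join(_BASES[s] for s in states[nm]) for nm in taxa]
    return Alignment(taxa, seqs)


def write_fixture(outdir, spec: SimSpec) -> dict:
    """Write aln.phy, sample.nwk, and truth.json for a simulated study.

    The alignment is simulated on a base tree; the tree sample is a
    perturbed cloud around that base.  Returns the truth record.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    base = random_tree(spec, rng)
    cloud = perturb_cloud(base, spec, rng)
    aln = simulate_alignment(base, spec.n_sites, rng)
    (outdir / "aln.phy").write_text(write_phylip(aln))
    (outdir / "sample.nwk").write_text(write_newicks(cloud))
    truth = {
        "generating_tree": write_newick(base),
        "n_leaves": spec.n_leaves,
        "n_sites": spec.n_sites,
        "n_trees": spec.n_trees,
        "branch_dist": list(spec.branch_dist),
        "perturb_moves": spec.perturb_moves,
        "jitter_sigma": spec.jitter_sigma,
        "seed": spec.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
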