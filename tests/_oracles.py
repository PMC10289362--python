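"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: the likelihood oracle
sums over every ancestral state assignment instead of pruning, and the
direction-sweep hull oracle uses support functions instead of a hull
algorithm.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pathscape.likelihood import jc69_transition


def exhaustive_log_likelihood(tree, aln) -> float:
    """JC69 log-likelihood by summation over all internal-node states.

    Marginalizes the 4^(number of internal nodes) ancestral assignments per
    site pattern explicitly; exponential, for small trees only.
    """
    labels = sorted(node.label for node in tree.leaf_nodes())
    patterns, counts = aln.site_patterns(labels)
    col = {label: i for i, label in enumerate(labels)}
    internals = [n for n in tree.iter_nodes() if not n.is_leaf]
    parent_of = {}
    for node in tree.iter_nodes():
        for child in node.children:
            parent_of[id(child)] = node
    matrices = {
        id(n): jc69_transition(n.length)
        for n in tree.iter_nodes()
        if n is not tree.root
    }
    total = 0.0
    for pattern, count in zip(patterns, counts):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            term = 0.25  # uniform root prior
            for node in tree.iter_nodes():
                if node is tree.root:
                    continue
                parent_state = state[id(parent_of[id(node)])]
                p = matrices[id(node)]
                if node.is_leaf:
                    code = pattern[col[node.label]]
                    if code != 4:
                        term *= p[parent_state, code]
                else:
                    term *= p[parent_state, state[id(node)]]
            site += term
        total += count * math.log(site)
    return total


def support_function_hull(coords: np.ndarray, n_directions: int = 360) -> set[int]:
    """Indices of points maximal in at least one of a sweep of directions."""
    coords = np.asarray(coords, dtype=float)
    angles = np.linspace(0.0, 2.0 * np.pi, n_directions, endpoint=False)
    directions = np.column_stack([np.cos(angles), np.sin(angles)])
    projections = coords @ directions.T
    return set(int(i) for i in projections.argmax(axis=0))
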