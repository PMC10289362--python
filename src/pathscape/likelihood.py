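"""JC69 likelihood via Felsenstein pruning, and branch-length optimization.

The Jukes-Cantor (1969) model has equal base frequencies (1/4 each) and a
single substitution rate; its transition probabilities have the closed form

    P(same)  = 1/4 + 3/4 exp(-4 t / 3)
    P(other) = 1/4 - 1/4 exp(-4 t / 3)

with t the branch length in expected substitutions per site.  The model is
time-reversible, so the log-likelihood does not depend on root placement.

Branch lengths are optimized by coordinate ascent: bounded Brent
maximization of the log-likelihood in one edge at a time, sweeping all edges
until the improvement per sweep falls below a tolerance.  This serves the
role that an external ML program (e.g. Paup*) plays in a conventional
pipeline: finding, for each topology, the branch lengths that maximize the
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .treeio import Alignment, Node, Tree

__all__ = [
    "LikelihoodResult",
    "LikelihoodError",
    "jc69_transition",
    "log_likelihood",
    "optimize_branch_lengths",
    "MIN_BRANCH_LENGTH",
    "MAX_BRANCH_LENGTH",
]

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0

#: Leaf partial-likelihood rows for codes A,C,G,T, missing.
_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])


class LikelihoodError(ValueError):
    """Likelihood cannot be computed (missing taxa, empty data, non-finite)."""


@dataclass
class LikelihoodResult:
    loglik: float
    per_pattern: np.ndarray  # natural-log likelihood of each site pattern
    tree: Tree
    n_sweeps: int = 0
    trace: list[float] = field(default_factory=list)


def jc69_transition(t: float) -> np.ndarray:
    """4x4 JC69 transition probability matrix for branch length ``t``."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    decay = math.exp(-4.0 * t / 3.0)
    p = np.full((4, 4), 0.25 * (1.0 - decay))
    np.fill_diagonal(p, 0.25 + 0.75 * decay)
    return p


def _pattern_data(tree: Tree, aln: Alignment):
    labels = sorted(n.label for n in tree.leaf_nodes())
    missing = [lb for lb in labels if lb not in aln.taxa]
    if missing:
        raise LikelihoodError(
            f"taxa of the tree absent from the alignment: {', '.join(missing)}"
        )
    patterns, counts = aln.site_patterns(labels)
    return {lb: i for i, lb in enumerate(labels)}, patterns, counts


def _prune(node: Node, root: Node, patterns: np.ndarray, col_of: dict[str, int]):
    """Return (partials (4, n_patterns), log-scale (n_patterns,))."""
    if node.is_leaf:
        codes = patterns[:, col_of[node.label]]
        return _LEAF_PARTIALS[codes].T, np.zeros(patterns.shape[0])
    partials = np.ones((4, patterns.shape[0]))
    logscale = np.zeros(patterns.shape[0])
    for child in node.children:
        child_partials, child_scale = _prune(child, root, patterns, col_of)
        partials *= jc69_transition(child.length) @ child_partials
        logscale += child_scale
    peak = partials.max(axis=0)
    peak[peak == 0.0] = 1.0  # impossible pattern; log handled by caller
    partials /= peak
    logscale += np.log(peak)
    return partials, logscale


def log_likelihood(tree: Tree, aln: Alignment) -> LikelihoodResult:
    """JC69 log-likelihood of ``tree`` given ``aln`` by pruning over patterns.

    The tree's leaf labels must be a subset of the alignment's taxa; sites
    are independent with stationary base frequencies 1/4.  Gaps and
    ambiguity codes are fully missing data.
    """
    if aln.n_sites == 0:
        raise LikelihoodError("alignment has no sites")
    col_of, patterns, counts = _pattern_data(tree, aln)
    partials, logscale = _prune(tree.root, tree.root, patterns, col_of)
    site_lik = 0.25 * partials.sum(axis=0)
    with np.errstate(divide="ignore"):
        per_pattern = np.log(site_lik) + logscale
    loglik = float(counts @ per_pattern)
    if not np.isfinite(loglik):
        raise LikelihoodError("non-finite log-likelihood")
    return LikelihoodResult(loglik, per_pattern, tree)


def optimize_branch_lengths(
    topology: Tree,
    aln: Alignment,
    max_sweeps: int = 50,
    tol: float = 1e-6,
    min_len: float = MIN_BRANCH_LENGTH,
    max_len: float = MAX_BRANCH_LENGTH,
) -> LikelihoodResult:
    """Maximize the JC69 log-likelihood over branch lengths, topology fixed.

    Coordinate ascent with bounded Brent per edge on ``[min_len, max_len]``,
    sweeping all edges until the per-sweep improvement is below ``tol`` log
    units or ``max_sweeps`` is reached.  Multifurcating topologies are
    optimized as-is.  The returned log-likelihood is never below that of the
    starting tree, and the per-sweep trace is non-decreasing.
    """
    work = topology.copy()
    col_of, patterns, counts = _pattern_data(work, aln)

    def current_loglik() -> float:
        partials, logscale = _prune(work.root, work.root, patterns, col_of)
        site_lik = 0.25 * partials.sum(axis=0)
        with np.errstate(divide="ignore"):
            return float(counts @ (np.log(site_lik) + logscale))

    best = current_loglik()
    if not np.isfinite(best):
        raise LikelihoodError("non-finite log-likelihood at the starting tree")
    trace = [best]
    edges = [n for n in work.iter_nodes() if n is not work.root]
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        sweep_start = best
        for node in edges:
            old = node.length

            def negll(x: float) -> float:
                node.length = x
                return -current_loglik()

            result = minimize_scalar(
                negll, bounds=(min_len, max_len), method="bounded",
                options={"xatol": 1e-10},
            )
            if -result.fun > best:
                node.length = float(result.x)
                best = -result.fun
            else:
                node.length = old
        trace.append(best)
        if best - sweep_start < tol:
            break
    final = log_likelihood(work, aln)
    return LikelihoodResult(final.loglik, final.per_pattern, work, sweeps, trace)
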