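"""The iterative landscape-exploration pipeline.

One iteration: embed the tree sample with MDS, take the convex-hull trees
as starting trees, sample m pathtrees along the geodesic of every starting
pair, score every current tree under JC69, select the n best, cluster them
by topology, optimize branch lengths once per topology, and render the
landscape.  Subsequent iterations zoom in: the starting trees become the
convex-hull vertices of the previous iteration's optimized trees in a fresh
embedding.

Selection uses the unoptimized pathtree log-likelihoods (scoring precedes
optimization in the iteration); optimized log-likelihoods are used for
reporting and coloring.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landscape as ls
from .likelihood import LikelihoodResult, log_likelihood, optimize_branch_lengths
from .pathsampler import PathTreeRecord, all_pairs_pathtrees
from .treeio import (
    Alignment,
    Tree,
    parse_phylip,
    read_newicks,
    topology_key,
    write_newick,
)

__all__ = [
    "RunConfig",
    "IterationState",
    "OptimizedTopology",
    "PipelineError",
    "subsample_trees",
    "select_starting_trees",
    "select_top_n",
    "cluster_and_optimize",
    "compare_topologies",
    "run",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters of a pipeline run.

    ``m`` may be a single int or one int per iteration.  ``metric`` applies
    to the first iteration; later iterations default to the faster ``wrf``
    unless ``later_metric`` says otherwise.
    """

    alignment_path: str
    trees_path: str
    m: int | tuple[int, ...] = 4
    n: int = 100
    metric: str = "bhv"
    later_metric: str = "wrf"
    interpolation: str = "tps"
    iterations: int = 1
    burnin_fraction: float = 0.0
    stride: int = 1
    seed: int = 0
    outdir: str = "pathscape_run"
    grid: int = 150
    max_sweeps: int = 50
    opt_tol: float = 1e-6
    figures: bool = True

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        ms = self.m_per_iteration()
        if any(m < 1 for m in ms):
            raise ValueError("m must be >= 1")
        for name in ("metric", "later_metric"):
            if getattr(self, name) not in ("bhv", "wrf"):
                raise ValueError(f"{name} must be 'bhv' or 'wrf'")
        if self.interpolation not in ("cubic", "tps"):
            raise ValueError("interpolation must be 'cubic' or 'tps'")

    def m_per_iteration(self) -> tuple[int, ...]:
        if isinstance(self.m, int):
            return (self.m,) * self.iterations
        ms = tuple(int(v) for v in self.m)
        if len(ms) != self.iterations:
            raise ValueError("need one m per iteration")
        return ms

    def metric_for(self, iteration: int) -> str:
        return self.metric if iteration == 1 else self.later_metric


@dataclass
class OptimizedTopology:
    """One branch-length-optimized representative of a topology cluster."""

    key: str
    cluster_size: int
    start_loglik: float
    result: LikelihoodResult


@dataclass
class IterationState:
    iteration: int
    starting_trees: list[Tree]
    pathtrees: list[PathTreeRecord]
    current_sample: list[Tree]
    logliks: np.ndarray
    topn_indices: list[int]
    optimized: list[OptimizedTopology]
    landscape: ls.Landscape | None = None
    annotations: dict = field(default_factory=dict)


def subsample_trees(trees: list, burnin_fraction: float, stride: int) -> list:
    """Drop the leading ``burnin_fraction`` of trees, then take every
    ``stride``-th of the remainder."""
    if not 0 <= burnin_fraction < 1:
        raise ValueError("burnin_fraction must be in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    start = int(round(burnin_fraction * len(trees)))
    kept = trees[start:][::stride]
    if not kept:
        raise ValueError("subsampling removed every tree")
    return kept


def select_starting_trees(trees: list[Tree], metric: str = "bhv",
                          return_indices: bool = False):
    """Convex-hull trees of the 2-D MDS embedding of the pairwise distances.

    Returns the trees at the hull vertices in counter-clockwise order (their
    indices as well when ``return_indices``).
    """
    if len(trees) < 3:
        raise ValueError("need at least 3 trees to take a convex hull")
    dist = ls.distance_matrix(trees, metric=metric)
    coords = ls.mds_embed(dist, dim=2)
    hull = ls.hull_vertices(coords)
    chosen = [trees[i] for i in hull]
    if return_indices:
        return chosen, list(map(int, hull))
    return chosen


def select_top_n(sample: list[tuple[Tree, float]], n: int) -> list[int]:
    """Indices of the ``n`` highest-likelihood trees, ties by insertion order."""
    if n > len(sample):
        raise ValueError(f"n={n} exceeds sample size {len(sample)}")
    order = sorted(range(len(sample)), key=lambda i: (-sample[i][1], i))
    return sorted(order[:n])


def cluster_and_optimize(
    selected: list[tuple[Tree, float]],
    alignment: Alignment,
    max_sweeps: int = 50,
    tol: float = 1e-6,
) -> list[OptimizedTopology]:
    """Group selected trees by topology; optimize one tree per topology.

    The optimization starts from the highest-likelihood member of each
    cluster (earliest on ties).
    """
    if not selected:
        raise ValueError("no trees selected")
    clusters: dict[str, list[int]] = {}
    for i, (tree, _) in enumerate(selected):
        clusters.setdefault(topology_key(tree), []).append(i)
    out = []
    for key, members in clusters.items():
        start = min(members, key=lambda i: (-selected[i][1], i))
        tree, start_ll = selected[start]
        result = optimize_branch_lengths(
            tree, alignment, max_sweeps=max_sweeps, tol=tol
        )
        out.append(OptimizedTopology(key, len(members), start_ll, result))
    return out


def compare_topologies(set_a: list[Tree], set_b: list[Tree]) -> dict:
    """Partition the topology keys of ``set_a`` by presence in ``set_b``."""
    keys_a = {topology_key(t) for t in set_a}
    keys_b = {topology_key(t) for t in set_b}
    shared = sorted(keys_a & keys_b)
    novel = sorted(keys_a - keys_b)
    return {
        "n_shared": len(shared),
        "n_novel": len(novel),
        "shared": shared,
        "novel": novel,
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _write_tsv(path: pathlib.Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _run_iteration(
    iteration: int,
    starting: list[Tree],
    starting_source: str,
    aln: Alignment,
    config: RunConfig,
    outdir: pathlib.Path,
) -> IterationState:
    m = config.m_per_iteration()[iteration - 1]
    metric = config.metric_for(iteration)
    itdir = outdir / f"iteration{iteration}"
    itdir.mkdir(parents=True, exist_ok=True)

    records = all_pairs_pathtrees(starting, m)
    current: list[Tree] = list(starting) + [r.tree for r in records]
    sources = [starting_source] * len(starting) + ["pathtree"] * len(records)

    logliks = np.array([log_likelihood(t, aln).loglik for t in current])
    sample = list(zip(current, logliks))
    topn = select_top_n(sample, min(config.n, len(sample)))
    optimized = cluster_and_optimize(
        [sample[i] for i in topn], aln,
        max_sweeps=config.max_sweeps, tol=config.opt_tol,
    )

    for opt in optimized:
        current.append(opt.result.tree)
        sources.append("optimized")
    logliks = np.append(logliks, [opt.result.loglik for opt in optimized])

    n_start = len(starting)
    n_path = len(records)
    opt_offset = n_start + n_path
    annotations = {
        "starting": list(range(n_start)),
        "selected": topn,
        "optimized": list(range(opt_offset, opt_offset + len(optimized))),
        "best": int(np.argmax(logliks)),
    }

    state = IterationState(
        iteration=iteration,
        starting_trees=list(starting),
        pathtrees=records,
        current_sample=current,
        logliks=logliks,
        topn_indices=topn,
        optimized=optimized,
        annotations=annotations,
    )

    # Artifacts -------------------------------------------------------
    (itdir / "starting.nwk").write_text(
        "".join(write_newick(t) + "\n" for t in starting)
    )
    (itdir / "pathtrees.nwk").write_text(
        "".join(write_newick(r.tree) + "\n" for r in records)
    )
    _write_tsv(
        itdir / "pathtrees.tsv",
        pd.DataFrame(
            {
                "pair_id": [f"{r.pair[0]}-{r.pair[1]}" for r in records],
                "lambda": [r.lam for r in records],
                "topology_key": [topology_key(r.tree) for r in records],
            }
        ),
    )
    _write_tsv(
        itdir / "logliks.tsv",
        pd.DataFrame(
            {
                "tree_id": range(len(current)),
                "source": sources,
                "topology_key": [topology_key(t) for t in current],
                "loglik": logliks,
            }
        ),
    )
    (itdir / "optimized.nwk").write_text(
        "".join(write_newick(o.result.tree) + "\n" for o in optimized)
    )
    _write_tsv(
        itdir / "optimized.tsv",
        pd.DataFrame(
            {
                "topology_key": [o.key for o in optimized],
                "cluster_size": [o.cluster_size for o in optimized],
                "start_loglik": [o.start_loglik for o in optimized],
                "loglik": [o.result.loglik for o in optimized],
                "n_sweeps": [o.result.n_sweeps for o in optimized],
            }
        ),
    )

    state.landscape = ls.build_landscape(
        current, logliks, metric=metric,
        interpolation=config.interpolation, grid=config.grid,
    )
    land = state.landscape
    _write_tsv(
        itdir / "coords.tsv",
        pd.DataFrame(
            {
                "tree_id": range(len(current)),
                "x": land.coords[:, 0],
                "y": land.coords[:, 1],
                "loglik": logliks,
                "topology_key": land.topology_keys,
                "is_hull_vertex": [
                    i in set(map(int, land.hull)) for i in range(len(current))
                ],
            }
        ),
    )
    _write_tsv(
        itdir / "shepard.tsv",
        pd.DataFrame(
            {"original": land.shepard.original, "embedded": land.shepard.embedded}
        ),
    )
    if config.figures:
        ls.plot_landscape(land, itdir / "contour.png", mode="contour",
                          annotations=annotations)
        ls.plot_landscape(land, itdir / "surface3d.png", mode="surface3d",
                          annotations=annotations)
    return state


def run(config: RunConfig) -> IterationState:
    """Execute the full pipeline; returns the final iteration's state.

    Artifacts (trees, TSVs, figures, ``runlog.json``, ``best_tree.nwk``) are
    written under ``config.outdir``, one subdirectory per iteration.  Output
    is deterministic for a fixed config and seed.
    """
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "iterations": [],
    }
    t0 = time.perf_counter()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            log["failed_stage"] = name
            (outdir / "runlog.json").write_text(json.dumps(log, indent=2))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    aln = stage("read_alignment", lambda: parse_phylip(
        pathlib.Path(config.alignment_path).read_text()))
    trees = stage("read_trees", lambda: read_newicks(
        pathlib.Path(config.trees_path).read_text()))
    sample = stage("subsample", subsample_trees, trees,
                   config.burnin_fraction, config.stride)

    starting = stage(
        "select_starting_trees", select_starting_trees, sample, config.metric
    )

    best_loglik = -np.inf
    best_tree: Tree | None = None
    best_where = None
    state: IterationState | None = None
    for iteration in range(1, config.iterations + 1):
        tic = time.perf_counter()
        if iteration > 1:
            prev_opt = [o.result.tree for o in state.optimized]
            try:
                starting = select_starting_trees(
                    prev_opt, config.metric_for(iteration)
                )
            except (ValueError, ls.DegenerateHullError) as exc:
                # Fewer than 3 distinct optimized topologies (or a collinear
                # embedding): there is no region left to zoom into.
                log["stopped_early"] = {
                    "iteration": iteration,
                    "reason": str(exc),
                }
                break
        state = stage(
            f"iteration{iteration}",
            _run_iteration, iteration, starting, "starting",
            aln, config, outdir,
        )
        idx = int(np.argmax(state.logliks))
        if state.logliks[idx] > best_loglik:
            best_loglik = float(state.logliks[idx])
            best_tree = state.current_sample[idx]
            best_where = {"iteration": iteration, "tree_id": idx}
        log["iterations"].append(
            {
                "iteration": iteration,
                "metric": config.metric_for(iteration),
                "m": config.m_per_iteration()[iteration - 1],
                "n_starting": len(state.starting_trees),
                "n_pathtrees": len(state.pathtrees),
                "n_selected": len(state.topn_indices),
                "n_topologies": len(state.optimized),
                "best_loglik": float(np.max(state.logliks)),
                "best_optimized_loglik": max(
                    o.result.loglik for o in state.optimized
                ),
                "shepard_pearson_r": state.landscape.shepard.pearson_r,
                "starting_tree_newicks": [
                    write_newick(t) for t in state.starting_trees
                ],
                "seconds": round(time.perf_counter() - tic, 3),
            }
        )

    (outdir / "best_tree.nwk").write_text(write_newick(best_tree) + "\n")
    log["best"] = {"loglik": best_loglik, **best_where}
    log["total_seconds"] = round(time.perf_counter() - t0, 3)
    (outdir / "runlog.json").write_text(json.dumps(log, indent=2))
    return state
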