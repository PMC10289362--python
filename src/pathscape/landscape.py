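"""Treespace landscapes: MDS embedding, convex hull, interpolated surfaces.

Because the orthants of treespace have dimension 2n-3, a likelihood
landscape cannot be drawn directly.  Instead, a pairwise tree-distance
matrix (BHV or weighted RF) is embedded in 2-D by classical (Torgerson)
multidimensional scaling, the embedding quality is validated by Shepard
correlations between original and embedded distances, and the per-tree
log-likelihoods are interpolated to a surface over the convex hull of the
embedded points.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from matplotlib.path import Path as MplPath
from scipy.interpolate import CloughTocher2DInterpolator, RBFInterpolator
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kendalltau, pearsonr, spearmanr

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .distances import distance_matrix  # noqa: E402
from .treeio import topology_key  # noqa: E402

__all__ = [
    "Landscape",
    "ShepardStats",
    "Surface",
    "DegenerateHullError",
    "mds_embed",
    "hull_vertices",
    "shepard_stats",
    "interpolate_surface",
    "build_landscape",
    "plot_landscape",
]


class DegenerateHullError(ValueError):
    """The point configuration has no 2-D convex hull (e.g. collinear)."""


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    return dist


def mds_embed(
    dist: np.ndarray,
    dim: int = 2,
    method: str = "classical",
    seed: int | None = None,
) -> np.ndarray:
    """Embed a distance matrix in ``dim`` Euclidean dimensions.

    ``classical`` (default) is Torgerson MDS: double-center -1/2 J D^2 J,
    take the top ``dim`` eigenpairs, and scale eigenvectors by the square
    roots of their eigenvalues.  Negative eigenvalues -- produced by
    non-Euclidean matrices such as BHV distances -- are truncated to zero.
    Each axis is flipped so its largest-magnitude coordinate is positive,
    making the output deterministic.  ``smacof`` (seeded, via scikit-learn)
    is available for comparison with stress-minimizing MDS.
    """
    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if method == "smacof":
        from sklearn.manifold import MDS

        model = MDS(
            n_components=dim,
            dissimilarity="precomputed",
            random_state=seed if seed is not None else 0,
            normalized_stress=False,
        )
        return model.fit_transform(dist)
    if method != "classical":
        raise ValueError(f"unknown MDS method {method!r}")
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * centering @ (dist**2) @ centering
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1][:dim]
    top = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(top)
    for axis in range(coords.shape[1]):
        extreme = np.argmax(np.abs(coords[:, axis]))
        if coords[extreme, axis] < 0:
            coords[:, axis] *= -1.0
    return coords


def hull_vertices(coords: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex-hull vertex indices of 2-D points.

    Edge-interior and interior points are excluded.  Raises
    :class:`DegenerateHullError` for fewer than 3 points or a collinear
    configuration.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array")
    if coords.shape[0] < 3:
        raise DegenerateHullError("need at least 3 points for a 2-D hull")
    try:
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate point configuration: {exc}") from exc
    return hull.vertices.copy()


@dataclass
class ShepardStats:
    """Embedding-validation correlations and the paired distance vectors."""

    pearson_r: float
    spearman_rho: float
    kendall_tau: float
    original: np.ndarray
    embedded: np.ndarray


def shepard_stats(dist: np.ndarray, coords: np.ndarray) -> ShepardStats:
    """Correlations between original and embedded pairwise distances.

    Computed over the strict upper triangle; the paired vectors are
    returned for Shepard-diagram plotting.
    """
    dist = _check_distance_matrix(dist)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != dist.shape[0]:
        raise ValueError("coordinate count does not match distance matrix")
    iu = np.triu_indices(dist.shape[0], k=1)
    if iu[0].size < 2:
        raise ValueError("need at least 2 distance pairs")
    original = dist[iu]
    diff = coords[iu[0]] - coords[iu[1]]
    embedded = np.hypot(*diff.T) if coords.shape[1] == 2 else np.linalg.norm(diff, axis=1)
    if np.allclose(original, original[0]) or np.allclose(embedded, embedded[0]):
        # Constant vectors: perfect embedding of an equidistant configuration.
        exact = np.allclose(original - original.mean(), embedded - embedded.mean())
        value = 1.0 if exact else float("nan")
        return ShepardStats(value, value, value, original, embedded)
    return ShepardStats(
        float(pearsonr(original, embedded).statistic),
        float(spearmanr(original, embedded).statistic),
        float(kendalltau(original, embedded).statistic),
        original,
        embedded,
    )


@dataclass
class Surface:
    """Interpolated log-likelihood surface, masked outside the convex hull."""

    xs: np.ndarray  # grid x coordinates (grid,)
    ys: np.ndarray  # grid y coordinates (grid,)
    values: np.ma.MaskedArray  # (grid, grid), ys along axis 0


def interpolate_surface(
    coords: np.ndarray,
    values: np.ndarray,
    method: str = "tps",
    grid: int = 300,
) -> Surface:
    """Interpolate scattered values onto a grid over the bounding box.

    ``cubic`` is piecewise-cubic interpolation on a Delaunay triangulation
    (Clough-Tocher); ``tps`` is a thin-plate-spline radial basis with zero
    smoothing, which reproduces affine fields exactly.  Cells outside the
    convex hull of the data points are masked.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coordinate and value counts differ")
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 points to interpolate a surface")
    hull = hull_vertices(coords)

    xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid)
    ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid)
    gx, gy = np.meshgrid(xs, ys)
    sites = np.column_stack([gx.ravel(), gy.ravel()])

    if method == "cubic":
        try:
            interp = CloughTocher2DInterpolator(coords, values)
        except QhullError as exc:
            raise ValueError(
                "cubic interpolation needs a non-degenerate triangulation; "
                "try method='tps'"
            ) from exc
        flat = interp(sites)
    elif method == "tps":
        rbf = RBFInterpolator(coords, values, kernel="thin_plate_spline", smoothing=0.0)
        flat = rbf(sites)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")

    polygon = MplPath(coords[hull])
    inside = polygon.contains_points(sites, radius=1e-9)
    masked = np.ma.masked_invalid(
        np.ma.masked_array(flat, mask=~inside).reshape(grid, grid)
    )
    return Surface(xs, ys, masked)


@dataclass
class Landscape:
    """A set of trees with coordinates, log-likelihoods, and a surface."""

    trees: list
    dist: np.ndarray
    coords: np.ndarray
    loglik: np.ndarray
    topology_keys: list[str]
    hull: np.ndarray
    surface: Surface
    shepard: ShepardStats
    metric: str
    interpolation: str


def build_landscape(
    trees,
    logliks,
    metric: str = "bhv",
    interpolation: str = "tps",
    grid: int = 300,
) -> Landscape:
    """Distance matrix -> MDS -> hull -> interpolated surface, in one call."""
    logliks = np.asarray(logliks, dtype=float)
    dist = distance_matrix(trees, metric=metric)
    coords = mds_embed(dist, dim=2)
    hull = hull_vertices(coords)
    surface = interpolate_surface(coords, logliks, method=interpolation, grid=grid)
    return Landscape(
        trees=list(trees),
        dist=dist,
        coords=coords,
        loglik=logliks,
        topology_keys=[topology_key(t) for t in trees],
        hull=hull,
        surface=surface,
        shepard=shepard_stats(dist, coords),
        metric=metric,
        interpolation=interpolation,
    )


def plot_landscape(
    landscape: Landscape,
    path,
    mode: str = "contour",
    annotations: dict | None = None,
) -> None:
    """Render a landscape to an image file.

    ``annotations`` may hold index lists: ``starting`` (triangles),
    ``selected`` (small circles) and ``optimized`` (medium circles), both on
    a purple spectrum ordered by log-likelihood (lighter = lower), and
    ``best`` (red square).
    """
    if len(landscape.trees) == 0:
        raise ValueError("cannot plot an empty landscape")
    annotations = annotations or {}
    surf = landscape.surface
    gx, gy = np.meshgrid(surf.xs, surf.ys)

    if mode == "contour":
        fig, ax = plt.subplots(figsize=(7, 6))
        contour = ax.contourf(gx, gy, surf.values, levels=30, cmap="viridis")
        fig.colorbar(contour, ax=ax, label="log likelihood")
        ax.scatter(
            landscape.coords[:, 0],
            landscape.coords[:, 1],
            c=landscape.loglik,
            cmap="viridis",
            s=12,
            edgecolors="k",
            linewidths=0.3,
        )
    elif mode == "surface3d":
        fig = plt.figure(figsize=(8, 6))
        ax = fig.add_subplot(projection="3d")
        ax.plot_surface(gx, gy, surf.values.filled(np.nan), cmap="viridis", alpha=0.85)
        ax.scatter(
            landscape.coords[:, 0],
            landscape.coords[:, 1],
            landscape.loglik,
            c=landscape.loglik,
            cmap="viridis",
            s=12,
        )
        ax.set_zlabel("log likelihood")
    else:
        raise ValueError(f"unknown plot mode {mode!r}")

    def scatter2d(idx, **kwargs):
        idx = np.asarray(idx, dtype=int)
        if mode == "surface3d":
            ax.scatter(
                landscape.coords[idx, 0],
                landscape.coords[idx, 1],
                landscape.loglik[idx],
                **kwargs,
            )
        else:
            ax.scatter(landscape.coords[idx, 0], landscape.coords[idx, 1], **kwargs)

    purples = plt.get_cmap("Purples")
    for key, marker, size in (("selected", "o", 18), ("optimized", "o", 55)):
        idx = annotations.get(key)
        if idx is not None and len(idx) > 0:
            ranks = np.argsort(np.argsort(landscape.loglik[np.asarray(idx)]))
            shades = purples(0.3 + 0.7 * ranks / max(len(idx) - 1, 1))
            scatter2d(idx, marker=marker, s=size, c=shades, edgecolors="k", linewidths=0.4)
    if annotations.get("starting") is not None:
        scatter2d(annotations["starting"], marker="^", s=70, c="orange",
                  edgecolors="k", label="starting trees")
    if annotations.get("best") is not None:
        scatter2d([annotations["best"]], marker="s", s=90, c="red",
                  edgecolors="k", label="best tree")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
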