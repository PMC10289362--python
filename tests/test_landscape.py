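import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from pathscape.landscape import (
    DegenerateHullError,
    build_landscape,
    hull_vertices,
    interpolate_surface,
    mds_embed,
    plot_landscape,
    shepard_stats,
)
from pathscape.likelihood import log_likelihood
from pathscape.simulate import SimSpec, perturb_cloud, random_tree, simulate_alignment

from _oracles import support_function_hull


class TestMDS:
    def test_recovers_planar_configuration_exactly(self, rng):
        points = rng.normal(size=(25, 2))
        dist = squareform(pdist(points))
        coords = mds_embed(dist)
        recovered = squareform(pdist(coords))
        assert np.allclose(recovered, dist, atol=1e-9)
        assert shepard_stats(dist, coords).pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_equilateral_triangle(self):
        dist = np.ones((3, 3)) - np.eye(3)
        coords = mds_embed(dist)
        sides = pdist(coords)
        assert np.allclose(sides, 1.0, atol=1e-9)

    def test_duplicate_points_coincide(self, rng):
        points = rng.normal(size=(10, 2))
        points[3] = points[7]
        dist = squareform(pdist(points))
        coords = mds_embed(dist)
        assert np.allclose(coords[3], coords[7], atol=1e-9)

    def test_deterministic_sign_convention(self, rng):
        points = rng.normal(size=(12, 2))
        dist = squareform(pdist(points))
        c1, c2 = mds_embed(dist), mds_embed(dist)
        assert np.array_equal(c1, c2)
        for axis in range(2):
            assert c1[np.abs(c1[:, axis]).argmax(), axis] >= 0

    @pytest.mark.parametrize(
        "bad",
        [np.array([[0.0, 1.0], [2.0, 0.0]]), -np.ones((3, 3)) + np.eye(3)],
        ids=["asymmetric", "negative"],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            mds_embed(bad)

    def test_smacof_variant_runs(self, rng):
        points = rng.normal(size=(10, 2))
        dist = squareform(pdist(points))
        coords = mds_embed(dist, method="smacof", seed=0)
        assert coords.shape == (10, 2)


class TestHull:
    def test_square_plus_center(self):
        coords = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], float)
        assert set(hull_vertices(coords)) == {0, 1, 2, 3}

    def test_collinear_plus_one_gives_triangle(self):
        coords = np.array([[0, 0], [1, 0], [2, 0], [3, 0], [1, 2]], float)
        assert set(hull_vertices(coords)) == {0, 3, 4}

    def test_matches_direction_sweep_oracle(self, rng):
        coords = rng.normal(size=(1000, 2))
        vertices = set(hull_vertices(coords))
        extremes = support_function_hull(coords)
        # every sweep-extreme point is a hull vertex, and every hull vertex
        # is extreme in some direction
        assert extremes <= vertices
        assert vertices <= support_function_hull(coords, n_directions=5000)

    def test_interior_point_never_changes_hull(self, rng):
        coords = rng.normal(size=(40, 2))
        vertices = hull_vertices(coords)
        centroid = coords.mean(axis=0, keepdims=True)
        augmented = np.vstack([coords, centroid])
        assert set(hull_vertices(augmented)) == set(vertices)

    def test_collinear_configuration_raises(self):
        coords = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(DegenerateHullError):
            hull_vertices(coords)


class TestShepard:
    def test_shifted_distances_keep_correlations(self, rng):
        points = rng.normal(size=(15, 2))
        dist = squareform(pdist(points))
        stats = shepard_stats(dist + 0.5 - 0.5 * np.eye(15), points)
        assert stats.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert stats.spearman_rho == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        points = rng.normal(size=(15, 2))
        dist = squareform(pdist(points))
        theta = 1.1
        rotation = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = points @ rotation.T * np.array([1, -1]) + np.array([3.0, -7.0])
        s0, s1 = shepard_stats(dist, points), shepard_stats(dist, moved)
        assert s0.pearson_r == pytest.approx(s1.pearson_r, abs=1e-12)
        assert s0.kendall_tau == pytest.approx(s1.kendall_tau, abs=1e-12)

    def test_anti_ordered_kendall(self):
        # original pair distances (1, 2, 3) embedded as (3, 2, 1)
        dist = np.array(
            [[0, 1, 2], [1, 0, 3], [2, 3, 0]], float
        )
        coords = np.array([[0, 0], [3, 0], [2, 0]], float)
        stats = shepard_stats(dist, coords)
        assert stats.kendall_tau == pytest.approx(-1.0)


class TestInterpolation:
    def test_constant_field_stays_constant(self, rng):
        coords = rng.uniform(size=(30, 2))
        values = np.full(30, -1234.5)
        for method in ("cubic", "tps"):
            surf = interpolate_surface(coords, values, method=method, grid=25)
            inside = surf.values[~surf.values.mask]
            assert np.allclose(inside, -1234.5, atol=1e-6)

    def test_interpolant_reproduces_data_at_sites(self, rng):
        # data sites placed on the evaluation lattice so the surface grid
        # passes exactly through them
        axis = np.linspace(0.0, 1.0, 5)
        gx, gy = np.meshgrid(axis, axis)
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        values = rng.normal(size=len(coords))
        for method, tol in (("cubic", 1e-9), ("tps", 1e-6)):
            surf = interpolate_surface(coords, values, method=method, grid=5)
            flat = np.asarray(surf.values).ravel()
            assert np.allclose(flat, values, atol=tol)

    def test_tps_reproduces_affine_field(self, rng):
        coords = rng.uniform(size=(50, 2))
        values = 2 * coords[:, 0] - coords[:, 1] + 3
        surf = interpolate_surface(coords, values, method="tps", grid=30)
        gx, gy = np.meshgrid(surf.xs, surf.ys)
        plane = 2 * gx - gy + 3
        residual = (surf.values - plane)[~surf.values.mask]
        assert np.max(np.abs(residual)) < 1e-6

    def test_collinear_cubic_suggests_tps(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises((ValueError, DegenerateHullError)):
            interpolate_surface(coords, np.arange(5.0), method="cubic", grid=10)


class TestPlotting:
    @pytest.fixture()
    def small_landscape(self, rng):
        base = random_tree(SimSpec(n_leaves=6, seed=9), rng)
        spec = SimSpec(n_leaves=6, n_trees=12, perturb_moves=2, jitter_sigma=0.3)
        trees = perturb_cloud(base, spec, rng)
        aln = simulate_alignment(base, 150, rng)
        logliks = [log_likelihood(t, aln).loglik for t in trees]
        return build_landscape(trees, logliks, metric="wrf", grid=25)

    def test_contour_and_surface_files(self, small_landscape, tmp_path):
        for mode in ("contour", "surface3d"):
            out = tmp_path / f"{mode}.png"
            plot_landscape(
                small_landscape, out, mode=mode,
                annotations={"starting": [0, 1], "best": 2, "optimized": [3, 4]},
            )
            assert out.stat().st_size > 0

    def test_unknown_mode_rejected(self, small_landscape, tmp_path):
        with pytest.raises(ValueError):
            plot_landscape(small_landscape, tmp_path / "x.png", mode="holo")
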