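import numpy as np
import pytest
from scipy.stats import chisquare

import smlmwrap as sw
from smlmwrap.simulate import sample_surface


def _brute_force_distance(shape, points, n_samples=60_000, seed=0):
    """Independent oracle: unsigned distance via dense surface sampling."""
    rng = np.random.default_rng(seed)
    surf = sample_surface(shape, n_samples, rng)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(surf).query(points)
    return d


class TestFigureEight:
    def test_tube_circle_center_sdf(self):
        shape = sw.make_figure_eight(800.0, 100.0)
        # lobe center +-200; ring radius 150 -> deepest interior points
        for p in ([200.0 + 150.0, 0, 0], [200.0 - 150.0, 0, 0],
                  [-200.0 - 150.0, 0, 0]):
            assert shape.sdf(np.array([p]))[0] == pytest.approx(-50.0)

    def test_reflection_symmetry(self, rng):
        shape = sw.make_figure_eight(800.0, 100.0)
        pts = rng.uniform(-450, 450, (500, 3))
        mirrored = pts * [-1, 1, 1]
        np.testing.assert_allclose(shape.sdf(pts), shape.sdf(mirrored),
                                   atol=1e-9)

    def test_far_point_distance(self, rng):
        shape = sw.make_figure_eight(800.0, 100.0)
        pts = rng.uniform(-600, 600, (40, 3))
        pts[:, 2] += 400.0  # keep them outside
        sdf = shape.sdf(pts)
        brute = _brute_force_distance(shape, pts)
        assert (sdf > 0).all()
        np.testing.assert_allclose(sdf, brute, atol=1.5)

    def test_extent_matches_diameter(self):
        shape = sw.make_figure_eight(800.0, 100.0)
        rng = np.random.default_rng(0)
        pts = sample_surface(shape, 4000, rng)
        assert np.ptp(pts[:, 0]) == pytest.approx(800.0, abs=10.0)
        assert np.ptp(pts[:, 2]) == pytest.approx(100.0, abs=5.0)

    def test_gradient_is_unit_in_shell(self, rng):
        shape = sw.make_figure_eight(800.0, 100.0)
        pts = sample_surface(shape, 2000, np.random.default_rng(1))
        shell = pts + rng.normal(0, 20, pts.shape)  # within +-50 nm mostly
        gn = np.linalg.norm(shape.gradient(shell), axis=1)
        assert np.mean(np.abs(gn - 1) < 0.01) > 0.99


class TestTaperedCylinder:
    def test_zero_level_radius_at_midlength(self):
        shape = sw.make_tapered_cylinder(30.0, 200.0, 2000.0)
        rmid = (30.0 + 200.0) / 2
        p = np.array([[rmid, 0.0, 1000.0]])
        assert abs(shape.sdf(p)[0]) < 1e-6

    def test_on_axis_points(self):
        shape = sw.make_tapered_cylinder(30.0, 200.0, 2000.0)
        assert shape.sdf(np.array([[0.0, 0, -10.0]]))[0] == pytest.approx(10.0)
        assert abs(shape.sdf(np.array([[0.0, 0, 0.0]]))[0]) < 1e-9
        # interior point near the narrow cap: nearest boundary is the cap
        assert shape.sdf(np.array([[0.0, 0, 10.0]]))[0] == pytest.approx(-10.0)

    def test_sdf_against_brute_force(self, rng):
        shape = sw.make_tapered_cylinder(30.0, 200.0, 2000.0)
        pts = rng.uniform([-250, -250, -100], [250, 250, 2100], (60, 3))
        brute = _brute_force_distance(shape, pts)
        np.testing.assert_allclose(np.abs(shape.sdf(pts)), brute, atol=2.0)

    def test_lateral_curvature(self):
        shape = sw.make_tapered_cylinder(30.0, 200.0, 2000.0)
        # r(z) = 100 at z ~ 823.5; circumferential curvature 1/r = 0.01
        z = (100.0 - 30.0) / ((200.0 - 30.0) / 2000.0)
        p = np.array([[100.0, 0.0, z]])
        assert shape.curvature_radius(p)[0] == pytest.approx(100.0)
        slope = (200.0 - 30.0) / 2000.0
        cosb = 1 / np.hypot(1, slope)
        assert shape.mean_curvature(p)[0] == pytest.approx(0.5 * cosb / 100.0)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            sw.make_tapered_cylinder(200.0, 30.0, 2000.0)


class TestSimulateLocalizations:
    def test_no_background_points_stay_near_surface(self):
        shape = sw.make_sphere(100.0)
        spec = sw.SimulationSpec(shape=shape, density=2e-2,
                                 background_ratio=0.0, sigma_median=10.0,
                                 seed=1)
        cloud, _ = sw.simulate_localizations(spec)
        assert np.abs(shape.sdf(cloud.positions)).max() < 5 * cloud.sigmas.max()

    def test_displacement_std_matches_sigma(self):
        shape = sw.make_sphere(150.0)
        spec = sw.SimulationSpec(shape=shape, density=4e-2,
                                 background_ratio=0.0, sigma_median=10.0,
                                 sigma_shape=1e-9, seed=2)
        cloud, _ = sw.simulate_localizations(spec)
        # signed distance along the local normal ~ N(0, sigma)
        s = shape.sdf(cloud.positions).std()
        assert abs(s - 10.0) < 0.3

    def test_background_count(self):
        shape = sw.make_sphere(150.0)
        spec = sw.SimulationSpec(shape=shape, density=4e-2,
                                 background_ratio=0.2, seed=3)
        cloud, _ = sw.simulate_localizations(spec)
        n_surface = int(round(4e-2 * shape.area))
        n_bg = len(cloud) - n_surface
        assert n_bg / len(cloud) == pytest.approx(0.2, abs=0.01)

    def test_determinism(self):
        shape = sw.make_sphere(100.0)
        spec = sw.SimulationSpec(shape=shape, density=1e-2,
                                 background_ratio=0.3, seed=11)
        c1, v1 = sw.simulate_localizations(spec)
        c2, v2 = sw.simulate_localizations(spec)
        np.testing.assert_array_equal(c1.positions, c2.positions)
        np.testing.assert_array_equal(c1.sigmas, c2.sigmas)
        np.testing.assert_array_equal(v1, v2)

    def test_verification_noise_free_and_separate(self):
        shape = sw.make_sphere(100.0)
        spec = sw.SimulationSpec(shape=shape, density=2e-2,
                                 background_ratio=0.0, seed=4)
        cloud, verification = sw.simulate_localizations(spec)
        assert np.abs(shape.sdf(verification)).max() < 1e-6
        assert len(verification) >= 100

    def test_low_density_warns(self):
        shape = sw.make_sphere(20.0)
        spec = sw.SimulationSpec(shape=shape, density=5e-3,
                                 background_ratio=0.0, seed=5)
        with pytest.warns(UserWarning):
            sw.simulate_localizations(spec)

    def test_axial_inflation(self):
        shape = sw.make_sphere(100.0)
        spec = sw.SimulationSpec(shape=shape, density=1e-2,
                                 background_ratio=0.0, axial_inflation=3.0,
                                 seed=6)
        cloud, _ = sw.simulate_localizations(spec)
        np.testing.assert_allclose(cloud.sigmas[:, 2] / cloud.sigmas[:, 0], 3.0)

    def test_invalid_spec_rejected(self):
        shape = sw.make_sphere(100.0)
        with pytest.raises(ValueError):
            sw.SimulationSpec(shape=shape, density=-1.0)
        with pytest.raises(ValueError):
            sw.SimulationSpec(shape=shape, background_ratio=1.0)


def test_area_uniform_sampling_chi_square():
    """Counts in equal-area patches (octants of a sphere) are consistent
    with a uniform multinomial."""
    shape = sw.make_sphere(100.0)
    rng = np.random.default_rng(21)
    pts = sample_surface(shape, 16_000, rng)
    octant = ((pts[:, 0] > 0).astype(int) + 2 * (pts[:, 1] > 0)
              + 4 * (pts[:, 2] > 0))
    counts = np.bincount(octant, minlength=8)
    _, p = chisquare(counts)
    assert p > 0.01
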