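"""Diffusion forward model: reflectance, Green's functions, Jacobian,
closed-form moments, and moment-based optical-property estimation."""

import numpy as np
import pytest
from scipy.integrate import quad

from dtofsense.dtof import MomentSet, moments_from_counts
from dtofsense.forward import (
    OpticalProperties,
    OptodeGeometry,
    TimeGrid,
    absorption_jacobian_td,
    estimate_optical_properties,
    greens_fluence,
    reflectance_td,
    theoretical_moments,
)
from dtofsense.forward import _effective_endpoints, _free_kernel, _mirror
from dtofsense.phantom import apply_irf, gaussian_irf


@pytest.fixture(scope="module")
def grid():
    return TimeGrid(10_000.0, 2048)


class TestReflectance:
    def test_absorption_enters_only_through_exponential(self, grid):
        base = OpticalProperties(1e-9, 10.0)
        r0 = reflectance_td(base, 3.0, grid, check_coverage=False)
        for mu_a in (0.05, 0.1, 0.3):
            props = OpticalProperties(mu_a, 10.0)
            r = reflectance_td(props, 3.0, grid, check_coverage=False)
            expected = r0 * np.exp(-(mu_a - base.mu_a) * props.v * grid.centers)
            np.testing.assert_allclose(r, expected, rtol=1e-9, atol=r.max() * 1e-12)

    def test_total_reflectance_decreases_with_separation(self, grid, props10=None):
        props = OpticalProperties(0.1, 10.0)
        i1 = reflectance_td(props, 2.0, grid).sum()
        i2 = reflectance_td(props, 4.0, grid).sum()
        assert i2 < i1

    def test_curve_nonnegative_and_vanishing_at_ends(self, grid):
        r = reflectance_td(OpticalProperties(0.1, 10.0), 3.0, grid)
        assert np.all(r >= 0)
        assert r[0] < 1e-12 * r.max()
        assert r[-1] < 1e-6 * r.max()

    def test_short_grid_raises_naming_uncovered_mass(self):
        with pytest.raises(ValueError, match="grid too short"):
            reflectance_td(OpticalProperties(0.01, 5.0), 4.0, TimeGrid(1500.0, 128))

    def test_binned_m1_matches_quadrature(self, grid):
        props = OpticalProperties(0.1, 10.0)
        r = reflectance_td(props, 3.0, grid)
        t = grid.centers
        m1_binned = (r * t).sum() / r.sum()
        r_s, r_d = _effective_endpoints(props, 3.0)
        d1 = np.linalg.norm(r_d - r_s)
        d2 = np.linalg.norm(_mirror(r_d, props.zb()) - r_s)

        def curve(tt):
            return float(
                _free_kernel(d1, np.array([tt]), props)[0, 0]
                - _free_kernel(d2, np.array([tt]), props)[0, 0]
            )

        i0 = quad(curve, 1e-6, 30_000, limit=300)[0]
        i1 = quad(lambda tt: tt * curve(tt), 1e-6, 30_000, limit=300)[0]
        assert m1_binned == pytest.approx(i1 / i0, rel=1e-4)


class TestGreensFunction:
    def test_reciprocity(self, grid):
        props = OpticalProperties(0.1, 10.0)
        a = np.array([0.0, 0.0, 0.5])
        b = np.array([2.0, 1.0, 1.5])
        np.testing.assert_array_equal(
            greens_fluence(props, a, b, grid), greens_fluence(props, b, a, grid)
        )

    def test_vanishes_on_extrapolated_boundary(self, grid):
        props = OpticalProperties(0.1, 10.0)
        interior = np.array([0.0, 0.0, 1.0])
        on_plane = np.array([1.0, 0.0, -props.zb()])
        g_plane = greens_fluence(props, interior, on_plane, grid)
        g_interior = greens_fluence(props, interior, np.array([1.0, 0.0, 1.0]), grid)
        assert np.max(np.abs(g_plane)) < 1e-9 * g_interior.max()

    def test_coincident_points_rejected(self, grid):
        props = OpticalProperties(0.1, 10.0)
        p = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="singular"):
            greens_fluence(props, p, p, grid)


class TestJacobian:
    def test_source_detector_reciprocity(self, grid):
        props = OpticalProperties(0.1, 10.0)
        src = np.array([0.0, 0.0, 0.0])
        det = np.array([3.0, 0.0, 0.0])
        vox = np.array([1.0, 0.3, 1.2])
        a = absorption_jacobian_td(props, src, det, vox, grid)
        b = absorption_jacobian_td(props, det, src, vox, grid)
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=a.max() * 1e-14)

    def test_absorption_scaling(self, grid):
        src = np.array([0.0, 0.0, 0.0])
        det = np.array([3.0, 0.0, 0.0])
        vox = np.array([1.5, 0.0, 1.0])
        k0 = absorption_jacobian_td(OpticalProperties(1e-9, 10.0), src, det, vox, grid)
        props = OpticalProperties(0.2, 10.0)
        k = absorption_jacobian_td(props, src, det, vox, grid)
        expected = k0 * np.exp(-props.mu_a * props.v * grid.centers)
        # discrete convolution puts bin k at t=(k+1)dt; compare with that shift
        expected_shifted = k0 * np.exp(
            -props.mu_a * props.v * (grid.centers + grid.dt / 2)
        )
        np.testing.assert_allclose(k, expected_shifted, rtol=1e-6, atol=k.max() * 1e-9)

    def test_remote_voxel_negligible(self, grid):
        props = OpticalProperties(0.1, 10.0)
        src = np.array([0.0, 0.0, 0.0])
        det = np.array([3.0, 0.0, 0.0])
        near = absorption_jacobian_td(props, src, det, np.array([1.5, 0.0, 0.5]), grid)
        far = absorption_jacobian_td(props, src, det, np.array([31.5, 0.0, 0.5]), grid)
        assert far.max() < 1e-6 * near.max()

    def test_voxel_outside_medium_rejected(self, grid):
        props = OpticalProperties(0.1, 10.0)
        with pytest.raises(ValueError, match="inside the medium"):
            absorption_jacobian_td(
                props, np.zeros(3), np.array([3.0, 0, 0]), np.array([1.0, 0, -0.5]), grid
            )


class TestTheoreticalMoments:
    @pytest.mark.parametrize("attr", ["m1", "V"])
    def test_moments_decrease_with_absorption(self, attr):
        vals = [
            getattr(theoretical_moments(OpticalProperties(mu_a, 10.0), 3.0), attr)
            for mu_a in (0.05, 0.1, 0.2, 0.4)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_closed_form_matches_binned_curve(self, grid):
        props = OpticalProperties(0.1, 10.0)
        r = reflectance_td(props, 3.0, grid)
        m = moments_from_counts(grid.centers, r)
        tm = theoretical_moments(props, 3.0)
        assert tm.m1 == pytest.approx(m.m1, rel=1e-3)
        assert tm.V == pytest.approx(m.V, rel=1e-3)
        assert tm.N == pytest.approx(m.N * grid.dt, rel=1e-3)

    def test_convolution_moment_additivity(self, grid):
        props = OpticalProperties(0.1, 10.0)
        r = reflectance_td(props, 3.0, grid)
        irf = gaussian_irf(grid, 650.0, 1500.0)
        conv = apply_irf(r, irf, grid.dt)
        m_r = moments_from_counts(grid.centers, r)
        m_i = moments_from_counts(grid.centers, irf)
        m_c = moments_from_counts(grid.centers, conv)
        assert m_c.m1 == pytest.approx(m_r.m1 + m_i.m1, abs=2 * grid.dt)
        assert m_c.V == pytest.approx(m_r.V + m_i.V, rel=1e-3)


class TestPropertyEstimation:
    def test_round_trip_delta_irf(self):
        truth = OpticalProperties(0.098, 10.13)
        meas = theoretical_moments(truth, 3.0)
        est, info = estimate_optical_properties(meas, MomentSet(1.0, 0.0, 0.0), 3.0)
        assert est.mu_a == pytest.approx(truth.mu_a, rel=0.02)
        assert est.mu_s_prime == pytest.approx(truth.mu_s_prime, rel=0.02)
        assert np.max(np.abs(info["residuals"])) < 1e-5

    def test_round_trip_gaussian_irf(self, grid):
        truth = OpticalProperties(0.098, 10.13)
        curve = reflectance_td(truth, 3.0, grid)
        irf = gaussian_irf(grid, 650.0, 1000.0)
        conv = apply_irf(curve, irf, grid.dt)
        meas = moments_from_counts(grid.centers, conv)
        irf_m = moments_from_counts(grid.centers, irf)
        est, _ = estimate_optical_properties(meas, irf_m, 3.0)
        assert est.mu_a == pytest.approx(truth.mu_a, rel=0.02)
        assert est.mu_s_prime == pytest.approx(truth.mu_s_prime, rel=0.02)

    def test_nonphysical_variance_rejected(self):
        meas = MomentSet(1e6, 1500.0, 1000.0)
        irf = MomentSet(1.0, 500.0, 2000.0)
        with pytest.raises(ValueError, match="variance"):
            estimate_optical_properties(meas, irf, 3.0)

    @pytest.mark.parametrize("mu_s_prime", [5.0, 20.0])
    def test_recovery_across_scattering_range(self, mu_s_prime):
        truth = OpticalProperties(0.1, mu_s_prime)
        meas = theoretical_moments(truth, 3.0)
        est, _ = estimate_optical_properties(meas, MomentSet(1.0, 0.0, 0.0), 3.0)
        assert est.mu_a == pytest.approx(truth.mu_a, rel=0.02)
        assert est.mu_s_prime == pytest.approx(truth.mu_s_prime, rel=0.02)


class TestGeometry:
    def test_channel_separations(self):
        geom = OptodeGeometry()
        assert geom.separation("left_2") == pytest.approx(3.0)
        assert geom.separation("right_1") == pytest.approx(3.0)
        assert geom.separation("left_1") == pytest.approx(2.5)
        assert geom.separation("right_2") == pytest.approx(2.5)

    def test_layout_symmetric_about_detector_midpoint(self):
        geom = OptodeGeometry()
        srcs = geom.source_positions
        dets = geom.detector_positions
        assert srcs["left"][0] == -srcs["right"][0]
        assert dets["1"][0] == -dets["2"][0]
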