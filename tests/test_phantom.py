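"""Synthetic sweep simulator: IRF handling, counting noise, dead time,
symmetries, and determinism."""

import numpy as np
import pytest

from dtofsense import (
    DeadTimeModel,
    Inclusion,
    NoiseConfig,
    OpticalProperties,
    OptodeGeometry,
    SweepGrid,
    TimeGrid,
    add_poisson_noise,
    apply_deadtime,
    apply_irf,
    correct_deadtime,
    gaussian_irf,
    simulate_sweep,
)
from dtofsense.dtof import moments_from_counts
from dtofsense.forward import reflectance_td


@pytest.fixture(scope="module")
def tiny_grid():
    return SweepGrid.from_extents(16, 8, 8, 4, 4, 4, 4)


@pytest.fixture(scope="module")
def tg512():
    return TimeGrid(8000.0, 512)


class TestSweepGrid:
    def test_default_position_counts_match_protocol(self):
        grid = SweepGrid.from_extents()
        # floor(extent/step) + 1 positions per axis: 38 x 18 x 21
        assert grid.shape == (38, 18, 21)

    def test_positions_inside_medium(self):
        grid = SweepGrid.from_extents()
        assert np.all(grid.positions_mm()[:, 2] > 0)

    def test_sweep_order_reshapes_to_xzy(self, tiny_grid):
        pos = tiny_grid.positions_mm()
        nx, nz, ny = tiny_grid.shape
        cube_x = pos[:, 0].reshape(nx, nz, ny)
        assert np.allclose(cube_x[0], tiny_grid.x_mm[0])
        cube_z = pos[:, 2].reshape(nx, nz, ny)
        assert np.allclose(cube_z[:, 1, :], tiny_grid.z_mm[1])

    def test_surface_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            SweepGrid(np.array([0.0]), np.array([0.0]), np.array([0.0]))


class TestInclusion:
    def test_cylinder_volume(self):
        inc = Inclusion(diameter_mm=3.0, height_mm=5.0)
        assert inc.volume_cm3 == pytest.approx(np.pi * 0.15**2 * 0.5)


class TestIRF:
    def test_near_delta_irf_is_identity(self, tg512):
        curve = reflectance_td(OpticalProperties(0.1, 10.0), 3.0, tg512)
        delta = np.zeros(tg512.n_bins)
        delta[0] = 1.0 / tg512.dt
        out = apply_irf(curve, delta, tg512.dt)
        np.testing.assert_allclose(out, curve, rtol=1e-9, atol=curve.max() * 1e-12)

    def test_integral_preserved(self, tg512):
        curve = reflectance_td(OpticalProperties(0.1, 10.0), 3.0, tg512)
        irf = gaussian_irf(tg512, 650.0, 1000.0)
        out = apply_irf(curve, irf, tg512.dt)
        assert out.sum() == pytest.approx(curve.sum(), rel=1e-4)

    def test_successive_convolutions_commute(self, tg512):
        rng = np.random.default_rng(9)
        t = tg512.centers
        a = np.exp(-0.5 * ((t - 2000) / 300.0) ** 2)
        b = np.exp(-((t - 1000) / 400.0) ** 2) * (1 + 0.1 * rng.random(t.size))
        c = np.exp(-t / 2500.0)
        ab_c = apply_irf(apply_irf(c, a, tg512.dt), b, tg512.dt)
        ba_c = apply_irf(apply_irf(c, b, tg512.dt), a, tg512.dt)
        np.testing.assert_allclose(ab_c, ba_c, rtol=1e-8, atol=ab_c.max() * 1e-10)


class TestPoissonNoise:
    def test_mean_total_counts(self, tg512):
        curve = reflectance_td(OpticalProperties(0.1, 10.0), 3.0, tg512)
        rng = np.random.default_rng(4)
        totals = [add_poisson_noise(curve, 1e5, rng).sum() for _ in range(50)]
        assert abs(np.mean(totals) - 1e5) < 4 * np.sqrt(1e5)

    def test_per_bin_variance_matches_mean(self):
        lam = np.array([5.0, 50.0, 500.0, 50.0, 5.0])
        rng = np.random.default_rng(8)
        draws = np.array(
            [add_poisson_noise(lam, lam.sum(), rng) for _ in range(10_000)]
        )
        ratio = draws.var(axis=0) / lam
        assert np.all(np.abs(ratio - 1) < 0.1)

    def test_zero_bins_stay_zero(self):
        lam = np.array([0.0, 100.0, 0.0])
        out = add_poisson_noise(lam, 300.0, 1)
        assert out[0] == 0 and out[2] == 0

    def test_reproducible_given_seed(self):
        lam = np.linspace(1, 50, 20)
        a = add_poisson_noise(lam, 1e4, 42)
        b = add_poisson_noise(lam, 1e4, 42)
        np.testing.assert_array_equal(a, b)


class TestDeadTime:
    def test_zero_tau_is_identity(self):
        model = DeadTimeModel(tau_ns=0.0)
        a = np.array([100.0, 200.0])
        b = np.array([300.0, 50.0])
        out_a, out_b = apply_deadtime(a, b, model)
        np.testing.assert_array_equal(out_a, a)
        np.testing.assert_array_equal(out_b, b)

    def test_five_percent_loss_round_trip(self):
        # tau chosen so the companion rate removes ~5% of the counts
        n_a, n_b = 150_000.0, 160_000.0
        model = DeadTimeModel(tau_ns=0.05 * 0.09 / n_b * 1e9)
        a = np.full(10, n_a / 10)
        b = np.full(10, n_b / 10)
        lost_a, lost_b = apply_deadtime(a, b, model)
        assert lost_a.sum() == pytest.approx(n_a / 1.05, rel=1e-6)
        back_a, back_b = correct_deadtime(lost_a, lost_b, model)
        assert back_a.sum() == pytest.approx(n_a, rel=1e-3)
        assert back_b.sum() == pytest.approx(n_b, rel=1e-3)

    def test_nonphysical_inversion_rejected(self):
        model = DeadTimeModel(tau_ns=1e9)
        with pytest.raises(ValueError, match="non-physical"):
            model.correct(1e6, 1e6)


class TestSimulateSweep:
    def test_zero_strength_matches_baseline(self, tiny_grid, tg512):
        ds = simulate_sweep(
            OpticalProperties(0.1, 10.0), OptodeGeometry(), tiny_grid,
            Inclusion(delta_mu_a=1e-30), NoiseConfig(poisson=False),
            seed=0, time_grid=tg512, n_replicates=1,
        )
        for ch in ds.channels:
            diff = ds.channels[ch][:, 0, :] - ds.baselines[ch][0][None, :]
            assert np.max(np.abs(diff)) < 1e-9 * ds.baselines[ch].max()

    def test_baseline_far_channels_identical(self, tiny_grid, tg512):
        ds = simulate_sweep(
            OpticalProperties(0.1, 10.0), OptodeGeometry(), tiny_grid,
            Inclusion(), NoiseConfig(poisson=False), seed=0,
            time_grid=tg512, n_replicates=1,
        )
        np.testing.assert_allclose(ds.baselines["left_2"], ds.baselines["right_1"])
        np.testing.assert_allclose(ds.baselines["left_1"], ds.baselines["right_2"])

    def test_mirror_positions_swap_left_right_channels(self, tg512):
        grid = SweepGrid.from_extents(20, 10, 8, 4, 2, 2, 4)
        ds = simulate_sweep(
            OpticalProperties(0.1, 10.0), OptodeGeometry(), grid,
            Inclusion(), NoiseConfig(poisson=False), seed=0,
            time_grid=tg512, n_replicates=1,
        )
        pos = grid.positions_mm()
        nx, nz, ny = grid.shape
        idx = np.arange(pos.shape[0]).reshape(nx, nz, ny)
        mirrored = idx[::-1]  # x -> -x (y symmetric about 0 here)
        np.testing.assert_allclose(
            ds.channels["left_2"][idx.ravel(), 0],
            ds.channels["right_1"][mirrored.ravel(), 0],
            rtol=1e-9,
        )

    def test_deterministic_given_seed(self, tiny_grid, tg512):
        kwargs = dict(
            props=OpticalProperties(0.1, 10.0), geometry=OptodeGeometry(),
            grid=tiny_grid, inclusion=Inclusion(),
            noise=NoiseConfig(poisson=True, count_rate_per_detector=1e5),
            seed=17, time_grid=tg512, n_replicates=3,
        )
        a = simulate_sweep(**kwargs)
        b = simulate_sweep(**kwargs)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])
            np.testing.assert_array_equal(a.baselines[ch], b.baselines[ch])

    def test_deep_inclusion_weaker_attenuation_stronger_variance_effect(self, tg512):
        """A deep midline inclusion yields a smaller ΔA but a larger ΔV per
        unit ΔA than a shallow one under a detector, on the far channel."""
        props = OpticalProperties(0.1, 10.0)
        geom = OptodeGeometry()
        grid = SweepGrid(
            x_mm=np.array([2.5]), z_mm=np.array([4.0, 30.0]), y_mm=np.array([0.0])
        )
        ds = simulate_sweep(
            props, geom, grid, Inclusion(), NoiseConfig(poisson=False),
            seed=0, time_grid=tg512, n_replicates=1,
        )
        t = tg512.centers
        base = moments_from_counts(t, ds.baselines["left_2"][0])
        shallow = moments_from_counts(t, ds.channels["left_2"][0, 0])
        deep = moments_from_counts(t, ds.channels["left_2"][1, 0])
        dA_shallow = -np.log(shallow.N / base.N)
        dA_deep = -np.log(deep.N / base.N)
        dV_shallow = base.V - shallow.V
        dV_deep = base.V - deep.V
        assert dA_deep < dA_shallow
        assert dV_deep / dA_deep > dV_shallow / dA_shallow

    def test_born_violation_warns(self, tg512):
        grid = SweepGrid(x_mm=np.array([0.0]), z_mm=np.array([6.0]), y_mm=np.array([0.0]))
        with pytest.warns(UserWarning, match="Born"):
            simulate_sweep(
                OpticalProperties(0.1, 10.0), OptodeGeometry(), grid,
                Inclusion(delta_mu_a=100.0), NoiseConfig(poisson=False),
                seed=0, time_grid=tg512, n_replicates=1,
            )
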