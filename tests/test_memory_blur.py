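"""Fourier-space memory blur of speed maps and the 1/w density prediction."""

import warnings

import numpy as np
import pytest
from scipy.integrate import IntegrationWarning, quad
from scipy.special import j0

from photokin.memory_blur import (
    blur_speed_map,
    density_vs_inverse_speed,
    fit_density_line,
    kernel_3d,
    kernel_ft,
    predict_density,
)


class TestKernelFT:
    def test_unit_mass_at_zero_q(self):
        assert kernel_ft(0.0, 0.017) == 1.0

    def test_value_at_q_equals_k(self):
        assert kernel_ft(1.0, 1.0) == pytest.approx(np.pi / 4.0)

    def test_monotone_decreasing_and_bounded(self):
        q = np.linspace(0.0, 5.0, 200)
        g = kernel_ft(q, 0.3)
        assert np.all(np.diff(g) < 0)
        assert np.all(g > 0) and np.all(g <= 1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            kernel_ft(1.0, 0.0)
        with pytest.raises(ValueError):
            kernel_ft(-1.0, 1.0)

    def test_matches_projected_kernel_transform(self):
        # brute-force oracle: z-project the 3-D kernel numerically, then
        # Hankel-transform the projection; closed form must agree to <1e-4
        k = 1.0 / 59.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IntegrationWarning)

            def gamma_rho(rho):
                val, _ = quad(
                    lambda z: kernel_3d(np.hypot(rho, z), k), 1e-9, 50.0 / k,
                    limit=400,
                )
                return 2.0 * val

            for q in (0.2 * k, k, 3.7 * k, 10.0 * k):
                ref, _ = quad(
                    lambda rho: 2.0 * np.pi * rho * gamma_rho(rho) * j0(q * rho),
                    1e-9, 60.0 / k, limit=800,
                )
                assert abs(kernel_ft(q, k) - ref) < 1e-4


class TestKernel3D:
    def test_unit_normalization(self):
        k = 0.02
        val, _ = quad(lambda r: 4.0 * np.pi * r**2 * kernel_3d(r, k), 1e-12, 80.0 / k)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decreasing(self):
        r = np.linspace(0.1, 100.0, 50)
        assert np.all(np.diff(kernel_3d(r, 0.05)) < 0)

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            kernel_3d(0.0, 1.0)


class TestBlurSpeedMap:
    def test_uniform_map_is_fixed_point(self):
        V = np.full((32, 48), 5.0)
        w = blur_speed_map(V, beta=0.44, tau_m=35.0)
        assert w == pytest.approx(V, abs=1e-12)

    def test_memoryless_identity(self, rng):
        V = 5.0 + rng.random((16, 16))
        assert blur_speed_map(V, beta=1.0, tau_m=35.0) is not V
        assert blur_speed_map(V, beta=1.0, tau_m=35.0) == pytest.approx(V)

    def test_plane_wave_is_eigenfunction(self):
        # cos(qx) maps to [beta + (1-beta)*gamma_tilde(q)] cos(qx) on a
        # periodic domain: the analytic transfer factor
        nx, ny, px = 128, 16, 2.0
        q = 2.0 * np.pi * 4 / (nx * px)
        x = np.arange(nx) * px
        V = 5.0 + 0.5 * np.tile(np.cos(q * x), (ny, 1))
        k = 1.0 / (V.mean() * 35.0)
        w = blur_speed_map(V, beta=0.44, k=k, pixel_size=px)
        factor = 0.44 + 0.56 * kernel_ft(q, k)
        expected = 5.0 + 0.5 * factor * np.tile(np.cos(q * x), (ny, 1))
        assert w == pytest.approx(expected, abs=1e-10)

    def test_mean_preserved(self, rng):
        V = 4.0 + rng.random((64, 64))
        w = blur_speed_map(V, beta=0.3, tau_m=20.0)
        assert w.mean() == pytest.approx(V.mean(), rel=1e-10)

    def test_mirror_boundary_runs_and_preserves_mean(self, rng):
        V = 4.0 + rng.random((32, 32))
        w = blur_speed_map(V, beta=0.3, tau_m=20.0, boundary="mirror")
        assert w.shape == V.shape
        assert w.mean() == pytest.approx(V.mean(), rel=1e-3)

    def test_non_positive_speed_rejected(self):
        V = np.ones((8, 8))
        V[0, 0] = 0.0
        with pytest.raises(ValueError):
            blur_speed_map(V, beta=0.5, tau_m=35.0)


class TestPredictDensity:
    def test_uniform_speed_gives_unit_density(self):
        rho = predict_density(np.full((10, 10), 3.0), alpha=0.7)
        assert rho == pytest.approx(1.0)

    def test_two_level_fully_responsive(self):
        w = np.where(np.arange(8) < 4, 5.0, 10.0)[None, :] * np.ones((4, 1))
        rho = predict_density(w, alpha=1.0)
        lo, hi = np.unique(np.round(rho, 12))
        assert lo == pytest.approx(2.0 / 3.0)
        assert hi == pytest.approx(4.0 / 3.0)

    def test_two_level_half_responsive_ratio(self):
        w = np.where(np.arange(8) < 4, 5.0, 10.0)[None, :] * np.ones((4, 1))
        rho = predict_density(w, alpha=0.5)
        lo, hi = np.unique(np.round(rho, 12))
        assert hi == pytest.approx(7.0 / 6.0)
        assert lo == pytest.approx(5.0 / 6.0)
        # baseline-subtracted modulation ratio of the responsive part
        assert (hi - 0.5) / (lo - 0.5) == pytest.approx(2.0)

    def test_mean_exactly_one(self, rng):
        w = 3.0 + rng.random((40, 40))
        assert predict_density(w, alpha=0.5).mean() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            predict_density(np.zeros((4, 4)), alpha=0.5)
        with pytest.raises(ValueError):
            predict_density(np.ones((4, 4)), alpha=1.5)


class TestDensityVsInverseSpeed:
    def _three_level_maps(self, alpha):
        speed = np.repeat([4.0, 6.0, 8.0], 10)[None, :] * np.ones((6, 1))
        levels = np.repeat([0, 1, 2], 10)[None, :] * np.ones((6, 1), dtype=int)
        rho = predict_density(speed, alpha=alpha)
        return rho, speed, levels

    def test_unblurred_points_exactly_on_line(self):
        alpha = 0.6
        rho, speed, levels = self._three_level_maps(alpha)
        table = density_vs_inverse_speed(rho, speed, levels)
        fit = fit_density_line(table)
        assert fit.intercept == pytest.approx(1.0 - alpha, abs=1e-12)
        assert abs(fit.r_value) == pytest.approx(1.0, abs=1e-12)

    def test_single_level_refused(self):
        rho = np.ones((4, 4))
        speed = np.full((4, 4), 5.0)
        levels = np.zeros((4, 4), dtype=int)
        with pytest.raises(ValueError):
            density_vs_inverse_speed(rho, speed, levels)

    def test_blur_bends_low_speed_branch_down(self):
        # on a fine pattern the blurred prediction falls below the straight
        # line at low speed — the qualitative signature of memory blur
        px = 2.0
        intensity_levels = np.array([2.5, 4.0, 5.5, 7.0])
        nx = 128
        idx = (np.arange(nx) // 8) % 4
        speed = intensity_levels[idx][None, :] * np.ones((8, 1))
        levels = idx[None, :] * np.ones((8, 1), dtype=int)
        w = blur_speed_map(speed, beta=0.44, tau_m=35.0, pixel_size=px)
        rho = predict_density(w, alpha=1.0)
        table = density_vs_inverse_speed(rho, speed, levels)
        fit = fit_density_line(table, n_high=2)
        slowest = table.iloc[-1]
        line_value = fit.slope * slowest["inv_speed_s_um"] + fit.intercept
        assert slowest["mean_density"] < line_value


class TestFitDensityLine:
    def test_refuses_single_point(self):
        speed = np.where(np.arange(8) < 4, 4.0, 8.0)[None, :] * np.ones((4, 1))
        levels = (np.arange(8) < 4).astype(int)[None, :] * np.ones((4, 1), dtype=int)
        table = density_vs_inverse_speed(
            predict_density(speed, 0.5), speed, levels
        )
        with pytest.raises(ValueError):
            fit_density_line(table, n_high=1)
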