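"""LGN, DoG, simple-cell, double-opponent and foveal models."""

import math

import numpy as np
import pytest

from rfkit.grid import STGridSpec
from rfkit.models import (FovealParams, ReceptiveFieldSpec, dog_kernel,
                          dog_laplacian_error, double_opponent_st_kernel,
                          double_opponent_st_response, foveal_min_scale,
                          foveal_tiling, lgn_kernel, lgn_temporal_factor,
                          simple_cell_kernel)
from rfkit.spatial import (SpatialCovariance, laplacian_kernel,
                           make_spatial_covariance)
from rfkit.stgauss import GaussianTemporal


class TestLGN:
    def test_log_origin_value(self):
        # Laplacian of Gaussian at the origin: -2s/(2 pi s^3) = -1/(pi s^2)
        for s in (0.4, 1.0, 2.5):
            k = laplacian_kernel(s, moment_correct=False)
            c = k.grid.shape[0] // 2
            assert k.values[c, c] == pytest.approx(-1 / (math.pi * s ** 2),
                                                   rel=1e-12)

    def test_spatial_factor_zero_sum(self):
        for s in (0.5, 1.0, 3.0):
            assert abs(laplacian_kernel(s).values.sum()) < 1e-12

    def test_separable_composition(self):
        s, tau, n = 1.0, 4.0, 1
        k = lgn_kernel(s, tau, n, family="gaussian")
        log = laplacian_kernel(s, k.grid.spatial)
        temporal = GaussianTemporal(tau, 3.5 * math.sqrt(tau)).deriv(n)(
            k.grid.times())
        np.testing.assert_allclose(
            k.values, temporal[:, None, None] * log.values[None], atol=1e-15)

    def test_polarity_flips_sign(self):
        kp = lgn_kernel(1.0, 1.0, 0, polarity=+1, family="timecausal_phi")
        km = lgn_kernel(1.0, 1.0, 0, polarity=-1, family="timecausal_phi")
        np.testing.assert_allclose(kp.values, -km.values)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            lgn_kernel(1.0, 1.0, 0, family="nonsense")

    @pytest.mark.parametrize("family", ["timecausal_phi",
                                        "integrator_cascade"])
    def test_nonlagged_first_lobe_dominant(self, family):
        # n=1 gives the non-lagged signature: first temporal lobe largest
        t = np.linspace(0, 30, 20001)
        y = lgn_temporal_factor(1.0, 1, family, t)
        peaks = _lobe_peaks(y)
        assert len(peaks) >= 2 and peaks[0] > peaks[1]

    def test_lagged_second_lobe_dominant_cascade(self):
        # n=2 lagged signature holds for the integrator cascade
        t = np.linspace(0, 30, 20001)
        y = lgn_temporal_factor(1.0, 2, "integrator_cascade", t)
        peaks = _lobe_peaks(y)
        assert len(peaks) >= 2 and peaks[1] > peaks[0]


def _lobe_peaks(y, floor=1e-5):
    peaks, cur, amp = [], 0, 0.0
    top = np.abs(y).max()
    for v in y:
        sgn = 0 if v == 0 else (1 if v > 0 else -1)
        if sgn == 0:
            continue
        if sgn != cur:
            if cur != 0 and amp > floor * top:
                peaks.append(amp)
            cur, amp = sgn, abs(v)
        else:
            amp = max(amp, abs(v))
    if cur != 0 and amp > floor * top:
        peaks.append(amp)
    return peaks


class TestDoG:
    def test_zero_sum(self):
        assert abs(dog_kernel(1.0, 0.3).values.sum()) < 1e-12

    def test_linear_convergence_to_half_laplacian(self):
        errors = [dog_laplacian_error(1.0, ds) for ds in (0.4, 0.2, 0.1)]
        assert errors[0] > errors[1] > errors[2]
        for a, b in zip(errors, errors[1:]):
            assert 0.4 <= b / a <= 0.6  # halving ds halves the error

    def test_small_ds_limit(self):
        assert dog_laplacian_error(1.0, 1e-3) < 1e-3


class TestSimpleCell:
    def _grid(self, nt=33, n=17):
        return STGridSpec((nt, n, n), (1.0, 1.0, 1.0),
                          t0=-(nt - 1) / 2.0, kernel_grid=True)

    def test_axis_aligned_first_order_separable(self):
        spec = ReceptiveFieldSpec(orders=(1, 0), n=0, phi=0.0,
                                  cov=SpatialCovariance.from_scale(1.0),
                                  tau=2.0, family="gaussian", delta=0.0)
        k = simple_cell_kernel(spec, self._grid())
        # separates into g_x1 times a temporal Gaussian
        from rfkit.spatial import gaussian_derivative_kernel
        gx = gaussian_derivative_kernel(SpatialCovariance.from_scale(1.0),
                                        (1, 0), k.grid.spatial,
                                        moment_correct=False)
        temporal = GaussianTemporal(2.0, 0.0).value(k.grid.times())
        expected = temporal[:, None, None] * gx.values[None]
        expected -= expected.mean()  # zero-sum correction matches
        np.testing.assert_allclose(k.values, expected, atol=1e-12)

    def test_zero_sum_for_derivative_orders(self):
        for family in ("gaussian", "timecausal_phi", "integrator_cascade"):
            spec = ReceptiveFieldSpec(orders=(1, 1), n=1, phi=0.4,
                                      cov=make_spatial_covariance(4, 1, 0.4),
                                      v=(0.3, 0.0), tau=2.0, family=family)
            grid = STGridSpec((65, 21, 21), (0.25, 1, 1), t0=0.0,
                              kernel_grid=True)
            k = simple_cell_kernel(spec, grid)
            assert abs(k.values.sum()) < 1e-12

    def test_motion_adapted_kernel_matches_static_response(self):
        # response of the v-adapted kernel to a drifting pattern equals the
        # static kernel's response to the frame-0 pattern (steady state)
        from rfkit.fixtures import moving_grating
        from rfkit.stgauss import st_convolve
        from rfkit.spatial import convolve, gaussian_derivative_kernel
        v = (0.5, 0.0)
        g = moving_grating((32, 32), n_frames=41, freq=1 / 8, velocity=v)
        spec = ReceptiveFieldSpec(orders=(1, 0), n=0, phi=0.0,
                                  cov=SpatialCovariance.from_scale(2.0),
                                  v=v, tau=2.0, family="gaussian", delta=0.0)
        grid = self._grid(nt=17, n=17)
        k = simple_cell_kernel(spec, grid)
        resp = st_convolve(g, k)
        kx = gaussian_derivative_kernel(SpatialCovariance.from_scale(2.0),
                                        (1, 0), grid.spatial)
        static = convolve(g.frame(20), kx)
        inner = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(resp.values[20][inner],
                                   static.values[inner], atol=5e-3)

    def test_laplacian_spec_rejected(self):
        spec = ReceptiveFieldSpec(laplacian=True)
        with pytest.raises(ValueError):
            simple_cell_kernel(spec, self._grid())


class TestDoubleOpponentST:
    def test_achromatic_stimulus_silent(self, rng):
        gray = np.repeat(rng.uniform(0, 1, (16, 12, 12))[..., None], 3, -1)
        r1, r2 = double_opponent_st_response(gray, s=1.0, tau=1.0, n=0)
        np.testing.assert_allclose(r1, 0.0, atol=1e-12)
        np.testing.assert_allclose(r2, 0.0, atol=1e-12)

    def test_static_chromatic_with_temporal_derivative_decays(self):
        rgb = np.zeros((96, 16, 16, 3))
        rgb[..., 0] = _blob(16)[None]
        r1, _ = double_opponent_st_response(rgb, s=2.0, tau=4.0, n=1,
                                            family="gaussian")
        onset = np.abs(r1[3:20]).max()
        late = np.abs(r1[-1]).max()
        assert late < 0.05 * onset

    def test_steady_state_reduces_to_spatial_model(self):
        from rfkit.chromatic import double_opponent_response
        rgb_frame = np.zeros((16, 16, 3))
        rgb_frame[..., 0] = _blob(16)
        rgb = np.broadcast_to(rgb_frame, (96, 16, 16, 3)).copy()
        r1, _ = double_opponent_st_response(rgb, s=2.0, tau=1.0, n=0,
                                            family="integrator_cascade")
        ref1, _ = double_opponent_response(rgb_frame, s=2.0)
        inner = (slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(r1[-1][inner], ref1.values[inner],
                                   atol=2e-3 * np.abs(ref1.values).max()
                                   + 1e-12)

    def test_kernel_pair_shares_structure(self):
        k1, k2 = double_opponent_st_kernel(1.0, 1.0, 0)
        np.testing.assert_allclose(k1.values, k2.values)
        assert k1.params["channel"] == "c1"
        assert k2.params["channel"] == "c2"


def _blob(n, s=4.0):
    i2, i1 = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    return np.exp(-((i1 - c) ** 2 + (i2 - c) ** 2) / (2 * s))


class TestFoveal:
    def test_linear_law(self):
        p = FovealParams(sigma0=1.0, e0=20.0)
        assert foveal_min_scale(0.0, p) == 1.0
        assert foveal_min_scale(20.0, p) == 2.0
        assert foveal_min_scale(60.0, p) == 4.0

    def test_equal_counts_per_octave(self):
        p = FovealParams(sigma0=1.0, e0=10.0, s_max=64.0, capacity=32)
        tiling = foveal_tiling(p, field_radius=100.0)
        scales = sorted({s for _, s in tiling})
        counts = {s: sum(1 for _, sv in tiling if sv == s) for s in scales}
        assert len(set(counts.values())) == 1
        assert list(counts.values())[0] == 32

    def test_positions_respect_admissibility(self):
        p = FovealParams(sigma0=1.0, e0=10.0, s_max=64.0, capacity=16)
        for (x1, x2), s in foveal_tiling(p, field_radius=100.0):
            e = math.hypot(x1, x2)
            # a field at eccentricity e must have sigma >= sigma_min(e)
            assert math.sqrt(s) >= foveal_min_scale(e, p) - 1e-9
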