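"""Spatial kernel generation, steering, convolution and diffusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfkit.fixtures import bandlimited_noise, impulse
from rfkit.grid import GridSpec, ImageField
from rfkit.spatial import (DiffusionParams, SpatialCovariance,
                           convolve, diffusion_evolve,
                           directional_derivative_kernel,
                           gaussian_derivative_kernel, hemisphere_covariance,
                           kernel_second_moments, make_spatial_covariance,
                           steer)


class TestSpatialCovariance:
    @pytest.mark.parametrize("l1,l2,theta,expected", [
        (1.0, 1.0, 0.7, np.eye(2)),
        (2.0, 1.0, 0.0, np.diag([2.0, 1.0])),
        (2.0, 1.0, math.pi / 2, np.diag([1.0, 2.0])),
    ])
    def test_matrix_construction(self, l1, l2, theta, expected):
        cov = make_spatial_covariance(l1, l2, theta)
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-12)

    def test_swapped_eigenvalues_rotate_theta(self):
        cov = make_spatial_covariance(1.0, 2.0, 0.0)
        np.testing.assert_allclose(cov.matrix, np.diag([1.0, 2.0]),
                                   atol=1e-12)
        assert cov.lambda1 == 2.0

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            make_spatial_covariance(1.0, 0.0)

    @given(l1=st.floats(0.5, 10), ratio=st.floats(1.0, 8.0),
           theta=st.floats(0, math.pi - 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_eigendecomposition_roundtrip(self, l1, ratio, theta):
        cov = make_spatial_covariance(l1 * ratio, l1, theta)
        rec = SpatialCovariance.from_matrix(cov.matrix)
        np.testing.assert_allclose(rec.matrix, cov.matrix, atol=1e-10)

    def test_hemisphere_foreshortening(self):
        iso = hemisphere_covariance(0.0, 0.3, 2.0)
        np.testing.assert_allclose(iso.matrix, 2.0 * np.eye(2), atol=1e-12)
        tilted = hemisphere_covariance(math.pi / 3, 0.0, 1.0)
        np.testing.assert_allclose(tilted.matrix, np.diag([1.0, 0.25]),
                                   atol=1e-12)
        swapped = hemisphere_covariance(math.pi / 3, math.pi / 2, 1.0)
        np.testing.assert_allclose(swapped.matrix, np.diag([0.25, 1.0]),
                                   atol=1e-12)
        with pytest.raises(ValueError):
            hemisphere_covariance(math.pi / 2, 0.0, 1.0)


class TestGaussianKernels:
    def test_isotropic_origin_value(self):
        k = gaussian_derivative_kernel(SpatialCovariance.from_scale(1.0),
                                       (0, 0), normalize=False)
        c = k.grid.shape[0] // 2
        assert k.values[c, c] == pytest.approx(1 / (2 * math.pi), rel=1e-12)

    def test_anisotropic_origin_value(self):
        cov = SpatialCovariance.from_matrix(np.diag([2.0, 1.0]))
        k = gaussian_derivative_kernel(cov, (0, 0), normalize=False)
        c2, c1 = (s // 2 for s in k.grid.shape)
        assert k.values[c2, c1] == pytest.approx(
            1 / (2 * math.pi * math.sqrt(2)), rel=1e-12)

    def test_second_derivative_origin_value(self):
        # 1D factor: d^2/dx^2 of the unit Gaussian at 0 is (0 - s)/s^2 g(0)
        k = gaussian_derivative_kernel(SpatialCovariance.from_scale(1.0),
                                       (2, 0), moment_correct=False)
        c = k.grid.shape[0] // 2
        assert k.values[c, c] == pytest.approx(-1 / (2 * math.pi), rel=1e-12)

    def test_unit_mass_after_normalization(self):
        for s in (0.5, 1.0, 4.0):
            k = gaussian_derivative_kernel(SpatialCovariance.from_scale(s))
            assert k.mass == pytest.approx(1.0, abs=1e-12)

    def test_moment_corrected_derivatives_zero_sum(self):
        cov = make_spatial_covariance(2.0, 0.5, 0.4)
        for orders in [(1, 0), (2, 0), (1, 1), (0, 2)]:
            k = gaussian_derivative_kernel(cov, orders)
            assert abs(k.values.sum()) < 1e-12

    def test_parameter_recovery_from_second_moments(self):
        # anisotropy ratio up to 16: moments recover (lambda1, lambda2, theta)
        for l1, l2, th in [(4.0, 1.0, 0.3), (16.0, 1.0, 1.2), (8, 2, 2.6)]:
            cov = make_spatial_covariance(l1, l2, th)
            rec = kernel_second_moments(
                gaussian_derivative_kernel(cov, (0, 0)))
            assert rec.lambda1 == pytest.approx(l1, rel=0.01)
            assert rec.lambda2 == pytest.approx(l2, rel=0.01)
            assert rec.theta == pytest.approx(th, abs=0.01)

    def test_small_grid_flags_truncation(self):
        with pytest.warns(UserWarning):
            k = gaussian_derivative_kernel(
                SpatialCovariance.from_scale(4.0), (0, 0),
                GridSpec.centered(2))
        assert "truncated" in k.flags

    def test_rotational_symmetry_of_isotropic_kernel(self):
        k = gaussian_derivative_kernel(SpatialCovariance.from_scale(2.0),
                                       (0, 0))
        X2, X1 = k.grid.mesh()
        r2 = X1 ** 2 + X2 ** 2
        # all samples at equal radius agree
        for rv in np.unique(np.round(r2, 9))[:20]:
            vals = k.values[np.isclose(r2, rv)]
            assert vals.max() - vals.min() < 1e-10 * k.values.max()


class TestDirectionalDerivatives:
    def test_axis_aligned_matches_partials(self, iso_cov):
        for phi, orders in [(0.0, (1, 0)), (math.pi / 2, (0, 1))]:
            kd = directional_derivative_kernel(iso_cov, phi, 1,
                                               moment_correct=False)
            kp = gaussian_derivative_kernel(iso_cov, orders, kd.grid,
                                            moment_correct=False)
            np.testing.assert_allclose(kd.values, kp.values, atol=1e-13)

    def test_diagonal_binomial_expansion(self, iso_cov):
        kd = directional_derivative_kernel(iso_cov, math.pi / 4, 2,
                                           moment_correct=False)
        parts = {o: gaussian_derivative_kernel(iso_cov, o, kd.grid,
                                               moment_correct=False).values
                 for o in [(2, 0), (1, 1), (0, 2)]}
        expected = (0.5 * parts[(2, 0)] + parts[(1, 1)]
                    + 0.5 * parts[(0, 2)])
        np.testing.assert_allclose(kd.values, expected, atol=1e-13)

    def test_misaligned_phi_flagged(self):
        cov = make_spatial_covariance(4.0, 1.0, 0.0)
        k = directional_derivative_kernel(cov, 0.3, 1)
        assert "misaligned_phi" in k.flags
        aligned = directional_derivative_kernel(cov, math.pi / 2, 1)
        assert "misaligned_phi" not in aligned.flags


class TestSteering:
    def test_first_order_identity_and_coefficients(self, noise64, iso_cov):
        kx = gaussian_derivative_kernel(iso_cov, (1, 0))
        ky = gaussian_derivative_kernel(iso_cov, (0, 1))
        Lx = convolve(noise64, kx)
        Ly = convolve(noise64, ky)
        partials = {(1, 0): Lx, (0, 1): Ly}
        np.testing.assert_allclose(steer(partials, 0.0, 1).values, Lx.values)
        s30 = steer(partials, math.pi / 6, 1)
        np.testing.assert_allclose(
            s30.values, math.sqrt(3) / 2 * Lx.values + 0.5 * Ly.values,
            atol=1e-14)

    def test_steering_matches_rotated_kernel(self, noise64, iso_cov):
        # steering in the response domain equals filtering with the
        # directional kernel (isotropic case; exact up to convolution error)
        phi = 0.8
        partials = {o: convolve(noise64,
                                gaussian_derivative_kernel(iso_cov, o))
                    for o in [(2, 0), (1, 1), (0, 2)]}
        steered = steer(partials, phi, 2)
        kd = directional_derivative_kernel(iso_cov, phi, 2)
        direct = convolve(noise64, kd)
        np.testing.assert_allclose(steered.values, direct.values, atol=1e-10)

    def test_missing_partial_raises(self, noise64):
        with pytest.raises(ValueError):
            steer({(1, 0): noise64}, 0.1, 1)


class TestConvolve:
    def test_impulse_reproduces_kernel(self, iso_cov):
        k = gaussian_derivative_kernel(iso_cov, (0, 0))
        out = convolve(impulse((33, 33)), k)
        c = 16
        hw = k.grid.shape[0] // 2
        np.testing.assert_allclose(
            out.values[c - hw: c + hw + 1, c - hw: c + hw + 1],
            k.values, atol=1e-14)

    def test_constant_preserved_by_unit_mass_kernel(self, iso_cov):
        k = gaussian_derivative_kernel(iso_cov, (0, 0))
        img = ImageField(np.full((32, 32), 3.7))
        out = convolve(img, k, boundary="reflect")
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-12)

    def test_linearity(self, iso_cov):
        k = gaussian_derivative_kernel(iso_cov, (1, 0))
        f1 = bandlimited_noise((32, 32), seed=5)
        f2 = bandlimited_noise((32, 32), seed=6)
        lhs = convolve(ImageField(2.0 * f1.values - 3.0 * f2.values),
                       k).values
        rhs = 2.0 * convolve(f1, k).values - 3.0 * convolve(f2, k).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_direct_and_fft_routes_agree(self, noise64, iso_cov):
        k = gaussian_derivative_kernel(iso_cov, (1, 0))
        for boundary in ("reflect", "zero", "periodic"):
            a = convolve(noise64, k, boundary=boundary, route="direct")
            b = convolve(noise64, k, boundary=boundary, route="fft")
            np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_spacing_mismatch_rejected(self, noise64, iso_cov):
        k = gaussian_derivative_kernel(iso_cov, (0, 0),
                                       GridSpec.centered(8, 0.5))
        with pytest.raises(ValueError):
            convolve(noise64, k)


class TestDiffusion:
    def test_pure_transport_moves_centroid(self):
        f = np.zeros((65, 65))
        f[32, 32] = 1.0
        img = ImageField(f, GridSpec((65, 65), (0.5, 0.5)))
        params = DiffusionParams(np.zeros((2, 2)), (1.0, 0.0))
        out = diffusion_evolve(img, params, total_s=3.0, n_steps=60)
        X2, X1 = np.meshgrid((np.arange(65) - 32) * 0.5,
                             (np.arange(65) - 32) * 0.5, indexing="ij")
        w = out.values / out.values.sum()
        assert (w * X1).sum() == pytest.approx(3.0, abs=0.05)
        assert (w * X2).sum() == pytest.approx(0.0, abs=0.05)

    def test_two_half_evolutions_equal_one(self, noise64):
        params = DiffusionParams(np.eye(2))
        one = diffusion_evolve(noise64, params, 1.0, 40)
        half = diffusion_evolve(noise64, params, 0.5, 20)
        two = diffusion_evolve(half, params, 0.5, 20)
        np.testing.assert_allclose(two.values, one.values, atol=1e-10)

    def test_unstable_step_refused_with_requirement(self, noise64):
        params = DiffusionParams(np.eye(2))
        with pytest.raises(ValueError, match="n_steps >="):
            diffusion_evolve(noise64, params, 4.0, 2)
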