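"""Time-causal kernels: phi, integrator cascades, recursive filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfkit.grid import STGridSpec
from rfkit.spatial import SpatialCovariance
from rfkit.timecausal import (IntegratorCascade, compose_truncated_exponentials,
                              composed_exp_analytic, make_scale_profile,
                              phi_derivative, phi_kernel, phi_mass, phi_mode,
                              recursive_smooth, timecausal_st_kernel,
                              transformed_temporal_derivative,
                              truncated_exp_kernel)


class TestPhi:
    def test_causality(self):
        t = np.linspace(-5, 5, 101)
        vals = phi_kernel(1.0, t)
        assert np.all(vals[t <= 0] == 0.0)
        assert np.all(vals[t > 0] > 0.0)

    def test_mode_at_tau_squared_over_three(self):
        # d/dt log phi = -3/(2t) + tau^2/(2t^2) vanishes at t = tau^2/3
        for tau in (0.5, 1.0, 3.0):
            t = np.linspace(1e-4, 5 * tau ** 2, 200001)
            t_peak = t[np.argmax(phi_kernel(tau, t))]
            assert t_peak == pytest.approx(tau ** 2 / 3, rel=1e-3)
            assert phi_mode(tau) == pytest.approx(tau ** 2 / 3)

    def test_unit_mass(self):
        for tau in (0.5, 2.0):
            assert phi_mass(tau) == pytest.approx(1.0, abs=1e-3)

    def test_analytic_derivative_matches_finite_difference(self):
        t = np.arange(0.1, 10, 0.001)
        ana = phi_derivative(1.0, t, 1)
        num = np.gradient(phi_kernel(1.0, t), t, edge_order=2)
        assert np.abs(ana - num).max() < 5e-4 * np.abs(ana).max()

    def test_first_transformed_derivative_single_sign_change(self):
        # d/dt phi vanishes only at the mode, so t^kappa d/dt phi changes
        # sign exactly once on (0, 50 tau^2]
        tau = 1.0
        t = np.arange(1e-3, 50 * tau ** 2, 1e-3)
        d = transformed_temporal_derivative(phi_kernel(tau, t), t, 1, 0.5)
        signs = np.sign(d[np.abs(d) > 1e-12 * np.abs(d).max()])
        changes = int(np.sum(signs[1:] != signs[:-1]))
        assert changes == 1


class TestTruncatedExponentials:
    def test_value_mean_variance(self):
        mu = 2.0
        t = np.arange(0, 200, 0.001)
        k = truncated_exp_kernel(mu, t)
        assert k[0] == pytest.approx(1 / mu)
        dt = 0.001
        mass = k.sum() * dt
        mean = (t * k).sum() * dt / mass
        var = ((t - mean) ** 2 * k).sum() * dt / mass
        assert mass == pytest.approx(1.0, abs=1e-3)
        assert mean == pytest.approx(mu, rel=1e-3)
        assert var == pytest.approx(mu ** 2, rel=1e-2)

    def test_composition_moments(self):
        t = np.arange(0, 60, 0.002)
        k = compose_truncated_exponentials((1.0, 2.0), t)
        dt = 0.002
        mean = (t * k).sum() * dt
        var = ((t - mean) ** 2 * k).sum() * dt
        assert mean == pytest.approx(3.0, abs=0.01)   # sum mu_i
        assert var == pytest.approx(5.0, abs=0.05)    # sum mu_i^2

    def test_single_mu_reduces_to_truncated_exp(self):
        t = np.arange(0, 30, 0.01)
        np.testing.assert_allclose(
            compose_truncated_exponentials((1.5,), t),
            truncated_exp_kernel(1.5, t, normalize=True))

    def test_erlang2_analytic_oracle(self):
        # two equal stages mu = 1: density t e^{-t}
        t = np.arange(0, 40, 5e-4)
        k = compose_truncated_exponentials((1.0, 1.0), t)
        expected = t * np.exp(-t)
        assert np.abs(k - expected).max() < 1e-3

    def test_partial_fraction_closed_form(self):
        t = np.arange(0, 60, 0.005)
        mus = (1.0, 2.0, 4.0)
        num = compose_truncated_exponentials(mus, t)
        ana = composed_exp_analytic(mus, t)
        assert np.abs(num - ana).sum() * 0.005 < 5e-3


class TestScaleProfile:
    def test_geometric_example(self):
        prof = make_scale_profile(1.0, 64.0, 7)
        assert prof.gamma == pytest.approx(2.0)
        np.testing.assert_allclose(prof.tau_levels,
                                   [2.0 ** k for k in range(7)])
        np.testing.assert_allclose(prof.mu,
                                   [2.0 ** (k / 2) for k in range(6)])

    def test_two_level_profile(self):
        eps = 1e-3
        prof = make_scale_profile(1.0, 1.0 + eps, 2)
        assert len(prof.mu) == 1
        assert prof.mu[0] == pytest.approx(math.sqrt(eps), rel=1e-9)

    def test_cumulative_variances_reproduce_levels(self):
        prof = make_scale_profile(0.5, 40.0, 5)
        acc = prof.tau_min + np.cumsum(np.square(prof.mu))
        np.testing.assert_allclose(acc, prof.tau_levels[1:], rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_scale_profile(1.0, 2.0, 1)
        with pytest.raises(ValueError):
            make_scale_profile(2.0, 1.0, 3)


class TestRecursiveSmoothing:
    def test_constant_fixed_point(self):
        prof = make_scale_profile(1.0, 16.0, 5)
        sig = np.full(4000, 2.5)
        levels = recursive_smooth(sig, prof, dt=0.05)
        for lv in levels:
            assert lv[-1] == pytest.approx(2.5, rel=1e-3)

    def test_impulse_response_matches_composed_kernel(self):
        prof = make_scale_profile(1.0, 64.0, 7)
        dt = min(prof.mu) / 20
        t = np.arange(0, 45, dt)
        imp = np.zeros_like(t)
        imp[0] = 1 / dt
        rec = recursive_smooth(imp, prof, dt)[-1]
        comp = compose_truncated_exponentials(prof.mu, t)
        rel_l1 = np.abs(rec - comp).sum() / np.abs(comp).sum()
        assert rel_l1 < 0.02

    def test_causality_no_lookahead(self, rng):
        prof = make_scale_profile(1.0, 8.0, 4)
        sig = rng.standard_normal(200)
        full = recursive_smooth(sig, prof, dt=0.3)[-1]
        truncated = recursive_smooth(sig[:120], prof, dt=0.3)[-1]
        np.testing.assert_allclose(full[:120], truncated)

    def test_streaming_matches_batch(self, rng):
        prof = make_scale_profile(1.0, 8.0, 4)
        frames = rng.standard_normal((50, 4, 4))
        batch = recursive_smooth(frames, prof, dt=0.2)
        cascade = IntegratorCascade(prof.mu, 0.2)
        for n in range(50):
            levels = cascade.step(frames[n])
        np.testing.assert_allclose(levels[-1], batch[-1][-1])

    @given(c=st.floats(-5, 5), dt=st.floats(0.01, 2.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_backward_euler_unconditionally_bounded(self, c, dt):
        casc = IntegratorCascade([0.5, 1.0], dt)
        out = None
        for _ in range(50):
            out = casc.step(np.array([c]))
        assert abs(out[-1][0]) <= abs(c) + 1e-12


class TestTransformedDerivative:
    def test_kappa_zero_is_plain_difference(self, rng):
        t = np.arange(0, 10, 0.01)
        y = np.sin(t)
        d = transformed_temporal_derivative(y, t, 1, kappa=0.0)
        np.testing.assert_allclose(d[5:-5], np.cos(t)[5:-5], atol=1e-3)

    def test_constant_maps_to_zero(self):
        t = np.arange(0, 5, 0.01)
        d = transformed_temporal_derivative(np.ones_like(t), t, 1, 0.5)
        np.testing.assert_allclose(d[1:-1], 0.0, atol=1e-12)


class TestTimeCausalSTKernel:
    def _grid(self, nt=65, n=17, dt=0.25):
        return STGridSpec((nt, n, n), (dt, 1.0, 1.0), t0=0.0,
                          kernel_grid=True)

    def test_zero_velocity_separable(self):
        k = timecausal_st_kernel(SpatialCovariance.from_scale(1.0),
                                 (0.0, 0.0), 1.5, self._grid())
        spatial = k.values.sum(axis=0)
        temporal = k.values.sum(axis=(1, 2))
        outer = temporal[:, None, None] * spatial[None] / k.values.sum()
        np.testing.assert_allclose(k.values, outer, atol=1e-12)

    def test_causality(self):
        grid = STGridSpec((33, 9, 9), (0.5, 1, 1), t0=-4.0, kernel_grid=True)
        k = timecausal_st_kernel(SpatialCovariance.from_scale(1.0),
                                 (0.5, 0.0), 1.0, grid)
        times = grid.times()
        assert np.all(k.values[times <= 0] == 0.0)

    def test_unit_mass(self):
        # generous temporal horizon: phi's heavy tail converges slowly
        grid = self._grid(nt=4001, n=13, dt=0.05)
        k = timecausal_st_kernel(SpatialCovariance.from_scale(1.0),
                                 (0.0, 0.0), 0.8, grid)
        assert k.mass == pytest.approx(1.0, abs=1e-3)

    def test_cascade_family(self):
        k = timecausal_st_kernel(SpatialCovariance.from_scale(1.0),
                                 (0.0, 0.0), 1.0, self._grid(),
                                 temporal_family="cascade",
                                 mus=(0.5, 1.0, 2.0))
        assert k.mass == pytest.approx(1.0, abs=1e-2)
        with pytest.raises(ValueError):
            timecausal_st_kernel(SpatialCovariance.from_scale(1.0),
                                 (0, 0), 1.0, self._grid(),
                                 temporal_family="cascade")
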