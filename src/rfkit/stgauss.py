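"""Non-causal Gaussian spatio-temporal kernels and Galilean algebra.

The Gaussian spatio-temporal receptive field factorizes as

    h(x, t; Sigma, tau, v, delta) = g(x - v t; Sigma) * gbar(t; tau, delta)

where g is the (affine) spatial Gaussian, gbar a 1D Gaussian over time with
variance tau and delay delta, and v the image velocity.  The equivalent
3x3 space-time covariance is G_v diag(Sigma, tau) G_v^T with the Galilean
shear G_v = [[1,0,v1],[0,1,v2],[0,0,1]].

Derivative kernels are exact analytic samples.  They are represented
internally as sums of terms  c * (D^alpha g)(x - v t) * T^(n)(t):  spatial
derivatives act on the spatial factor in the co-moving frame, the
velocity-adapted temporal derivative  d/dtbar = v.grad_x + d/dt  acts on the
temporal factor alone (the transport parts cancel), and the plain d/dt
expands by the product rule into spatial terms weighted by -v plus a
temporal-derivative term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import ndimage

from scipy.signal import fftconvolve

from .grid import ImageStack, STGridSpec, STKernelGrid
from .spatial import (DerivativeSpec, SpatialCovariance,
                      gaussian_prefactor_poly, _evaluate_gaussian)

__all__ = [
    "Velocity",
    "STParams",
    "STDerivativeSpec",
    "GaussianTemporal",
    "galilean_matrix",
    "transform_covariance_galilean",
    "st_covariance",
    "galilean_warp",
    "st_gaussian_kernel",
    "st_derivative_kernel",
    "evaluate_st_terms",
]

Velocity = Tuple[float, float]


@dataclass(frozen=True)
class STParams:
    """Spatio-temporal Gaussian parameters.

    ``tau`` is the temporal variance (frame^2), ``v`` the image velocity in
    pixels/frame, ``delta`` the temporal delay in frames (default 3.5
    sqrt(tau), which leaves < 1e-3 of the non-causal kernel's mass at t<0).
    """

    cov: SpatialCovariance
    tau: float
    v: Velocity = (0.0, 0.0)
    delta: float | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delta is None:
            object.__setattr__(self, "delta", 3.5 * math.sqrt(self.tau))

    @property
    def covariance3(self) -> np.ndarray:
        return st_covariance(self.cov, self.tau, self.v)


@dataclass(frozen=True)
class STDerivativeSpec:
    spatial: DerivativeSpec | tuple = (0, 0)
    n: int = 0
    velocity_adapted: bool = True

    def __post_init__(self):
        sp = self.spatial
        if not isinstance(sp, DerivativeSpec):
            sp = DerivativeSpec(orders=tuple(sp))
        object.__setattr__(self, "spatial", sp)
        if self.n < 0 or self.n > 4:
            raise ValueError("temporal order must lie in [0, 4]")


def galilean_matrix(v: Velocity) -> np.ndarray:
    return np.array([[1.0, 0.0, v[0]],
                     [0.0, 1.0, v[1]],
                     [0.0, 0.0, 1.0]])


def transform_covariance_galilean(sigma3: np.ndarray,
                                  v: Velocity) -> np.ndarray:
    """Sigma' = G_v Sigma G_v^T."""
    S = np.asarray(sigma3, dtype=float)
    if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("expected a symmetric 3x3 matrix")
    G = galilean_matrix(v)
    return G @ S @ G.T


def st_covariance(cov: SpatialCovariance, tau: float,
                  v: Velocity = (0.0, 0.0)) -> np.ndarray:
    """3x3 covariance G_v diag(Sigma, tau) G_v^T of the factorized kernel."""
    base = np.zeros((3, 3))
    base[:2, :2] = cov.matrix
    base[2, 2] = tau
    return transform_covariance_galilean(base, v)


def galilean_warp(stack: ImageStack, v: Velocity,
                  interpolation: str = "bilinear",
                  boundary: str = "reflect") -> ImageStack:
    """Warp f'(x, t) = f(x - v t, t): each frame shifts by v * t.

    Integer per-frame shifts are exact; fractional shifts use bilinear
    (default) or cubic-spline interpolation.
    """
    order = {"bilinear": 1, "spline": 3}[interpolation]
    mode = {"reflect": "reflect", "zero": "constant",
            "periodic": "grid-wrap"}[boundary]
    dt = stack.grid.dt
    h2, h1 = stack.grid.spacing[1], stack.grid.spacing[2]
    out = np.empty_like(stack.values)
    for n in range(stack.values.shape[0]):
        t = stack.grid.t0 + n * dt
        shift = (v[1] * t / h2, v[0] * t / h1)  # (axis x2, axis x1)
        out[n] = ndimage.shift(stack.values[n], shift, order=order,
                               mode=mode, prefilter=(order > 1))
    return ImageStack(out, stack.grid, tag=stack.tag)


# ---------------------------------------------------------------------------
# temporal factors

class GaussianTemporal:
    """1D Gaussian over time with variance tau and delay delta."""

    causal = False

    def __init__(self, tau: float, delta: float = 0.0):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.tau = tau
        self.delta = delta

    def deriv(self, n: int):
        # prefactor polynomial recursion: p <- p' - p (t - delta)/tau
        p = np.array([1.0])
        lin = np.array([-self.delta / self.tau, 1.0 / self.tau])
        for _ in range(n):
            p = npoly.polysub(npoly.polyder(p), npoly.polymul(p, lin))
        tau, delta = self.tau, self.delta

        def f(t):
            t = np.asarray(t, dtype=float)
            g = np.exp(-(t - delta) ** 2 / (2 * tau)) \
                / math.sqrt(2 * math.pi * tau)
            return npoly.polyval(t, p) * g

        return f

    def value(self, t):
        return self.deriv(0)(t)


# ---------------------------------------------------------------------------
# term algebra

@dataclass
class STTerm:
    coeff: float
    spatial_dirs: tuple            # sequence of (a1, a2) direction pairs
    temporal_order: int


def _apply_spatial_dir(terms, a1: float, a2: float):
    return [STTerm(t.coeff, t.spatial_dirs + ((a1, a2),), t.temporal_order)
            for t in terms]


def _apply_adapted_dt(terms):
    return [STTerm(t.coeff, t.spatial_dirs, t.temporal_order + 1)
            for t in terms]


def _apply_plain_dt(terms, v: Velocity):
    out = []
    for t in terms:
        if v[0] != 0:
            out.append(STTerm(-v[0] * t.coeff,
                              t.spatial_dirs + ((1.0, 0.0),),
                              t.temporal_order))
        if v[1] != 0:
            out.append(STTerm(-v[1] * t.coeff,
                              t.spatial_dirs + ((0.0, 1.0),),
                              t.temporal_order))
        out.append(STTerm(t.coeff, t.spatial_dirs, t.temporal_order + 1))
    return out


def evaluate_st_terms(terms: Sequence[STTerm], cov: SpatialCovariance,
                      v: Velocity, temporal, grid: STGridSpec) -> np.ndarray:
    """Evaluate sum_i c_i (D^dirs_i g)(x - v t; Sigma) T^(n_i)(t) on a grid."""
    times = grid.times()
    x2, x1 = grid.spatial.axes()
    X2, X1 = np.meshgrid(x2, x1, indexing="ij")
    out = np.zeros(grid.shape)
    # group terms by spatial derivative signature to reuse polynomials
    for term in terms:
        P = (gaussian_prefactor_poly(cov, list(term.spatial_dirs))
             if term.spatial_dirs else None)
        tvals = temporal.deriv(term.temporal_order)(times)
        for i, t in enumerate(times):
            if tvals[i] == 0.0:
                continue
            sp = _evaluate_gaussian(cov, X1 - v[0] * t, X2 - v[1] * t, P)
            out[i] += term.coeff * tvals[i] * sp
    return out


def _check_temporal_support(params: STParams, grid: STGridSpec):
    times = grid.times()
    need_lo = params.delta - 4 * math.sqrt(params.tau)
    need_hi = params.delta + 4 * math.sqrt(params.tau)
    if times[0] > need_lo + 1e-9 or times[-1] < need_hi - 1e-9:
        warnings.warn("temporal grid does not cover delta +- 4 sqrt(tau); "
                      "kernel mass may be lost", stacklevel=3)
        return ("temporal_truncation",)
    return ()


def default_st_grid(params: STParams, spacing=(1.0, 1.0, 1.0),
                    order: int = 0) -> STGridSpec:
    dt, h2, h1 = spacing
    hw = max(1, math.ceil((4 + order) * math.sqrt(params.cov.lambda1)
                          / min(h1, h2)))
    # spatial support must also track the motion over the temporal window
    t_hi = params.delta + 4 * math.sqrt(params.tau)
    hw += math.ceil(max(abs(params.v[0]), abs(params.v[1])) * t_hi)
    nt = max(3, math.ceil(2 * t_hi / dt) + 1)
    t0 = params.delta - (nt - 1) / 2 * dt
    n = 2 * hw + 1
    return STGridSpec((nt, n, n), (dt, h2, h1), t0=t0, kernel_grid=True)


_ST_PAD = {"reflect": "symmetric", "zero": "constant", "periodic": "wrap"}


def st_convolve(stack: ImageStack, kernel: STKernelGrid,
                boundary: str = "reflect") -> ImageStack:
    """3D convolution of a stack with a spatio-temporal kernel.

    The kernel's grid center (odd sample counts) is taken as its origin, so
    a kernel with temporal delay delta built on a time axis centered at
    delta produces an output delayed by delta.  Boundary handling pads the
    stack on all axes (including time) with the chosen policy.
    """
    kv = kernel.values * kernel.grid.cell_volume
    if any(s % 2 == 0 for s in kv.shape):
        raise ValueError("st_convolve requires odd kernel sample counts")
    pads = tuple(s // 2 for s in kv.shape)
    padded = np.pad(stack.values, tuple((p, p) for p in pads),
                    mode=_ST_PAD[boundary])
    full = fftconvolve(padded, kv, mode="same")
    sl = tuple(slice(p, p + n) for p, n in zip(pads, stack.values.shape))
    return ImageStack(full[sl], stack.grid, tag="smoothed")


def st_gaussian_kernel(params: STParams,
                       grid: STGridSpec | None = None,
                       normalize: bool = True) -> STKernelGrid:
    """Zero-order kernel g(x - v t; Sigma) gbar(t; tau, delta)."""
    if grid is None:
        grid = default_st_grid(params)
    flags = _check_temporal_support(params, grid)
    temporal = GaussianTemporal(params.tau, params.delta)
    terms = [STTerm(1.0, (), 0)]
    values = evaluate_st_terms(terms, params.cov, params.v, temporal, grid)
    norm = "none"
    if normalize:
        values = values / (values.sum() * grid.cell_volume)
        norm = "unit_mass"
    return STKernelGrid(values, grid, params=dict(params=params, orders=None),
                        normalization=norm, flags=flags)


def st_derivative_kernel(params: STParams, spec: STDerivativeSpec,
                         grid: STGridSpec | None = None,
                         moment_correct: bool = True) -> STKernelGrid:
    """Spatio-temporal derivative kernel of the Gaussian family.

    Spatial partial derivatives act in the co-moving frame; the temporal
    derivative is either the velocity-adapted d/dtbar = v.grad + d/dt
    (default) or the plain d/dt expanded by the product rule.
    """
    total = spec.spatial.total_order + spec.n
    if grid is None:
        grid = default_st_grid(params, order=total)
    flags = _check_temporal_support(params, grid)
    terms = [STTerm(1.0, (), 0)]
    if spec.spatial.orders is not None:
        a1, a2 = spec.spatial.orders
        for _ in range(a1):
            terms = _apply_spatial_dir(terms, 1.0, 0.0)
        for _ in range(a2):
            terms = _apply_spatial_dir(terms, 0.0, 1.0)
    else:
        c, s = math.cos(spec.spatial.phi), math.sin(spec.spatial.phi)
        for _ in range(spec.spatial.m):
            terms = _apply_spatial_dir(terms, c, s)
    for _ in range(spec.n):
        if spec.velocity_adapted:
            terms = _apply_adapted_dt(terms)
        else:
            terms = _apply_plain_dt(terms, params.v)
    temporal = GaussianTemporal(params.tau, params.delta)
    values = evaluate_st_terms(terms, params.cov, params.v, temporal, grid)
    norm = "none"
    if total >= 1 and moment_correct:
        values = values - values.mean()
        norm = "zero_sum"
    elif total == 0:
        values = values / (values.sum() * grid.cell_volume)
        norm = "unit_mass"
    return STKernelGrid(values, grid,
                        params=dict(params=params, spec=spec),
                        normalization=norm, flags=flags)
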