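"""Idealized biological receptive-field models.

Assembles the kernel primitives into the standard model cells:

* LGN center-surround units: +-(Laplacian of Gaussian) over space times a
  temporal smoothing kernel differentiated n times with the transformed
  temporal derivative d/dt' = t^kappa d/dt (n=1 gives the "non-lagged",
  n=2 the "lagged" temporal signature for time-causal kernels);
* a difference-of-Gaussians (DoG) approximation of the LoG, exact in the
  limit of vanishing scale increment;
* V1 simple cells: oriented directional derivatives of an elongated affine
  Gaussian in a moving frame, times a temporal derivative kernel;
* double-opponent cells: the LGN spatio-temporal operator routed through the
  color-opponent matrix;
* a foveal model in which the minimum receptive-field size grows linearly
  with eccentricity and each scale octave holds the same number of fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .chromatic import OPPONENT_MATRIX
from .grid import GridSpec, KernelGrid, STGridSpec, STKernelGrid
from .spatial import (SpatialCovariance, gaussian_derivative_kernel,
                      laplacian_kernel, default_kernel_grid)
from .stgauss import GaussianTemporal, STTerm, evaluate_st_terms
from .timecausal import (PhiTemporal, compose_truncated_exponentials,
                         make_scale_profile, transformed_temporal_derivative)

__all__ = [
    "ReceptiveFieldSpec",
    "FovealParams",
    "TEMPORAL_FAMILIES",
    "lgn_temporal_factor",
    "lgn_kernel",
    "dog_kernel",
    "dog_laplacian_error",
    "simple_cell_kernel",
    "double_opponent_st_kernel",
    "double_opponent_st_response",
    "foveal_min_scale",
    "foveal_tiling",
    "logpolar_resample",
]

TEMPORAL_FAMILIES = ("gaussian", "timecausal_phi", "integrator_cascade")


@dataclass(frozen=True)
class ReceptiveFieldSpec:
    """Full parameterization of a model cell.

    Exactly one of ``orders`` (directional orders (m1, m2) along phi and
    phi+pi/2) or ``laplacian`` must be set.  ``tau`` follows the family's
    unit convention: variance (frame^2) for 'gaussian' and
    'integrator_cascade', sqrt-time units for 'timecausal_phi'.
    """

    polarity: int = +1
    orders: Tuple[int, int] | None = None
    laplacian: bool = False
    n: int = 0
    phi: float = 0.0
    cov: SpatialCovariance = None
    v: Tuple[float, float] = (0.0, 0.0)
    tau: float = 1.0
    family: str = "integrator_cascade"
    kappa: float = 0.5
    delta: float | None = None  # gaussian family only

    def __post_init__(self):
        if (self.orders is None) == (not self.laplacian):
            raise ValueError("set exactly one of orders / laplacian")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +-1")
        if self.family not in TEMPORAL_FAMILIES:
            raise ValueError(f"unknown temporal family {self.family!r}")
        if self.cov is None:
            object.__setattr__(self, "cov", SpatialCovariance.from_scale(1.0))
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _cascade_mus(tau: float, K: int = 7, ratio: float = 64.0):
    """Default geometric cascade accumulating temporal variance tau."""
    return make_scale_profile(tau / ratio, tau, K).mu


def lgn_temporal_factor(tau: float, n: int, family: str,
                        t_grid: np.ndarray, kappa: float = 0.5,
                        delta: float | None = None,
                        mus: Sequence[float] | None = None) -> np.ndarray:
    """Temporal part of the LGN model: d/dt'^n of the smoothing kernel."""
    t = np.asarray(t_grid, dtype=float)
    if family == "gaussian":
        if delta is None:
            delta = 3.5 * math.sqrt(tau)
        return GaussianTemporal(tau, delta).deriv(n)(t)
    if family == "timecausal_phi":
        base = PhiTemporal(tau).value(t)
    elif family == "integrator_cascade":
        if mus is None:
            mus = _cascade_mus(tau)
        base = compose_truncated_exponentials(mus, t)
        base = np.where(t >= 0, base, 0.0)
    else:
        raise ValueError(f"unknown temporal family {family!r}")
    if n == 0:
        return base
    return transformed_temporal_derivative(base, t, order=n, kappa=kappa)


def lgn_kernel(s: float, tau: float, n: int, polarity: int = +1,
               family: str = "integrator_cascade",
               grid: STGridSpec | None = None, kappa: float = 0.5,
               delta: float | None = None,
               mus: Sequence[float] | None = None) -> STKernelGrid:
    """LGN model: +-(d_x1x1 + d_x2x2) g(x; s) * d/dt'^n h(t; tau).

    Space-time separable by construction: the returned values are the outer
    product of the spatial LoG factor and the temporal factor.
    """
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +-1")
    if family not in TEMPORAL_FAMILIES:
        raise ValueError(f"unknown temporal family {family!r}")
    if grid is None:
        sp = default_kernel_grid(SpatialCovariance.from_scale(s), 2)
        if family == "gaussian":
            d = 3.5 * math.sqrt(tau) if delta is None else delta
            T = d + 4 * math.sqrt(tau)
        elif family == "timecausal_phi":
            T = 20.0 * tau ** 2 / 3.0
        else:
            T = 10.0 * math.sqrt(tau)
        nt = 129
        grid = STGridSpec((nt,) + tuple(sp.shape),
                          (T / (nt - 1), *sp.spacing), t0=0.0,
                          kernel_grid=True)
    log = laplacian_kernel(s, grid.spatial)
    tvals = lgn_temporal_factor(tau, n, family, grid.times(), kappa=kappa,
                                delta=delta, mus=mus)
    values = polarity * tvals[:, None, None] * log.values[None, :, :]
    return STKernelGrid(values, grid,
                        params=dict(s=s, tau=tau, n=n, polarity=polarity,
                                    family=family, kappa=kappa),
                        normalization="zero_sum")


def dog_kernel(s: float, delta_s: float,
               grid: GridSpec | None = None) -> KernelGrid:
    """Difference-of-Gaussians (g(x; s+ds) - g(x; s)) / ds.

    Approximates the scale derivative d_s g = 1/2 Laplacian(g); the error is
    O(ds).  Sums to 0 exactly (difference of two unit-mass kernels).
    """
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    if grid is None:
        grid = default_kernel_grid(SpatialCovariance.from_scale(s + delta_s),
                                   2)
    g1 = gaussian_derivative_kernel(SpatialCovariance.from_scale(s + delta_s),
                                    (0, 0), grid)
    g0 = gaussian_derivative_kernel(SpatialCovariance.from_scale(s),
                                    (0, 0), grid)
    values = (g1.values - g0.values) / delta_s
    return KernelGrid(values, grid,
                      params=dict(s=s, delta_s=delta_s, op="dog"),
                      normalization="zero_sum")


def dog_laplacian_error(s: float, delta_s: float,
                        grid: GridSpec | None = None) -> float:
    """Relative L2 distance between the DoG/ds and 1/2 Laplacian(g(.; s))."""
    if grid is None:
        grid = default_kernel_grid(SpatialCovariance.from_scale(s + delta_s),
                                   2)
    dog = dog_kernel(s, delta_s, grid)
    target = 0.5 * laplacian_kernel(s, grid, moment_correct=False).values
    return float(np.linalg.norm(dog.values - target)
                 / np.linalg.norm(target))


class _SampledTemporal:
    """Temporal factor known only by samples; derivatives by differences."""

    def __init__(self, times: np.ndarray, values: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)

    def deriv(self, n: int):
        y = self.values
        dt = self.times[1] - self.times[0]
        for _ in range(n):
            y = np.gradient(y, dt)

        def f(t):
            return np.interp(t, self.times, y)

        return f


def simple_cell_kernel(spec: ReceptiveFieldSpec,
                       grid: STGridSpec) -> STKernelGrid:
    """V1 simple-cell model:

    (cos phi d1 + sin phi d2)^m1 (sin phi d1 - cos phi d2)^m2
    (v . grad + d/dt)^n  g(x - v t; Sigma) h(t; tau).

    The velocity-adapted temporal derivative differentiates the temporal
    factor alone (the transport terms cancel in the moving frame).
    """
    if spec.laplacian:
        raise ValueError("use lgn_kernel for the Laplacian (center-surround) "
                         "model")
    m1, m2 = spec.orders
    c, s_ = math.cos(spec.phi), math.sin(spec.phi)
    dirs = [(c, s_)] * m1 + [(s_, -c)] * m2
    terms = [STTerm(float(spec.polarity), tuple(dirs), spec.n)]
    times = grid.times()
    if spec.family == "gaussian":
        delta = spec.delta if spec.delta is not None \
            else 3.5 * math.sqrt(spec.tau)
        temporal = GaussianTemporal(spec.tau, delta)
    elif spec.family == "timecausal_phi":
        temporal = PhiTemporal(spec.tau)
    else:
        base = compose_truncated_exponentials(_cascade_mus(spec.tau), times)
        base = np.where(times >= 0, base, 0.0)
        temporal = _SampledTemporal(times, base)
    values = evaluate_st_terms(terms, spec.cov, spec.v, temporal, grid)
    norm = "none"
    if m1 + m2 + spec.n >= 1:
        values = values - values.mean()
        norm = "zero_sum"
    else:
        total = values.sum() * grid.cell_volume
        if total > 0:
            values = values / total
            norm = "unit_mass"
    return STKernelGrid(values, grid, params=dict(spec=spec),
                        normalization=norm)


def double_opponent_st_kernel(s: float, tau: float, n: int,
                              polarity: int = +1,
                              family: str = "integrator_cascade",
                              grid: STGridSpec | None = None,
                              kappa: float = 0.5):
    """Spatio-chrom-temporal double-opponent model.

    The LGN spatio-temporal operator applied through the opponent matrix:
    one kernel per opponent channel (c1 = red/green, c2 = yellow/blue);
    the two kernels share the +-LoG x temporal structure.
    """
    k = lgn_kernel(s, tau, n, polarity, family, grid, kappa=kappa)
    k2 = STKernelGrid(k.values.copy(), k.grid, params=dict(k.params),
                      normalization=k.normalization)
    k.params["channel"] = "c1"
    k2.params["channel"] = "c2"
    return k, k2


def double_opponent_st_response(rgb_stack: np.ndarray, s: float, tau: float,
                                n: int, polarity: int = +1,
                                family: str = "integrator_cascade",
                                grid: STGridSpec | None = None,
                                kappa: float = 0.5, dt: float = 1.0):
    """Apply the double-opponent ST kernels to an (nt, n2, n1, 3) RGB stack.

    Returns the (c1, c2) response stacks, convolved over space and causally
    over time (temporal kernel support lies in t >= 0).  ``dt`` is the
    stack's frame spacing; the default kernel grid samples the temporal
    factor at the same spacing.
    """
    from scipy.signal import fftconvolve
    if grid is None:
        sp = default_kernel_grid(SpatialCovariance.from_scale(s), 2)
        nt = 49
        grid = STGridSpec((nt,) + tuple(sp.shape), (dt, *sp.spacing),
                          t0=0.0, kernel_grid=True)
    k1, _ = double_opponent_st_kernel(s, tau, n, polarity, family, grid,
                                      kappa)
    arr = np.asarray(rgb_stack, dtype=float)
    opp = arr @ OPPONENT_MATRIX.T
    kv = k1.values * k1.grid.cell_volume
    out = []
    for ch in (1, 2):
        full = fftconvolve(opp[..., ch], kv, mode="full")
        nt, n2, n1 = arr.shape[:3]
        r2, r1 = kv.shape[1] // 2, kv.shape[2] // 2
        out.append(full[: nt, r2: r2 + n2, r1: r1 + n1])
    return out[0], out[1]


# ---------------------------------------------------------------------------
# foveal model

@dataclass(frozen=True)
class FovealParams:
    """sigma0: minimum RF std dev at the fovea (px); e0: eccentricity
    constant (px); s_max: coarsest scale (variance, px^2); capacity:
    receptive fields per scale octave."""

    sigma0: float = 1.0
    e0: float = 20.0
    s_max: float = 256.0
    capacity: int = 64

    def __post_init__(self):
        if min(self.sigma0, self.e0, self.s_max) <= 0 or self.capacity < 1:
            raise ValueError("all foveal parameters must be positive")


def foveal_min_scale(eccentricity: float, params: FovealParams) -> float:
    """sigma_min(e) = sigma0 (1 + e/e0): linear growth with eccentricity."""
    if eccentricity < 0:
        raise ValueError("eccentricity must be nonnegative")
    return params.sigma0 * (1.0 + eccentricity / params.e0)


def foveal_tiling(params: FovealParams,
                  field_radius: float) -> List[Tuple[Tuple[float, float],
                                                     float]]:
    """Place receptive fields with equal counts per scale octave.

    Scale octaves run sigma_j = sigma0 2^j up to sqrt(s_max).  A field of
    size sigma_j is admissible out to the eccentricity e_j where
    sigma_min(e_j) = sigma_j; within that disk, ``capacity`` positions are
    laid out on a sunflower (Fermat spiral) pattern, whose spacing scales
    with the disk radius and hence with sigma_j ~ sqrt(s).
    Returns a list of ((x1, x2), s) pairs.
    """
    out = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    j = 0
    while params.sigma0 * 2 ** j <= math.sqrt(params.s_max) + 1e-12:
        sigma_j = params.sigma0 * 2 ** j
        e_j = params.e0 * (sigma_j / params.sigma0 - 1.0)
        r_j = min(e_j, field_radius)  # finest octave collapses to the fovea
        for i in range(params.capacity):
            r = r_j * math.sqrt((i + 0.5) / params.capacity)
            a = i * golden
            out.append(((r * math.cos(a), r * math.sin(a)), sigma_j ** 2))
        j += 1
    return out


def logpolar_resample(image: np.ndarray, n_r: int = 64, n_theta: int = 64,
                      r_min: float = 1.0) -> np.ndarray:
    """Log-polar resampling about the image center (utility).

    Rows are log-radius (from r_min to the inscribed radius), columns polar
    angle; bilinear interpolation.
    """
    from scipy.ndimage import map_coordinates
    img = np.asarray(image, dtype=float)
    c2, c1 = (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
    r_max = min(c1, c2)
    logr = np.linspace(math.log(r_min), math.log(r_max), n_r)
    theta = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    R, TH = np.meshgrid(np.exp(logr), theta, indexing="ij")
    coords = np.stack([c2 + R * np.sin(TH), c1 + R * np.cos(TH)])
    return map_coordinates(img, coords, order=1, mode="reflect")
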