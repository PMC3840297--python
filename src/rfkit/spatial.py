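"""Isotropic and affine Gaussian kernels, derivatives, convolution, diffusion.

The spatial smoothing kernel is the (possibly anisotropic) Gaussian

    g(x; Sigma) = 1 / (2 pi sqrt(det Sigma)) * exp(-x^T Sigma^{-1} x / 2),

parameterized by a symmetric positive-definite 2x2 covariance Sigma =
R(theta) diag(lambda1, lambda2) R(theta)^T.  The isotropic scale-space at
scale s is the special case Sigma = s I.  Derivative kernels are exact
samples of the analytic partial (or directional) derivatives, obtained from
the Hermite-type recursion: if K = P(x) g(x) for a polynomial prefactor P,
then d/dx_i K = (dP/dx_i - P * (Sigma^{-1} x)_i) g(x).

Sampled zero-order kernels are renormalized to unit mass; derivative kernels
are, by default, moment-corrected to exact zero sum (the residual raw sum is
a Poisson-summation aliasing term that grows as the scale shrinks).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import ndimage, signal

from .grid import GridSpec, ImageField, KernelGrid

__all__ = [
    "SpatialCovariance",
    "DerivativeSpec",
    "DiffusionParams",
    "AffineMap",
    "make_spatial_covariance",
    "hemisphere_covariance",
    "gaussian_derivative_kernel",
    "directional_derivative_kernel",
    "laplacian_kernel",
    "steer",
    "convolve",
    "diffusion_evolve",
    "default_kernel_grid",
    "kernel_second_moments",
]

MAX_ORDER = 4
DIRECT_CONV_MAX = 31  # direct spatial convolution up to this kernel side


# ---------------------------------------------------------------------------
# covariance parameterization

@dataclass(frozen=True)
class SpatialCovariance:
    """2x2 shape matrix via (lambda1, lambda2, theta).

    lambda1 >= lambda2 > 0 are the eigenvalue variances (length^2); theta is
    the major-axis orientation in [0, pi), counterclockwise from x1.
    """

    lambda1: float
    lambda2: float
    theta: float = 0.0

    def __post_init__(self):
        if not (self.lambda1 >= self.lambda2 > 0):
            raise ValueError("require lambda1 >= lambda2 > 0")
        object.__setattr__(self, "theta", float(self.theta) % math.pi)

    @property
    def matrix(self) -> np.ndarray:
        """Sigma in (x1, x2) coordinates."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        return R @ np.diag([self.lambda1, self.lambda2]) @ R.T

    @property
    def det(self) -> float:
        return self.lambda1 * self.lambda2

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def isotropic(self) -> bool:
        return math.isclose(self.lambda1, self.lambda2, rel_tol=1e-12)

    @staticmethod
    def from_scale(s: float) -> "SpatialCovariance":
        if s <= 0:
            raise ValueError("scale must be positive")
        return SpatialCovariance(s, s, 0.0)

    @staticmethod
    def from_matrix(sigma: np.ndarray) -> "SpatialCovariance":
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (2, 2) or abs(sigma[0, 1] - sigma[1, 0]) > 1e-12:
            raise ValueError("expected a symmetric 2x2 matrix")
        w, V = np.linalg.eigh(sigma)
        if w[0] <= 0:
            raise ValueError("matrix is not positive-definite")
        # eigh returns ascending eigenvalues; major axis is the second column
        v = V[:, 1]  # components (x1, x2)
        theta = math.atan2(v[1], v[0]) % math.pi
        return SpatialCovariance(float(w[1]), float(w[0]), theta)


def make_spatial_covariance(lambda1: float, lambda2: float,
                            theta: float = 0.0) -> SpatialCovariance:
    """Build Sigma = R(theta) diag(lambda1, lambda2) R(theta)^T.

    If lambda1 < lambda2 the eigenvalues are swapped and theta rotated by
    pi/2, so the stored major axis is always the larger variance.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("eigenvalue variances must be positive")
    if lambda1 < lambda2:
        lambda1, lambda2 = lambda2, lambda1
        theta = theta + math.pi / 2
    return SpatialCovariance(lambda1, lambda2, theta)


def hemisphere_covariance(tilt: float, azimuth: float,
                          s_base: float) -> SpatialCovariance:
    """Covariance of a surface patch slanted by ``tilt`` toward ``azimuth``.

    Foreshortening compresses the kernel by cos(tilt) along the tilt azimuth:
    Sigma = R(azimuth) diag(s_base, s_base cos^2 tilt) R(azimuth)^T.  With
    tilt drawn from a uniform distribution on the visible hemisphere this
    generates the family of affine kernels needed to handle slanted surfaces.
    """
    if not (0 <= tilt < math.pi / 2):
        raise ValueError("tilt must lie in [0, pi/2)")
    if s_base <= 0:
        raise ValueError("s_base must be positive")
    lam2 = s_base * math.cos(tilt) ** 2
    return make_spatial_covariance(s_base, lam2, azimuth)


@dataclass(frozen=True)
class DerivativeSpec:
    """Partial orders (a1, a2), or directional (phi, m)."""

    orders: Tuple[int, int] | None = None
    phi: float | None = None
    m: int | None = None

    def __post_init__(self):
        if self.orders is not None:
            a1, a2 = self.orders
            if a1 < 0 or a2 < 0:
                raise ValueError("derivative orders must be nonnegative")
            if a1 + a2 > MAX_ORDER:
                raise ValueError(f"total order exceeds maximum {MAX_ORDER}")
        elif self.phi is not None and self.m is not None:
            if not (0 <= self.m <= MAX_ORDER):
                raise ValueError(f"order must lie in [0, {MAX_ORDER}]")
        else:
            raise ValueError("specify either partial orders or (phi, m)")

    @property
    def total_order(self) -> int:
        if self.orders is not None:
            return self.orders[0] + self.orders[1]
        return self.m


@dataclass(frozen=True)
class AffineMap:
    """x' = A x + b with det A != 0."""

    A: np.ndarray
    b: np.ndarray = None

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        b = np.zeros(2) if self.b is None else np.asarray(self.b, dtype=float)
        if A.shape != (2, 2):
            raise ValueError("A must be 2x2")
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("A must be nonsingular")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    def inverse(self) -> "AffineMap":
        Ainv = np.linalg.inv(self.A)
        return AffineMap(Ainv, -Ainv @ self.b)


# ---------------------------------------------------------------------------
# polynomial-prefactor machinery for exact Gaussian derivatives
#
# Polynomials in (x1, x2) are stored as coefficient matrices C with
# C[i, j] multiplying x1^i x2^j (numpy polyval2d convention).

def _poly_mul_linear(P: np.ndarray, c0: float, c1: float, c2: float) -> np.ndarray:
    """P(x) * (c0 + c1*x1 + c2*x2)."""
    out = np.zeros((P.shape[0] + 1, P.shape[1] + 1))
    out[: P.shape[0], : P.shape[1]] += c0 * P
    out[1:, : P.shape[1]] += c1 * P
    out[: P.shape[0], 1:] += c2 * P
    return out

def _poly_diff(P: np.ndarray, axis: int) -> np.ndarray:
    if P.shape[axis] == 1:
        return np.zeros((1, 1))
    if axis == 0:
        i = np.arange(1, P.shape[0])
        return P[1:, :] * i[:, None]
    j = np.arange(1, P.shape[1])
    return P[:, 1:] * j[None, :]

def _apply_gaussian_derivative(P: np.ndarray, Lam: np.ndarray,
                               a1: float, a2: float) -> np.ndarray:
    """Prefactor of (a1 d/dx1 + a2 d/dx2)(P g) for g with Sigma^{-1} = Lam."""
    d1 = _poly_diff(P, 0)
    d2 = _poly_diff(P, 1)
    # -(Lam x)_i terms
    t1 = _poly_mul_linear(P, 0.0, -Lam[0, 0], -Lam[0, 1])
    t2 = _poly_mul_linear(P, 0.0, -Lam[1, 0], -Lam[1, 1])
    shapes = [d1.shape, d2.shape, t1.shape, t2.shape]
    n = max(s[0] for s in shapes)
    m = max(s[1] for s in shapes)
    out = np.zeros((n, m))
    for w, Q in ((a1, d1), (a2, d2), (a1, t1), (a2, t2)):
        out[: Q.shape[0], : Q.shape[1]] += w * Q
    return out


def gaussian_prefactor_poly(cov: SpatialCovariance,
                            directions: list[tuple[float, float]]) -> np.ndarray:
    """Prefactor polynomial of successive first-order derivatives of g."""
    Lam = cov.inverse
    P = np.ones((1, 1))
    for a1, a2 in directions:
        P = _apply_gaussian_derivative(P, Lam, a1, a2)
    return P


def _evaluate_gaussian(cov: SpatialCovariance, X1, X2,
                       P: np.ndarray | None = None) -> np.ndarray:
    Lam = cov.inverse
    quad = (Lam[0, 0] * X1 * X1 + 2 * Lam[0, 1] * X1 * X2
            + Lam[1, 1] * X2 * X2)
    g = np.exp(-0.5 * quad) / (2 * math.pi * math.sqrt(cov.det))
    if P is None:
        return g
    return npoly.polyval2d(X1, X2, P) * g


# ---------------------------------------------------------------------------
# kernel generation

def default_kernel_grid(cov: SpatialCovariance, total_order: int = 0,
                        spacing: float = 1.0,
                        radius_factor: float | None = None) -> GridSpec:
    """Truncation policy: half-width ceil((4 + m) sqrt(lambda1)) samples."""
    factor = (4.0 + total_order) if radius_factor is None else radius_factor
    hw = max(1, math.ceil(factor * math.sqrt(cov.lambda1) / spacing))
    return GridSpec.centered(hw, spacing)


def _finalize_kernel(values: np.ndarray, grid: GridSpec, params: dict,
                     order: int, normalize: bool, moment_correct: bool,
                     flags: tuple = ()) -> KernelGrid:
    norm = "none"
    if order == 0 and normalize:
        values = values / (values.sum() * grid.cell_area)
        norm = "unit_mass"
    elif order >= 1 and moment_correct:
        values = values - values.mean()
        norm = "zero_sum"
    return KernelGrid(values, grid, params=params, normalization=norm,
                      flags=flags)


def _truncation_flags(cov: SpatialCovariance, order: int,
                      grid: GridSpec) -> tuple:
    want = (4.0 + order) * math.sqrt(cov.lambda1)
    have2 = (grid.shape[0] - 1) / 2 * grid.spacing[0]
    have1 = (grid.shape[1] - 1) / 2 * grid.spacing[1]
    if min(have1, have2) < want - 1e-9:
        warnings.warn("kernel grid smaller than the truncation policy; "
                      "mass loss may exceed tolerance", stacklevel=3)
        return ("truncated",)
    return ()


def gaussian_derivative_kernel(cov: SpatialCovariance,
                               spec: DerivativeSpec | Tuple[int, int] = (0, 0),
                               grid: GridSpec | None = None,
                               normalize: bool = True,
                               moment_correct: bool = True) -> KernelGrid:
    """Sample an affine Gaussian kernel or one of its partial derivatives."""
    if not isinstance(spec, DerivativeSpec):
        spec = DerivativeSpec(orders=tuple(spec))
    if spec.orders is None:
        return directional_derivative_kernel(cov, spec.phi, spec.m, grid,
                                             normalize=normalize,
                                             moment_correct=moment_correct)
    a1, a2 = spec.orders
    m = a1 + a2
    if grid is None:
        grid = default_kernel_grid(cov, m)
    flags = _truncation_flags(cov, m, grid)
    X2, X1 = grid.mesh()
    dirs = [(1.0, 0.0)] * a1 + [(0.0, 1.0)] * a2
    P = gaussian_prefactor_poly(cov, dirs) if dirs else None
    values = _evaluate_gaussian(cov, X1, X2, P)
    params = dict(cov=cov, orders=(a1, a2))
    return _finalize_kernel(values, grid, params, m, normalize,
                            moment_correct, flags)


def directional_derivative_kernel(cov: SpatialCovariance, phi: float, m: int,
                                  grid: GridSpec | None = None,
                                  normalize: bool = True,
                                  moment_correct: bool = True,
                                  allow_misaligned: bool = True) -> KernelGrid:
    """Sample (cos phi d/dx1 + sin phi d/dx2)^m g(x; Sigma).

    By convention phi should align with an eigendirection of Sigma (theta or
    theta + pi/2); misaligned angles are permitted but flagged.
    """
    if grid is None:
        grid = default_kernel_grid(cov, m)
    flags = _truncation_flags(cov, m, grid)
    if not cov.isotropic:
        rel = (phi - cov.theta) % (math.pi / 2)
        if min(rel, math.pi / 2 - rel) > 1e-9:
            if not allow_misaligned:
                raise ValueError("phi not aligned with an eigendirection")
            flags = flags + ("misaligned_phi",)
    X2, X1 = grid.mesh()
    dirs = [(math.cos(phi), math.sin(phi))] * m
    P = gaussian_prefactor_poly(cov, dirs) if dirs else None
    values = _evaluate_gaussian(cov, X1, X2, P)
    params = dict(cov=cov, phi=phi, m=m)
    return _finalize_kernel(values, grid, params, m, normalize,
                            moment_correct, flags)


def laplacian_kernel(s: float, grid: GridSpec | None = None,
                     moment_correct: bool = True) -> KernelGrid:
    """Laplacian of Gaussian (d_x1x1 + d_x2x2) g(x; s)."""
    cov = SpatialCovariance.from_scale(s)
    if grid is None:
        grid = default_kernel_grid(cov, 2)
    gxx = gaussian_derivative_kernel(cov, (2, 0), grid, moment_correct=False)
    gyy = gaussian_derivative_kernel(cov, (0, 2), grid, moment_correct=False)
    values = gxx.values + gyy.values
    if moment_correct:
        values = values - values.mean()
    return KernelGrid(values, grid, params=dict(s=s, op="laplacian"),
                      normalization="zero_sum" if moment_correct else "none")


def kernel_second_moments(kernel: KernelGrid) -> SpatialCovariance:
    """Recover (lambda1, lambda2, theta) from the sampled second moments."""
    grid = kernel.grid
    X2, X1 = grid.mesh()
    w = kernel.values * grid.cell_area
    w = w / w.sum()
    m1 = (w * X1).sum()
    m2 = (w * X2).sum()
    c11 = (w * (X1 - m1) ** 2).sum()
    c22 = (w * (X2 - m2) ** 2).sum()
    c12 = (w * (X1 - m1) * (X2 - m2)).sum()
    return SpatialCovariance.from_matrix(np.array([[c11, c12], [c12, c22]]))


# ---------------------------------------------------------------------------
# steering of derivative responses

def steer(partials: Dict[Tuple[int, int], ImageField], phi: float,
          m: int) -> ImageField:
    """Directional derivative response from the m+1 partials of order m.

    L_phi^m = sum_k C(m,k) cos^k(phi) sin^(m-k)(phi) L_{x1^k x2^(m-k)}.
    """
    out = None
    grid = None
    for k in range(m + 1):
        key = (k, m - k)
        if key not in partials:
            raise ValueError(f"missing partial derivative {key}")
        field = partials[key]
        if grid is None:
            grid = field.grid
        coeff = (math.comb(m, k) * math.cos(phi) ** k
                 * math.sin(phi) ** (m - k))
        term = coeff * field.values
        out = term if out is None else out + term
    return ImageField(out, grid, tag="derivative")


# ---------------------------------------------------------------------------
# convolution

_PAD_MODE = {"reflect": "symmetric", "zero": "constant", "periodic": "wrap"}
_NDI_MODE = {"reflect": "reflect", "zero": "constant", "periodic": "wrap"}


def convolve(image: ImageField, kernel: KernelGrid,
             boundary: str = "reflect", route: str = "auto") -> ImageField:
    """Discrete 2D convolution with the stated boundary policy.

    Small kernels use direct spatial convolution; larger ones an FFT on a
    boundary-padded copy.  Both routes agree to ~1e-14.
    """
    if boundary not in _PAD_MODE:
        raise ValueError(f"unknown boundary policy {boundary!r}")
    if tuple(image.grid.spacing) != tuple(kernel.grid.spacing):
        raise ValueError("image and kernel grid spacings differ")
    kv = kernel.values * kernel.grid.cell_area
    if route == "auto":
        route = "direct" if max(kv.shape) <= DIRECT_CONV_MAX else "fft"
    if route == "direct":
        out = ndimage.convolve(image.values, kv, mode=_NDI_MODE[boundary])
    elif route == "fft":
        r2, r1 = kv.shape[0] // 2, kv.shape[1] // 2
        padded = np.pad(image.values, ((r2, r2), (r1, r1)),
                        mode=_PAD_MODE[boundary])
        full = signal.fftconvolve(padded, kv, mode="same")
        out = full[r2: r2 + image.values.shape[0],
                   r1: r1 + image.values.shape[1]]
    else:
        raise ValueError(f"unknown route {route!r}")
    return ImageField(out, image.grid, tag="smoothed")


# ---------------------------------------------------------------------------
# diffusion evolution

@dataclass(frozen=True)
class DiffusionParams:
    """d_s L = 1/2 div(Sigma0 grad L) - delta0 . grad L.

    Sigma0 may be positive semi-definite here (pure-transport case allowed).
    """

    Sigma0: np.ndarray
    delta0: np.ndarray = None

    def __post_init__(self):
        S = np.asarray(self.Sigma0, dtype=float)
        d = (np.zeros(2) if self.delta0 is None
             else np.asarray(self.delta0, dtype=float))
        if S.shape != (2, 2) or abs(S[0, 1] - S[1, 0]) > 1e-12:
            raise ValueError("Sigma0 must be symmetric 2x2")
        if np.linalg.eigvalsh(S)[0] < -1e-12:
            raise ValueError("Sigma0 must be positive semi-definite")
        object.__setattr__(self, "Sigma0", S)
        object.__setattr__(self, "delta0", d)


def _stable_step(params: DiffusionParams, spacing) -> float:
    h2, h1 = spacing
    S = params.Sigma0
    d = params.delta0
    diff = 0.5 * (S[0, 0] / h1**2 + S[1, 1] / h2**2
                  + abs(S[0, 1]) / (h1 * h2))
    adv = abs(d[0]) / h1 + abs(d[1]) / h2
    bound = diff + adv
    if bound == 0:
        return math.inf
    return 0.5 / bound


def diffusion_evolve(image: ImageField, params: DiffusionParams,
                     total_s: float, n_steps: int,
                     boundary: str = "reflect") -> ImageField:
    """Explicit finite-difference integration of the diffusion equation."""
    if total_s < 0:
        raise ValueError("total_s must be nonnegative")
    ds = total_s / n_steps
    ds_max = _stable_step(params, image.grid.spacing)
    if ds > ds_max:
        need = math.ceil(total_s / ds_max)
        raise ValueError(
            f"step size {ds:.4g} exceeds the stability bound {ds_max:.4g}; "
            f"use n_steps >= {need}")
    h2, h1 = image.grid.spacing
    S = params.Sigma0
    d1, d2 = params.delta0
    pad_mode = _PAD_MODE[boundary]
    L = image.values.copy()
    for _ in range(n_steps):
        P = np.pad(L, 1, mode=pad_mode)
        # axis 1 is x1, axis 0 is x2
        L11 = (P[1:-1, 2:] - 2 * L + P[1:-1, :-2]) / h1**2
        L22 = (P[2:, 1:-1] - 2 * L + P[:-2, 1:-1]) / h2**2
        L12 = (P[2:, 2:] - P[2:, :-2] - P[:-2, 2:] + P[:-2, :-2]) \
            / (4 * h1 * h2)
        G1 = (P[1:-1, 2:] - P[1:-1, :-2]) / (2 * h1)
        G2 = (P[2:, 1:-1] - P[:-2, 1:-1]) / (2 * h2)
        L = L + ds * (0.5 * (S[0, 0] * L11 + 2 * S[0, 1] * L12
                             + S[1, 1] * L22) - d1 * G1 - d2 * G2)
    return ImageField(L, image.grid, tag="smoothed")
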