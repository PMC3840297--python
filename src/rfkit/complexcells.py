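"""Quasi-quadrature complex-cell models.

Complex cells are modelled as phase-insensitive energy units built from
squared scale-normalized derivative responses.  Over one dimension,

    Q L = s L_x^2 + C s^2 L_xx^2,

an approximate Hilbert-pair energy with weighting constant C (default 2/3,
the ripple-minimizing value; C = e/4 from scale-selection arguments is the
alternative -- the source literature prints "e/4 ~ 0.670" although e/4 =
0.6796 to four digits, a rounding inconsistency we document rather than
correct).  Three spatio-temporal generalizations are provided:

    Q1 = s L_x^2 + tau L_t^2 + C (s^2 L_xx^2 + 2 s tau L_xt^2 + tau^2 L_tt^2)
    Q2 = sqrt((s L_x^2 + C s^2 L_xx^2)(tau L_t^2 + C tau^2 L_tt^2))
    Q3 = s tau L_xt^2 + C s^2 tau L_xxt^2 + C s tau^2 L_xtt^2
         + C^2 s^2 tau^2 L_xxtt^2

with t-derivatives replaced by transformed t'-derivatives for the
time-causal family.  A second-stage smoothing at integration scale
Sigma_int renders the response phase-invariant, and divisive normalization
over an ensemble gives contrast gain control r = Q / (sum_i w_i Q_i + c^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .grid import ImageField, ImageStack
from .spatial import SpatialCovariance, convolve, gaussian_derivative_kernel

__all__ = [
    "C_RIPPLE",
    "C_SCALESEL",
    "QuadratureParams",
    "PoolingParams",
    "NormalizationEnsemble",
    "scale_normalized_derivative",
    "quasi_quadrature_1d",
    "quasi_quadrature_st",
    "second_stage_pool",
    "divisive_normalize",
]

C_RIPPLE = 2.0 / 3.0
C_SCALESEL = math.e / 4.0

_VARIANT_KEYS = {
    "Q1": ("x", "t", "xx", "xt", "tt"),
    "Q2": ("x", "xx", "t", "tt"),
    "Q3": ("xt", "xxt", "xtt", "xxtt"),
}


@dataclass(frozen=True)
class QuadratureParams:
    C: float = C_RIPPLE
    variant: str = "Q1"
    temporal_family: str = "gaussian"  # 'gaussian' | 'timecausal'

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.variant not in _VARIANT_KEYS:
            raise ValueError("variant must be one of Q1, Q2, Q3")


@dataclass(frozen=True)
class PoolingParams:
    """Sigma_int: integration scale; Sigma_der: derivation scale of the
    underlying responses (bookkeeping; pooling convolves at Sigma_int)."""

    Sigma_int: SpatialCovariance
    Sigma_der: SpatialCovariance | None = None
    tau_int: float | None = None  # temporal integration scale for stacks


@dataclass
class NormalizationEnsemble:
    """Ensemble of Q responses with weights and stabilization constant c."""

    members: Sequence  # Q response arrays/fields
    weights: Sequence[float] = None
    c: float = 1.0

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError("ensemble must be non-empty")
        if self.weights is None:
            self.weights = [1.0] * len(self.members)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if not self.c > 0:
            raise ValueError("stabilization constant c must be positive")


def _vals(field):
    return field.values if hasattr(field, "values") else np.asarray(field,
                                                                    float)


def scale_normalized_derivative(field, s: float, tau: float = 1.0,
                                spatial_order: int = 0,
                                temporal_order: int = 0,
                                gamma_exponent: float = 1.0):
    """Multiply a derivative response by s^(m/2) tau^(n gamma / 2).

    Corresponds to derivatives with respect to the dimensionless coordinates
    xi = x/sqrt(s) and lambda = t/tau^(gamma/2).
    """
    factor = s ** (spatial_order / 2.0) \
        * tau ** (temporal_order * gamma_exponent / 2.0)
    v = _vals(field) * factor
    if isinstance(field, ImageField):
        return ImageField(v, field.grid, tag="derivative")
    return v


def quasi_quadrature_1d(L_x, L_xx, s: float, C: float = C_RIPPLE):
    """Q = s L_x^2 + C s^2 L_xx^2, pointwise."""
    q = s * _vals(L_x) ** 2 + C * s ** 2 * _vals(L_xx) ** 2
    if isinstance(L_x, ImageField):
        return ImageField(q, L_x.grid, tag="derivative")
    return q


def quasi_quadrature_st(derivs: Dict[str, np.ndarray], s: float, tau: float,
                        params: QuadratureParams = QuadratureParams()):
    """Spatio-temporal quasi-quadrature, variant Q1, Q2 or Q3.

    ``derivs`` maps component names ('x', 'xx', 't', 'xt', ...) to response
    arrays; for the time-causal family the 't' slots hold transformed
    t'-derivative responses.  All variants are nonnegative by construction.
    """
    need = _VARIANT_KEYS[params.variant]
    missing = [k for k in need if k not in derivs]
    if missing:
        raise ValueError(f"variant {params.variant} missing components "
                         f"{missing}")
    d = {k: _vals(derivs[k]) for k in need}
    C = params.C
    if params.variant == "Q1":
        return (s * d["x"] ** 2 + tau * d["t"] ** 2
                + C * (s ** 2 * d["xx"] ** 2 + 2 * s * tau * d["xt"] ** 2
                       + tau ** 2 * d["tt"] ** 2))
    if params.variant == "Q2":
        prod = ((s * d["x"] ** 2 + C * s ** 2 * d["xx"] ** 2)
                * (tau * d["t"] ** 2 + C * tau ** 2 * d["tt"] ** 2))
        return np.sqrt(prod)
    return (s * tau * d["xt"] ** 2 + C * s ** 2 * tau * d["xxt"] ** 2
            + C * s * tau ** 2 * d["xtt"] ** 2
            + C ** 2 * s ** 2 * tau ** 2 * d["xxtt"] ** 2)


def second_stage_pool(Q, pooling: PoolingParams, family: str = "gaussian",
                      boundary: str = "reflect",
                      radius_factor: float | None = None):
    """Smooth a quadrature response at the integration scale.

    Spatial fields are pooled with the zero-order kernel at Sigma_int; for
    stacks a separable temporal Gaussian (non-causal family) or integrator
    cascade (time-causal family) at tau_int follows the spatial pooling.
    Preserves non-negativity (nonnegative kernel).
    """
    from .spatial import default_kernel_grid
    grid = default_kernel_grid(pooling.Sigma_int,
                               radius_factor=radius_factor) \
        if radius_factor is not None else None
    kernel = gaussian_derivative_kernel(pooling.Sigma_int, (0, 0), grid)
    if isinstance(Q, ImageField) or (hasattr(Q, "ndim") and Q.ndim == 2):
        f = Q if isinstance(Q, ImageField) else ImageField(np.asarray(Q))
        return convolve(f, kernel, boundary=boundary)
    if not isinstance(Q, ImageStack):
        Q = ImageStack(np.asarray(Q, dtype=float))
    out = np.empty_like(Q.values)
    for n in range(Q.values.shape[0]):
        out[n] = convolve(Q.frame(n), kernel, boundary=boundary).values
    if pooling.tau_int:
        if family == "timecausal":
            from .timecausal import IntegratorCascade, make_scale_profile
            prof = make_scale_profile(pooling.tau_int / 16, pooling.tau_int,
                                      5)
            casc = IntegratorCascade(prof.mu, Q.grid.dt)
            for n in range(out.shape[0]):
                out[n] = casc.step(out[n])[-1]
        else:
            from scipy.ndimage import gaussian_filter1d
            sigma = math.sqrt(pooling.tau_int) / Q.grid.dt
            out = gaussian_filter1d(out, sigma, axis=0, mode="nearest")
    return ImageStack(out, Q.grid, tag="derivative")


def divisive_normalize(Q, ensemble: NormalizationEnsemble):
    """r = Q / (sum_i w_i Q_i + c^2), pointwise.

    The denominator is strictly positive; on a single-member ensemble with
    w = 1 and Q_1 = Q the response is Q/(Q + c^2) in [0, 1).
    """
    denom = ensemble.c ** 2
    for w, m in zip(ensemble.weights, ensemble.members):
        denom = denom + w * _vals(m)
    r = _vals(Q) / denom
    if isinstance(Q, ImageField):
        return ImageField(r, Q.grid, tag="derivative")
    return r
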