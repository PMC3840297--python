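"""Color-opponent channels and spatio-chromatic receptive-field responses.

RGB sensor channels are mapped to an intensity channel f = (R+G+B)/3, a
red/green opponent channel c1 = (R-G)/2 and a yellow/blue opponent channel
c2 = (R+G)/2 - B (yellow approximated as the R,G average).  Gaussian
derivative filtering of c1 and c2 gives idealized spatio-chromatic receptive
fields; applying +-(Laplacian of Gaussian) to both opponent channels models
double-opponent cells (red-center/green-surround etc.).

The transform is applied to the channel values as given; no gamma handling
is performed here (see the photometry module for log-brightness issues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, ImageField
from .spatial import (DerivativeSpec, SpatialCovariance, convolve,
                      gaussian_derivative_kernel, laplacian_kernel)

__all__ = [
    "OPPONENT_MATRIX",
    "OpponentImage",
    "rgb_to_opponent",
    "opponent_to_rgb",
    "spatio_chromatic_response",
    "double_opponent_response",
]

OPPONENT_MATRIX = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [1 / 2, -1 / 2, 0.0],
    [1 / 2, 1 / 2, -1.0],
])
_OPPONENT_INV = np.linalg.inv(OPPONENT_MATRIX)


@dataclass
class OpponentImage:
    f: ImageField    # intensity
    c1: ImageField   # red/green
    c2: ImageField   # yellow/blue

    @property
    def grid(self) -> GridSpec:
        return self.f.grid


def _as_rgb_array(rgb) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (n2, n1, 3) RGB array")
    return arr


def rgb_to_opponent(rgb, grid: GridSpec | None = None) -> OpponentImage:
    """(f, c1, c2) = M (R, G, B) with the fixed opponent matrix."""
    arr = _as_rgb_array(rgb)
    opp = arr @ OPPONENT_MATRIX.T
    grid = grid or GridSpec(arr.shape[:2])
    return OpponentImage(
        f=ImageField(opp[..., 0], grid, tag="raw"),
        c1=ImageField(opp[..., 1], grid, tag="raw"),
        c2=ImageField(opp[..., 2], grid, tag="raw"),
    )


def opponent_to_rgb(opp: OpponentImage) -> np.ndarray:
    """Exact inverse of the opponent transform, per pixel."""
    stacked = np.stack([opp.f.values, opp.c1.values, opp.c2.values], axis=-1)
    return stacked @ _OPPONENT_INV.T


def spatio_chromatic_response(rgb, channel: str, cov: SpatialCovariance,
                              spec: DerivativeSpec | tuple,
                              boundary: str = "reflect") -> ImageField:
    """Gaussian-derivative filtering of an opponent channel (c1 or c2)."""
    opp = rgb_to_opponent(rgb)
    if channel not in ("c1", "c2"):
        raise ValueError("channel must be 'c1' or 'c2'")
    field = getattr(opp, channel)
    kernel = gaussian_derivative_kernel(cov, spec)
    out = convolve(field, kernel, boundary=boundary)
    out.tag = "derivative"
    return out


def double_opponent_response(rgb, s: float, polarity: int = +1,
                             boundary: str = "reflect"):
    """+-LoG applied to both opponent channels: the double-opponent model.

    Returns the (c1, c2) response pair; polarity +1 gives e.g. the
    red-center/green-surround sign convention, -1 the reverse.
    """
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    opp = rgb_to_opponent(rgb)
    kernel = laplacian_kernel(s)
    kernel.values = polarity * kernel.values
    r1 = convolve(opp.c1, kernel, boundary=boundary)
    r2 = convolve(opp.c2, kernel, boundary=boundary)
    r1.tag = r2.tag = "derivative"
    return r1, r2
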