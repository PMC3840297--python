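"""Log-brightness image formation and illumination-invariance checks.

Image brightness on a logarithmic scale decomposes additively,

    f(x) = log rho(x) + log i(x) + log C_cam - 2 log(1 + x1^2 + x2^2),

into surface albedo rho, illumination i, the camera exposure constant
C_cam (a function of the effective f-number), and natural vignetting
cos^4 phi(x) with cos phi = 1/sqrt(1 + x1^2 + x2^2) (image coordinates in
units of the focal length).  Multiplicative changes of illumination or
exposure shift f by a constant, which any zero-sum (derivative) kernel
cancels exactly; a sensor gamma I -> I^gamma merely rescales log I by
gamma.  Time-varying exposure adds a spatially constant, time-varying term
that spatial derivative kernels cancel frame by frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .grid import ImageField, KernelGrid
from .spatial import convolve

__all__ = [
    "SceneModel",
    "CameraModel",
    "vignetting_factor",
    "log_vignetting",
    "render_log_image",
    "apply_multiplicative_illumination",
    "response_decomposition_check",
]


@dataclass(frozen=True)
class SceneModel:
    """Strictly positive albedo and illumination maps on a shared grid.

    ``coords_scale`` converts pixel offsets from the image center into
    focal-length units for the vignetting term.
    """

    albedo: np.ndarray
    illumination: np.ndarray
    coords_scale: float = 0.005

    def __post_init__(self):
        rho = np.asarray(self.albedo, dtype=float)
        ill = np.asarray(self.illumination, dtype=float)
        if rho.min() <= 0 or ill.min() <= 0:
            raise ValueError("albedo and illumination must be > 0")
        object.__setattr__(self, "albedo", rho)
        object.__setattr__(self, "illumination", ill)


@dataclass(frozen=True)
class CameraModel:
    """Exposure constant C_cam, vignetting switch, optional per-frame
    exposure C_cam(t), optional sensor gamma in (0, 1]."""

    C_cam: float = 1.0
    vignetting: bool = False
    C_cam_t: Callable[[float], float] | None = None
    gamma: float = 1.0

    def __post_init__(self):
        if self.C_cam <= 0:
            raise ValueError("C_cam must be positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")


def _focal_coords(shape, coords_scale):
    c2 = (shape[0] - 1) / 2.0
    c1 = (shape[1] - 1) / 2.0
    x2 = (np.arange(shape[0]) - c2) * coords_scale
    x1 = (np.arange(shape[1]) - c1) * coords_scale
    X2, X1 = np.meshgrid(x2, x1, indexing="ij")
    return X1, X2


def vignetting_factor(x1, x2):
    """cos^4 phi = (1 + x1^2 + x2^2)^-2, focal-length units."""
    return (1.0 + np.asarray(x1) ** 2 + np.asarray(x2) ** 2) ** -2.0


def log_vignetting(x1, x2):
    """-2 log(1 + x1^2 + x2^2): the additive log-domain vignetting term."""
    return -2.0 * np.log1p(np.asarray(x1) ** 2 + np.asarray(x2) ** 2)


def render_log_image(scene: SceneModel, camera: CameraModel,
                     t: float | None = None) -> ImageField:
    """f = gamma (log rho + log i + log C_cam) + vignetting term.

    With a per-frame exposure model, pass the frame time ``t``; rendering a
    gamma-compressed sensor output I^gamma then taking logs equals scaling
    log I by gamma, so gamma multiplies the scene terms directly.
    """
    C = camera.C_cam_t(t) if (camera.C_cam_t is not None and t is not None) \
        else camera.C_cam
    if C <= 0:
        raise ValueError("exposure must be positive")
    f = np.log(scene.albedo) + np.log(scene.illumination) + math.log(C)
    if camera.vignetting:
        X1, X2 = _focal_coords(scene.albedo.shape, scene.coords_scale)
        f = f + log_vignetting(X1, X2)
    return ImageField(camera.gamma * f, tag="raw")


def apply_multiplicative_illumination(scene: SceneModel,
                                      C_illum: float) -> SceneModel:
    """i <- C_illum * i (a multiplicative illumination transformation)."""
    if C_illum <= 0:
        raise ValueError("C_illum must be positive")
    return replace(scene, illumination=scene.illumination * C_illum)


def response_decomposition_check(scene: SceneModel, camera: CameraModel,
                                 kernel: KernelGrid,
                                 boundary: str = "reflect") -> dict:
    """Verify additivity of derivative responses over the log-image terms.

    The response to the rendered f must equal the sum of the responses to
    log(albedo), log(illumination) and the vignetting map (linearity of
    convolution); the exposure constant contributes nothing because the
    kernel sums to zero.  Returns the component responses and the maximum
    additivity defect.
    """
    ksum = float(kernel.values.sum() * kernel.grid.cell_area)
    if abs(ksum) > 1e-6:
        raise ValueError("decomposition check requires a zero-sum kernel")
    f = render_log_image(scene, camera)
    resp_f = convolve(f, kernel, boundary=boundary).values

    def respond(arr):
        return convolve(ImageField(arr), kernel, boundary=boundary).values

    g = camera.gamma
    parts = {
        "albedo": respond(g * np.log(scene.albedo)),
        "illumination": respond(g * np.log(scene.illumination)),
    }
    if camera.vignetting:
        X1, X2 = _focal_coords(scene.albedo.shape, scene.coords_scale)
        parts["vignetting"] = respond(g * log_vignetting(X1, X2))
    else:
        parts["vignetting"] = np.zeros_like(resp_f)
    total = parts["albedo"] + parts["illumination"] + parts["vignetting"]
    defect = float(np.abs(resp_f - total).max())
    scale = float(np.abs(resp_f).max()) or 1.0
    return dict(response=resp_f, parts=parts, additivity_defect=defect,
                additivity_defect_rel=defect / scale)
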