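"""Deterministic synthetic stimuli for tests and verification.

All patterns are generated analytically; moving gratings translate by an
exact per-frame phase increment, so there is no resampling error in the
"ground-truth" motion.  Noise fixtures are seeded and band-limited by a
hard spectral cutoff below Nyquist, matching the smoothness assumptions of
the covariance and non-enhancement checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .grid import GridSpec, ImageField, ImageStack, STGridSpec
from .spatial import AffineMap

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "impulse",
    "sine_grating",
    "moving_grating",
    "gaussian_blob",
    "bandlimited_noise",
    "bandlimited_noise_1d",
    "step_edge",
    "affine_warp",
]

FIXTURE_KINDS = ("impulse", "sine_grating", "moving_grating",
                 "gaussian_blob", "bandlimited_noise", "step_edge")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    size: tuple = (64, 64)
    dt: float = 1.0
    n_frames: int = 1
    params: dict = dfield(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def make_fixture(spec: FixtureSpec):
    """Dispatch on the fixture kind; returns ImageField or ImageStack."""
    p = dict(spec.params)
    if spec.kind == "impulse":
        return impulse(spec.size)
    if spec.kind == "sine_grating":
        return sine_grating(spec.size, **p)
    if spec.kind == "moving_grating":
        return moving_grating(spec.size, n_frames=spec.n_frames, dt=spec.dt,
                              **p)
    if spec.kind == "gaussian_blob":
        return gaussian_blob(spec.size, **p)
    if spec.kind == "bandlimited_noise":
        return bandlimited_noise(spec.size, seed=spec.seed, **p)
    return step_edge(spec.size, **p)


def impulse(size=(64, 64), spacing: float = 1.0) -> ImageField:
    """A single 1.0 at the central sample."""
    v = np.zeros(size)
    v[size[0] // 2, size[1] // 2] = 1.0
    return ImageField(v, GridSpec(tuple(size), (spacing, spacing)))


def _check_nyquist(freq):
    if abs(freq) > 0.5:
        raise ValueError("frequency exceeds the Nyquist limit 0.5 c/px")


def sine_grating(size=(64, 64), freq: float = 1 / 8, orientation: float = 0.0,
                 phase: float = 0.0, amplitude: float = 1.0) -> ImageField:
    """sin(2 pi freq (x1 cos o + x2 sin o) + phase); freq in cycles/px."""
    _check_nyquist(freq)
    i2, i1 = np.mgrid[0: size[0], 0: size[1]].astype(float)
    u = i1 * math.cos(orientation) + i2 * math.sin(orientation)
    v = amplitude * np.sin(2 * math.pi * freq * u + phase)
    return ImageField(v, GridSpec(tuple(size)))


def moving_grating(size=(64, 64), n_frames: int = 64, dt: float = 1.0,
                   freq: float = 1 / 8, orientation: float = 0.0,
                   velocity=(1.0, 0.0), phase: float = 0.0) -> ImageStack:
    """Grating translating at exactly ``velocity`` px/frame (analytic phase).

    Frame n shows sin(2 pi f (u - v_u t) + phase) with u the coordinate
    along the grating normal and v_u the velocity component along it.
    """
    _check_nyquist(freq)
    i2, i1 = np.mgrid[0: size[0], 0: size[1]].astype(float)
    u = i1 * math.cos(orientation) + i2 * math.sin(orientation)
    v_u = velocity[0] * math.cos(orientation) \
        + velocity[1] * math.sin(orientation)
    frames = np.empty((n_frames,) + tuple(size))
    for n in range(n_frames):
        t = n * dt
        frames[n] = np.sin(2 * math.pi * freq * (u - v_u * t) + phase)
    grid = STGridSpec((n_frames,) + tuple(size), (dt, 1.0, 1.0))
    return ImageStack(frames, grid)


def gaussian_blob(size=(64, 64), s: float = 4.0, center=None,
                  amplitude: float = 1.0) -> ImageField:
    """Gaussian bump of variance s, default at the grid center."""
    if center is None:
        center = ((size[1] - 1) / 2.0, (size[0] - 1) / 2.0)  # (x1, x2)
    i2, i1 = np.mgrid[0: size[0], 0: size[1]].astype(float)
    r2 = (i1 - center[0]) ** 2 + (i2 - center[1]) ** 2
    return ImageField(amplitude * np.exp(-r2 / (2 * s)),
                      GridSpec(tuple(size)))


def bandlimited_noise(size=(64, 64), cutoff: float = 0.15, seed: int = 0,
                      rms: float = 1.0) -> ImageField:
    """Gaussian white noise low-passed by a hard radial spectral cutoff."""
    if not (0 < cutoff <= 0.5):
        raise ValueError("cutoff must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(size)
    F = np.fft.fft2(white)
    f2 = np.fft.fftfreq(size[0])[:, None]
    f1 = np.fft.fftfreq(size[1])[None, :]
    F[np.hypot(f1, f2) > cutoff] = 0.0
    v = np.fft.ifft2(F).real
    v *= rms / max(v.std(), 1e-30)
    return ImageField(v, GridSpec(tuple(size)))


def bandlimited_noise_1d(n: int = 256, cutoff: float = 0.1,
                         seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    F = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    F[f > cutoff] = 0.0
    v = np.fft.irfft(F, n)
    return v / max(v.std(), 1e-30)


def step_edge(size=(64, 64), orientation: float = 0.0, lo: float = 0.0,
              hi: float = 1.0, position: float | None = None) -> ImageField:
    """Step edge: hi where the signed distance along the normal is >= 0."""
    i2, i1 = np.mgrid[0: size[0], 0: size[1]].astype(float)
    if position is None:
        position = (size[1] - 1) / 2.0
    u = (i1 - position) * math.cos(orientation) \
        + (i2 - (size[0] - 1) / 2.0) * math.sin(orientation)
    return ImageField(np.where(u >= 0, hi, lo), GridSpec(tuple(size)))


def affine_warp(image: ImageField, amap: AffineMap,
                interpolation: str = "bilinear",
                boundary: str = "reflect") -> ImageField:
    """Resample f'(x) = f(A^{-1}(x - b)) about the image center.

    Inverse mapping with bilinear (default) or cubic-spline interpolation.
    The map acts on (x1, x2) offsets from the center, matching the kernel
    coordinate convention.
    """
    order = {"bilinear": 1, "spline": 3}[interpolation]
    mode = {"reflect": "reflect", "zero": "constant",
            "periodic": "grid-wrap"}[boundary]
    Ainv = np.linalg.inv(amap.A)
    n2, n1 = image.values.shape
    c1, c2 = (n1 - 1) / 2.0, (n2 - 1) / 2.0
    i2, i1 = np.mgrid[0: n2, 0: n1].astype(float)
    X1 = i1 - c1 - amap.b[0]
    X2 = i2 - c2 - amap.b[1]
    src1 = Ainv[0, 0] * X1 + Ainv[0, 1] * X2 + c1
    src2 = Ainv[1, 0] * X1 + Ainv[1, 1] * X2 + c2
    out = ndimage.map_coordinates(image.values, [src2, src1], order=order,
                                  mode=mode, prefilter=(order > 1))
    return ImageField(out, image.grid, tag=image.tag)
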