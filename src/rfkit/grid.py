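"""Grid and field containers.

Coordinate convention: arrays are indexed ``[i2, i1]`` (row, column); the
coordinate ``x1`` runs along axis 1 and ``x2`` along axis 0, both increasing
with the index.  The orientation angle ``theta`` is measured counterclockwise
from the ``x1`` axis toward ``x2``.  Kernel grids have odd sample counts with
the kernel origin at the central sample.  Image stacks carry a leading time
axis ``[t, i2, i1]`` with frame spacing ``dt`` and frame times ``t0 + n*dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "GridSpec",
    "STGridSpec",
    "ImageField",
    "ImageStack",
    "KernelGrid",
    "STKernelGrid",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular 2D grid: ``shape=(n2, n1)``, ``spacing=(h2, h1)``."""

    shape: Tuple[int, int]
    spacing: Tuple[float, float] = (1.0, 1.0)
    kernel_grid: bool = False  # odd shape, origin at the central sample

    def __post_init__(self):
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(h <= 0 for h in self.spacing):
            raise ValueError("grid spacing must be > 0")
        if self.kernel_grid and any(n % 2 == 0 for n in self.shape):
            raise ValueError("kernel grids require odd sample counts")

    @property
    def cell_area(self) -> float:
        return self.spacing[0] * self.spacing[1]

    def axes(self) -> Tuple[np.ndarray, np.ndarray]:
        """Coordinate axes (x2, x1), centered if this is a kernel grid."""
        out = []
        for n, h in zip(self.shape, self.spacing):
            idx = np.arange(n, dtype=float)
            if self.kernel_grid:
                idx -= (n - 1) / 2.0
            out.append(idx * h)
        return out[0], out[1]

    def mesh(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X2, X1) of shape ``shape``."""
        x2, x1 = self.axes()
        return np.meshgrid(x2, x1, indexing="ij")

    @staticmethod
    def centered(half_width: int, spacing: float = 1.0) -> "GridSpec":
        n = 2 * half_width + 1
        return GridSpec((n, n), (spacing, spacing), kernel_grid=True)


@dataclass(frozen=True)
class STGridSpec:
    """A 2+1D grid over (t, x2, x1).

    ``t0`` is the time of the first frame; for non-causal kernels it is
    typically negative or zero with the kernel delayed by ``delta``, while
    time-causal kernels use ``t0 = 0``.
    """

    shape: Tuple[int, int, int]  # (nt, n2, n1)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # (dt, h2, h1)
    t0: float = 0.0
    kernel_grid: bool = False  # odd *spatial* counts, origin central

    def __post_init__(self):
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(h <= 0 for h in self.spacing):
            raise ValueError("grid spacing must be > 0")
        if self.kernel_grid and any(n % 2 == 0 for n in self.shape[1:]):
            raise ValueError("kernel grids require odd spatial sample counts")

    @property
    def dt(self) -> float:
        return self.spacing[0]

    @property
    def spatial(self) -> GridSpec:
        return GridSpec(self.shape[1:], self.spacing[1:],
                        kernel_grid=self.kernel_grid)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.shape[0], dtype=float) * self.dt

    @property
    def cell_volume(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class ImageField:
    """Scalar data f or L on a 2D grid with a semantic tag."""

    values: np.ndarray
    grid: GridSpec | None = None
    tag: str = "raw"  # raw f | smoothed L | derivative response

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ImageField requires a 2D array")
        if self.grid is None:
            self.grid = GridSpec(self.values.shape)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")
        _check_finite(self.values, "ImageField")

    @property
    def spacing(self):
        return self.grid.spacing


@dataclass
class ImageStack:
    """Scalar data over space-time, indexed ``[t, i2, i1]``."""

    values: np.ndarray
    grid: STGridSpec | None = None
    tag: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ImageStack requires a 3D array")
        if self.grid is None:
            self.grid = STGridSpec(self.values.shape)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")
        _check_finite(self.values, "ImageStack")

    @property
    def dt(self) -> float:
        return self.grid.dt

    def frame(self, n: int) -> ImageField:
        return ImageField(self.values[n], self.grid.spatial, tag=self.tag)


@dataclass
class KernelGrid:
    """Sampled kernel values plus the parameters that generated them."""

    values: np.ndarray
    grid: GridSpec
    params: dict = field(default_factory=dict)
    normalization: str = "none"  # none | unit_mass | zero_sum
    flags: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_finite(self.values, "KernelGrid")

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.cell_area)


@dataclass
class STKernelGrid:
    """Sampled spatio-temporal kernel on an STGridSpec."""

    values: np.ndarray
    grid: STGridSpec
    params: dict = field(default_factory=dict)
    normalization: str = "none"
    flags: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_finite(self.values, "STKernelGrid")

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.cell_volume)
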