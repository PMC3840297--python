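"""Standard-format I/O: images, stacks, kernel banks.

Images: 8/16-bit PNG and float32 TIFF; integer inputs are rescaled to
[0, 1] doubles in memory.  Stacks: multi-page float32 TIFF, or a directory
of numbered PNG frames with a JSON manifest carrying dt and units.  Kernel
banks: a flat little-endian float32 binary array plus a JSON sidecar with
shape, spacing and generating parameters; small kernels also export as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .grid import (GridSpec, ImageField, ImageStack, KernelGrid, STGridSpec,
                   STKernelGrid)

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "save_kernel_bank",
    "load_kernel_bank",
    "kernel_to_csv",
]


def read_image(path) -> ImageField:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float)
    else:
        img = Image.open(path)
        arr = np.asarray(img).astype(float)
        if arr.ndim == 3:  # average channels for the scalar container
            arr = arr.mean(axis=-1)
        if img.mode in ("I;16", "I;16B"):
            arr /= 65535.0
        elif img.mode in ("L", "P", "RGB", "RGBA"):
            arr /= 255.0
    return ImageField(arr[::-1].copy())  # PNG row 0 is the top; x2 points up


def write_image(path, field: ImageField, bitdepth: int = 16) -> None:
    path = Path(path)
    arr = field.values[::-1]
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
        return
    lo, hi = float(arr.min()), float(arr.max())
    scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if bitdepth == 16:
        Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)
    else:
        Image.fromarray((scaled * 255).astype(np.uint8)).save(path)


def read_stack(path, dt: float = 1.0) -> ImageStack:
    path = Path(path)
    if path.is_dir():
        manifest = json.loads((path / "manifest.json").read_text())
        dt = manifest.get("dt", dt)
        frames = [read_image(path / name).values
                  for name in manifest["frames"]]
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(path).astype(float)
        if arr.ndim == 2:
            arr = arr[None]
    grid = STGridSpec(arr.shape, (dt, 1.0, 1.0))
    return ImageStack(arr, grid)


def write_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(Path(path), stack.values.astype(np.float32))


def _kernel_meta(kernel) -> dict:
    meta = dict(shape=list(kernel.values.shape),
                normalization=kernel.normalization,
                dtype="<f4")
    if isinstance(kernel, KernelGrid):
        meta["spacing"] = list(kernel.grid.spacing)
    else:
        meta["spacing"] = list(kernel.grid.spacing)
        meta["t0"] = kernel.grid.t0
    meta["params"] = _jsonable(kernel.params)
    return meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    if isinstance(obj, np.generic):
        return obj.item()
    return repr(obj)


def save_kernel_bank(path, kernels: list) -> None:
    """Flat little-endian float32 binary + JSON sidecar."""
    path = Path(path)
    data = np.concatenate([k.values.astype("<f4").ravel() for k in kernels])
    data.tofile(path.with_suffix(".bin"))
    sidecar = dict(kernels=[_kernel_meta(k) for k in kernels])
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_kernel_bank(path) -> list:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".bin"), dtype="<f4").astype(float)
    out = []
    offset = 0
    for meta in sidecar["kernels"]:
        shape = tuple(meta["shape"])
        n = int(np.prod(shape))
        values = data[offset: offset + n].reshape(shape)
        offset += n
        if len(shape) == 2:
            grid = GridSpec(shape, tuple(meta["spacing"]),
                            kernel_grid=all(s % 2 for s in shape))
            out.append(KernelGrid(values, grid, params=meta.get("params", {}),
                                  normalization=meta["normalization"]))
        else:
            grid = STGridSpec(shape, tuple(meta["spacing"]),
                              t0=meta.get("t0", 0.0),
                              kernel_grid=all(s % 2 for s in shape[1:]))
            out.append(STKernelGrid(values, grid,
                                    params=meta.get("params", {}),
                                    normalization=meta["normalization"]))
    return out


def kernel_to_csv(path, kernel: KernelGrid) -> None:
    np.savetxt(Path(path), kernel.values, delimiter=",")
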