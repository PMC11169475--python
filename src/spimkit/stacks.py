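"""Core containers: time-lapse movies and voxel stacks, plus TIFF I/O.

Axis convention (fixed throughout the toolkit): stacks are indexed
``(z, y, x)``, movies ``(t, y, x)``, both 0-based, with z increasing along
the stage-travel direction.  Voxel sizes are ``(dz, dy, dx)`` in µm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "ImageStack",
    "MovieStack",
    "bit_depth_max",
    "clamp_to_bit_depth",
    "read_stack",
    "write_stack",
]


def bit_depth_max(bit_depth: int) -> int:
    """Largest representable intensity for a given bit depth (8, 12 or 16)."""
    if bit_depth not in (8, 12, 16):
        raise ValidationError(f"unsupported bit depth: {bit_depth}")
    return (1 << bit_depth) - 1


def _storage_dtype(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth == 8 else np.dtype(np.uint16)


def clamp_to_bit_depth(values: np.ndarray, bit_depth: int) -> np.ndarray:
    """Clip to ``[0, 2**bit_depth - 1]``.

    Integer output is rounded and cast to the storage dtype; float input
    stays float (only clipped), so intermediate arithmetic keeps precision.
    """
    hi = bit_depth_max(bit_depth)
    if np.issubdtype(np.asarray(values).dtype, np.floating):
        return np.clip(values, 0, hi)
    return np.clip(values, 0, hi).astype(_storage_dtype(bit_depth))


@dataclass
class MovieStack:
    """Time-ordered frame sequence ``(t, y, x)`` as acquired by the camera."""

    frames: np.ndarray
    exposure: float  # s
    bit_depth: int = 8
    source_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("movie frames must be a (t, y, x) array with t >= 1")
        if self.exposure <= 0:
            raise ValidationError("exposure must be positive")
        bit_depth_max(self.bit_depth)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ImageStack:
    """3-D voxel grid ``(z, y, x)`` with physical voxel size in µm."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) µm
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError("stack voxels must be a (z, y, x) array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive lengths (dz, dy, dx)")
        bit_depth_max(self.bit_depth)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy_with(self, voxels: np.ndarray, voxel_size=None) -> "ImageStack":
        return ImageStack(voxels, voxel_size or self.voxel_size, self.bit_depth)


def write_stack(stack: ImageStack, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar carrying voxel size.

    BigTIFF is enabled automatically above 2 GiB.
    """
    path = Path(path)
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating):
        data = clamp_to_bit_depth(np.rint(data), stack.bit_depth).astype(
            _storage_dtype(stack.bit_depth)
        )
    tifffile.imwrite(path, data, bigtiff=data.nbytes > 2**31, photometric="minisblack")
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
        "axes": "zyx",
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path, voxel_size=None, bit_depth=None) -> ImageStack:
    """Read a TIFF stack; voxel size comes from the sidecar unless given."""
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = voxel_size or tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))
        bit_depth = bit_depth or meta.get("bit_depth")
    voxel_size = voxel_size or (1.0, 1.0, 1.0)
    if bit_depth is None:
        bit_depth = 16 if voxels.dtype.itemsize > 1 else 8
    return ImageStack(voxels, voxel_size, bit_depth)
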