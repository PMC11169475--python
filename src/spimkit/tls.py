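"""Tiling light-sheet fusion.

Two stacks acquired with the sheet waist at different x positions are each
sharp only near their own focus.  On an x–z reslice, axially focused
high-contrast structure raises the local standard deviation after
band-pass filtering, so tiling per-window SDs along x gives a focus
contrast curve per stack.  The x where the two curves invert (the sharper
stack changes) is the tiling coordinate; the fused stack takes each side
from its sharper source, blended across a 100-pixel overlap (or joined
hard at the split column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import difference_of_gaussians

from .errors import FormatError, NoInversionError, ValidationError
from .stacks import ImageStack, clamp_to_bit_depth

__all__ = ["FocusContrastCurve", "TilingResult", "focus_contrast", "find_inversion", "combine_tiles", "fuse_pair"]


@dataclass
class FocusContrastCurve:
    """Per-x-window focus contrast of one reslice."""

    window_x_centers: np.ndarray  # px
    sd_values: np.ndarray
    kernel: tuple[int, int]  # (x, z) window size in px


@dataclass
class TilingResult:
    x_split: int  # px
    curve1: FocusContrastCurve
    curve2: FocusContrastCurve
    overlap: int = 100


def focus_contrast(
    xz_image: np.ndarray,
    kernel: tuple[int, int] = (50, 100),
    band: tuple[float, float] = (3.0, 40.0),
) -> FocusContrastCurve:
    """Band-passed per-window SD along x of an x–z reslice (rows = z).

    The image is difference-of-Gaussians filtered to pass structure between
    ``band`` pixel sizes, then tiled (stride = kernel, no overlap) into
    ``kernel`` = (x, z) windows; each window contributes its SD, and the z
    tiles at the same x are averaged into a single curve point.
    """
    img = np.asarray(xz_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError("reslice must be 2-D (z, x)")
    kx, kz = kernel
    nz_px, nx_px = img.shape
    if nx_px < kx or nz_px < kz:
        raise ValidationError(f"image {img.shape} smaller than kernel (x={kx}, z={kz})")
    if np.ptp(img) == 0:
        filtered = np.zeros_like(img)
    else:
        filtered = difference_of_gaussians(img, low_sigma=band[0] / 2.0, high_sigma=band[1] / 2.0)
    n_x, n_z = nx_px // kx, nz_px // kz
    tiles = filtered[: n_z * kz, : n_x * kx].reshape(n_z, kz, n_x, kx)
    sd = tiles.std(axis=(1, 3))  # (n_z, n_x)
    return FocusContrastCurve(
        window_x_centers=(np.arange(n_x) + 0.5) * kx,
        sd_values=sd.mean(axis=0),
        kernel=(kx, kz),
    )


def find_inversion(curve1: FocusContrastCurve, curve2: FocusContrastCurve) -> int:
    """x pixel of the window boundary where the two SD curves invert.

    With several crossings, the one nearest the midpoint between the two
    curves' argmax positions wins (tie-break).  Indistinguishable stacks
    (no sign change) raise :class:`NoInversionError`.
    """
    if curve1.kernel != curve2.kernel or len(curve1.sd_values) != len(curve2.sd_values):
        raise ValidationError("curves must share kernel and window grid")
    d = curve1.sd_values - curve2.sd_values
    sign = np.sign(d)
    # a window with exactly equal SDs inherits the preceding sign so a
    # touch-without-crossing is not an inversion
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if crossings.size == 0:
        raise NoInversionError("focus contrast curves never invert; tiles are indistinguishable")
    kx = curve1.kernel[0]
    boundaries = (crossings + 1) * kx  # boundary between window i and i+1
    mid = 0.5 * (
        curve1.window_x_centers[int(np.argmax(curve1.sd_values))]
        + curve2.window_x_centers[int(np.argmax(curve2.sd_values))]
    )
    return int(boundaries[np.argmin(np.abs(boundaries - mid))])


def combine_tiles(
    stack1: ImageStack,
    stack2: ImageStack,
    result: TilingResult | int,
    overlap: int = 100,
    mode: str = "blend",
) -> ImageStack:
    """Fuse two focus-shifted stacks at the tiling coordinate.

    ``blend`` linearly ramps stack1→stack2 across ``overlap`` pixels
    centered on x_split; ``hard`` takes columns < x_split from stack1 and
    the rest from stack2 (the plain combine).
    """
    if stack1.shape != stack2.shape:
        raise FormatError(f"stacks not congruent: {stack1.shape} vs {stack2.shape}")
    if isinstance(result, TilingResult):
        x_split, overlap = result.x_split, result.overlap
    else:
        x_split = int(result)
    nx = stack1.shape[2]
    if not 0 <= x_split <= nx:
        raise ValidationError(f"x_split {x_split} outside image width {nx}")
    if mode == "hard":
        out = np.concatenate([stack1.voxels[:, :, :x_split], stack2.voxels[:, :, x_split:]], axis=2)
        return stack1.copy_with(out)
    if mode != "blend":
        raise ValidationError("mode must be 'blend' or 'hard'")
    half = overlap // 2
    if x_split - half < 0 or x_split + half > nx:
        raise ValidationError(
            f"overlap {overlap} around x_split {x_split} exceeds image width {nx}"
        )
    w2 = np.clip((np.arange(nx) - (x_split - half)) / max(overlap, 1), 0.0, 1.0)
    fused = stack1.voxels.astype(np.float64) * (1.0 - w2) + stack2.voxels.astype(np.float64) * w2
    if np.issubdtype(stack1.voxels.dtype, np.integer):
        fused = clamp_to_bit_depth(np.rint(fused).astype(np.int64), stack1.bit_depth)
    return stack1.copy_with(fused)


def fuse_pair(
    stack1: ImageStack,
    stack2: ImageStack,
    kernel: tuple[int, int] = (50, 100),
    band: tuple[float, float] = (3.0, 40.0),
    overlap: int = 100,
    mode: str = "blend",
    y_index: int | None = None,
) -> tuple[ImageStack, TilingResult]:
    """End-to-end pair fusion: reslice → contrast curves → inversion → combine.

    The reslice is the maximum projection over y by default (``y_index``
    selects a single x–z plane instead).  Multi-tile fusion chains this
    pairwise left-to-right.
    """
    def reslice(s: ImageStack) -> np.ndarray:
        v = s.voxels.astype(np.float64)
        return v[:, y_index, :] if y_index is not None else v.max(axis=1)

    c1 = focus_contrast(reslice(stack1), kernel, band)
    c2 = focus_contrast(reslice(stack2), kernel, band)
    x_split = find_inversion(c1, c2)
    result = TilingResult(x_split=x_split, curve1=c1, curve2=c2, overlap=overlap)
    # orient so the left-focused stack contributes the left side
    left_first = c1.sd_values.argmax() <= c2.sd_values.argmax()
    if left_first:
        fused = combine_tiles(stack1, stack2, result, mode=mode)
    else:
        fused = combine_tiles(stack2, stack1, result, mode=mode)
    return fused, result
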