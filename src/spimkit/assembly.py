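"""Movie-to-stack assembly and stack reshaping.

A continuous z-scan records an ``(x, y, t)`` movie; because the stage moves
at constant velocity, frame t sits at depth z = t × v_stage × exposure, so
the movie re-indexes bit-exactly into a ``(z, y, x)`` stack.  Camera
software splits movies at 1 GB, so parts are concatenated first.  Stacks
acquired from the opposite direction (180°) are brought into the 0° frame
by flipping z and mirroring x.  For deformable registration, stacks are
downsized 50% (or 25%) in xy by local averaging and one-in-k z-slice
subsampling.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import downscale_local_mean

from .errors import DegenerateInputError, FormatError, ValidationError
from .geometry import AcquisitionPlan
from .stacks import ImageStack, MovieStack

__all__ = [
    "concat_movie_parts",
    "movie_to_stack",
    "orient_opposite_view",
    "downsize_for_registration",
]


def concat_movie_parts(parts: list[MovieStack]) -> MovieStack:
    """Concatenate split movie files in list order.

    All parts must share frame shape, bit depth and exposure; the offending
    part index is named on mismatch.
    """
    if not parts:
        raise ValidationError("no movie parts given")
    first = parts[0]
    for i, p in enumerate(parts[1:], start=1):
        if p.frame_shape != first.frame_shape:
            raise FormatError(
                f"part {i}: frame shape {p.frame_shape} != {first.frame_shape} of part 0"
            )
        if p.bit_depth != first.bit_depth:
            raise FormatError(f"part {i}: bit depth {p.bit_depth} != {first.bit_depth} of part 0")
        if p.exposure != first.exposure:
            raise FormatError(f"part {i}: exposure {p.exposure} != {first.exposure} of part 0")
    frames = np.concatenate([p.frames for p in parts], axis=0)
    sources: list[str] = []
    for p in parts:
        sources.extend(p.source_files)
    return MovieStack(frames, first.exposure, first.bit_depth, sources)


def movie_to_stack(
    movie: MovieStack, plan: AcquisitionPlan, pixel_size: float = 3.45
) -> ImageStack:
    """Re-index an (t, y, x) movie as a (z, y, x) stack, bit-exact.

    dz = plan.z_interval; dy = dx = camera pixel size (µm).  Pixel values
    are never resampled.
    """
    if abs(movie.exposure - plan.exposure) > 1e-12:
        raise ValidationError(
            f"movie exposure {movie.exposure} s does not match plan exposure {plan.exposure} s"
        )
    return ImageStack(
        movie.frames.copy(),
        (plan.z_interval, pixel_size, pixel_size),
        movie.bit_depth,
    )


def orient_opposite_view(stack: ImageStack) -> ImageStack:
    """Map a 180°-acquisition stack into the 0° frame: flip z, mirror x.

    Involution: applying twice restores the original bit-exactly.
    """
    return stack.copy_with(stack.voxels[::-1, :, ::-1].copy())


def downsize_for_registration(
    stack: ImageStack, xy_factor: float = 0.5, z_keep_every: int = 4
) -> ImageStack:
    """Downsize for memory-bounded registration.

    xy is reduced by local-mean (area) pooling with block size 1/xy_factor;
    z keeps slices 0, k, 2k, ... literally.  Voxel sizes scale accordingly.
    """
    if xy_factor not in (1.0, 0.5, 0.25):
        raise ValidationError("xy_factor must be one of 1, 0.5, 0.25")
    if z_keep_every < 1:
        raise ValidationError("z_keep_every must be >= 1")
    block = int(round(1.0 / xy_factor))
    sub = stack.voxels[::z_keep_every]
    if sub.shape[0] < 1 or sub.shape[1] // block < 1 or sub.shape[2] // block < 1:
        raise DegenerateInputError("downsizing would produce an empty stack")
    # trim so xy divides evenly; local means then stay exact block averages
    ny = (sub.shape[1] // block) * block
    nx = (sub.shape[2] // block) * block
    small = downscale_local_mean(sub[:, :ny, :nx].astype(np.float64), (1, block, block))
    if np.issubdtype(stack.voxels.dtype, np.integer):
        small = np.rint(small).astype(stack.voxels.dtype)
    dz, dy, dx = stack.voxel_size
    return ImageStack(small, (dz * z_keep_every, dy * block, dx * block), stack.bit_depth)
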