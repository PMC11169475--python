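"""Flat-field correction of the Gaussian illumination fall-off along y.

A cylindrical-lens sheet is brightest at its vertical center and dims
toward the top and bottom rows.  A reference image of a homogeneous dye
solution (e.g. 1 µM fluorescein in the clearing reagent) captures that
fall-off; its per-row medians m(y) yield dimensionless gain coefficients
c(y) = max_y m / m(y) that, multiplied into every slice of a sample stack,
equalize intensities along y.  The coefficients are ratios, so a 12-bit
reference corrects an 8-bit stack without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .stacks import ImageStack, clamp_to_bit_depth

__all__ = ["FlatFieldModel", "fit_flatfield", "apply_flatfield"]


@dataclass
class FlatFieldModel:
    """Per-row median profile and the gain coefficients derived from it."""

    median_profile: np.ndarray  # m(y), reference intensity units
    coefficients: np.ndarray  # c(y) = max m / m(y), dimensionless, >= 1

    def __len__(self) -> int:
        return len(self.coefficients)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y": np.arange(len(self.coefficients)),
                "median": self.median_profile,
                "coefficient": self.coefficients,
            }
        )


def fit_flatfield(reference: np.ndarray) -> FlatFieldModel:
    """Build the correction model from a dye-solution reference image.

    A zero (or negative) row median makes the gain undefined and raises
    :class:`DegenerateInputError` naming the first offending row.
    """
    ref = np.asarray(reference, dtype=np.float64)
    if ref.ndim != 2:
        raise ValidationError("reference must be a single 2-D image")
    medians = np.median(ref, axis=1)
    peak = medians.max()
    if peak <= 0:
        raise DegenerateInputError("reference image has no positive row median")
    bad = np.flatnonzero(medians <= 0)
    if bad.size:
        raise DegenerateInputError(f"zero row median at y={int(bad[0])}: gain undefined")
    return FlatFieldModel(median_profile=medians, coefficients=peak / medians)


def apply_flatfield(stack: ImageStack, model: FlatFieldModel) -> ImageStack:
    """Multiply every voxel at row y by c(y); clamp to the bit-depth range.

    z and x are untouched.  Integer input is rounded back to its storage
    dtype; float input stays float (clip only), which keeps the operation
    exactly linear for headroom-safe data.
    """
    if stack.shape[1] != len(model):
        raise ValidationError(
            f"stack height {stack.shape[1]} does not match model length {len(model)}"
        )
    corrected = stack.voxels.astype(np.float64) * model.coefficients[None, :, None]
    if np.issubdtype(stack.voxels.dtype, np.integer):
        out = clamp_to_bit_depth(np.rint(corrected).astype(np.int64), stack.bit_depth)
    else:
        out = clamp_to_bit_depth(corrected, stack.bit_depth)
    return stack.copy_with(out)
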