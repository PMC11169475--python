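"""Registration quality metrics and integer z-shift correction.

Two replicate stacks of the same sample (e.g. opposite-direction
acquisitions after deformable registration) are compared slice by slice
with two complementary similarity scores:

* normalized mutual information,
  MI(X,Y) = H(X) + H(Y) − H(X,Y),  nMI = MI / sqrt(H(X)·H(Y)),
  from the joint intensity histogram (entropies in bits);
* zero-mean normalized cross-correlation,
  ZNCC = Σ(X−µX)(Y−µY) / sqrt(Σ(X−µX)² · Σ(Y−µY)²).

Residual misalignment along the scan axis is estimated as the integer
z-shift maximizing the mean ZNCC over overlapping slices, and corrected by
crop/pad.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ValidationError
from .stacks import ImageStack

__all__ = [
    "MIResult",
    "ZShift",
    "mutual_information",
    "zncc",
    "metric_profile",
    "estimate_z_shift",
    "apply_z_shift",
]


class MIResult(NamedTuple):
    mi: float  # bits
    mi_normalized: float  # dimensionless; NaN for degenerate (constant) slices
    entropy_x: float
    entropy_y: float
    joint_entropy: float


class ZShift(NamedTuple):
    shift: int  # slices (positive: B lags A)
    score: float  # mean ZNCC at the best shift, for gating


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return max(float(-(p * np.log2(p)).sum()), 0.0)  # guard float cancellation


def mutual_information(slice_x: np.ndarray, slice_y: np.ndarray, bins: int = 256) -> MIResult:
    """Normalized MI of two congruent slices from their joint histogram.

    256 bins align with 8-bit intensity levels.  A constant slice has zero
    entropy; its normalized MI is undefined and returned as NaN (the raw MI,
    zero, is still reported).
    """
    x = np.asarray(slice_x, dtype=np.float64).ravel()
    y = np.asarray(slice_y, dtype=np.float64).ravel()
    if x.size == 0 or x.size != y.size:
        raise ValidationError("slices must be congruent and non-empty")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    h_x = _entropy_bits(pxy.sum(axis=1))
    h_y = _entropy_bits(pxy.sum(axis=0))
    h_xy = _entropy_bits(pxy.ravel())
    mi = max(h_x + h_y - h_xy, 0.0)
    if h_x == 0 or h_y == 0:
        return MIResult(mi, np.nan, h_x, h_y, h_xy)
    return MIResult(mi, mi / np.sqrt(h_x * h_y), h_x, h_y, h_xy)


def zncc(slice_x: np.ndarray, slice_y: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation in [−1, 1].

    The denominator carries the square root of the product of the two sum
    of squares, making the score exactly 1 for identical inputs and
    invariant under positive affine intensity rescaling.
    """
    x = np.asarray(slice_x, dtype=np.float64).ravel()
    y = np.asarray(slice_y, dtype=np.float64).ravel()
    if x.size == 0 or x.size != y.size:
        raise ValidationError("slices must be congruent and non-empty")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0:
        raise DegenerateInputError("zero-variance slice: ZNCC undefined")
    return float((dx @ dy) / denom)


def metric_profile(stack_a: ImageStack, stack_b: ImageStack, bins: int = 256) -> pd.DataFrame:
    """Both metrics for every corresponding z-slice pair.

    Degenerate (constant) slices get ``valid=False`` and NaN metrics; the
    caller's summaries should aggregate over valid rows only (as
    ``summarize_metrics`` does).
    """
    if stack_a.shape != stack_b.shape:
        raise FormatError(f"stacks not congruent: {stack_a.shape} vs {stack_b.shape}")
    rows = []
    for z in range(stack_a.shape[0]):
        xa, xb = stack_a.voxels[z], stack_b.voxels[z]
        res = mutual_information(xa, xb, bins)
        try:
            zn = zncc(xa, xb)
        except DegenerateInputError:
            zn = np.nan
        rows.append(
            {
                "z": z,
                "entropy_x": res.entropy_x,
                "entropy_y": res.entropy_y,
                "joint_entropy": res.joint_entropy,
                "mean_x": float(np.mean(xa)),
                "mean_y": float(np.mean(xb)),
                "mi": res.mi,
                "mi_normalized": res.mi_normalized,
                "zncc": zn,
                "valid": np.isfinite(res.mi_normalized) and np.isfinite(zn),
            }
        )
    return pd.DataFrame(rows)


def summarize_metrics(profile: pd.DataFrame) -> dict:
    """Mean and min of each metric over valid slices."""
    valid = profile[profile["valid"]]
    if valid.empty:
        raise DegenerateInputError("no valid slices to summarize")
    return {
        "mi_normalized_mean": float(valid["mi_normalized"].mean()),
        "mi_normalized_min": float(valid["mi_normalized"].min()),
        "zncc_mean": float(valid["zncc"].mean()),
        "zncc_min": float(valid["zncc"].min()),
        "n_valid": int(len(valid)),
    }


def estimate_z_shift(stack_a: ImageStack, stack_b: ImageStack, max_shift: int = 10) -> ZShift:
    """Integer z-shift of B relative to A maximizing mean ZNCC over the
    overlapping slices.

    Ties prefer the smaller |shift|.  The score is returned so callers can
    gate on it (a maximum is always found, even for unrelated stacks).
    """
    if stack_a.shape != stack_b.shape:
        raise FormatError("stacks must be congruent")
    nz = stack_a.shape[0]
    if not 0 <= max_shift < nz:
        raise ValidationError("|max_shift| must be smaller than the stack depth")
    best: ZShift | None = None
    for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
        # convention: B[z] ≈ A[z − shift], i.e. B is A displaced by +shift;
        # apply_z_shift(B, −shift) realigns B to A
        if shift >= 0:
            a_sl, b_sl = stack_a.voxels[: nz - shift], stack_b.voxels[shift:]
        else:
            a_sl, b_sl = stack_a.voxels[-shift:], stack_b.voxels[:shift]
        if len(a_sl) == 0:
            raise DegenerateInputError("empty overlap at requested shift")
        scores = []
        for za, zb in zip(a_sl, b_sl):
            try:
                scores.append(zncc(za, zb))
            except DegenerateInputError:
                continue
        if not scores:
            continue
        mean_score = float(np.mean(scores))
        if best is None or mean_score > best.score:
            best = ZShift(shift, mean_score)
    if best is None:
        raise DegenerateInputError("all slice pairs degenerate; cannot estimate shift")
    return best


def apply_z_shift(stack: ImageStack, shift: int, pad_value: int = 0) -> ImageStack:
    """Shift a stack along z by an integer number of slices (crop + pad).

    Positive shift moves content toward larger z.
    """
    out = np.full_like(stack.voxels, pad_value)
    if shift >= 0:
        out[shift:] = stack.voxels[: stack.shape[0] - shift]
    else:
        out[:shift] = stack.voxels[-shift:]
    return stack.copy_with(out)
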