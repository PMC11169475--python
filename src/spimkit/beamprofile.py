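"""Light-sheet shape metrology: focal FWHM, Rayleigh length and eFOV.

A static sheet formed by a cylindrical lens thins to a waist and re-expands
along the propagation axis x.  The sheet thickness at each x is measured as
the FWHM of a Gaussian fit to the axial intensity profile.  The Rayleigh
length z_R is the propagation distance over which the fitted thickness
grows by √2 from its minimum; because spherical aberration makes measured
curves asymmetric, FWHM(x) is fitted with an unconstrained 5th-order
polynomial and the √2 crossings are solved on the fit, one per side.  The
effective field of view is eFOV = 2 × z_R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit, minimize_scalar

from .errors import FitError, ValidationError

__all__ = ["BeamProfile", "LightSheetFit", "profile_fwhm", "fit_beam", "efov_in_medium"]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass
class BeamProfile:
    """Measured sheet thickness along the propagation axis."""

    x_positions: np.ndarray  # µm, strictly increasing
    fwhm_values: np.ndarray  # µm

    def __post_init__(self) -> None:
        self.x_positions = np.asarray(self.x_positions, dtype=float)
        self.fwhm_values = np.asarray(self.fwhm_values, dtype=float)
        if self.x_positions.shape != self.fwhm_values.shape or self.x_positions.ndim != 1:
            raise ValidationError("x_positions and fwhm_values must be matching 1-D arrays")
        if np.any(np.diff(self.x_positions) <= 0):
            raise ValidationError("x_positions must be strictly increasing")
        if np.any(self.fwhm_values <= 0):
            raise ValidationError("fwhm values must be positive")


@dataclass
class LightSheetFit:
    """Result of the polynomial beam fit."""

    fwhm0: float  # µm, minimum fitted thickness
    focus_x: float  # µm
    rayleigh_length: float  # µm
    efov: float  # µm, = 2 × rayleigh_length
    poly_coeffs: np.ndarray  # 6 coefficients, highest power first (np.polyval order)
    half_width_left: float = np.nan  # µm, one-sided √2 half-widths
    half_width_right: float = np.nan


def _gaussian(x, amp, center, sigma, offset):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def profile_fwhm(intensity_profile: np.ndarray, pixel_size: float = 1.0) -> float:
    """FWHM (µm) of a 1-D intensity profile by least-squares Gaussian fit.

    Fits amplitude/center/sigma/offset around the central peak; the profile
    must have a strict interior maximum and the fitted center must lie
    inside the window, otherwise :class:`FitError` is raised.
    """
    y = np.asarray(intensity_profile, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise FitError("profile must be 1-D with at least 5 samples")
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    i_max = int(np.argmax(y))
    if i_max in (0, y.size - 1) or y.max() <= y.min():
        raise FitError("profile has no strict interior maximum")
    x = np.arange(y.size, dtype=float)
    amp0 = y.max() - y.min()
    # moment-based sigma start: half-max crossing width estimate
    above = y >= y.min() + amp0 / 2
    sigma0 = max(above.sum() / FWHM_PER_SIGMA, 0.5)
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=(amp0, i_max, sigma0, y.min()),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - curve_fit convergence
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, center, sigma, _ = popt
    if not 0 <= center <= y.size - 1:
        raise FitError(f"fitted center {center:.2f} outside the profile window")
    if amp <= 0 or not np.isfinite(sigma):
        raise FitError("fit collapsed (non-positive amplitude or invalid width)")
    return abs(sigma) * FWHM_PER_SIGMA * pixel_size


def fit_beam(profile: BeamProfile) -> LightSheetFit:
    """Fit FWHM(x) with a 5th-order polynomial and derive z_R and eFOV.

    The polynomial is deliberately unconstrained (no symmetry assumption),
    so aberrated, asymmetric beams are handled.  z_R is the mean of the two
    one-sided distances from the focus to where the fitted thickness
    reaches √2 × its minimum; a side whose crossing falls outside the data
    range raises :class:`FitError` (extrapolation is refused).
    """
    x, w = profile.x_positions, profile.fwhm_values
    if x.size < 7:
        raise ValidationError("need at least 7 points spanning the focus")
    coeffs = np.polyfit(x, w, 5)
    poly = np.poly1d(coeffs)

    grid = np.linspace(x[0], x[-1], 4001)
    vals = poly(grid)
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    if lo < hi:
        res = minimize_scalar(poly, bounds=(lo, hi), method="bounded")
        focus_x = float(res.x)
    else:  # minimum at a data-range edge
        focus_x = float(grid[i0])
    fwhm0 = float(poly(focus_x))
    if fwhm0 <= 0:
        raise FitError("fitted minimum thickness is non-positive")
    target = np.sqrt(2.0) * fwhm0

    def crossing(side: int) -> float:
        """Distance from focus to the first √2 crossing on one side."""
        g = grid[grid > focus_x] if side > 0 else grid[grid < focus_x][::-1]
        above = poly(g) >= target
        if not above.any():
            raise FitError(
                "no sqrt(2) enlargement inside the data range on the "
                f"{'right' if side > 0 else 'left'} side; measure further from focus"
            )
        j = int(np.argmax(above))
        a, b = (g[j - 1], g[j]) if j > 0 else (focus_x, g[0])
        root = brentq(lambda t: poly(t) - target, min(a, b), max(a, b))
        return abs(root - focus_x)

    half_r = crossing(+1)
    half_l = crossing(-1)
    z_r = 0.5 * (half_l + half_r)
    return LightSheetFit(
        fwhm0=fwhm0,
        focus_x=focus_x,
        rayleigh_length=z_r,
        efov=2.0 * z_r,
        poly_coeffs=coeffs,
        half_width_left=half_l,
        half_width_right=half_r,
    )


def efov_in_medium(efov_air: float, n: float) -> float:
    """Convert an in-air eFOV to the clearing medium: the higher refractive
    index elongates the Rayleigh length by the factor n.  Exposed as an
    explicit converter, never applied silently."""
    if efov_air < 0:
        raise ValidationError("eFOV must be non-negative")
    if n < 1:
        raise ValidationError(f"refractive index {n} < 1 is non-physical")
    return efov_air * n
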