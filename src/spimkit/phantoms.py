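"""Synthetic phantoms with known ground truth for every downstream module.

The generators emulate the data a cuvette light-sheet instrument produces:

* **bead stacks** — sub-resolution fluorescent spheres in gel, blurred by an
  anisotropic PSF whose axial width follows the Gaussian-beam law
  ``FWHM(x) = FWHM0 · sqrt(1 + ((x − focus_x)/z_R)²)`` along the sheet
  propagation axis x, plus Poisson shot noise and Gaussian read noise;
* **illumination references** — the Gaussian y-fall-off of a cylindrical-lens
  sheet imaged in a homogeneous dye solution (flat-field references);
* **vessel/drug masks** — 2-D binary channels: tubular vessels and a drug
  halo produced by dilating each vessel by a known radius;
* **tiling pairs** — the same nuclei volume rendered with the sheet focused
  at two different x positions, for focus-fusion testing.

Every generator is deterministic for a fixed seed and returns a truth
manifest sufficient to score its downstream consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, gaussian_filter1d
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .errors import ValidationError
from .stacks import ImageStack, bit_depth_max

__all__ = [
    "PhantomTruth",
    "gen_bead_stack",
    "gen_illumination_profile",
    "gen_vessel_drug_masks",
    "gen_tls_pair",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomTruth:
    """Ground-truth manifest written alongside every generated phantom."""

    object_kind: str  # bead | nucleus | vessel | drug_halo
    centers: np.ndarray  # (N, 3) µm, (z, y, x)
    radii: np.ndarray  # (N,) µm
    psf_lateral_fwhm: float  # µm
    psf_axial_fwhm_at_focus: float  # µm
    focus_x: float  # µm
    rayleigh_length: float  # µm
    illum_sigma_y: float  # µm
    seed: int
    extras: dict = field(default_factory=dict)

    def axial_fwhm_at(self, x_um: float | np.ndarray) -> np.ndarray:
        """Gaussian-beam axial FWHM at propagation position x (µm)."""
        u = (np.asarray(x_um, dtype=float) - self.focus_x) / self.rayleigh_length
        return self.psf_axial_fwhm_at_focus * np.sqrt(1.0 + u * u)

    def as_dict(self) -> dict:
        return {
            "object_kind": self.object_kind,
            "centers_um": np.asarray(self.centers).tolist(),
            "radii_um": np.asarray(self.radii).tolist(),
            "psf_lateral_fwhm_um": self.psf_lateral_fwhm,
            "psf_axial_fwhm_at_focus_um": self.psf_axial_fwhm_at_focus,
            "focus_x_um": self.focus_x,
            "rayleigh_length_um": self.rayleigh_length,
            "illum_sigma_y_um": self.illum_sigma_y,
            "seed": self.seed,
            **self.extras,
        }


def _sample_centers(
    rng: np.random.Generator,
    n: int,
    extent_um: np.ndarray,
    margin_um: np.ndarray,
    min_spacing_um: float | None,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform centers inside [margin, extent - margin], optionally spaced."""
    lo, hi = margin_um, extent_um - margin_um
    if np.any(hi <= lo):
        raise ValidationError("volume too small for the requested margins")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        c = rng.uniform(lo, hi)
        if min_spacing_um and centers:
            d = np.linalg.norm(np.asarray(centers) - c, axis=1)
            if d.min() < min_spacing_um:
                continue
        centers.append(c)
    return np.asarray(centers)


def _variable_axial_blur(
    vol: np.ndarray, dz: float, dx: float, fwhm0: float, focus_x: float, z_r: float
) -> np.ndarray:
    """Blur along z with a sigma that depends on the x position of each column.

    Applied column-by-column so each object's axial width is set by the beam
    thickness at its own x, per the Gaussian-beam law.
    """
    out = np.empty_like(vol)
    for ix in range(vol.shape[2]):
        x_um = ix * dx
        fwhm = fwhm0 * np.sqrt(1.0 + ((x_um - focus_x) / z_r) ** 2)
        out[:, :, ix] = gaussian_filter1d(
            vol[:, :, ix], sigma=fwhm * _FWHM_TO_SIGMA / dz, axis=0, mode="constant"
        )
    return out


def _rasterize_spheres(
    shape: tuple[int, int, int],
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    amplitudes: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Additively rasterize spheres; sub-voxel spheres become single-voxel
    deposits scaled by amplitude (a point source on this grid)."""
    vol = np.zeros(shape, dtype=np.float64)
    vs = np.asarray(voxel_size)
    for c, r, a in zip(centers_um, radii_um, amplitudes):
        half = np.maximum(np.ceil(r / vs).astype(int), 0)
        idx = np.rint(c / vs).astype(int)
        if r <= vs.min() / 2:  # sub-voxel sphere: a point source on this grid
            iz, iy, ix = np.clip(idx, 0, np.asarray(shape) - 1)
            vol[iz, iy, ix] += a
            continue
        lo = np.maximum(idx - half - 1, 0)
        hi = np.minimum(idx + half + 2, shape)
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]) * vs[0],
            np.arange(lo[1], hi[1]) * vs[1],
            np.arange(lo[2], hi[2]) * vs[2],
            indexing="ij",
        )
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
        vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += a * inside
    return vol


def _add_noise(
    signal: np.ndarray, snr: float | None, rng: np.random.Generator, read_noise_frac: float = 0.2
) -> np.ndarray:
    """Poisson shot noise + additive Gaussian read noise.

    ``snr`` is the peak signal-to-noise ratio: the peak is scaled to snr²
    photons so its shot noise is peak/snr; read noise adds a further
    ``read_noise_frac × snr`` counts of Gaussian noise.  ``None`` disables
    noise entirely.
    """
    if snr is None:
        return signal
    if snr <= 0:
        raise ValidationError("snr must be positive (or None for noise-free)")
    peak = signal.max()
    if peak <= 0:
        return signal
    photons = signal / peak * snr**2
    noisy = rng.poisson(photons).astype(np.float64)
    noisy += rng.normal(0.0, read_noise_frac * snr, size=signal.shape)
    return np.clip(noisy, 0, None) / (snr**2) * peak


def _quantize(signal: np.ndarray, bit_depth: int, headroom: float = 0.8) -> np.ndarray:
    hi = bit_depth_max(bit_depth)
    peak = signal.max()
    if peak <= 0:
        return np.zeros_like(signal, dtype=np.uint8 if bit_depth == 8 else np.uint16)
    img = np.rint(signal / peak * headroom * hi)
    return np.clip(img, 0, hi).astype(np.uint8 if bit_depth == 8 else np.uint16)


def gen_bead_stack(
    shape: tuple[int, int, int] = (40, 64, 96),
    voxel_size: tuple[float, float, float] = (3.0, 3.45, 3.45),
    n_beads: int = 40,
    bead_radius_um: float = 0.5,
    fwhm_lateral_um: float = 4.4,
    fwhm_axial_um: float = 7.2,
    focus_x_um: float | None = None,
    rayleigh_length_um: float = 450.0,
    min_spacing_um: float | None = 20.0,
    snr: float | None = 30.0,
    bit_depth: int = 8,
    seed: int = 0,
    centers_um: Sequence | None = None,
    blur: bool = True,
    stripe_contrast: float = 0.0,
    stripe_period_um: float = 40.0,
) -> tuple[ImageStack, PhantomTruth]:
    """Sub-resolution bead-in-gel stack with a defocus-dependent axial PSF.

    Defaults emulate the fine-axial imaging regime: 3.45 µm lateral pixels,
    3 µm z-steps, Φ1 µm beads sparse enough (20 µm spacing, the dilute
    suspension case) that single-bead profiles dominate, axial FWHM 7.2 µm
    at focus and lateral FWHM 4.4 µm.  The default peak SNR of 30 is the
    bright-bead regime (near-saturation 8-bit counts); the smallest-N
    selection rule assumes measurement noise is small against the
    contamination effects it guards, which holds here but not for very dim
    beads (see the methods note).
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(voxel_size)
    extent = np.asarray(shape) * vs
    rejected = 0
    if centers_um is None:
        margin = np.asarray([3 * fwhm_axial_um, 2 * fwhm_lateral_um, 2 * fwhm_lateral_um])
        centers = _sample_centers(rng, n_beads, extent, margin, min_spacing_um)
    else:
        centers = np.asarray(centers_um, dtype=float).reshape(-1, 3)
        keep = np.all((centers >= 0) & (centers < extent), axis=1)
        rejected = int((~keep).sum())
        centers = centers[keep]
    amplitudes = rng.uniform(0.7, 1.0, size=len(centers))
    radii = np.full(len(centers), bead_radius_um)
    vol = _rasterize_spheres(shape, centers, radii, amplitudes, voxel_size)
    focus_x = extent[2] / 2 if focus_x_um is None else focus_x_um
    if blur:
        vol = _variable_axial_blur(vol, vs[0], vs[2], fwhm_axial_um, focus_x, rayleigh_length_um)
        lat_sigma = fwhm_lateral_um * _FWHM_TO_SIGMA
        vol = gaussian_filter(vol, sigma=(0, lat_sigma / vs[1], lat_sigma / vs[2]), mode="constant")
    if stripe_contrast > 0:
        # shadow bands cast along the propagation axis: attenuation varies
        # with y, constant along x (the instrument's acknowledged artifact)
        y_um = np.arange(shape[1]) * vs[1]
        atten = 1.0 - stripe_contrast * (0.5 + 0.5 * np.sin(2 * np.pi * y_um / stripe_period_um))
        vol = vol * atten[None, :, None]
    vol = _add_noise(vol, snr, rng)
    stack = ImageStack(_quantize(vol, bit_depth), voxel_size, bit_depth)
    truth = PhantomTruth(
        object_kind="bead",
        centers=centers,
        radii=radii,
        psf_lateral_fwhm=fwhm_lateral_um,
        psf_axial_fwhm_at_focus=fwhm_axial_um,
        focus_x=focus_x,
        rayleigh_length=rayleigh_length_um,
        illum_sigma_y=np.inf,
        seed=seed,
        extras={"rejected_outside": rejected, "snr": snr, "blurred": blur},
    )
    return stack, truth


def gen_illumination_profile(
    shape: tuple[int, int] = (256, 256),
    illum_sigma_y: float = 400.0,
    peak: float = 3000.0,
    peak_row: int | None = None,
    pixel_size_um: float = 3.45,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Dye-solution reference image: Gaussian fall-off along y, flat along x.

    Emulates imaging a homogeneous fluorescein solution with a cylindrical
    lens sheet (the flat-field reference), optionally with Gaussian noise.
    """
    if illum_sigma_y <= 0:
        raise ValidationError("illum_sigma_y must be positive")
    h, w = shape
    y0 = (h - 1) / 2 if peak_row is None else peak_row
    y_um = (np.arange(h) - y0) * pixel_size_um
    profile = peak * np.exp(-0.5 * (y_um / illum_sigma_y) ** 2)
    img = np.tile(profile[:, None], (1, w))
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, None)


def gen_vessel_drug_masks(
    shape: tuple[int, int] = (256, 256),
    n_vessels: int = 3,
    vessel_radius_px: int = 3,
    halo_radius_px: float | Sequence[float] = 12,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-slice vessel and drug-halo masks with known halo radii.

    Each vessel is a random polyline dilated to a tube; the drug mask is the
    union of per-vessel dilations of the same centerlines by
    ``vessel_radius + halo_radius``, so the drug boundary sits a known
    distance from the vessel boundary.  Returns (vessel_mask, drug_mask,
    truth) where truth lists each vessel's nominal halo radius.
    """
    if len(shape) != 2:
        raise ValidationError("vessel/drug masks are per-MIP-slice 2-D")
    rng = np.random.default_rng(seed)
    halos = np.broadcast_to(np.asarray(halo_radius_px, dtype=float), (n_vessels,)).copy()
    vessel = np.zeros(shape, dtype=bool)
    drug = np.zeros(shape, dtype=bool)
    margin = vessel_radius_px + (int(np.ceil(halos.max())) if n_vessels else 0) + 2
    truth: dict = {"halo_radius_px": halos.tolist(), "centerlines": [], "seed": seed}
    for i in range(n_vessels):
        n_seg = rng.integers(2, 5)
        pts = [rng.integers(margin, np.asarray(shape) - margin, size=2)]
        for _ in range(n_seg):
            step = rng.integers(-60, 61, size=2)
            nxt = np.clip(pts[-1] + step, margin, np.asarray(shape) - margin - 1)
            pts.append(nxt)
        centerline = np.zeros(shape, dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
            centerline[rr, cc] = True
        vessel |= binary_dilation(centerline, structure=disk(vessel_radius_px))
        drug |= binary_dilation(centerline, structure=disk(int(round(vessel_radius_px + halos[i]))))
        truth["centerlines"].append([p.tolist() for p in pts])
    return vessel, drug, truth


def gen_tls_pair(
    shape: tuple[int, int, int] = (120, 32, 300),
    voxel_size: tuple[float, float, float] = (3.0, 3.45, 3.45),
    n_nuclei: int = 160,
    nucleus_radius_um: float = 5.0,
    fwhm_axial_um: float = 7.2,
    fwhm_lateral_um: float = 4.4,
    rayleigh_length_um: float = 150.0,
    focus_x1_um: float | None = None,
    focus_x2_um: float | None = None,
    snr: float | None = 20.0,
    bit_depth: int = 8,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, dict]:
    """Same nuclei volume rendered with the sheet focused at two x positions.

    Emulates the tiling acquisition: the cylindrical lens is translated so
    the thin waist sits at ``focus_x1`` for the first stack and ``focus_x2``
    for the second.  Truth records both foci and their midpoint (µm and px).
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(voxel_size)
    extent = np.asarray(shape) * vs
    f1 = extent[2] * 0.3 if focus_x1_um is None else focus_x1_um
    f2 = extent[2] * 0.7 if focus_x2_um is None else focus_x2_um
    margin = np.asarray([3 * nucleus_radius_um, nucleus_radius_um, nucleus_radius_um])
    centers = _sample_centers(rng, n_nuclei, extent, margin, min_spacing_um=None)
    radii = rng.uniform(0.8, 1.2, size=len(centers)) * nucleus_radius_um
    amps = rng.uniform(0.6, 1.0, size=len(centers))
    base = _rasterize_spheres(shape, centers, radii, amps, voxel_size)
    lat_sigma = fwhm_lateral_um * _FWHM_TO_SIGMA
    stacks = []
    for focus in (f1, f2):
        vol = _variable_axial_blur(base, vs[0], vs[2], fwhm_axial_um, focus, rayleigh_length_um)
        vol = gaussian_filter(vol, sigma=(0, lat_sigma / vs[1], lat_sigma / vs[2]), mode="constant")
        # same noise stream for both foci: equal foci then yield identical stacks
        vol = _add_noise(vol, snr, np.random.default_rng([seed, 7]))
        stacks.append(ImageStack(_quantize(vol, bit_depth), voxel_size, bit_depth))
    truth = {
        "focus_x1_um": f1,
        "focus_x2_um": f2,
        "midpoint_um": (f1 + f2) / 2,
        "focus_x1_px": f1 / vs[2],
        "focus_x2_px": f2 / vs[2],
        "midpoint_px": (f1 + f2) / 2 / vs[2],
        "centers_um": centers.tolist(),
        "seed": seed,
    }
    return stacks[0], stacks[1], truth
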