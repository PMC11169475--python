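# Methods

This note documents the models, algorithms and numerical choices behind
spimkit, module by module, together with what the synthetic phantoms do and
do not emulate.

## Acquisition geometry (`geometry`)

A cuvette SPIM images a cleared sample immersed in a refractive-index-matched
medium while the detection objective stays in air. The detection focal length
is a sum of per-segment optical path lengths, f = Σ D_i / n_i. Moving the
sample by dz_sample inside the medium (index n) while moving the detection
optics by dz_detect in air leaves f unchanged exactly when
dz_detect = (n − 1)/n · dz_sample. This ratio — the synchronous speed
correction — is 0.342 at n = 1.52 (CUBIC-R class media) and 0.359 at n = 1.56
(BABB/ECi). Continuous scanning at stage velocities in this ratio keeps the
focal plane on the camera during the whole z-scan; the z-interval of the
resulting stack is v_stage × exposure.

Real actuators under load deviate from theory, so every planning function
accepts a *calibrated* correction that overrides (n − 1)/n when supplied
(e.g. 17.3/50 = 0.346 measured on an instrument). The calibration procedure
itself is instrument-side and out of scope; the toolkit treats the value as
an externally supplied constant. Units are µm and seconds internally; the
CLI accepts mm for travel-scale lengths.

One deliberate interpretation: for a 10 mm stage travel at a 50 : 17.3
velocity ratio the *detection-path* travel is 10 × 17.3/50 = 3.46 mm. We
compute it as stage_travel × velocity ratio and label it `detect_travel`,
which is the only dimensionally consistent reading. Similarly, `z_range` is
always n_frames × z_interval; we never report a nominal travel figure that
disagrees with the frame arithmetic.

## Stack assembly (`assembly`)

The axis convention is fixed throughout: stacks are (z, y, x), movies
(t, y, x), 0-based, z increasing along stage travel. Movie-to-stack
conversion is a pure re-indexing (bit-exact; the pixel-value multiset is
preserved). Opposite-direction (180°) stacks are mapped into the 0° frame by
reversing z and mirroring x — an involution. Registration downsizing uses
local-mean (area) pooling in xy (blocks of 2 or 4) and literal one-in-k
slice subsampling in z, because subsampled z-slices must remain acquired
planes. 8-bit arithmetic clamps to [0, 255] rather than rescaling, keeping
the output contract of the 8-bit acquisition path.

## Synthetic phantoms (`phantoms`)

The generators provide ground truth for every downstream module. All are
deterministic per seed (byte-identical output) and emit a truth manifest.

**Bead stacks.** Sub-resolution spheres are rasterized (a sphere smaller
than half a voxel becomes a single-voxel point source), blurred axially
column-by-column with a sigma following the Gaussian-beam law
FWHM(x) = FWHM0 √(1 + ((x − focus_x)/z_R)²), then blurred laterally with a
constant sigma. Defaults are the fine-axial imaging regime: 3.45 µm lateral
pixels, 3 µm z-steps, FWHM0 = 7.2 µm axial and 4.4 µm lateral, z_R = 450 µm,
40 beads with ≥ 20 µm spacing in a 40×64×96-voxel volume
(≈ 0.12 × 0.22 × 0.33 mm³). The volume size was chosen so each phantom
yields "dozens" of measurable beads while generation stays sub-second;
nothing downstream depends on the absolute volume.

**Noise model.** Poisson shot noise plus Gaussian read noise; `snr` is the
*peak* signal-to-shot-noise ratio (the peak maps to snr² expected photons).
The default snr = 30 models bright beads recorded near 8-bit saturation.
This matters for the smallest-N rule (below): an unweighted Gaussian fit to
an axial profile sampled at 3 µm with a 100-photon peak (snr = 10) has an
irreducible per-fit scatter of ≈ 0.5 µm — at that scatter, selecting the 10
smallest of ~40 values is dominated by noise ordering and biases the
summary low by ~0.6 µm. At snr = 30 the scatter is ≈ 0.17 µm and the
selection rule behaves as intended (residual bias ≈ −0.2 µm). Tests cover
both regimes: the all-beads mean is unbiased even at snr = 10; the
smallest-10 summary is validated in the bright-bead regime.

**What the phantoms do not emulate:** stripe shadows (an optional
multiplicative attenuation flag exists but is off by default), scattering,
depth-dependent aberration, spectral bleed-through, or sub-voxel PSF
structure. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated optical model, not instrument performance on
tissue.

**Illumination references** are separable: a Gaussian fall-off along y,
constant along x, plus optional Gaussian noise — the idealized dye-cuvette
image. Real references also carry x-attenuation, which the flat-field model
deliberately ignores (multi-directional acquisition handles x).

**Vessel/drug masks** are random polylines dilated to tubes
(vessel radius 3 px) and halos (vessel + halo radius, default 12 px). Disk
dilation makes the drug boundary sit at a known Euclidean distance from the
vessel boundary, so the pooled 95th-percentile distance should recover the
halo radius. Euclidean disks on a pixel grid quantize the boundary by up to
~1 px, which bounds the achievable agreement.

**Tiling pairs** render the same nuclei volume (spheres of ~5 µm radius)
under two focus positions with z_R = 150 µm over a 300-column (≈ 1 mm)
field, giving a strong sharpness gradient; the two stacks share one noise
stream so equal foci produce identical stacks.

## Beam-shape metrology (`beamprofile`)

Per-position sheet thickness comes from a 4-parameter Gaussian fit
(amplitude, center, sigma, offset) of the axial intensity profile; FWHM =
2√(2 ln 2) σ. Fits are rejected (never silently coerced) when the profile
has no strict interior maximum or the fitted center leaves the window.

FWHM(x) is fitted with an unconstrained 5th-order polynomial because
measured curves are asymmetric under spherical aberration. The focus is the
polynomial's minimum inside the data range (grid scan + bounded
refinement); the √2 · FWHM0 crossing is bracketed on a 4001-point grid and
solved with Brent's method on each side independently. The Rayleigh length
is the mean of the two one-sided half-widths, and eFOV = 2 z_R by
definition. A side with no crossing inside the data range raises an error —
extrapolating a degree-5 polynomial is meaningless, and the measurement
protocol (sample out to the √2 points) guarantees coverage. Conversion of
an in-air eFOV to the medium (× n) is an explicit function, never applied
implicitly. Recovery on exact Gaussian-beam hyperbolas sampled at the 0.1 mm
(fine-axial) and 1 mm (full-FOV) regimes is within 5% for both FWHM0 and
z_R; the residual error is polynomial-approximation bias, not noise.

## PSF metrology (`psfmetrics`)

Puncta are local maxima (3³ non-maximum suppression) above a threshold
(default 30% of the stack maximum); any *pair* closer than the isolation
radius (default 15 µm) is discarded entirely, so no profile mixes two
sources. The 1-D profile window spans 6 × the expected FWHM (configurable);
windows truncated by the volume boundary are rejected. The smallest-N
summary sorts ascending, keeps N = 10 by default, and reports mean ±
sample (n−1) SD — the rationale being that neighbour contamination and
defocus only ever inflate a measured FWHM, so the smallest values are the
least-contaminated ones. If fewer than N values exist, all are used and the
summary is flagged. The elongation ratio is mean axial / mean lateral FWHM.

## Flat-field correction (`flatfield`)

Per-row medians m(y) of the reference give gains c(y) = max m / m(y) ≥ 1.
The median already suppresses reference noise, so no extra smoothing is
applied by default. Coefficients are dimensionless ratios, so a 12-bit
reference corrects an 8-bit stack without rescaling. Correction multiplies
each row and clamps to the bit-depth ceiling (clamping, not rescaling,
preserves the 8-bit contract); float inputs skip rounding so the operation
is exactly linear for data with headroom. A zero row median is an error
(named row), not a silent infinity.

## Tiling fusion (`tls`)

The x–z reslice (maximum projection over y by default, a single y-plane
optionally) is difference-of-Gaussians filtered to pass structure between
3 and 40 px (the band-pass parameters are exposed; sigma = structure/2),
then tiled into non-overlapping 50 × 100 px (x × z) windows — tiling, not
sliding, keeps cost linear and matches per-kernel-area statistics. Each
window's SD is a focus-contrast sample; z-tiles at the same x average into
one curve point. The tiling coordinate is the window boundary where the two
stacks' curves invert; among multiple crossings the one nearest the
midpoint of the two argmax positions wins, and equal-SD windows inherit the
preceding sign so a tangential touch is not an inversion. Fusion takes each
side from its sharper stack with a linear 100-px ramp (or a hard column
split); identical inputs pass through unchanged. Multi-tile fusion chains
pairwise left-to-right.

## Registration QC (`regqc`)

Normalized MI uses base-2 entropies from a 256 × 256 joint histogram
(256 bins align with 8-bit levels; the normalized score is base-invariant).
MI is clipped at 0 against float cancellation. A constant slice has zero
entropy; its normalized MI is reported as NaN with the slice flagged, and
summaries aggregate valid slices only. ZNCC carries the square root of the
product of the two sums of squares in its denominator, which is the only
normalization under which the score of a slice with itself is 1 and the
score is invariant under positive affine intensity maps. Metrics are
computed per z-slice (the slice is the unit the registration pipeline
compares). The residual axial misalignment estimator scans integer z-shifts
within ±max_shift, scores each by mean ZNCC over the overlap, prefers
smaller |shift| on ties, and returns the score alongside the shift so
callers can gate on it.

## Vessel-distance quantification (`vesseldist`)

Per channel: rolling-ball background subtraction (radius 4 px for thin
vessel signal, 50 px for broad drug distributions; scikit-image's
Sternberg rolling ball, i.e. the ball-kernel background — ImageJ's
paraboloid variant is not replicated bit-exactly), grouped MIPs over 10
consecutive slices (trailing partial group kept), and a single Otsu
threshold taken from a central reference MIP and applied to *all* MIPs so
binarization is depth-consistent. Otsu is implemented as an explicit
between-class-variance maximization over a 256-bin histogram; cuts ending
on empty bins are excluded (they duplicate the previous partition) and
residual ties resolve to the lowest cut, making the result bit-reproducible
against an exhaustive-search oracle.

Contours are outer boundary pixel sets (foreground pixels with an
8-connected background neighbour), in row-major order; sub-pixel contour
tracing was rejected to keep exact oracle comparability. For each
drug-contour point the nearest vessel-contour point comes from a kd-tree,
with exact-distance ties resolved to the lowest point index. A pairing is
valid only if its Bresenham-rasterized segment lies entirely inside the
drug mask — a segment crossing background connects unrelated structures.
Valid distances group by vessel point and average, yielding one distance
per vessel point; omitting the validity rule can only add pairings, never
change a retained distance. Summaries give per-slice quartiles and 1.5-IQR
whiskers plus the pooled distribution and its linearly interpolated 95th
percentile. The analysis is 2-D per MIP slice by design (matching the
grouped-MIP preprocessing); no volumetric distance transform is attempted.

## Virtual H&E (`falsecolor`)

Transmitted-light rendering by Beer–Lambert absorption: each channel is
normalized to [0, 1] by its own maximum and attenuates a white background
exponentially through an RGB absorption triplet. Defaults are the classic
hematoxylin (0.65, 0.70, 0.29) and eosin (0.07, 0.99, 0.11)
optical-density vectors with gain 2.0 per channel; all six numbers are
plain dataclass fields, so the coefficients of any published renderer can
be substituted. The scheme is exactly multiplicative across stains
(render(n,0) ⊙ render(0,p) = render(n,p) · background), which the tests
assert to float precision.

## Problem sizes

Test and acceptance runs use phantom volumes of order 10⁵–10⁶ voxels
(bead stacks 40×64×96; tiling pairs 120×32×300; masks 256²) and 10 seeds
per stochastic check. These sizes were chosen because every estimator's
error at these scales is already dominated by its intrinsic bias/variance
rather than by sample count, so larger volumes would not change any
conclusion.

## Known limitations

- The Gaussian-beam blur model ignores diffraction integrals and
  aberrations; beam metrology is validated on the model it assumes.
- The flat-field model is y-only; x-attenuation is out of scope.
- Rolling-ball background differs from ImageJ's paraboloid at the few-count
  level.
- The mapping from effective NA to eFOV/FWHM used to cross-check lens
  specifications is empirical in the source literature and is not
  implemented as a formula; only the focal-length ratio scaling of NA is.
- Real-instrument figures (measured eFOVs, whole-brain soma FWHMs,
  tumor drug-distance distributions) require instrument data and are not
  reproduced; the parameter-recovery tests on phantoms stand in for them.
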