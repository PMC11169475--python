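"""Closed-form acquisition optics for cuvette SPIM with synchronized stages.

The sample sits in a refractive-index-matched medium (RI ``n`` ≈ 1.52 for
CUBIC-R, 1.56 for BABB/ECi) while the air objective stays outside the
cuvette.  The focal length of the detection path is a sum of physical
distances divided by the refractive index of each segment,

    f = Σ D_i / n_i .

Moving the sample by ``dz_sample`` (into the medium) while moving the
detection optics by ``dz_detect`` (in air) keeps f constant exactly when

    dz_detect = (n − 1)/n · dz_sample ,

so two motorized stages scanning at velocities in that ratio hold the focal
plane fixed during a continuous z-scan.  ``(n − 1)/n`` is the *synchronous
speed correction*; at n = 1.52 it is 0.342.  In practice actuator load can
shift the effective ratio, so every function here accepts an optional
calibrated ``correction`` that overrides the theoretical value.

All lengths are µm internally; the CLI accepts mm and converts on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError, ValidationError

__all__ = [
    "RefractivePath",
    "SyncModel",
    "AcquisitionPlan",
    "speed_correction",
    "detection_velocity",
    "focal_invariance_residual",
    "plan_acquisition",
    "tile_displacement_in_medium",
    "scale_effective_na",
]


@dataclass
class RefractivePath:
    """Ordered optical path: ``segments`` of (physical distance µm, RI)."""

    segments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for i, (d, n) in enumerate(self.segments):
            if d < 0:
                raise DomainError(f"segment {i}: negative distance {d}")
            if n < 1:
                raise DomainError(f"segment {i}: non-physical refractive index {n}")

    @property
    def focal_sum(self) -> float:
        """f = Σ D_i / n_i, in µm."""
        return sum(d / n for d, n in self.segments)


def speed_correction(n: float) -> float:
    """Synchronous speed correction (n − 1)/n for medium refractive index n.

    Monotone increasing on [1, ∞), bounded in [0, 1); 0 exactly for air.
    """
    if n < 1:
        raise DomainError(f"refractive index {n} < 1 is non-physical")
    return (n - 1.0) / n


def detection_velocity(v_stage: float, n: float, correction: float | None = None) -> float:
    """Detection-optics velocity (µm/s) matching a sample-stage velocity.

    ``correction`` overrides the theoretical (n − 1)/n with an empirically
    calibrated value when the actuators deviate from theory.
    """
    if v_stage < 0:
        raise DomainError("stage velocity must be non-negative")
    c = speed_correction(n) if correction is None else correction
    if not 0 <= c < 1:
        raise DomainError(f"correction {c} outside [0, 1)")
    return v_stage * c


@dataclass
class SyncModel:
    """Refractive-path state of the synchronized two-stage scan.

    ``A`` is the in-medium distance, ``B`` the in-air distance (µm) of the
    detection path in the initial state; ``dz_sample``/``dz_detect`` are the
    two stage displacements.
    """

    n: float
    A: float
    B: float
    dz_sample: float = 0.0
    dz_detect: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"refractive index {self.n} < 1 is non-physical")

    @property
    def correction(self) -> float:
        return speed_correction(self.n)


def focal_invariance_residual(model: SyncModel) -> float:
    """Focal-length change (µm) after the two stage moves.

    residual = (A − dz_sample)/n + (B + dz_sample − dz_detect) − (A/n + B).
    Zero exactly when dz_detect = (n − 1)/n · dz_sample.
    """
    if model.A - model.dz_sample < 0:
        raise DomainError("dz_sample exceeds the available in-medium distance A")
    moved = (model.A - model.dz_sample) / model.n + (
        model.B + model.dz_sample - model.dz_detect
    )
    initial = model.A / model.n + model.B
    return moved - initial


@dataclass
class AcquisitionPlan:
    """Fully determined z-scan: velocities, exposure, frame count, travels."""

    v_stage: float  # µm/s
    v_detect: float  # µm/s
    exposure: float  # s
    n_frames: int
    z_interval: float = field(init=False)  # µm
    z_range: float = field(init=False)  # µm
    stage_travel: float = field(init=False)  # µm
    detect_travel: float = field(init=False)  # µm

    def __post_init__(self) -> None:
        if min(self.v_stage, self.exposure) <= 0 or self.n_frames < 1:
            raise ValidationError("v_stage, exposure must be > 0 and n_frames >= 1")
        if self.v_detect < 0:
            raise ValidationError("v_detect must be non-negative")
        self.z_interval = self.v_stage * self.exposure
        self.z_range = self.n_frames * self.z_interval
        self.stage_travel = self.z_range
        self.detect_travel = self.stage_travel * self.v_detect / self.v_stage

    def as_dict(self) -> dict:
        return {
            "v_stage_um_s": self.v_stage,
            "v_detect_um_s": self.v_detect,
            "exposure_s": self.exposure,
            "n_frames": self.n_frames,
            "z_interval_um": self.z_interval,
            "z_range_um": self.z_range,
            "stage_travel_um": self.stage_travel,
            "detect_travel_um": self.detect_travel,
        }


def plan_acquisition(
    v_stage: float,
    exposure: float,
    n_frames: int,
    n: float,
    correction: float | None = None,
) -> AcquisitionPlan:
    """Plan a continuous z-scan: z-interval = v_stage × exposure.

    The detection velocity follows the speed correction (theoretical or, if
    ``correction`` is given, calibrated).
    """
    if v_stage <= 0 or exposure <= 0 or n_frames <= 0:
        raise ValidationError("all plan inputs must be positive")
    v_detect = detection_velocity(v_stage, n, correction)
    return AcquisitionPlan(v_stage=v_stage, v_detect=v_detect, exposure=exposure, n_frames=n_frames)


def tile_displacement_in_medium(physical_shift: float, n: float) -> float:
    """Optical focus displacement (µm) inside the medium for a physical lens
    translation, = shift × n (500 µm → ≈760 µm at RI 1.52)."""
    if physical_shift < 0:
        raise DomainError("physical shift must be non-negative")
    if n < 1:
        raise DomainError(f"refractive index {n} < 1 is non-physical")
    return physical_shift * n


def scale_effective_na(na_ref: float, f_ref: float, f_target: float) -> float:
    """Scale an effective NA between cylindrical lenses by focal-length ratio.

    NA ratios equal inverse focal-length ratios for the same input beam, so
    na_target = na_ref × f_ref / f_target.
    """
    if na_ref <= 0 or f_ref <= 0 or f_target <= 0:
        raise DomainError("NA and focal lengths must be positive")
    return na_ref * f_ref / f_target
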