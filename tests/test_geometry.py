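"""Closed-form acquisition-optics math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spimkit.errors import DomainError, ValidationError
from spimkit.geometry import (
    AcquisitionPlan,
    RefractivePath,
    SyncModel,
    detection_velocity,
    focal_invariance_residual,
    plan_acquisition,
    scale_effective_na,
    speed_correction,
    tile_displacement_in_medium,
)


class TestSpeedCorrection:
    @pytest.mark.parametrize(
        "n, expected, places",
        [
            (1.52, 0.342, 3),  # CUBIC-R class media
            (1.00, 0.0, 12),  # air: no focal shift
            (1.56, 0.3590, 4),  # BABB/ECi: 0.56/1.56
        ],
    )
    def test_values(self, n, expected, places):
        assert speed_correction(n) == pytest.approx(expected, abs=0.5 * 10**-places)

    def test_non_physical_medium_rejected(self):
        with pytest.raises(DomainError):
            speed_correction(0.9)

    @given(st.floats(min_value=1.0, max_value=3.0))
    def test_bounded(self, n):
        c = speed_correction(n)
        assert 0.0 <= c < 1.0

    @given(st.floats(min_value=1.0, max_value=2.9), st.floats(min_value=1e-6, max_value=0.1))
    def test_monotone_in_n(self, n, dn):
        assert speed_correction(n + dn) > speed_correction(n)


class TestDetectionVelocity:
    @pytest.mark.parametrize(
        "v, n, expected",
        [
            (100.0, 1.52, 34.2),  # theoretical synchronized pair
            (0.0, 1.52, 0.0),
            (50.0, 1.52, 17.1),  # theory; calibrated instruments may run 17.3
        ],
    )
    def test_values(self, v, n, expected):
        assert detection_velocity(v, n) == pytest.approx(expected, abs=0.06)

    def test_calibrated_override(self):
        # an empirically calibrated correction replaces theory
        assert detection_velocity(50.0, 1.52, correction=0.346) == pytest.approx(17.3)


class TestFocalInvariance:
    def test_synchronized_motion_leaves_focus_fixed(self):
        m = SyncModel(n=1.52, A=5000.0, B=20000.0, dz_sample=1000.0)
        m.dz_detect = m.correction * m.dz_sample
        assert abs(focal_invariance_residual(m)) < 1e-9

    def test_unsynchronized_residual(self):
        # detection stage held still: residual = dz_sample (1 - 1/n)
        m = SyncModel(n=1.52, A=5000.0, B=20000.0, dz_sample=1000.0, dz_detect=0.0)
        assert focal_invariance_residual(m) == pytest.approx(342.1, abs=0.05)

    def test_identity_state(self):
        m = SyncModel(n=1.52, A=5000.0, B=20000.0)
        assert focal_invariance_residual(m) == 0.0

    @given(
        st.floats(min_value=1.0, max_value=1.7),
        st.floats(min_value=100.0, max_value=20000.0),
        st.floats(min_value=100.0, max_value=50000.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200)
    def test_residual_zero_for_synchronized_motion(self, n, a, b, frac):
        dz_s = frac * a
        m = SyncModel(n=n, A=a, B=b, dz_sample=dz_s, dz_detect=speed_correction(n) * dz_s)
        assert abs(focal_invariance_residual(m)) < 1e-8


class TestAcquisitionPlan:
    @pytest.mark.parametrize(
        "v, t, frames, interval, z_range",
        [
            (50.0, 0.2, 900, 10.0, 9000.0),  # full-FOV regime
            (25.0, 0.2, 1860, 5.0, 9300.0),  # fine-axial regime
        ],
    )
    def test_z_sampling(self, v, t, frames, interval, z_range):
        p = plan_acquisition(v, t, frames, 1.52)
        assert p.z_interval == pytest.approx(interval)
        assert p.z_range == pytest.approx(z_range)

    def test_single_slice_plan(self):
        p = plan_acquisition(40.0, 0.5, 1, 1.0)
        assert p.z_range == pytest.approx(40.0 * 0.5)
        assert p.v_detect == 0.0  # air

    def test_detect_travel_scales_with_velocity_ratio(self):
        # 10 mm stage travel at 50/17.3 µm/s → 3.46 mm detection travel
        p = plan_acquisition(50.0, 0.2, 1000, 1.52, correction=17.3 / 50.0)
        assert p.stage_travel == pytest.approx(10000.0)
        assert p.detect_travel == pytest.approx(3460.0)

    def test_invariants(self):
        p = plan_acquisition(50.0, 0.2, 900, 1.52)
        assert p.detect_travel / p.stage_travel == pytest.approx(p.v_detect / p.v_stage)

    def test_rejects_non_positive(self):
        with pytest.raises(ValidationError):
            plan_acquisition(0.0, 0.2, 900, 1.52)
        with pytest.raises(ValidationError):
            AcquisitionPlan(v_stage=50.0, v_detect=17.1, exposure=-1.0, n_frames=10)

    @given(
        st.floats(min_value=1.0, max_value=200.0),
        st.floats(min_value=0.01, max_value=2.0),
        st.integers(min_value=1, max_value=5000),
    )
    def test_round_trip_recovers_stage_velocity(self, v, t, frames):
        p = plan_acquisition(v, t, frames, 1.52)
        assert p.z_interval / p.exposure == pytest.approx(v, rel=1e-12)


class TestTileDisplacement:
    @pytest.mark.parametrize(
        "shift, n, expected",
        [(500.0, 1.52, 760.0), (123.0, 1.0, 123.0), (500.0, 1.56, 780.0)],
    )
    def test_values(self, shift, n, expected):
        assert tile_displacement_in_medium(shift, n) == pytest.approx(expected)


class TestEffectiveNaScaling:
    @pytest.mark.parametrize(
        "na, f_ref, f_tgt, expected",
        [(0.033, 150.0, 500.0, 0.0099), (0.05, 200.0, 200.0, 0.05), (0.033, 150.0, 300.0, 0.0165)],
    )
    def test_values(self, na, f_ref, f_tgt, expected):
        assert scale_effective_na(na, f_ref, f_tgt) == pytest.approx(expected)

    def test_zero_focal_length_rejected(self):
        with pytest.raises(DomainError):
            scale_effective_na(0.033, 150.0, 0.0)


class TestRefractivePath:
    def test_focal_sum(self):
        path = RefractivePath([(5000.0, 1.52), (20000.0, 1.0)])
        assert path.focal_sum == pytest.approx(5000.0 / 1.52 + 20000.0)

    def test_invalid_segments_rejected(self):
        with pytest.raises(DomainError):
            RefractivePath([(-1.0, 1.52)])
        with pytest.raises(DomainError):
            RefractivePath([(10.0, 0.5)])
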