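"""Mechanistic GRF/JRF model: ramp validation, components, directions."""

import math

import numpy as np
import pytest

from hipforce import (
    ForceVector,
    Frame,
    GRAVITY,
    SubjectRecord,
    abductor_force,
    component_labels,
    grf_direction,
    grf_mechanistic,
    jrf_direction,
    jrf_mechanistic,
    relabel_frame,
    validate_ramp,
)
from hipforce.errors import RampRangeError, UndefinedDirectionError

SQRT3 = math.sqrt(3.0)


def rotated_vertical(weight, theta_deg):
    """Independent oracle: GRF = vertical unit vector rotated onto the ramp
    normal by a 2D rotation matrix, scaled by body weight."""
    t = np.radians(theta_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    ap, vert = rot @ np.array([0.0, weight])
    return -abs(ap), vert  # horizontal component points against progression


class TestRampValidation:
    @pytest.mark.parametrize(
        "theta, theta_ground", [(0.0, 90.0), (15.0, 105.0), (70.0, 160.0)]
    )
    def test_second_quadrant_construction(self, theta, theta_ground):
        ramp = validate_ramp(theta)
        assert ramp.theta == theta
        assert ramp.theta_ground == theta_ground

    @pytest.mark.parametrize("theta", [-0.001, 70.001, 90, -5])
    def test_out_of_range_rejected(self, theta):
        with pytest.raises(RampRangeError, match="0-70"):
            validate_ramp(theta)

    @pytest.mark.parametrize("theta", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, theta):
        with pytest.raises(ValueError):
            validate_ramp(theta)


class TestGrfMechanistic:
    def test_level_ground_is_purely_vertical(self):
        res = grf_mechanistic(600.0, validate_ramp(0))
        assert res.vector.ap == 0.0
        assert res.vector.ml == 0.0
        assert res.vector.vert == 600.0
        assert res.alpha == 90.0

    def test_incline_components_match_rotation_oracle(self):
        res = grf_mechanistic(600.0, validate_ramp(30))
        ap, vert = rotated_vertical(600.0, 30)
        assert res.vector.ap == pytest.approx(ap, rel=1e-12)
        assert res.vector.ap == pytest.approx(-300.0, rel=1e-12)
        assert res.vector.vert == pytest.approx(vert, rel=1e-12)
        assert res.vector.vert == pytest.approx(519.6152422706632, rel=1e-12)
        assert res.vector.resultant_3d == pytest.approx(600.0, rel=1e-9)

    def test_zero_weight_gives_zero_vector(self):
        res = grf_mechanistic(0.0, validate_ramp(15))
        assert res.vector.is_zero
        assert res.vector.resultant_3d == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            grf_mechanistic(-1.0, validate_ramp(0))


class TestDirection:
    def test_vertical_vector_is_90(self):
        assert grf_direction(ForceVector(0.0, 0.0, 600.0)) == 90.0

    def test_incline_direction_negative_principal_value(self):
        alpha = grf_direction(ForceVector(-300.0, 0.0, 519.6152422706632))
        assert alpha == pytest.approx(-60.0, abs=1e-9)

    def test_zero_vector_undefined(self):
        with pytest.raises(UndefinedDirectionError):
            grf_direction(ForceVector(0.0, 0.0, 0.0))

    def test_direction_in_open_interval_on_inclines(self):
        for theta in (5, 30, 69.5):
            alpha = grf_direction(grf_mechanistic(700, validate_ramp(theta)).vector)
            assert -90 < alpha < 0


class TestAbductor:
    @pytest.mark.parametrize("weight", [1.0, 600.0, 823.5])
    def test_components(self, weight):
        a = abductor_force(weight)
        assert a.magnitude == 2.0 * weight  # exact
        assert a.ax == weight  # sin(30 deg) = 1/2 exactly
        assert a.ay == pytest.approx(SQRT3 * weight, rel=1e-9)
        assert a.angle_from_vertical == 30.0

    def test_specific_vertical_component(self):
        assert abductor_force(600.0).ay == pytest.approx(1039.23, abs=5e-3)

    def test_zero_weight(self):
        a = abductor_force(0.0)
        assert (a.magnitude, a.ax, a.ay) == (0.0, 0.0, 0.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            abductor_force(-10.0)


def jrf_summation_oracle(weight, theta_deg):
    """Independent oracle: sum abductor pull and transmitted load
    component-wise, return the Euclidean norm of the balancing reaction."""
    t = np.radians(theta_deg)
    abductor = np.array([-weight, -SQRT3 * weight])
    transmitted = np.array([-weight * np.sin(t), -weight * np.cos(t)])
    return float(np.linalg.norm(-(abductor + transmitted)))


class TestJrfMechanistic:
    @pytest.mark.parametrize(
        "theta, expected_n, expected_bw",
        [(0.0, 1745.6, 2.909), (15.0, 1786.3, 2.977)],
    )
    def test_frozen_magnitudes_at_600N(self, theta, expected_n, expected_bw):
        res = jrf_mechanistic(600.0, validate_ramp(theta), "2d")
        assert res.magnitude_n == pytest.approx(expected_n, abs=0.05)
        assert res.magnitude_bw == pytest.approx(expected_bw, abs=5e-4)
        assert res.magnitude_n == pytest.approx(
            jrf_summation_oracle(600.0, theta), rel=1e-12
        )

    def test_zero_weight(self):
        res = jrf_mechanistic(0.0, validate_ramp(25), "2d")
        assert res.magnitude_n == 0.0

    def test_3d_vector_populates_all_axes(self):
        res = jrf_mechanistic(600.0, validate_ramp(10), "3d")
        assert res.vector.ml == 600.0  # abductor horizontal stays mediolateral
        assert res.vector.ap == pytest.approx(600 * math.sin(math.radians(10)))
        assert res.vector.vert > 0
        assert res.vector.resultant_3d >= res.vector.resultant_2d("frontal")
        assert res.magnitude_bw >= 2.0

    def test_direction_is_frontal_plane_angle(self):
        res = jrf_mechanistic(600.0, validate_ramp(0), "2d")
        expected = math.degrees(math.atan(res.vector.vert / res.vector.ml))
        assert jrf_direction(res.vector) == pytest.approx(expected)

    def test_bad_dims_rejected(self):
        with pytest.raises(ValueError):
            jrf_mechanistic(600.0, validate_ramp(0), "4d")


class TestFrames:
    def test_grf_frame_labels_y_vertical(self):
        assert component_labels(Frame.grf_paper_frame) == {
            "ap": "X", "ml": "Z", "vert": "Y",
        }

    def test_jrf_frame_labels_z_vertical(self):
        assert component_labels(Frame.jrf_paper_frame)["vert"] == "Fz"

    def test_relabel_round_trip_preserves_components(self):
        v = ForceVector(1.5, -2.5, 3.5)
        there = relabel_frame(v, Frame.jrf_paper_frame)
        back = relabel_frame(there, Frame.internal)
        assert (back.ap, back.ml, back.vert) == (v.ap, v.ml, v.vert)
        assert there.resultant_3d == v.resultant_3d

    def test_unknown_frame_rejected(self):
        with pytest.raises(ValueError):
            relabel_frame(ForceVector(0, 0, 1), "sideways_frame")


class TestSubjectRecord:
    def test_weight_derived_from_mass(self):
        s = SubjectRecord(
            subject_id="a", gender="male", age_years=20, height_cm=180,
            body_mass_kg=70,
        )
        assert s.body_weight_n == pytest.approx(70 * GRAVITY)
        assert s.body_weight_n == pytest.approx(686.47, abs=5e-3)

    def test_mass_derived_from_weight(self):
        s = SubjectRecord(
            subject_id="a", gender="female", age_years=20, height_cm=160,
            body_weight_n=600,
        )
        assert s.body_mass_kg == pytest.approx(600 / GRAVITY)

    @pytest.mark.parametrize(
        "extra", [{}, {"body_mass_kg": 70, "body_weight_n": 686}]
    )
    def test_exactly_one_of_mass_weight(self, extra):
        with pytest.raises(ValueError):
            SubjectRecord(
                subject_id="a", gender="male", age_years=20, height_cm=180,
                **extra,
            )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            SubjectRecord(
                subject_id="a", gender="male", age_years=20, height_cm=180,
                body_mass_kg=-70,
            )
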