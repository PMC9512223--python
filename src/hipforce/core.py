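"""Static-equilibrium model of hip loading during single-limb support.

During the single-limb support sub-phase of gait (roughly 30-60 % of the
gait cycle) the stance hip is loaded by two forces:

* the ground reaction force (GRF) transmitted up the limb, oriented
  perpendicular to the walking surface, so that on a ramp inclined at
  ``theta`` degrees its horizontal (anteroposterior) component is
  ``-W*sin(theta)`` and its vertical component ``W*cos(theta)`` for a
  subject of body weight ``W``;
* the hip abductor muscle force, modelled as a single equivalent force of
  magnitude ``2*W`` acting 30 degrees from the vertical axis, which keeps
  the pelvis level in the frontal plane.

The joint reaction force (JRF) on the femoral head is the force that
balances both, obtained by component-wise vector summation.  All angles at
the public surface are degrees; all math is done in radians in a single
internal anatomical frame (anteroposterior, mediolateral, vertical) and
relabelled to the reporting conventions only at output time
(:func:`relabel_frame`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from pydantic import BaseModel, model_validator

from .errors import RampRangeError, UndefinedDirectionError

#: Standard gravity used to convert body mass (kg) to body weight (N).
GRAVITY = 9.80665

#: Inclination of the single-equivalent abductor force from the vertical axis.
ABDUCTOR_ANGLE_DEG = 30.0

#: Maximum ramp inclination the estimator accepts, in degrees.
MAX_RAMP_DEG = 70.0

SQRT3 = math.sqrt(3.0)


class Gender(str, Enum):
    male = "male"
    female = "female"


class Frame(str, Enum):
    """Axis-labelling conventions for reporting force components.

    ``internal`` is the computation frame (ap, ml, vert).  The two paper
    frames only relabel axes: GRF reports use Y-up labels (X, Z, Y) while
    JRF reports use Z-up labels (Fy, Fx, Fz).  Values never change.
    """

    internal = "internal"
    grf_paper_frame = "grf_paper_frame"
    jrf_paper_frame = "jrf_paper_frame"


#: internal axis -> display label, per frame.
FRAME_LABELS: dict[Frame, dict[str, str]] = {
    Frame.internal: {"ap": "ap", "ml": "ml", "vert": "vert"},
    Frame.grf_paper_frame: {"ap": "X", "ml": "Z", "vert": "Y"},
    Frame.jrf_paper_frame: {"ap": "Fy", "ml": "Fx", "vert": "Fz"},
}


class Engine(str, Enum):
    """Which computation produced a result.

    ``mechanistic`` evaluates the closed-form static-equilibrium model;
    ``empirical`` interpolates the published per-ramp cohort means.
    """

    mechanistic = "mechanistic"
    empirical = "empirical"


@dataclass(frozen=True)
class PhaseWindow:
    """Portion of the gait cycle a result refers to (single-limb support)."""

    start_fraction: float = 0.30
    end_fraction: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 < self.start_fraction < self.end_fraction < 1.0):
            raise ValueError(
                "phase window fractions must satisfy 0 < start < end < 1"
            )

    def __str__(self) -> str:
        return f"{self.start_fraction:.2f}-{self.end_fraction:.2f}"


SINGLE_LIMB_SUPPORT = PhaseWindow()


class SubjectRecord(BaseModel):
    """One subject's anthropometric inputs.

    Exactly one of ``body_mass_kg`` / ``body_weight_n`` must be supplied;
    the other is derived with standard gravity (9.80665 m/s^2).
    """

    subject_id: str
    gender: Gender
    age_years: float
    height_cm: float
    body_mass_kg: Optional[float] = None
    body_weight_n: Optional[float] = None

    @model_validator(mode="after")
    def _derive_and_check(self) -> "SubjectRecord":
        if (self.body_mass_kg is None) == (self.body_weight_n is None):
            raise ValueError(
                "exactly one of body_mass_kg / body_weight_n must be supplied"
            )
        if self.body_mass_kg is None:
            object.__setattr__(
                self, "body_mass_kg", self.body_weight_n / GRAVITY
            )
        else:
            object.__setattr__(
                self, "body_weight_n", self.body_mass_kg * GRAVITY
            )
        for name in ("age_years", "height_cm", "body_mass_kg", "body_weight_n"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite number")
        return self


@dataclass(frozen=True)
class RampAngle:
    """Walking-surface inclination above horizontal, degrees, in [0, 70].

    ``theta_ground`` is the second-quadrant angle between the GRF vector
    and the ground, ``90 + theta``: on level ground the GRF is vertical
    (90 deg); on an incline the angle opens past 90 deg, which is what
    makes the horizontal GRF component negative.
    """

    theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError("ramp angle must be a finite number")
        if not (0.0 <= self.theta <= MAX_RAMP_DEG):
            raise RampRangeError(
                f"ramp inclination {self.theta} deg is outside the supported "
                f"0-{MAX_RAMP_DEG:g} deg range"
            )

    @property
    def theta_ground(self) -> float:
        return 90.0 + self.theta

    @property
    def radians(self) -> float:
        return math.radians(self.theta)


def validate_ramp(theta: float) -> RampAngle:
    """Validate a ramp inclination and return it as a :class:`RampAngle`.

    Raises :class:`~hipforce.errors.RampRangeError` outside [0, 70] degrees
    and ``ValueError`` for non-finite input.
    """
    return RampAngle(float(theta))


@dataclass(frozen=True)
class ForceVector:
    """A 3-component force (N) in the internal anatomical frame.

    ap   -- anteroposterior, positive in the direction of progression
    ml   -- mediolateral, positive toward the stance-side midline
    vert -- vertical, positive upward
    """

    ap: float
    ml: float
    vert: float
    frame_label: Frame = Frame.internal

    def resultant_2d(self, plane: str = "sagittal") -> float:
        """Planar resultant: sagittal (ap, vert), frontal (ml, vert) or
        transverse (ap, ml)."""
        pairs = {
            "sagittal": (self.ap, self.vert),
            "frontal": (self.ml, self.vert),
            "transverse": (self.ap, self.ml),
        }
        try:
            a, b = pairs[plane]
        except KeyError:
            raise ValueError(f"unknown plane {plane!r}") from None
        return math.hypot(a, b)

    @property
    def resultant_3d(self) -> float:
        return math.sqrt(self.ap**2 + self.ml**2 + self.vert**2)

    @property
    def is_zero(self) -> bool:
        return self.ap == 0.0 and self.ml == 0.0 and self.vert == 0.0


def relabel_frame(vector: ForceVector, target: Frame | str) -> ForceVector:
    """Return the same vector tagged with a reporting frame.

    Relabelling never changes component values or resultants; it only
    switches which axis names (:data:`FRAME_LABELS`) a writer should print.
    """
    target = Frame(target)
    return replace(vector, frame_label=target)


def component_labels(frame: Frame | str) -> dict[str, str]:
    """Display labels for the internal (ap, ml, vert) axes in ``frame``."""
    return dict(FRAME_LABELS[Frame(frame)])


@dataclass(frozen=True)
class AbductorForce:
    """Single-equivalent hip abductor force during one-legged stance.

    magnitude = 2 W, inclined 30 deg from vertical, so the horizontal
    component equals W exactly and the vertical component sqrt(3) W.
    """

    magnitude: float
    ax: float
    ay: float
    angle_from_vertical: float = ABDUCTOR_ANGLE_DEG


def abductor_force(body_weight: float) -> AbductorForce:
    """Abductor force components for a subject of weight ``body_weight`` N."""
    if not math.isfinite(body_weight) or body_weight < 0:
        raise ValueError("body weight must be a non-negative finite number")
    # sin(30 deg) = 1/2 exactly, so ax == body_weight bit-exactly.
    return AbductorForce(
        magnitude=2.0 * body_weight,
        ax=body_weight,
        ay=SQRT3 * body_weight,
    )


@dataclass(frozen=True)
class GrfResult:
    """GRF at the hip for one subject on one ramp."""

    vector: ForceVector
    alpha: float  # direction vs the horizontal plane, degrees, signed
    engine: Engine
    theta: RampAngle
    body_weight: float
    phase_window: PhaseWindow = field(default=SINGLE_LIMB_SUPPORT)


def direction_angle(horizontal: float, vertical: float) -> float:
    """Signed direction of a planar force relative to the horizontal.

    Exactly zero horizontal component means a vertical force: +90 deg by
    the level-ground convention.  Otherwise the principal arctangent of
    vertical/horizontal in (-90, 90), negative whenever the horizontal
    component is negative and the vertical one positive — the sign the
    second-quadrant GRF geometry produces on any incline.
    """
    if horizontal == 0.0 and vertical == 0.0:
        raise UndefinedDirectionError(
            "direction is undefined for a zero force vector"
        )
    if horizontal == 0.0:
        return 90.0
    return math.degrees(math.atan(vertical / horizontal))


def grf_direction(vector: ForceVector) -> float:
    """Direction angle alpha of a GRF vector (sagittal plane), degrees."""
    if vector.is_zero:
        raise UndefinedDirectionError(
            "direction is undefined for a zero force vector"
        )
    return direction_angle(vector.ap, vector.vert)


def grf_mechanistic(body_weight: float, theta: RampAngle) -> GrfResult:
    """GRF of magnitude W perpendicular to a ramp inclined ``theta`` deg.

    Components follow the second-quadrant construction with
    ``theta_ground = 90 + theta``: ap = W*cos(theta_ground) = -W*sin(theta),
    vert = W*sin(theta_ground) = W*cos(theta), ml = 0.  The resultant is W
    for every inclination.
    """
    if not math.isfinite(body_weight) or body_weight < 0:
        raise ValueError("body weight must be a non-negative finite number")
    t = theta.radians
    vector = ForceVector(
        ap=-body_weight * math.sin(t) + 0.0,  # normalise -0.0 at level ground
        ml=0.0,
        vert=body_weight * math.cos(t),
    )
    if vector.is_zero:
        alpha = 90.0  # zero weight: report the level-ground convention
    else:
        alpha = grf_direction(vector)
    return GrfResult(
        vector=vector,
        alpha=alpha,
        engine=Engine.mechanistic,
        theta=theta,
        body_weight=body_weight,
    )


@dataclass(frozen=True)
class JrfResult:
    """JRF at the hip for one subject on one ramp.

    The mechanistic engine carries a full component vector and a magnitude
    as a true multiple of body weight.  The empirical engine carries only
    the scalar published per-ramp cohort value, reported verbatim in its
    printed unit.
    """

    engine: Engine
    theta: RampAngle
    magnitude_bw: Optional[float] = None
    magnitude_n: Optional[float] = None
    vector: Optional[ForceVector] = None
    empirical_value: Optional[float] = None
    unit: str = "N"
    dims: str = "3d"
    phase_window: PhaseWindow = field(default=SINGLE_LIMB_SUPPORT)


def jrf_mechanistic(
    body_weight: float, theta: RampAngle, dims: str = "3d"
) -> JrfResult:
    """JRF on the femoral head from frontal-plane static equilibrium.

    The joint reaction balances the abductor pull on the pelvis
    (components -W horizontal, -sqrt(3) W vertical) plus the transmitted
    load (-W*sin(theta) horizontal, -W*cos(theta) vertical), so its
    components are positive:

    * 2d  — both horizontal terms act in the frontal plane, giving
      magnitude ``W*sqrt(5 + 2 sin(theta) + 2 sqrt(3) cos(theta))``;
    * 3d  — the abductor horizontal term stays mediolateral while the
      ramp-tilt term is carried anteroposteriorly.

    The 2d magnitude grows strictly with inclination up to 30 deg,
    covering the whole experimentally tested 0-15 deg range.
    """
    if not math.isfinite(body_weight) or body_weight < 0:
        raise ValueError("body weight must be a non-negative finite number")
    dims = dims.lower()
    if dims not in ("2d", "3d"):
        raise ValueError("dims must be '2d' or '3d'")
    t = theta.radians
    sin_t, cos_t = math.sin(t), math.cos(t)
    if dims == "2d":
        vector = ForceVector(
            ap=0.0,
            ml=body_weight * (1.0 + sin_t),
            vert=body_weight * (SQRT3 + cos_t),
        )
        magnitude = vector.resultant_2d("frontal")
        ratio = math.sqrt(5.0 + 2.0 * sin_t + 2.0 * SQRT3 * cos_t)
    else:
        vector = ForceVector(
            ap=body_weight * sin_t,
            ml=body_weight,
            vert=body_weight * (SQRT3 + cos_t),
        )
        magnitude = vector.resultant_3d
        ratio = math.sqrt(5.0 + 2.0 * SQRT3 * cos_t)
    return JrfResult(
        engine=Engine.mechanistic,
        theta=theta,
        magnitude_bw=ratio,
        magnitude_n=magnitude,
        vector=vector,
        unit="N",
        dims=dims,
    )


def jrf_direction(vector: ForceVector) -> float:
    """Frontal-plane direction of a JRF vector vs the horizontal, degrees."""
    if vector.is_zero:
        raise UndefinedDirectionError(
            "direction is undefined for a zero force vector"
        )
    return direction_angle(vector.ml, vector.vert)
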