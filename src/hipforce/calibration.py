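"""Empirical per-ramp calibration engine.

The study measured hip JRF and GRF cohort means on four ramps (0, 5, 10,
15 degrees).  Those printed means are treated as calibration anchors; the
empirical engine returns them bit-exactly at the measured ramps and
estimates any other inclination up to 70 degrees:

* between 0 and 15 degrees — piecewise-linear interpolation between the
  neighbouring anchors;
* above 15 degrees — a least-squares straight line through all four
  anchors, extrapolated ("new ramp estimation").

The anchors ship in a versioned plain-text file
(``hipforce/data/calibration.txt``) so their provenance is auditable, and
can be replaced by any file in the same format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core import Engine, Gender, JrfResult, RampAngle
from .errors import CalibrationError

ANCHOR_RAMPS = (0.0, 5.0, 10.0, 15.0)

#: Unit label of the published JRF table, reported verbatim.
JRF_PRINTED_UNIT = "BW"

POLICY = "linear_interp_then_least_squares"


@dataclass(frozen=True)
class CalibrationTable:
    """Printed per-ramp anchors plus the interpolation/extrapolation policy."""

    jrf_anchors: dict[float, float]
    jrf_sd: dict[float, float]
    grf_anchors: dict[tuple[Gender, float], float]
    grf_sd: dict[tuple[Gender, float], float]
    policy: str = POLICY
    version: str = "1"
    source: str = "builtin"

    def __post_init__(self) -> None:
        expected = set(ANCHOR_RAMPS)
        if set(self.jrf_anchors) != expected:
            raise CalibrationError(
                f"JRF anchor ramps must be exactly {sorted(expected)}"
            )
        for gender in Gender:
            ramps = {r for g, r in self.grf_anchors if g is gender}
            if ramps != expected:
                raise CalibrationError(
                    f"GRF anchor ramps for {gender.value} must be exactly "
                    f"{sorted(expected)}"
                )
        for value in list(self.jrf_anchors.values()) + list(
            self.grf_anchors.values()
        ):
            if not (math.isfinite(value) and value > 0):
                raise CalibrationError("anchor values must be positive finite")
        ordered = [self.jrf_anchors[r] for r in ANCHOR_RAMPS]
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise CalibrationError(
                "JRF anchors must increase strictly with ramp angle"
            )
        if self.policy != POLICY:
            raise CalibrationError(f"unknown calibration policy {self.policy!r}")

    # -- evaluation -------------------------------------------------------

    @staticmethod
    def _evaluate(anchors: dict[float, float], theta: RampAngle) -> float:
        if theta.theta in anchors:  # exact anchor: stored constant verbatim
            return anchors[theta.theta]
        x = np.asarray(ANCHOR_RAMPS)
        y = np.asarray([anchors[r] for r in ANCHOR_RAMPS])
        if theta.theta <= ANCHOR_RAMPS[-1]:
            return float(np.interp(theta.theta, x, y))
        slope, intercept = np.polyfit(x, y, 1)
        return float(intercept + slope * theta.theta)

    def jrf(self, theta: RampAngle) -> float:
        """Cohort-mean JRF at ``theta``, in the printed unit."""
        return self._evaluate(self.jrf_anchors, theta)

    def grf(self, gender: Gender | str, theta: RampAngle) -> float:
        """Cohort-mean GRF (N) at ``theta`` for one gender."""
        gender = Gender(gender)
        anchors = {r: v for (g, r), v in self.grf_anchors.items() if g is gender}
        return self._evaluate(anchors, theta)

    # -- loading ----------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationTable":
        """Parse a key-value anchor file (see ``data/calibration.txt``)."""
        jrf_anchors: dict[float, float] = {}
        jrf_sd: dict[float, float] = {}
        grf_anchors: dict[tuple[Gender, float], float] = {}
        grf_sd: dict[tuple[Gender, float], float] = {}
        policy = POLICY
        version = "1"
        for lineno, raw in enumerate(
            Path(path).read_text().splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                if "version" in line and lineno == 1:
                    version = line.rstrip().rsplit(None, 1)[-1]
                continue
            fields = line.split()
            try:
                key = fields[0]
                if key == "jrf_anchor":
                    jrf_anchors[float(fields[1])] = float(fields[2])
                elif key == "jrf_sd":
                    jrf_sd[float(fields[1])] = float(fields[2])
                elif key == "grf_anchor":
                    grf_anchors[(Gender(fields[1]), float(fields[2]))] = float(
                        fields[3]
                    )
                elif key == "grf_sd":
                    grf_sd[(Gender(fields[1]), float(fields[2]))] = float(
                        fields[3]
                    )
                elif key == "policy":
                    policy = fields[1]
                else:
                    raise CalibrationError(
                        f"unknown record type {key!r} on line {lineno}"
                    )
            except (IndexError, ValueError) as exc:
                raise CalibrationError(
                    f"malformed calibration record on line {lineno}: {raw!r}"
                ) from exc
        return cls(
            jrf_anchors=jrf_anchors,
            jrf_sd=jrf_sd,
            grf_anchors=grf_anchors,
            grf_sd=grf_sd,
            policy=policy,
            version=version,
            source=str(path),
        )

    @classmethod
    def default(cls) -> "CalibrationTable":
        """The table shipped with the package."""
        with resources.as_file(
            resources.files("hipforce").joinpath("data/calibration.txt")
        ) as path:
            table = cls.from_file(path)
        return CalibrationTable(
            jrf_anchors=table.jrf_anchors,
            jrf_sd=table.jrf_sd,
            grf_anchors=table.grf_anchors,
            grf_sd=table.grf_sd,
            policy=table.policy,
            version=table.version,
            source="builtin",
        )


_DEFAULT: CalibrationTable | None = None


def default_calibration() -> CalibrationTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = CalibrationTable.default()
    return _DEFAULT


def jrf_empirical(
    body_weight: float,
    theta: RampAngle,
    calib: CalibrationTable | None = None,
) -> JrfResult:
    """Published cohort-mean JRF at ``theta``, in the printed table unit.

    The value is a cohort mean and does not depend on ``body_weight``;
    the argument is accepted for interface symmetry with the mechanistic
    engine.
    """
    calib = calib or default_calibration()
    value = calib.jrf(theta)
    return JrfResult(
        engine=Engine.empirical,
        theta=theta,
        empirical_value=value,
        unit=JRF_PRINTED_UNIT,
    )


def grf_empirical(
    gender: Gender | str,
    theta: RampAngle,
    calib: CalibrationTable | None = None,
) -> float:
    """Published cohort-mean GRF (N) at ``theta`` for one gender."""
    calib = calib or default_calibration()
    return calib.grf(gender, theta)
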