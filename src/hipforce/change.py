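"""Percent increase/decrease of hip force quantities.

Two sweep modes mirror the original analysis options: hold body weight
fixed and compare ramps, or hold the ramp fixed and compare body weights.
The first element of the swept list is the reference; each report carries
the signed relative change ``(comparison - reference) / reference * 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .calibration import CalibrationTable, grf_empirical, jrf_empirical
from .core import (
    Engine,
    Gender,
    RampAngle,
    grf_mechanistic,
    jrf_mechanistic,
)
from .errors import HipForceError

#: Scalar quantities a sweep can track.
QUANTITIES = ("ap", "ml", "vert", "resultant_2d", "resultant_3d")

ANALYSES = ("jrf", "grf")


@dataclass(frozen=True)
class PercentChangeReport:
    reference_label: str
    comparison_label: str
    analysis: str  # "jrf" | "grf"
    quantity: str  # one of QUANTITIES
    reference_value: float
    comparison_value: float
    percent: float
    unit: str


def percent_change(reference: float, comparison: float) -> float:
    """Signed relative change of ``comparison`` vs ``reference``, percent."""
    if not math.isfinite(reference) or reference <= 0:
        raise ValueError(
            "percent change needs a strictly positive finite reference value"
        )
    return (comparison - reference) / reference * 100.0


def evaluate_quantity(
    analysis: str,
    engine: Engine | str,
    body_weight: float,
    theta: RampAngle,
    quantity: str,
    dims: str = "3d",
    gender: Gender | str = Gender.male,
    calib: Optional[CalibrationTable] = None,
) -> tuple[float, str]:
    """One scalar force quantity and its unit, via the selected engine.

    The empirical engine publishes only resultant cohort means, so
    per-component quantities are available mechanistically only.
    """
    engine = Engine(engine)
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}")
    if quantity not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}")
    if engine is Engine.empirical:
        if quantity not in ("resultant_2d", "resultant_3d"):
            raise HipForceError(
                "the empirical engine publishes resultant cohort means only; "
                "use the mechanistic engine for per-component quantities"
            )
        if analysis == "jrf":
            result = jrf_empirical(body_weight, theta, calib)
            return result.empirical_value, result.unit
        return grf_empirical(gender, theta, calib), "N"
    if analysis == "grf":
        vector = grf_mechanistic(body_weight, theta).vector
        plane = "sagittal"
    else:
        result = jrf_mechanistic(body_weight, theta, dims)
        vector = result.vector
        plane = "frontal"
    if quantity == "resultant_3d":
        return vector.resultant_3d, "N"
    if quantity == "resultant_2d":
        return vector.resultant_2d(plane), "N"
    return getattr(vector, quantity), "N"


def series_fixed_weight(
    body_weight: float,
    thetas: Sequence[RampAngle],
    engine: Engine | str,
    quantity: str = "resultant_3d",
    analysis: str = "jrf",
    dims: str = "3d",
    gender: Gender | str = Gender.male,
    calib: Optional[CalibrationTable] = None,
) -> list[PercentChangeReport]:
    """Percent change across ramps at fixed body weight.

    The first ramp is the reference; one report per remaining ramp.
    """
    if len(thetas) < 2:
        raise ValueError("need at least two ramps (reference + comparison)")

    def value(theta: RampAngle) -> tuple[float, str]:
        return evaluate_quantity(
            analysis, engine, body_weight, theta, quantity, dims, gender, calib
        )

    ref, unit = value(thetas[0])
    reports = []
    for theta in thetas[1:]:
        cmp_value, _ = value(theta)
        reports.append(
            PercentChangeReport(
                reference_label=f"ramp {thetas[0].theta:g} deg",
                comparison_label=f"ramp {theta.theta:g} deg",
                analysis=analysis,
                quantity=quantity,
                reference_value=ref,
                comparison_value=cmp_value,
                percent=percent_change(ref, cmp_value),
                unit=unit,
            )
        )
    return reports


def series_fixed_ramp(
    theta: RampAngle,
    weights: Sequence[float],
    engine: Engine | str,
    quantity: str = "resultant_3d",
    analysis: str = "grf",
    dims: str = "3d",
    gender: Gender | str = Gender.male,
    calib: Optional[CalibrationTable] = None,
) -> list[PercentChangeReport]:
    """Percent change across body weights at a fixed ramp.

    The first weight is the reference.  Mechanistic forces are homogeneous
    of degree one in body weight, so there the percent change equals the
    percent change of the weights themselves.
    """
    if len(weights) < 2:
        raise ValueError("need at least two weights (reference + comparison)")
    for w in weights:
        if not math.isfinite(w) or w <= 0:
            raise ValueError("body weights must be strictly positive")

    def value(w: float) -> tuple[float, str]:
        return evaluate_quantity(
            analysis, engine, w, theta, quantity, dims, gender, calib
        )

    ref, unit = value(weights[0])
    reports = []
    for w in weights[1:]:
        cmp_value, _ = value(w)
        reports.append(
            PercentChangeReport(
                reference_label=f"weight {weights[0]:g} N",
                comparison_label=f"weight {w:g} N",
                analysis=analysis,
                quantity=quantity,
                reference_value=ref,
                comparison_value=cmp_value,
                percent=percent_change(ref, cmp_value),
                unit=unit,
            )
        )
    return reports
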