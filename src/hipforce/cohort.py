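"""Synthetic gait-study cohort generation and summary tables.

The original study measured forty healthy university students (twenty per
gender) walking four ramps.  No per-subject data were deposited, so this
module generates a stand-in cohort: gender-stratified body masses from
truncated normal distributions, and per-subject force observations built
by perturbing an engine value (mechanistic or empirical) with
multiplicative lognormal noise.

The noise factor has unit mean, so cell means converge to the engine
value, and a coefficient of variation ``noise_cv`` whose default 0.135
reproduces the dispersion of the published JRF table (SD/mean at level
ground, 16.1/119.4).  Multiplicative noise is used because the published
per-ramp SDs scale with the cell means.  Summaries report the sample mean,
sample SD (n-1 denominator) and n per (gender, ramp, quantity) cell,
mirroring the published table layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .calibration import CalibrationTable, grf_empirical, jrf_empirical
from .core import (
    Engine,
    Gender,
    RampAngle,
    SubjectRecord,
    grf_mechanistic,
    jrf_mechanistic,
)
from .errors import EmptyInputError

#: Columns of an observation table.
OBSERVATION_COLUMNS = (
    "subject_id",
    "gender",
    "ramp_deg",
    "engine",
    "quantity",
    "value",
    "unit",
)

#: Hard floor on generated body mass, kg.
MIN_MASS_KG = 30.0


class CohortConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Anthropometric defaults are declared plumbing constants for a young
    adult student population; the study printed none.
    """

    n_male: int = Field(default=20, ge=0)
    n_female: int = Field(default=20, ge=0)
    mass_mean_male: float = Field(default=70.0, gt=0)
    mass_sd_male: float = Field(default=8.0, ge=0)
    mass_mean_female: float = Field(default=58.0, gt=0)
    mass_sd_female: float = Field(default=7.0, ge=0)
    age_mean: float = Field(default=21.0, gt=0)
    height_mean_male: float = Field(default=175.0, gt=0)
    height_mean_female: float = Field(default=162.0, gt=0)
    noise_cv: float = Field(default=0.135, ge=0, lt=1)
    random_seed: int = 0

    @model_validator(mode="after")
    def _finite(self) -> "CohortConfig":
        for name in (
            "mass_mean_male",
            "mass_sd_male",
            "mass_mean_female",
            "mass_sd_female",
            "noise_cv",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        return self


def _truncated_masses(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Body masses ~ Normal(mean, sd) truncated at +/-3 SD, floored at 30 kg."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        masses = np.full(n, mean)
    else:
        dist = stats.truncnorm(-3.0, 3.0, loc=mean, scale=sd)
        masses = dist.rvs(size=n, random_state=rng)
    return np.maximum(masses, MIN_MASS_KG)


def generate_cohort(config: Optional[CohortConfig] = None) -> list[SubjectRecord]:
    """Generate a gender-stratified synthetic cohort.

    Deterministic for a fixed ``config.random_seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.random_seed)
    subjects: list[SubjectRecord] = []
    for gender, n, mean, sd, height in (
        (Gender.male, config.n_male, config.mass_mean_male,
         config.mass_sd_male, config.height_mean_male),
        (Gender.female, config.n_female, config.mass_mean_female,
         config.mass_sd_female, config.height_mean_female),
    ):
        masses = _truncated_masses(rng, n, mean, sd)
        ages = rng.integers(18, 26, size=n)
        heights = rng.normal(height, 6.0, size=n)
        for i in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"{gender.value[0].upper()}{i + 1:03d}",
                    gender=gender,
                    age_years=float(ages[i]),
                    height_cm=float(max(heights[i], 120.0)),
                    body_mass_kg=float(masses[i]),
                )
            )
    return subjects


def _engine_value(
    subject: SubjectRecord,
    theta: RampAngle,
    engine: Engine,
    analysis: str,
    dims: str,
    calib: Optional[CalibrationTable],
) -> tuple[float, str, str]:
    """(value, quantity label, unit) of one noiseless observation."""
    if analysis == "jrf":
        if engine is Engine.empirical:
            res = jrf_empirical(subject.body_weight_n, theta, calib)
            return res.empirical_value, f"jrf_resultant_{dims}", res.unit
        res = jrf_mechanistic(subject.body_weight_n, theta, dims)
        # body-weight multiple: constant across subjects at a given ramp,
        # which is what makes per-cell dispersion purely the noise model's
        return res.magnitude_bw, f"jrf_resultant_{dims}", "xBW"
    if engine is Engine.empirical:
        return (
            grf_empirical(subject.gender, theta, calib),
            f"grf_resultant_{dims}",
            "N",
        )
    return (
        grf_mechanistic(subject.body_weight_n, theta).vector.resultant_3d,
        f"grf_resultant_{dims}",
        "N",
    )


def simulate_observations(
    cohort: Sequence[SubjectRecord],
    thetas: Sequence[RampAngle],
    engine: Engine | str = Engine.empirical,
    config: Optional[CohortConfig] = None,
    analysis: str = "jrf",
    dims: str = "3d",
    calib: Optional[CalibrationTable] = None,
) -> pd.DataFrame:
    """One noisy observation per subject x ramp.

    Each engine value is multiplied by an independent unit-mean lognormal
    factor with coefficient of variation ``config.noise_cv``; with
    ``noise_cv = 0`` observations equal the engine values exactly.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cannot simulate observations for an empty cohort")
    if len(thetas) == 0:
        raise EmptyInputError("need at least one ramp")
    config = config or CohortConfig()
    engine = Engine(engine)
    rng = np.random.default_rng(config.random_seed)
    cv = config.noise_cv
    sigma = math.sqrt(math.log1p(cv * cv))
    rows = []
    for subject in cohort:
        for theta in thetas:
            value, quantity, unit = _engine_value(
                subject, theta, engine, analysis, dims, calib
            )
            if cv > 0:
                value *= rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
            rows.append(
                (
                    subject.subject_id,
                    subject.gender.value,
                    theta.theta,
                    engine.value,
                    quantity,
                    value,
                    unit,
                )
            )
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- SD table per (gender, ramp, quantity) cell.

    ``table`` has columns gender, ramp_deg, quantity, unit, mean, sd, n;
    gender includes an ``all`` row pooling both strata, mirroring the
    published all-subjects table.
    """

    table: pd.DataFrame

    def cell(self, gender: str, ramp_deg: float, quantity: str):
        t = self.table
        row = t[
            (t.gender == gender)
            & (t.ramp_deg == ramp_deg)
            & (t.quantity == quantity)
        ]
        if row.empty:
            raise KeyError((gender, ramp_deg, quantity))
        r = row.iloc[0]
        return float(r["mean"]), float(r["sd"]), int(r["n"])

    def to_text(self) -> str:
        """Aligned mean (+/-SD) grid, ramps as columns, one row per stratum."""
        ramps = sorted(self.table.ramp_deg.unique())
        lines = []
        for quantity in sorted(self.table.quantity.unique()):
            unit = self.table[self.table.quantity == quantity].unit.iloc[0]
            lines.append(f"{quantity} ({unit}), mean (±SD)")
            header = "gender".ljust(8) + "".join(
                f"{f'{r:g}°':>18}" for r in ramps
            )
            lines.append(header)
            for gender in ("male", "female", "all"):
                cells = []
                for r in ramps:
                    try:
                        mean, sd, _ = self.cell(gender, r, quantity)
                        cells.append(f"{mean:.2f} (±{sd:.2f})")
                    except KeyError:
                        cells.append("-")
                lines.append(
                    gender.ljust(8) + "".join(f"{c:>18}" for c in cells)
                )
            lines.append("")
        return "\n".join(lines).rstrip() + "\n"


def summarize(observations: pd.DataFrame) -> CohortSummary:
    """Sample mean, sample SD (n-1) and n per (gender, ramp, quantity) cell."""
    if observations is None or len(observations) == 0:
        raise EmptyInputError("cannot summarize an empty observation table")

    def agg(df: pd.DataFrame, label: str) -> pd.DataFrame:
        grouped = (
            df.groupby(["ramp_deg", "quantity", "unit"], as_index=False)
            .agg(mean=("value", "mean"), sd=("value", lambda v: v.std(ddof=1)),
                 n=("value", "size"))
        )
        grouped.insert(0, "gender", label)
        return grouped

    parts = [
        agg(sub, gender)
        for gender, sub in observations.groupby("gender")
    ]
    parts.append(agg(observations, "all"))
    table = pd.concat(parts, ignore_index=True)
    table["sd"] = table["sd"].fillna(0.0)  # single-observation cells
    return CohortSummary(table=table)
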