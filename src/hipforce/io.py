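"""Subject-data files, force-result files and report rendering.

Two plain-text formats:

* **person data** — delimited text (comma or tab), mandatory header, one
  subject per row with columns ``subject_id, gender, age_years,
  height_cm`` and either ``body_mass_kg`` or ``body_weight_N``;
* **force results** — tab-separated, one row per (subject, ramp,
  quantity), preceded by ``#`` comment lines recording tool version, seed
  and calibration provenance.  Floats are written with ``repr`` precision
  so a write/read round trip is lossless.

All writers go through an atomic write-to-temp + rename, so a failed run
never leaves a partial result file behind.
"""

from __future__ import annotations

import csv
import io as _io
import os
import tempfile
import warnings
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .calibration import CalibrationTable, default_calibration
from .core import (
    Engine,
    Frame,
    GRAVITY,
    RampAngle,
    SINGLE_LIMB_SUPPORT,
    SubjectRecord,
    component_labels,
    grf_mechanistic,
    jrf_direction,
    jrf_mechanistic,
)
from .calibration import grf_empirical, jrf_empirical
from .errors import EmptyInputError, PersonDataError

PERSON_REQUIRED = ("subject_id", "gender", "age_years", "height_cm")
PERSON_WEIGHT_COLUMNS = ("body_mass_kg", "body_weight_N")

RESULT_COLUMNS = (
    "subject_id",
    "ramp_deg",
    "engine",
    "quantity",
    "value",
    "unit",
    "frame_label",
    "phase_window",
)


# ---------------------------------------------------------------------------
# person data


def read_person_data(
    path: str | Path,
) -> tuple[list[SubjectRecord], list[tuple[int, str]]]:
    """Read and validate a subject-data file.

    Returns ``(records, row_errors)`` where ``row_errors`` lists
    ``(line_number, message)`` for every rejected row.  Raises
    :class:`~hipforce.errors.PersonDataError` for file-level problems
    (missing file, empty file, missing header column).  Unknown columns
    are ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise PersonDataError(f"no such subject data file: {path}")
    if not path.read_text().strip():
        raise PersonDataError(f"subject data file is empty: {path}")
    try:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        raise PersonDataError(f"subject data file is empty: {path}") from None
    if frame.empty and frame.columns.empty:
        raise PersonDataError(f"subject data file is empty: {path}")
    columns = list(frame.columns)
    for required in PERSON_REQUIRED:
        if required not in columns:
            raise PersonDataError(
                f"subject data file is missing required column {required!r}"
            )
    if not any(c in columns for c in PERSON_WEIGHT_COLUMNS):
        raise PersonDataError(
            "subject data file needs a 'body_mass_kg' or 'body_weight_N' column"
        )
    known = set(PERSON_REQUIRED) | set(PERSON_WEIGHT_COLUMNS)
    unknown = [c for c in columns if c not in known]
    if unknown:
        warnings.warn(
            f"ignoring unknown subject data columns: {', '.join(unknown)}",
            stacklevel=2,
        )
    records: list[SubjectRecord] = []
    row_errors: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            mass = row.get("body_mass_kg")
            weight = row.get("body_weight_N")
            kwargs = dict(
                subject_id=str(row["subject_id"]),
                gender=str(row["gender"]).strip().lower(),
                age_years=float(row["age_years"]),
                height_cm=float(row["height_cm"]),
            )
            if mass is not None and not pd.isna(mass):
                kwargs["body_mass_kg"] = float(mass)
            elif weight is not None and not pd.isna(weight):
                kwargs["body_weight_n"] = float(weight)
            records.append(SubjectRecord(**kwargs))
        except (TypeError, ValueError) as exc:
            row_errors.append((lineno, _one_line(exc)))
    return records, row_errors


def _one_line(exc: Exception) -> str:
    return " ".join(str(exc).split())


# ---------------------------------------------------------------------------
# analysis runner


def run_analysis(
    subjects: Sequence[SubjectRecord],
    thetas: Sequence[RampAngle],
    analysis_type: str,
    engine: Engine | str = Engine.mechanistic,
    dims: str = "3d",
    calib: Optional[CalibrationTable] = None,
) -> pd.DataFrame:
    """Per-dimension components, 2D/3D resultants and direction angle.

    One row per (subject, ramp, quantity), in the paper's axis labels for
    the chosen analysis type, tagged with the single-limb-support phase
    window.  The empirical engine emits the published resultant only.
    """
    if len(subjects) == 0:
        raise EmptyInputError("no subjects to analyse")
    if len(thetas) == 0:
        raise EmptyInputError("no ramp inclinations to analyse")
    if analysis_type not in ("jrf", "grf"):
        raise ValueError("analysis_type must be 'jrf' or 'grf'")
    engine = Engine(engine)
    frame = (
        Frame.grf_paper_frame if analysis_type == "grf" else Frame.jrf_paper_frame
    )
    labels = component_labels(frame)
    phase = str(SINGLE_LIMB_SUPPORT)
    rows: list[tuple] = []

    def add(subject_id: str, theta: RampAngle, quantity: str, value: float,
            unit: str) -> None:
        rows.append(
            (subject_id, theta.theta, engine.value, quantity, value, unit,
             frame.value, phase)
        )

    for subject in subjects:
        for theta in thetas:
            try:
                if engine is Engine.empirical:
                    if analysis_type == "jrf":
                        res = jrf_empirical(subject.body_weight_n, theta, calib)
                        add(subject.subject_id, theta, "resultant_3d",
                            res.empirical_value, res.unit)
                    else:
                        add(subject.subject_id, theta, "resultant_3d",
                            grf_empirical(subject.gender, theta, calib), "N")
                    continue
                if analysis_type == "grf":
                    res = grf_mechanistic(subject.body_weight_n, theta)
                    vector, direction = res.vector, res.alpha
                    r2 = vector.resultant_2d("sagittal")
                else:
                    res = jrf_mechanistic(subject.body_weight_n, theta, dims)
                    vector = res.vector
                    direction = jrf_direction(vector)
                    r2 = vector.resultant_2d("frontal")
                for axis in ("ap", "ml", "vert"):
                    add(subject.subject_id, theta,
                        f"component_{labels[axis]}", getattr(vector, axis), "N")
                add(subject.subject_id, theta, "resultant_2d", r2, "N")
                add(subject.subject_id, theta, "resultant_3d",
                    vector.resultant_3d, "N")
                add(subject.subject_id, theta, "direction_deg", direction,
                    "deg")
            except Exception as exc:
                raise type(exc)(
                    f"subject {subject.subject_id!r}, ramp {theta.theta:g} deg: "
                    f"{exc}"
                ) from exc
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


# ---------------------------------------------------------------------------
# force-result files


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temp file + atomic rename in the target directory."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent or Path("."), prefix=f".{path.name}.", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def format_force_results(
    results: pd.DataFrame,
    seed: Optional[int] = None,
    calib: Optional[CalibrationTable] = None,
) -> str:
    """Render a result table as commented TSV text (lossless floats)."""
    calib = calib or default_calibration()
    lines = [
        f"# hipforce {__version__} force results",
        f"# gravity_m_per_s2 {GRAVITY}",
        f"# calibration {calib.source} v{calib.version} policy={calib.policy}",
        f"# seed {'none' if seed is None else seed}",
    ]
    buffer = _io.StringIO()
    out = results.copy()
    out["value"] = out["value"].map(repr)
    out.to_csv(buffer, sep="\t", index=False)
    lines.append(buffer.getvalue().rstrip("\n"))
    return "\n".join(lines) + "\n"


def write_force_results(
    results: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    calib: Optional[CalibrationTable] = None,
) -> None:
    atomic_write_text(path, format_force_results(results, seed, calib))


def read_force_results(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a force-result file; returns (table, comment lines)."""
    path = Path(path)
    comments: list[str] = []
    body: list[str] = []
    for line in path.read_text().splitlines():
        (comments if line.startswith("#") else body).append(line)
    if not body:
        raise EmptyInputError(f"force result file has no data rows: {path}")
    frame = pd.read_csv(
        _io.StringIO("\n".join(body)), sep="\t", float_precision="round_trip"
    )
    return frame, comments


# ---------------------------------------------------------------------------
# human-readable rendering


def render_text(results: pd.DataFrame) -> str:
    """Fixed-width report: one block per subject x ramp, one line per
    quantity, angles and forces to two decimals."""
    lines: list[str] = []
    for (subject_id, ramp), block in results.groupby(
        ["subject_id", "ramp_deg"], sort=False
    ):
        engine = block["engine"].iloc[0]
        lines.append(f"subject {subject_id}  ramp {ramp:g} deg  [{engine}]")
        for _, row in block.iterrows():
            lines.append(
                f"  {row['quantity']:<16} {row['value']:>12.2f} {row['unit']}"
            )
    lines.append(f"phase window: {SINGLE_LIMB_SUPPORT} of gait cycle")
    return "\n".join(lines) + "\n"


def to_json_records(results: pd.DataFrame) -> list[dict]:
    """Result rows as JSON-ready dicts (full float precision)."""
    return results.to_dict(orient="records")
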