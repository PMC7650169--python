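"""Participant-table I/O and the canonical cohort schema.

Every pipeline stage exchanges data as a flat per-participant table. This
module defines that schema once — field names, types, legal ranges,
missing-value handling — and provides a validating CSV reader and a
round-trip-safe writer.

Missingness is a first-class value: empty cells and ``NA`` (case-insensitive)
parse to ``None``, and the writer emits an empty cell for ``None``, so a
write/read cycle is lossless.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "ParticipantRecord",
    "CohortReadResult",
    "RowError",
    "SchemaError",
    "SCHEMA_COLUMNS",
    "read_cohort",
    "write_table",
    "records_to_frame",
    "frame_to_records",
]

MISSING_TOKENS = {"", "na", "nan", "none", "null"}
TRUE_TOKENS = {"1", "true", "yes", "y"}
FALSE_TOKENS = {"0", "false", "no", "n"}

CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


class SchemaError(ValueError):
    """The file cannot be read at all (e.g. a required column is absent)."""


@dataclass(frozen=True)
class RowError:
    """A single rejected row: where it failed and why."""

    row_index: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row_index}, column {self.column!r}: {self.message}"


@dataclass
class ParticipantRecord:
    """One participant: demographics, risk factors, cognition, biomarkers.

    ``None`` always means "missing"; it is distinguishable from every legal
    value. Units: age and education in years, CSF analytes in pg/ml,
    systolic BP in mmHg, BMI in kg/m², WML as a scaled fraction of total
    brain volume.
    """

    participant_id: str
    site_id: str
    age: float
    sex_female: bool | None = None
    education_years: float | None = None
    apoe4_carrier: bool | None = None
    family_history: bool | None = None
    dementia_or_mci_dx: bool | None = None
    cdr_global: float | None = None
    mmse_total: int | None = None
    rbans_list_learning: float | None = None
    rbans_coding: float | None = None
    systolic_bp: float | None = None
    bmi: float | None = None
    high_cholesterol: bool | None = None
    physical_inactivity: bool | None = None
    ever_smoked: bool | None = None
    bp_medication: bool | None = None
    diabetes: bool | None = None
    prior_cvd: bool | None = None
    atrial_fibrillation: bool | None = None
    left_ventricular_hypertrophy: bool | None = False
    csf_abeta42: float | None = None
    csf_ptau: float | None = None
    scheltens_mta: float | None = None
    wml_fraction: float | None = None


@dataclass
class CohortReadResult:
    """Outcome of a validating read: accepted records plus located errors."""

    records: list[ParticipantRecord]
    errors: list[RowError]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len({e.row_index for e in self.errors})


# ---------------------------------------------------------------------------
# Per-column parsers


def _parse_float(token: str, low: float | None = None, high: float | None = None,
                 low_open: bool = False) -> float:
    value = float(token)
    if not math.isfinite(value):
        raise ValueError("non-finite value")
    if low is not None and (value < low or (low_open and value == low)):
        raise ValueError(f"value {value} below legal minimum {low}")
    if high is not None and value > high:
        raise ValueError(f"value {value} above legal maximum {high}")
    return value


def _parse_flag(token: str) -> bool:
    t = token.strip().lower()
    if t in TRUE_TOKENS:
        return True
    if t in FALSE_TOKENS:
        return False
    raise ValueError(f"unrecognised flag token {token!r}")


def _parse_cdr(token: str) -> float:
    value = float(token)
    if value not in CDR_LEVELS:
        raise ValueError(f"cdr_global must be one of {CDR_LEVELS}, got {value}")
    return value


def _parse_mmse(token: str) -> int:
    value = float(token)
    if value != int(value):
        raise ValueError("mmse_total must be an integer")
    if not 0 <= value <= 30:
        raise ValueError(f"mmse_total must lie in [0, 30], got {value}")
    return int(value)


def _parse_scheltens(token: str) -> float:
    value = float(token)
    if not 0.0 <= value <= 4.0:
        raise ValueError(f"scheltens_mta must lie in [0, 4], got {value}")
    if (value * 2) != int(value * 2):
        raise ValueError("scheltens_mta uses half-point steps")
    return value


def _parse_str(token: str) -> str:
    return token.strip()


# column name -> (parser, required-at-read)
SCHEMA: dict[str, Callable[[str], Any]] = {
    "participant_id": _parse_str,
    "site_id": _parse_str,
    "age": lambda t: _parse_float(t, low=0.0, low_open=True),
    "sex_female": _parse_flag,
    "education_years": lambda t: _parse_float(t, low=0.0),
    "apoe4_carrier": _parse_flag,
    "family_history": _parse_flag,
    "dementia_or_mci_dx": _parse_flag,
    "cdr_global": _parse_cdr,
    "mmse_total": _parse_mmse,
    "rbans_list_learning": lambda t: _parse_float(t, low=0.0),
    "rbans_coding": lambda t: _parse_float(t, low=0.0),
    "systolic_bp": lambda t: _parse_float(t, low=0.0, low_open=True),
    "bmi": lambda t: _parse_float(t, low=0.0, low_open=True),
    "high_cholesterol": _parse_flag,
    "physical_inactivity": _parse_flag,
    "ever_smoked": _parse_flag,
    "bp_medication": _parse_flag,
    "diabetes": _parse_flag,
    "prior_cvd": _parse_flag,
    "atrial_fibrillation": _parse_flag,
    "left_ventricular_hypertrophy": _parse_flag,
    "csf_abeta42": lambda t: _parse_float(t, low=0.0, low_open=True),
    "csf_ptau": lambda t: _parse_float(t, low=0.0, low_open=True),
    "scheltens_mta": _parse_scheltens,
    "wml_fraction": lambda t: _parse_float(t, low=0.0),
}

SCHEMA_COLUMNS: tuple[str, ...] = tuple(SCHEMA.keys())

# columns that must carry a value for the row to be accepted at all
_NEVER_MISSING = ("participant_id", "site_id", "age")


def read_cohort(path: str | Path, delimiter: str = ",") -> CohortReadResult:
    """Read and validate a participant CSV.

    Every row is either accepted as a :class:`ParticipantRecord` or rejected
    with a :class:`RowError` naming the row and column; the two counts always
    sum to the number of input rows. Unknown columns are ignored with a
    warning; a missing schema column raises :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    return frame_to_records(frame)


def frame_to_records(frame: pd.DataFrame) -> CohortReadResult:
    """Validate a string-typed DataFrame against the cohort schema."""
    warnings: list[str] = []
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")
    extra = [c for c in frame.columns if c not in SCHEMA]
    if extra:
        warnings.append(f"ignoring unknown column(s): {', '.join(extra)}")

    records: list[ParticipantRecord] = []
    errors: list[RowError] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        parsed: dict[str, Any] = {}
        row_errors: list[RowError] = []
        for col, parser in SCHEMA.items():
            token = row_map[col]
            token = "" if token is None else str(token)
            if token.strip().lower() in MISSING_TOKENS:
                if col in _NEVER_MISSING:
                    row_errors.append(RowError(idx, col, "value required"))
                else:
                    parsed[col] = None
                continue
            try:
                parsed[col] = parser(token)
            except (ValueError, TypeError) as exc:
                row_errors.append(RowError(idx, col, str(exc)))
        if row_errors:
            errors.extend(row_errors)
        else:
            if parsed.get("left_ventricular_hypertrophy") is None:
                parsed["left_ventricular_hypertrophy"] = False
            records.append(ParticipantRecord(**parsed))
    return CohortReadResult(records, errors, warnings)


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with schema column order, None preserved."""
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
    return frame


def write_table(rows: Iterable[ParticipantRecord] | pd.DataFrame, path: str | Path,
                delimiter: str = ",") -> None:
    """Write records (or any tabular result) as CSV, missing values as empty cells.

    ``read_cohort`` after ``write_table`` round-trips participant tables
    losslessly, including missingness.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows and isinstance(rows[0], ParticipantRecord):
            frame = records_to_frame(rows)
        else:
            frame = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS) if not rows else None)

    out = frame.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].map(
                lambda v: "" if v is None else (int(v) if isinstance(v, bool) else v))
    out.to_csv(path, sep=delimiter, index=False, na_rep="")
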