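"""Composite vascular/dementia risk scores via declarative scoring tables.

Three point systems ship as editable YAML data files under
``atnpredict/tables/``: the CAIDE mid-life dementia risk score (non-APOE
variant), the Framingham general cardiovascular disease score, and the
Framingham stroke risk profile — each with the self-report adaptations used
for cohorts without blood lipid panels (self-reported hypercholesterolaemia
scores the CAIDE cholesterol points, and the Framingham diabetes points,
respectively).

The engine is table-driven: a :class:`ScoringTable` is a list of components,
each mapping a participant field through sex-specific numeric bands or flag
points. Band partitions (no gaps, no overlaps over the field's legal range)
are validated at load time. A missing required field yields an *incomplete*
result rather than an error; incomplete results are excluded from cohort
z-standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

from .cohort_io import ParticipantRecord

__all__ = [
    "Band",
    "Component",
    "ScoringTable",
    "CompositeResult",
    "TableValidationError",
    "load_table",
    "load_default_table",
    "score_record",
    "caide_score",
    "framingham_cvd_score",
    "framingham_stroke_score",
    "standardize",
    "score_cohort",
]

Sex = Literal["both", "female", "male"]


class TableValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    low: float
    high: float  # half-open: value in [low, high)
    points: int

    def contains(self, value: float) -> bool:
        return self.low <= value < self.high


@dataclass(frozen=True)
class Component:
    name: str
    field: str
    sex: Sex
    kind: Literal["numeric", "flag"]
    bands: tuple[Band, ...] = ()
    range: tuple[float, float] | None = None
    points_true: int = 0
    points_false: int = 0
    condition_field: str | None = None
    condition_value: bool | None = None

    def applies_to_sex(self, sex_female: bool) -> bool:
        if self.sex == "both":
            return True
        return self.sex == ("female" if sex_female else "male")

    def points_for(self, value: float | bool) -> int:
        if self.kind == "flag":
            return self.points_true if value else self.points_false
        for band in self.bands:
            if band.contains(float(value)):
                return band.points
        raise ValueError(
            f"value {value} outside the banded range of component {self.name!r}")


@dataclass
class ScoringTable:
    score_name: str
    sex_specific: bool
    components: list[Component]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every numeric component's bands tile its legal range exactly."""
        for comp in self.components:
            if comp.kind != "numeric":
                continue
            if comp.range is None or not comp.bands:
                raise TableValidationError(
                    f"numeric component {comp.name!r} needs a range and bands")
            lo, hi = comp.range
            bands = sorted(comp.bands, key=lambda b: b.low)
            if bands[0].low != lo:
                raise TableValidationError(
                    f"{comp.name!r}: first band starts at {bands[0].low}, not {lo}")
            for prev, nxt in zip(bands, bands[1:]):
                if prev.high != nxt.low:
                    raise TableValidationError(
                        f"{comp.name!r}: gap or overlap between bands at "
                        f"{prev.high} / {nxt.low}")
            if bands[-1].high != hi:
                raise TableValidationError(
                    f"{comp.name!r}: last band ends at {bands[-1].high}, not {hi}")
        if self.sex_specific:
            names = {c.name for c in self.components}
            for name in names:
                comps = [c for c in self.components if c.name == name]
                sexes = {c.sex for c in comps}
                if "both" not in sexes and sexes != {"female", "male"}:
                    raise TableValidationError(
                        f"sex-specific table must cover both sexes for {name!r}")

    @property
    def max_points(self) -> int:
        """Sum of per-component maxima (one sex's worst case)."""
        total = 0
        for name in dict.fromkeys(c.name for c in self.components):
            comps = [c for c in self.components if c.name == name]
            per_comp = max(
                max((b.points for b in c.bands), default=max(c.points_true, c.points_false))
                for c in comps)
            total += per_comp
        return total


@dataclass
class CompositeResult:
    score_name: str
    participant_id: str
    raw_points: int | None
    components_applied: list[tuple[str, int]] = field(default_factory=list)
    incomplete: bool = False
    z_score: float | None = None


def _build_component(raw: dict) -> Component:
    cond = raw.get("condition")
    bands = tuple(Band(float(b["low"]), float(b["high"]), int(b["points"]))
                  for b in raw.get("bands", []))
    rng = raw.get("range")
    return Component(
        name=raw["name"], field=raw["field"], sex=raw.get("sex", "both"),
        kind=raw["kind"], bands=bands,
        range=(float(rng[0]), float(rng[1])) if rng else None,
        points_true=int(raw.get("points_true", 0)),
        points_false=int(raw.get("points_false", 0)),
        condition_field=cond["field"] if cond else None,
        condition_value=bool(cond["value"]) if cond else None)


def load_table(path: str | Path) -> ScoringTable:
    """Load and validate a scoring table from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ScoringTable(
        score_name=raw["score_name"], sex_specific=bool(raw["sex_specific"]),
        components=[_build_component(c) for c in raw["components"]],
        provenance=raw.get("provenance", ""))


def load_default_table(score_name: Literal["caide", "framingham_cvd", "framingham_stroke"]) -> ScoringTable:
    ref = resources.files("atnpredict") / "tables" / f"{score_name}.yml"
    with resources.as_file(ref) as path:
        return load_table(path)


def score_record(record: ParticipantRecord, table: ScoringTable) -> CompositeResult:
    """Sum the table's points for one participant.

    Sex selects the applicable sub-table; conditioned components (e.g.
    treated vs untreated systolic-BP bands) are resolved through their
    condition flag. Any missing required field marks the result incomplete,
    with no raw point total.
    """
    pid = record.participant_id
    if record.sex_female is None:
        return CompositeResult(table.score_name, pid, None, incomplete=True)
    applied: list[tuple[str, int]] = []
    for name in dict.fromkeys(c.name for c in table.components):
        candidates = [c for c in table.components
                      if c.name == name and c.applies_to_sex(record.sex_female)]
        if not candidates:
            continue
        if candidates[0].condition_field is not None:
            cond_value = getattr(record, candidates[0].condition_field)
            if cond_value is None:
                return CompositeResult(table.score_name, pid, None, incomplete=True)
            candidates = [c for c in candidates if c.condition_value == bool(cond_value)]
            if not candidates:
                return CompositeResult(table.score_name, pid, None, incomplete=True)
        comp = candidates[0]
        value = getattr(record, comp.field)
        if value is None:
            return CompositeResult(table.score_name, pid, None, incomplete=True)
        applied.append((name, comp.points_for(value)))
    return CompositeResult(table.score_name, pid,
                           raw_points=sum(p for _, p in applied),
                           components_applied=applied)


def caide_score(record: ParticipantRecord, table: ScoringTable | None = None) -> CompositeResult:
    return score_record(record, table or load_default_table("caide"))


def framingham_cvd_score(record: ParticipantRecord, table: ScoringTable | None = None) -> CompositeResult:
    return score_record(record, table or load_default_table("framingham_cvd"))


def framingham_stroke_score(record: ParticipantRecord, table: ScoringTable | None = None) -> CompositeResult:
    return score_record(record, table or load_default_table("framingham_stroke"))


def standardize(results: Sequence[CompositeResult], ddof: int = 1) -> list[CompositeResult]:
    """Fill cohort-wide z-scores over the complete results (sample SD).

    Incomplete results keep ``z_score = None``. Requires at least two
    complete results with positive variance.
    """
    complete = [r for r in results if not r.incomplete and r.raw_points is not None]
    if len(complete) < 2:
        raise ValueError("need at least two complete results to standardize")
    values = np.array([r.raw_points for r in complete], dtype=float)
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance across complete scores")
    mean = values.mean()
    for r in results:
        if not r.incomplete and r.raw_points is not None:
            r.z_score = (r.raw_points - mean) / sd
    return list(results)


def score_cohort(records: Iterable[ParticipantRecord],
                 tables: Sequence[ScoringTable] | None = None,
                 standardized: bool = True) -> dict[str, list[CompositeResult]]:
    """Score every participant with every table; optionally fill z-scores."""
    if tables is None:
        tables = [load_default_table(n)
                  for n in ("caide", "framingham_cvd", "framingham_stroke")]
    out: dict[str, list[CompositeResult]] = {}
    records = list(records)
    for table in tables:
        results = [score_record(r, table) for r in records]
        if standardized and sum(not r.incomplete for r in results) >= 2:
            standardize(results)
        out[table.score_name] = results
    return out
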