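"""A/T/N flag assignment, five-group classification, and the analytic-sample
exclusion cascade.

The ATN framework classifies individuals by three biomarker axes —
Amyloid (CSF Aβ42), Tau (CSF p-Tau), Neurodegeneration (Scheltens MTA score
against an age-specific threshold) — independent of clinical symptoms. The
eight non-missing flag combinations collapse into five biological categories:

========  =================================
A−T−N−    normal AD biomarkers
A+T−N−    Alzheimer's pathologic change
A+T+N±    Alzheimer's disease
A+T−N+    AD and concomitant non-AD pathologic change
A−T+N±, A−T−N+   non-AD pathologic change
========  =================================

All threshold comparisons are strict, exactly as the cut-offs are stated
(A+ below 1025 pg/ml, T+ above 24 pg/ml, N+ above the age threshold); a
value equal to its threshold is negative. Any missing biomarker makes the
corresponding flag missing and the participant unclassifiable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cohort_io import ParticipantRecord
from .thresholds import CutoffRule, default_abeta_rule, default_ptau_rule, scheltens_threshold

__all__ = [
    "Flag",
    "ATNGroup",
    "ATNStatus",
    "ExclusionReport",
    "classify_flags",
    "assign_group",
    "classify_record",
    "classify_cohort",
    "apply_exclusions",
]


class Flag(enum.Enum):
    POSITIVE = "+"
    NEGATIVE = "-"
    MISSING = "?"

    @classmethod
    def from_bool(cls, value: bool | None) -> "Flag":
        if value is None:
            return cls.MISSING
        return cls.POSITIVE if value else cls.NEGATIVE


class ATNGroup(enum.Enum):
    NORMAL = "normal_ad_biomarkers"
    AD_PATHOLOGIC_CHANGE = "alzheimers_pathologic_change"
    AD = "alzheimers_disease"
    AD_AND_NON_AD = "ad_and_non_ad_pathologic_change"
    NON_AD = "non_ad_pathologic_change"
    UNCLASSIFIABLE = "unclassifiable"


# total mapping on the 8 fully-observed combinations
_GROUP_TABLE: dict[tuple[Flag, Flag, Flag], ATNGroup] = {
    (Flag.NEGATIVE, Flag.NEGATIVE, Flag.NEGATIVE): ATNGroup.NORMAL,
    (Flag.POSITIVE, Flag.NEGATIVE, Flag.NEGATIVE): ATNGroup.AD_PATHOLOGIC_CHANGE,
    (Flag.POSITIVE, Flag.POSITIVE, Flag.NEGATIVE): ATNGroup.AD,
    (Flag.POSITIVE, Flag.POSITIVE, Flag.POSITIVE): ATNGroup.AD,
    (Flag.POSITIVE, Flag.NEGATIVE, Flag.POSITIVE): ATNGroup.AD_AND_NON_AD,
    (Flag.NEGATIVE, Flag.POSITIVE, Flag.NEGATIVE): ATNGroup.NON_AD,
    (Flag.NEGATIVE, Flag.POSITIVE, Flag.POSITIVE): ATNGroup.NON_AD,
    (Flag.NEGATIVE, Flag.NEGATIVE, Flag.POSITIVE): ATNGroup.NON_AD,
}


@dataclass(frozen=True)
class ATNStatus:
    a_flag: Flag
    t_flag: Flag
    n_flag: Flag
    group: ATNGroup

    @property
    def complete(self) -> bool:
        return Flag.MISSING not in (self.a_flag, self.t_flag, self.n_flag)


def assign_group(a: Flag, t: Flag, n: Flag) -> ATNGroup:
    """Map an (A, T, N) flag triple to its biological category."""
    if Flag.MISSING in (a, t, n):
        return ATNGroup.UNCLASSIFIABLE
    return _GROUP_TABLE[(a, t, n)]


def classify_flags(record: ParticipantRecord,
                   abeta_rule: CutoffRule | None = None,
                   ptau_rule: CutoffRule | None = None) -> tuple[Flag, Flag, Flag]:
    """Derive the A/T/N flags for one participant under the given cut-off rules."""
    abeta_rule = abeta_rule or default_abeta_rule()
    ptau_rule = ptau_rule or default_ptau_rule()
    a = Flag.from_bool(abeta_rule.is_positive(record.csf_abeta42))
    t = Flag.from_bool(ptau_rule.is_positive(record.csf_ptau))
    if record.scheltens_mta is None:
        n = Flag.MISSING
    else:
        n = Flag.from_bool(record.scheltens_mta > scheltens_threshold(record.age))
    return a, t, n


def classify_record(record: ParticipantRecord,
                    abeta_rule: CutoffRule | None = None,
                    ptau_rule: CutoffRule | None = None) -> ATNStatus:
    a, t, n = classify_flags(record, abeta_rule, ptau_rule)
    return ATNStatus(a, t, n, assign_group(a, t, n))


def classify_cohort(records: Sequence[ParticipantRecord],
                    abeta_rule: CutoffRule | None = None,
                    ptau_rule: CutoffRule | None = None) -> list[ATNStatus]:
    return [classify_record(r, abeta_rule, ptau_rule) for r in records]


@dataclass
class ExclusionReport:
    """Stage counts of the analytic-sample cascade, plus per-participant reasons.

    Stages apply in order — clinical dementia/MCI diagnosis, then CDR ≥ 0.5
    among the remainder, then incomplete ATN biomarkers — and each excluded
    participant is attributed to the first stage that catches them, so
    ``n_input == n_dementia_mci + n_cdr + n_missing_atn + n_analytic``.
    """

    n_input: int
    n_dementia_mci: int
    n_cdr: int
    n_missing_atn: int
    n_analytic: int
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_analytic == (
            self.n_input - self.n_dementia_mci - self.n_cdr - self.n_missing_atn)


class DuplicateIdError(ValueError):
    pass


def apply_exclusions(records: Sequence[ParticipantRecord],
                     statuses: Sequence[ATNStatus],
                     ) -> tuple[list[tuple[ParticipantRecord, ATNStatus]], ExclusionReport]:
    """Run the exclusion cascade and return the analytic sample with its report."""
    if len(records) != len(statuses):
        raise ValueError("records and statuses must align")
    seen: set[str] = set()
    for r in records:
        if r.participant_id in seen:
            raise DuplicateIdError(f"duplicate participant_id {r.participant_id!r}")
        seen.add(r.participant_id)

    reasons: dict[str, str] = {}
    survivors: list[tuple[ParticipantRecord, ATNStatus]] = []
    n_dx = n_cdr = n_missing = 0
    for rec, status in zip(records, statuses):
        if rec.dementia_or_mci_dx:
            n_dx += 1
            reasons[rec.participant_id] = "dementia_or_mci_dx"
        elif rec.cdr_global is not None and rec.cdr_global >= 0.5:
            n_cdr += 1
            reasons[rec.participant_id] = "cdr_ge_0.5"
        elif not status.complete:
            n_missing += 1
            reasons[rec.participant_id] = "missing_atn"
        else:
            survivors.append((rec, status))
    report = ExclusionReport(
        n_input=len(records), n_dementia_mci=n_dx, n_cdr=n_cdr,
        n_missing_atn=n_missing, n_analytic=len(survivors), reasons=reasons)
    return survivors, report
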