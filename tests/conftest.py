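import numpy as np
import pytest

from atnpredict import atn, risk_scores, stats, synthetic
from atnpredict.cohort_io import ParticipantRecord


def make_record(**overrides) -> ParticipantRecord:
    """A fully-specified low-risk participant; override fields per test."""
    base = dict(
        participant_id="P1", site_id="site01", age=60.0, sex_female=True,
        education_years=16.0, apoe4_carrier=False, family_history=False,
        dementia_or_mci_dx=False, cdr_global=0.0, mmse_total=29,
        rbans_list_learning=30.0, rbans_coding=50.0, systolic_bp=120.0,
        bmi=24.0, high_cholesterol=False, physical_inactivity=False,
        ever_smoked=False, bp_medication=False, diabetes=False,
        prior_cvd=False, atrial_fibrillation=False,
        left_ventricular_hypertrophy=False, csf_abeta42=1500.0,
        csf_ptau=15.0, scheltens_mta=0.5, wml_fraction=5.0)
    base.update(overrides)
    return ParticipantRecord(**base)


@pytest.fixture(scope="session")
def epad_cohort():
    """The default published-structure synthetic cohort (n=1500, seed 0)."""
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def analysis_frame(epad_cohort):
    """Analytic-sample analysis frame with flags, groups and z-scored composites."""
    statuses = atn.classify_cohort(epad_cohort)
    analytic, _ = atn.apply_exclusions(epad_cohort, statuses)
    records = [r for r, _ in analytic]
    scores = risk_scores.score_cohort(records)
    return stats.build_analysis_frame(records, [s for _, s in analytic], scores)
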