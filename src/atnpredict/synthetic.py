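"""Synthetic EPAD-like cohort generation.

Real CSF/MRI biomarker cohorts of this kind are access-controlled, so the
pipeline ships a generator that emulates the published cohort structure:
eight A/T/N biomarker combinations with configurable counts, group-specific
covariate marginals (age, sex, APOE4, vascular risk factors, cognition,
white-matter-lesion load), an exclusion cascade (clinical dementia/MCI
diagnosis, CDR >= 0.5, missing biomarkers), and 21 study sites.

Two generation modes:

* :func:`generate_cohort` — structure-first: you request counts per
  biomarker combination and the generator draws CSF and Scheltens values on
  the correct side of the active cut-offs (cut-off plus/minus a half-normal
  margin), so re-classification reproduces the requested counts exactly.
* :func:`generate_from_model` — model-first: covariates are drawn from
  stated base distributions and the outcome (binary pathology flag or
  five-category group) is sampled from a logistic/multinomial model with
  user-supplied coefficients, for parameter-recovery studies.

Default counts and marginals reproduce the published cohort: 1500
participants of whom 82 carry a dementia/MCI diagnosis, 171 more have
CDR >= 0.5, 237 more lack a biomarker, leaving 1010 analytic participants
split 567/211/67/31/134 across the five ATN groups. Covariates are sampled
independently within group — the published tables constrain only the
marginals, and this simplification is documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .cohort_io import ParticipantRecord
from .thresholds import ABETA42_CUTOFF, PTAU_CUTOFF, scheltens_threshold

__all__ = [
    "Combination",
    "CovariateMarginals",
    "ModelMode",
    "CohortConfig",
    "ConfigError",
    "DEFAULT_COMBINATION_COUNTS",
    "DEFAULT_EXCLUSION_COUNTS",
    "DEFAULT_GROUP_MARGINALS",
    "generate_cohort",
    "generate_from_model",
]

# (a, t, n) positivity triple, e.g. (True, False, False) is A+T-N-
Combination = tuple[bool, bool, bool]


class ConfigError(ValueError):
    pass


def _combo_key(combo: Combination) -> str:
    a, t, n = combo
    return f"A{'+' if a else '-'}T{'+' if t else '-'}N{'+' if n else '-'}"


# Published five-group sizes: 567 / 211 / 67 / 31 / 134 (analytic n = 1010),
# with A+ = 309, T+ = 158, N+ = 90. The within-group split of the two
# composite groups is not printed; the split below is a consistent completion
# of those marginals (AD = 57 + 10 across N-/N+; non-AD = 85 + 6 + 43 across
# A-T+N-, A-T+N+, A-T-N+).
DEFAULT_COMBINATION_COUNTS: dict[Combination, int] = {
    (False, False, False): 567,  # normal AD biomarkers
    (True, False, False): 211,   # Alzheimer's pathologic change
    (True, True, False): 57,     # Alzheimer's disease, N-
    (True, True, True): 10,      # Alzheimer's disease, N+
    (True, False, True): 31,     # AD and non-AD pathologic change
    (False, True, False): 85,    # non-AD pathologic change
    (False, True, True): 6,
    (False, False, True): 43,
}

DEFAULT_EXCLUSION_COUNTS: tuple[int, int, int] = (82, 171, 237)


@dataclass(frozen=True)
class CovariateMarginals:
    """Within-group marginal distributions for one ATN group.

    Continuous covariates are (mean, SD) normals (WML fraction is log-normal
    matched to its mean/SD, reflecting its strong right skew); flags are
    Bernoulli prevalences.
    """

    age: tuple[float, float] = (64.6, 6.8)
    female_p: float = 0.586
    education: tuple[float, float] = (14.7, 3.7)
    apoe4_p: float = 0.375
    family_history_p: float = 0.685
    systolic_bp: tuple[float, float] = (134.8, 17.8)
    bmi: tuple[float, float] = (26.4, 4.3)
    high_cholesterol_p: float = 0.163
    physical_inactivity_p: float = 0.430
    ever_smoked_p: float = 0.542
    bp_medication_p: float = 0.155
    diabetes_p: float = 0.045
    prior_cvd_p: float = 0.041
    atrial_fibrillation_p: float = 0.019
    wml: tuple[float, float] = (12.9, 30.0)
    mmse: tuple[float, float] = (28.8, 1.3)
    rbans_list_learning: tuple[float, float] = (29.1, 4.2)
    rbans_coding: tuple[float, float] = (46.3, 10.3)


# Published per-group marginals (normal / AD pathologic change / AD /
# AD+non-AD / non-AD).
DEFAULT_GROUP_MARGINALS: dict[str, CovariateMarginals] = {
    "normal_ad_biomarkers": CovariateMarginals(
        age=(63.6, 6.6), female_p=0.601, education=(14.8, 3.7), apoe4_p=0.322,
        family_history_p=0.721, systolic_bp=(133.5, 17.6), bmi=(26.4, 4.3),
        high_cholesterol_p=0.173, physical_inactivity_p=0.433,
        ever_smoked_p=0.521, bp_medication_p=0.176, diabetes_p=0.049,
        prior_cvd_p=0.037, atrial_fibrillation_p=0.016, wml=(9.3, 26.2),
        mmse=(28.9, 1.3), rbans_list_learning=(29.4, 4.2),
        rbans_coding=(47.5, 9.9)),
    "alzheimers_pathologic_change": CovariateMarginals(
        age=(64.7, 7.1), female_p=0.540, education=(14.9, 3.7), apoe4_p=0.475,
        family_history_p=0.692, systolic_bp=(136.4, 17.9), bmi=(26.5, 4.3),
        high_cholesterol_p=0.147, physical_inactivity_p=0.383,
        ever_smoked_p=0.531, bp_medication_p=0.133, diabetes_p=0.019,
        prior_cvd_p=0.028, atrial_fibrillation_p=0.014, wml=(17.3, 35.2),
        mmse=(28.9, 1.2), rbans_list_learning=(29.0, 4.2),
        rbans_coding=(45.5, 10.4)),
    "alzheimers_disease": CovariateMarginals(
        age=(69.1, 5.9), female_p=0.567, education=(13.9, 3.8), apoe4_p=0.692,
        family_history_p=0.866, systolic_bp=(137.8, 17.0), bmi=(24.8, 3.7),
        high_cholesterol_p=0.119, physical_inactivity_p=0.433,
        ever_smoked_p=0.582, bp_medication_p=0.134, diabetes_p=0.060,
        prior_cvd_p=0.045, atrial_fibrillation_p=0.015, wml=(27.8, 48.5),
        mmse=(28.2, 1.9), rbans_list_learning=(27.4, 4.5),
        rbans_coding=(41.6, 9.5)),
    "ad_and_non_ad_pathologic_change": CovariateMarginals(
        age=(62.4, 7.1), female_p=0.516, education=(15.8, 3.5), apoe4_p=0.367,
        family_history_p=0.613, systolic_bp=(136.9, 18.1), bmi=(27.2, 4.5),
        high_cholesterol_p=0.097, physical_inactivity_p=0.367,
        ever_smoked_p=0.600, bp_medication_p=0.161, diabetes_p=0.0,
        prior_cvd_p=0.065, atrial_fibrillation_p=0.0, wml=(24.1, 42.8),
        mmse=(29.0, 1.3), rbans_list_learning=(29.7, 3.6),
        rbans_coding=(47.5, 11.8)),
    "non_ad_pathologic_change": CovariateMarginals(
        age=(66.7, 6.2), female_p=0.605, education=(14.5, 3.6), apoe4_p=0.349,
        family_history_p=0.612, systolic_bp=(136.0, 18.8), bmi=(26.2, 4.6),
        high_cholesterol_p=0.172, physical_inactivity_p=0.459,
        ever_smoked_p=0.594, bp_medication_p=0.157, diabetes_p=0.082,
        prior_cvd_p=0.052, atrial_fibrillation_p=0.037, wml=(11.2, 27.8),
        mmse=(28.6, 1.2), rbans_list_learning=(28.5, 4.3),
        rbans_coding=(44.3, 11.2)),
}

_COMBO_TO_GROUP: dict[Combination, str] = {
    (False, False, False): "normal_ad_biomarkers",
    (True, False, False): "alzheimers_pathologic_change",
    (True, True, False): "alzheimers_disease",
    (True, True, True): "alzheimers_disease",
    (True, False, True): "ad_and_non_ad_pathologic_change",
    (False, True, False): "non_ad_pathologic_change",
    (False, True, True): "non_ad_pathologic_change",
    (False, False, True): "non_ad_pathologic_change",
}

_GROUP_TO_COMBO: dict[str, Combination] = {
    "normal_ad_biomarkers": (False, False, False),
    "alzheimers_pathologic_change": (True, False, False),
    "alzheimers_disease": (True, True, False),
    "ad_and_non_ad_pathologic_change": (True, False, True),
    "non_ad_pathologic_change": (False, True, False),
}


@dataclass
class ModelMode:
    """Outcome-model specification for :func:`generate_from_model`.

    ``covariates`` maps schema field names to base distributions, either
    ``("normal", mean, sd)`` or ``("bernoulli", p)``. For a binary outcome,
    ``intercepts`` holds one value and ``coefficients`` one log-odds per
    covariate; for a multinomial outcome over the five groups, one value per
    non-reference category (order = ``categories[1:]``, reference first).
    """

    outcome: Literal["binary", "multinomial"]
    covariates: Mapping[str, tuple]
    intercepts: Sequence[float]
    coefficients: Mapping[str, Sequence[float]]
    categories: Sequence[str] = ()
    binary_positive_combo: Combination = (True, False, False)


@dataclass
class CohortConfig:
    """Everything :func:`generate_cohort` needs, with published defaults."""

    seed: int = 0
    combination_counts: Mapping[Combination, int] = field(
        default_factory=lambda: dict(DEFAULT_COMBINATION_COUNTS))
    exclusion_counts: tuple[int, int, int] = DEFAULT_EXCLUSION_COUNTS
    group_marginals: Mapping[str, CovariateMarginals] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MARGINALS))
    site_count: int = 21
    abeta_cutoff: float = ABETA42_CUTOFF
    ptau_cutoff: float = PTAU_CUTOFF
    # half-normal margin scales placing CSF values away from their cut-off
    abeta_margin_scale: float = 220.0
    ptau_margin_scale: float = 6.0
    scheltens_max: float = 4.0
    missing_rate: float = 0.0  # extra covariate missingness in the analytic set
    model_mode: ModelMode | None = None

    def validate(self) -> None:
        if any(v < 0 for v in self.combination_counts.values()):
            raise ConfigError("combination counts must be non-negative")
        if any(v < 0 for v in self.exclusion_counts):
            raise ConfigError("exclusion counts must be non-negative")
        for name, m in self.group_marginals.items():
            for attr in ("age", "education", "systolic_bp", "bmi", "wml",
                         "mmse", "rbans_list_learning", "rbans_coding"):
                if getattr(m, attr)[1] <= 0:
                    raise ConfigError(f"{name}.{attr}: SD must be positive")
            for attr in ("female_p", "apoe4_p", "family_history_p",
                         "high_cholesterol_p", "physical_inactivity_p",
                         "ever_smoked_p", "bp_medication_p", "diabetes_p",
                         "prior_cvd_p", "atrial_fibrillation_p"):
                if not 0 <= getattr(m, attr) <= 1:
                    raise ConfigError(f"{name}.{attr}: prevalence outside [0, 1]")
        if self.scheltens_max <= 2.0:
            raise ConfigError(
                "scheltens_max must exceed the largest age threshold (2.0) "
                "or N+ is unreachable for older participants")


# ---------------------------------------------------------------------------
# sampling helpers

_HALF_STEPS = np.arange(0.0, 4.5, 0.5)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = -np.inf, high: float = np.inf,
                      size: int | None = None) -> np.ndarray | float:
    # resampling rejection; fine for mild truncation
    x = rng.normal(mean, sd, size=size)
    bad = (x < low) | (x > high)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = (x < low) | (x > high)
    return x


def _lognormal_matched(rng: np.random.Generator, mean: float, sd: float) -> float:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _scheltens_value(rng: np.random.Generator, positive: bool, threshold: float,
                     max_score: float) -> float:
    """A half-step MTA score strictly above (N+) or at/below (N-) threshold."""
    if positive:
        choices = _HALF_STEPS[(_HALF_STEPS > threshold) & (_HALF_STEPS <= max_score)]
    else:
        choices = _HALF_STEPS[_HALF_STEPS <= threshold]
    if choices.size == 0:
        raise ConfigError("no admissible Scheltens score for requested N flag")
    # geometric decay from the mildest admissible score
    w = 0.5 ** np.arange(choices.size)
    if positive:
        probs = w / w.sum()
    else:
        probs = w[::-1] / w.sum()  # mass near the threshold's lower scores
    return float(rng.choice(choices, p=probs))


def _draw_covariates(rng: np.random.Generator, m: CovariateMarginals) -> dict:
    mmse = int(round(float(_truncated_normal(rng, *m.mmse, low=0, high=30))))
    return dict(
        age=float(_truncated_normal(rng, *m.age, low=18.0, high=95.0)),
        sex_female=bool(rng.random() < m.female_p),
        education_years=float(_truncated_normal(rng, *m.education, low=0.0)),
        apoe4_carrier=bool(rng.random() < m.apoe4_p),
        family_history=bool(rng.random() < m.family_history_p),
        systolic_bp=float(_truncated_normal(rng, *m.systolic_bp, low=60.0)),
        bmi=float(_truncated_normal(rng, *m.bmi, low=12.0)),
        high_cholesterol=bool(rng.random() < m.high_cholesterol_p),
        physical_inactivity=bool(rng.random() < m.physical_inactivity_p),
        ever_smoked=bool(rng.random() < m.ever_smoked_p),
        bp_medication=bool(rng.random() < m.bp_medication_p),
        diabetes=bool(rng.random() < m.diabetes_p),
        prior_cvd=bool(rng.random() < m.prior_cvd_p),
        atrial_fibrillation=bool(rng.random() < m.atrial_fibrillation_p),
        left_ventricular_hypertrophy=False,
        wml_fraction=_lognormal_matched(rng, *m.wml),
        mmse_total=mmse,
        rbans_list_learning=float(_truncated_normal(rng, *m.rbans_list_learning, low=0.0)),
        rbans_coding=float(_truncated_normal(rng, *m.rbans_coding, low=0.0)),
    )


def _biomarkers_for_combo(rng: np.random.Generator, combo: Combination,
                          age: float, config: CohortConfig) -> dict:
    a, t, n = combo
    eps = 1e-6
    a_margin = abs(rng.normal(0.0, config.abeta_margin_scale)) + eps
    abeta = config.abeta_cutoff - a_margin if a else config.abeta_cutoff + a_margin
    abeta = max(abeta, 1.0)
    t_margin = abs(rng.normal(0.0, config.ptau_margin_scale)) + eps
    if t:
        ptau = config.ptau_cutoff + t_margin
    else:
        ptau = max(config.ptau_cutoff - t_margin, 0.5)
    thr = scheltens_threshold(age)
    mta = _scheltens_value(rng, n, thr, config.scheltens_max)
    return dict(csf_abeta42=float(abeta), csf_ptau=float(ptau), scheltens_mta=mta)


def generate_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Generate a cohort whose re-classification reproduces the configured
    combination counts exactly, plus the configured excluded participants.

    Deterministic given ``config.seed``; the generator algorithm is NumPy's
    PCG64 (``np.random.default_rng``).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ParticipantRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:05d}"

    def site() -> str:
        return f"site{int(rng.integers(1, config.site_count + 1)):02d}"

    # analytic participants, per requested combination
    for combo, count in config.combination_counts.items():
        marg = config.group_marginals[_COMBO_TO_GROUP[combo]]
        for _ in range(count):
            cov = _draw_covariates(rng, marg)
            bio = _biomarkers_for_combo(rng, combo, cov["age"], config)
            records.append(ParticipantRecord(
                participant_id=next_id(), site_id=site(), cdr_global=0.0,
                dementia_or_mci_dx=False, **cov, **bio))

    # excluded participants: dx-flagged, CDR >= 0.5, missing biomarker
    n_dx, n_cdr, n_miss = config.exclusion_counts
    pool = list(config.combination_counts)
    weights = np.array([config.combination_counts[c] for c in pool], dtype=float)
    probs = weights / weights.sum() if weights.sum() > 0 else None

    def random_base() -> tuple[dict, dict]:
        idx = int(rng.choice(len(pool), p=probs)) if probs is not None else 0
        combo = pool[idx]
        marg = config.group_marginals[_COMBO_TO_GROUP[combo]]
        cov = _draw_covariates(rng, marg)
        bio = _biomarkers_for_combo(rng, combo, cov["age"], config)
        return cov, bio

    for _ in range(n_dx):
        cov, bio = random_base()
        records.append(ParticipantRecord(
            participant_id=next_id(), site_id=site(),
            dementia_or_mci_dx=True,
            cdr_global=float(rng.choice([0.5, 1.0])), **cov, **bio))
    for _ in range(n_cdr):
        cov, bio = random_base()
        records.append(ParticipantRecord(
            participant_id=next_id(), site_id=site(),
            dementia_or_mci_dx=False, cdr_global=0.5, **cov, **bio))
    for i in range(n_miss):
        cov, bio = random_base()
        drop = ("csf_abeta42", "csf_ptau", "scheltens_mta")[i % 3]
        bio[drop] = None
        records.append(ParticipantRecord(
            participant_id=next_id(), site_id=site(),
            dementia_or_mci_dx=False, cdr_global=0.0, **cov, **bio))

    order = rng.permutation(len(records))
    return [records[i] for i in order]


def generate_from_model(config: CohortConfig) -> list[ParticipantRecord]:
    """Simulate covariates and a model-generated outcome for recovery studies.

    Requires ``config.model_mode``. For a binary outcome the single linear
    predictor drives a Bernoulli pathology flag; for a multinomial outcome
    the softmax over per-category linear predictors (reference first, linear
    predictor 0) drives the five-group label. Each sampled label is realised
    as biomarker values on the appropriate side of the cut-offs so the
    record classifies to its sampled group.

    ``n`` is the sum of the requested combination counts when positive,
    otherwise supply counts via ``config.combination_counts``; by convention
    the total cohort size for model mode is taken from
    ``sum(combination_counts.values())``.
    """
    mode = config.model_mode
    if mode is None:
        raise ConfigError("model_mode must be supplied")
    n = sum(config.combination_counts.values())
    rng = np.random.default_rng(config.seed)

    for name, spec in mode.covariates.items():
        if spec[0] not in ("normal", "bernoulli"):
            raise ConfigError(f"unknown covariate family {spec[0]!r}")
    intercepts = np.asarray(mode.intercepts, dtype=float)
    if not np.all(np.isfinite(intercepts)):
        raise ConfigError("non-finite intercepts")
    n_cat = intercepts.size  # non-reference categories
    coef = {}
    for name, values in mode.coefficients.items():
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if arr.size != n_cat or not np.all(np.isfinite(arr)):
            raise ConfigError(f"coefficient vector for {name!r} must hold "
                              f"{n_cat} finite values")
        coef[name] = arr

    # draw covariates
    cov_draws: dict[str, np.ndarray] = {}
    for name, spec in mode.covariates.items():
        if spec[0] == "normal":
            cov_draws[name] = rng.normal(spec[1], spec[2], size=n)
        else:
            cov_draws[name] = (rng.random(n) < spec[1]).astype(float)

    # linear predictors: reference category fixed at 0
    eta = np.zeros((n, n_cat + 1))
    eta[:, 1:] = intercepts[None, :]
    for name, arr in coef.items():
        eta[:, 1:] += cov_draws[name][:, None] * arr[None, :]
    expeta = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs = expeta / expeta.sum(axis=1, keepdims=True)
    u = rng.random(n)
    labels = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    if mode.outcome == "binary":
        combos = {0: (False, False, False), 1: mode.binary_positive_combo}
        categories = {0: "negative", 1: "positive"}
    else:
        cats = list(mode.categories) or list(_GROUP_TO_COMBO)
        if len(cats) != n_cat + 1:
            raise ConfigError("categories must list reference plus one name "
                              "per intercept")
        combos = {i: _GROUP_TO_COMBO[c] for i, c in enumerate(cats)}
        categories = dict(enumerate(cats))

    records: list[ParticipantRecord] = []
    for i in range(n):
        combo = combos[int(labels[i])]
        fields = dict(
            participant_id=f"M{i + 1:06d}",
            site_id=f"site{int(rng.integers(1, config.site_count + 1)):02d}",
            age=60.0, cdr_global=0.0, dementia_or_mci_dx=False)
        for name, draws in cov_draws.items():
            value = draws[i]
            if mode.covariates[name][0] == "bernoulli":
                fields[name] = bool(value)
            elif name == "mmse_total":
                fields[name] = int(np.clip(round(value), 0, 30))
            else:
                fields[name] = float(value)
        a, t, nn = combo
        eps = 1e-6
        fields["csf_abeta42"] = (config.abeta_cutoff - 100.0 if a
                                 else config.abeta_cutoff + 100.0)
        fields["csf_ptau"] = (config.ptau_cutoff + 5.0 if t
                              else config.ptau_cutoff - 5.0)
        thr = scheltens_threshold(fields["age"])
        fields["scheltens_mta"] = min(thr + 0.5, 4.0) if nn else 0.0
        records.append(ParticipantRecord(**fields))
    return records
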