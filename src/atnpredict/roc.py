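"""Nested prediction models and ROC analysis for pathology-group membership.

For each pathology group versus the normal-biomarker group, a ladder of
logistic models is fitted:

* model 1 (basic): age, sex, APOE4 — plus age x APOE4 and sex x MMSE product
  terms for the "Alzheimer's pathologic change" contrast only, where those
  interactions are established;
* models 2-5: basic plus one of family history, BMI, WML volume, MMSE;
* model 6: basic plus all four;
* models 7a-c: basic plus one z-scored composite risk score.

The apparent (in-sample) AUC is computed by the midrank Mann-Whitney
formulation, its 95% CI by DeLong's method, and each extended model is
compared with the basic model by the likelihood-ratio chi-square test on
their common complete-case subsample (the basic model is refitted on that
subsample so the deviances are comparable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import GROUP_ORDER, NonEstimableError, _numeric_design

__all__ = [
    "ModelSpec",
    "ROCModelResult",
    "MODEL_IDS",
    "build_model_set",
    "fit_and_auc",
    "compare_to_basic",
    "run_roc_battery",
    "auc_mann_whitney",
    "delong_ci",
]

MODEL_IDS = ("m1", "m2_family", "m3_bmi", "m4_wml", "m5_mmse", "m6_all",
             "m7a_caide", "m7b_fcvd", "m7c_stroke")

_BASIC_TERMS = ("age", "sex_female", "apoe4_carrier")
_ADDITIONS = {
    "m2_family": ("family_history",),
    "m3_bmi": ("bmi",),
    "m4_wml": ("wml_fraction",),
    "m5_mmse": ("mmse_total",),
    "m6_all": ("family_history", "bmi", "wml_fraction", "mmse_total"),
    "m7a_caide": ("caide_z",),
    "m7b_fcvd": ("framingham_cvd_z",),
    "m7c_stroke": ("framingham_stroke_z",),
}


@dataclass(frozen=True)
class ModelSpec:
    contrast: str
    model_id: str
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()


@dataclass
class ROCModelResult:
    contrast: str
    model_id: str
    coefficients: list[tuple[str, float, float, float]]  # term, OR, lo, hi
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    n_cases: int
    n_controls: int
    log_likelihood: float = float("nan")
    df_model: int = 0
    p_vs_basic: float | None = None
    interaction_terms: list[str] = field(default_factory=list)


def build_model_set(contrast: str) -> list[ModelSpec]:
    """Emit the nine nested model specifications for one group contrast.

    The Alzheimer's-pathologic-change contrast carries the age x APOE4 and
    sex x MMSE product terms in the basic model and every superset.
    """
    interactions: tuple[tuple[str, str], ...] = ()
    if contrast == "alzheimers_pathologic_change":
        interactions = (("age", "apoe4_carrier"), ("sex_female", "mmse_total"))
    specs = [ModelSpec(contrast, "m1", _BASIC_TERMS, interactions)]
    for mid in MODEL_IDS[1:]:
        specs.append(ModelSpec(contrast, mid,
                               _BASIC_TERMS + _ADDITIONS[mid], interactions))
    return specs


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Apparent AUC by the rank (Mann-Whitney) formulation with midranks.

    Equals the probability that a random case outranks a random control,
    counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise NonEstimableError("both classes required for AUC")
    ranks = sps.rankdata(scores)  # midranks
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong (1988) AUC and variance via placement values."""
    labels = np.asarray(labels).astype(bool)
    pos = np.asarray(scores, dtype=float)[labels]
    neg = np.asarray(scores, dtype=float)[~labels]
    m, n = pos.size, neg.size
    # placement of each case among controls and vice versa (midrank handling)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def delong_ci(scores: np.ndarray, labels: np.ndarray,
              alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with DeLong 95% CI, clipped to [0, 1]."""
    auc, var = _delong_variance(scores, labels)
    se = np.sqrt(var)
    z = sps.norm.ppf(1 - alpha / 2)
    return auc, float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


def _design_for_spec(frame: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    sub = frame[frame["group"].isin([GROUP_ORDER[0], spec.contrast])]
    terms = list(dict.fromkeys(spec.terms))
    for a, b in spec.interactions:
        for extra in (a, b):
            if extra not in terms:
                terms.append(extra)
    X = _numeric_design(sub, terms)
    for a, b in spec.interactions:
        X[f"{a}_x_{b}"] = X[a] * X[b]
    y = (sub["group"] == spec.contrast).astype(float)
    mask = X.notna().all(axis=1)
    return X[mask], y[mask]


def fit_and_auc(frame: pd.DataFrame, spec: ModelSpec) -> ROCModelResult:
    """Fit one logistic specification and report coefficients plus AUC/CI."""
    X, y = _design_for_spec(frame, spec)
    n_cases = int(y.sum())
    n_controls = int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise NonEstimableError("single class after listwise deletion")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise NonEstimableError(str(exc)) from exc
    z = 1.959963984540054
    coefs = []
    for term in X.columns:
        if term == "const":
            continue
        b, se = float(fit.params[term]), float(fit.bse[term])
        coefs.append((term, float(np.exp(b)), float(np.exp(b - z * se)),
                      float(np.exp(b + z * se))))
    scores = np.asarray(fit.predict(X))
    auc, lo, hi = delong_ci(scores, y.to_numpy().astype(bool))
    return ROCModelResult(
        contrast=spec.contrast, model_id=spec.model_id, coefficients=coefs,
        auc=auc, auc_ci_low=lo, auc_ci_high=hi,
        n_cases=n_cases, n_controls=n_controls,
        log_likelihood=float(fit.llf), df_model=int(fit.df_model),
        interaction_terms=[f"{a}_x_{b}" for a, b in spec.interactions])


def compare_to_basic(frame: pd.DataFrame, basic: ModelSpec,
                     extended: ModelSpec) -> float:
    """Likelihood-ratio chi-square p-value of extended over basic.

    The specs must be nested; both models are fitted on the extended model's
    complete-case rows so their deviances are comparable.
    """
    if not set(basic.terms) < set(extended.terms):
        raise ValueError("extended model must strictly contain the basic terms")
    X_ext, y = _design_for_spec(frame, extended)
    X_basic_full, _ = _design_for_spec(frame, basic)
    common = X_ext.index.intersection(X_basic_full.index)
    X_ext, y = X_ext.loc[common], y.loc[common]
    X_basic = X_basic_full.loc[common]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_b = sm.Logit(y, X_basic).fit(disp=0, maxiter=200)
        fit_e = sm.Logit(y, X_ext).fit(disp=0, maxiter=200)
    lr = 2 * (fit_e.llf - fit_b.llf)
    df = X_ext.shape[1] - X_basic.shape[1]
    if df <= 0:
        raise ValueError("extended model adds no parameters")
    return float(sps.chi2.sf(max(lr, 0.0), df))


def run_roc_battery(frame: pd.DataFrame, contrast: str,
                    model_ids: Sequence[str] = MODEL_IDS) -> list[ROCModelResult]:
    """Fit the full model ladder for one contrast, with p-values vs model 1."""
    specs = {s.model_id: s for s in build_model_set(contrast)}
    results = []
    for mid in model_ids:
        spec = specs[mid]
        try:
            res = fit_and_auc(frame, spec)
        except NonEstimableError:
            continue
        if mid != "m1":
            try:
                res.p_vs_basic = compare_to_basic(frame, specs["m1"], spec)
            except (NonEstimableError, np.linalg.LinAlgError, ValueError):
                # e.g. the added main effect is already carried by the basic
                # model's interaction terms for this contrast
                res.p_vs_basic = None
        results.append(res)
    return results
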