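"""Association analyses over the classified cohort.

Reproduces the analysis battery used for ATN risk-factor studies:

* age- and sex-adjusted binary logistic models of each pathology axis
  (A+/T+/N+) on individual risk factors (odds ratios, Wald 95% CI);
* multinomial logistic models of five-group membership on each risk factor,
  adjusting for age, sex and study site, with the normal-biomarker group as
  reference (relative risk ratios);
* interaction scans adding risk-factor x age / x APOE4 / x sex product terms;
* five-group omnibus comparisons: one-way ANOVA with Bonferroni-adjusted
  pairwise t-tests for continuous variables, chi-square with adjusted
  standardized residuals for binary variables.

All regression inference is Wald-based on the maximum-likelihood fit;
models are complete-case on the variables they use, so each result carries
its own ``n_used``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .atn import ATNGroup, ATNStatus, Flag
from .cohort_io import ParticipantRecord, records_to_frame
from .risk_scores import CompositeResult

__all__ = [
    "AssociationResult",
    "GroupComparisonResult",
    "NonEstimableError",
    "GROUP_ORDER",
    "build_analysis_frame",
    "fit_pathology_logistic",
    "fit_multinomial",
    "interaction_scan",
    "compare_groups",
    "bonferroni_threshold",
]

# reference category first
GROUP_ORDER: tuple[str, ...] = (
    "normal_ad_biomarkers",
    "alzheimers_pathologic_change",
    "alzheimers_disease",
    "ad_and_non_ad_pathologic_change",
    "non_ad_pathologic_change",
)


class NonEstimableError(RuntimeError):
    """The requested effect cannot be estimated (separation, empty cells...)."""


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    estimate_type: Literal["OR", "RRR", "mean_difference"]
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    covariates: list[str] = field(default_factory=list)
    reference_category: str | None = None
    estimable: bool = True
    note: str = ""


@dataclass
class GroupComparisonResult:
    variable: str
    test: Literal["anova", "chi_square"]
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    adjusted_residuals: dict[str, float] | None = None
    bonferroni_threshold: float | None = None
    warnings: list[str] = field(default_factory=list)


def bonferroni_threshold(family_alpha: float, m: int) -> float:
    """Per-test significance level after Bonferroni division."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / m

# named presets for the family-wise level (both conventions are in active
# use; the per-table division count is supplied by the caller)
BONFERRONI_PRESETS = {"strict": 0.05, "lenient": 0.5}


def build_analysis_frame(records: Sequence[ParticipantRecord],
                         statuses: Sequence[ATNStatus],
                         scores: Mapping[str, Sequence[CompositeResult]] | None = None,
                         ) -> pd.DataFrame:
    """Assemble the per-participant analysis table.

    Columns: the cohort schema, boolean pathology flags ``a_pos``/``t_pos``/
    ``n_pos`` (NaN when missing), the five-group ``group`` label, and — when
    composite scores are supplied — ``<score>_raw`` and ``<score>_z``.
    """
    if len(records) != len(statuses):
        raise ValueError("records and statuses must align")
    frame = records_to_frame(records)
    flag_to_num = {Flag.POSITIVE: 1.0, Flag.NEGATIVE: 0.0, Flag.MISSING: np.nan}
    frame["a_pos"] = [flag_to_num[s.a_flag] for s in statuses]
    frame["t_pos"] = [flag_to_num[s.t_flag] for s in statuses]
    frame["n_pos"] = [flag_to_num[s.n_flag] for s in statuses]
    frame["group"] = [s.group.value for s in statuses]
    if scores:
        for name, results in scores.items():
            by_id = {r.participant_id: r for r in results}
            frame[f"{name}_raw"] = [
                (by_id[p].raw_points if p in by_id and not by_id[p].incomplete
                 else np.nan) for p in frame["participant_id"]]
            frame[f"{name}_z"] = [
                (by_id[p].z_score if p in by_id and by_id[p].z_score is not None
                 else np.nan) for p in frame["participant_id"]]
    return frame


def _numeric_design(frame: pd.DataFrame, terms: Sequence[str],
                    include_site: bool = False) -> pd.DataFrame:
    """Build a numeric design matrix (constant first) from schema columns.

    Boolean-like columns become 0/1 floats; ``site_id`` expands to
    fixed-effect dummies (first site as reference).
    """
    X = pd.DataFrame(index=frame.index)
    for term in terms:
        col = frame[term]
        if col.dtype == object:
            col = col.map(lambda v: np.nan if v is None else float(v))
        X[term] = col.astype(float)
    if include_site:
        dummies = pd.get_dummies(frame["site_id"].astype(str), prefix="site",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return sm.add_constant(X, has_constant="add")


def _wald_row(params: pd.Series, bse: pd.Series, term: str,
              z975: float = 1.959963984540054) -> tuple[float, float, float, float]:
    beta = float(params[term])
    se = float(bse[term])
    ratio = float(np.exp(beta))
    lo = float(np.exp(beta - z975 * se))
    hi = float(np.exp(beta + z975 * se))
    p = float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return ratio, lo, hi, p


_SEPARATION_SE = 50.0  # |coef| or SE beyond this flags quasi-separation


def fit_pathology_logistic(frame: pd.DataFrame,
                           outcome: Literal["a_pos", "t_pos", "n_pos"],
                           exposure: str,
                           covariates: Sequence[str] = ("age", "sex_female"),
                           ) -> AssociationResult:
    """Age- and sex-adjusted logistic regression of one pathology flag.

    Complete-case on outcome, exposure and covariates; returns the
    exposure's odds ratio with Wald 95% CI. Perfect or quasi-separation is
    reported as a non-estimable result rather than a numeric artefact.
    """
    terms = [exposure] + [c for c in covariates if c != exposure]
    X = _numeric_design(frame, terms)
    y = frame[outcome].astype(float)
    mask = y.notna() & X.notna().all(axis=1)
    X, y = X[mask], y[mask]
    n_used = int(mask.sum())
    if n_used < X.shape[1] + 1:
        raise NonEstimableError(f"only {n_used} complete cases for {X.shape[1]} parameters")
    outcome_name = {"a_pos": "A+", "t_pos": "T+", "n_pos": "N+"}[outcome]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return AssociationResult(outcome_name, exposure, "OR",
                                 float("nan"), float("nan"), float("nan"),
                                 float("nan"), n_used, list(covariates),
                                 estimable=False, note=str(exc))
    if (abs(fit.params[exposure]) > _SEPARATION_SE
            or fit.bse[exposure] > _SEPARATION_SE
            or not np.isfinite(fit.bse[exposure])):
        return AssociationResult(outcome_name, exposure, "OR",
                                 float("nan"), float("nan"), float("nan"),
                                 float("nan"), n_used, list(covariates),
                                 estimable=False, note="separation suspected")
    orr, lo, hi, p = _wald_row(fit.params, fit.bse, exposure)
    return AssociationResult(outcome_name, exposure, "OR", orr, lo, hi, p,
                             n_used, list(covariates))


def _prepare_multinomial(frame: pd.DataFrame, terms: Sequence[str],
                         include_site: bool) -> tuple[pd.DataFrame, np.ndarray, list[str], int]:
    present = [g for g in GROUP_ORDER if g in set(frame["group"])]
    if GROUP_ORDER[0] not in present:
        raise NonEstimableError("reference group absent from data")
    if len(present) < 2:
        raise NonEstimableError("need at least two groups")
    sub = frame[frame["group"].isin(present)]
    X = _numeric_design(sub, terms, include_site=include_site)
    mask = X.notna().all(axis=1)
    X = X[mask]
    labels = sub.loc[mask, "group"]
    cats = [g for g in present if g in set(labels)]
    if cats[0] != GROUP_ORDER[0]:
        raise NonEstimableError("reference group lost after listwise deletion")
    codes = pd.Categorical(labels, categories=cats).codes
    return X, np.asarray(codes), cats, int(mask.sum())


def _fit_mnlogit(codes: np.ndarray, X: pd.DataFrame):
    """Newton fit with a quasi-Newton fallback for near-singular Hessians
    (small groups crossed with many site dummies)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MNLogit(codes, X).fit(disp=0, maxiter=300, method="newton")
            if np.all(np.isfinite(np.asarray(fit.params))):
                return fit
        except (np.linalg.LinAlgError, ValueError):
            pass
        try:
            fit = sm.MNLogit(codes, X).fit(disp=0, maxiter=2000, method="lbfgs")
        except (np.linalg.LinAlgError, PerfectSeparationError, ValueError) as exc:
            raise NonEstimableError(str(exc)) from exc
        if not np.all(np.isfinite(np.asarray(fit.params))):
            raise NonEstimableError("multinomial fit did not converge")
        return fit


def fit_multinomial(frame: pd.DataFrame, exposure: str,
                    include_site: bool = True,
                    covariates: Sequence[str] = ("age", "sex_female"),
                    ) -> list[AssociationResult]:
    """Multinomial logit of five-group membership on one risk factor.

    Adjusts for age, sex and (optionally) study site; the normal-biomarker
    group is the reference, and each non-reference group's relative risk
    ratio (RRR) for the exposure is returned with Wald 95% CI.
    """
    terms = [exposure] + [c for c in covariates if c != exposure]
    X, codes, cats, n_used = _prepare_multinomial(frame, terms, include_site)
    fit = _fit_mnlogit(codes, X)
    results = []
    exog_names = list(X.columns)
    row = exog_names.index(exposure)
    params = np.asarray(fit.params)     # (k_exog, n_cat-1)
    bse = np.asarray(fit.bse)
    for j, cat in enumerate(cats[1:]):
        beta, se = params[row, j], bse[row, j]
        if abs(beta) > _SEPARATION_SE or se > _SEPARATION_SE or not np.isfinite(se):
            results.append(AssociationResult(
                cat, exposure, "RRR", float("nan"), float("nan"), float("nan"),
                float("nan"), n_used, list(covariates), cats[0],
                estimable=False, note="separation suspected"))
            continue
        z = 1.959963984540054
        results.append(AssociationResult(
            cat, exposure, "RRR",
            float(np.exp(beta)), float(np.exp(beta - z * se)),
            float(np.exp(beta + z * se)),
            float(2 * sps.norm.sf(abs(beta) / se)), n_used,
            list(covariates), cats[0]))
    return results


def interaction_scan(frame: pd.DataFrame, exposure: str,
                     moderator: Literal["apoe4_carrier", "age", "sex_female"],
                     include_site: bool = False,
                     covariates: Sequence[str] = ("age", "sex_female"),
                     ) -> list[AssociationResult]:
    """Add an exposure x moderator product term to the multinomial model and
    test it per group contrast."""
    sub = frame.copy()
    mod_col = sub[moderator]
    if mod_col.dtype == object:
        mod_col = mod_col.map(lambda v: np.nan if v is None else float(v))
    mod_num = mod_col.astype(float)
    if mod_num.dropna().nunique() < 2:
        raise NonEstimableError("moderator is constant in the sample")
    exp_col = sub[exposure]
    if exp_col.dtype == object:
        exp_col = exp_col.map(lambda v: np.nan if v is None else float(v))
    product = f"{exposure}_x_{moderator}"
    sub[product] = exp_col.astype(float) * mod_num
    terms = [exposure]
    if moderator not in (exposure, *covariates):
        terms.append(moderator)
    terms += [c for c in covariates if c not in terms]
    terms.append(product)
    X, codes, cats, n_used = _prepare_multinomial(sub, terms, include_site)
    fit = _fit_mnlogit(codes, X)
    row = list(X.columns).index(product)
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    out = []
    for j, cat in enumerate(cats[1:]):
        beta, se = params[row, j], bse[row, j]
        z = 1.959963984540054
        estimable = np.isfinite(se) and se <= _SEPARATION_SE and abs(beta) <= _SEPARATION_SE
        out.append(AssociationResult(
            cat, product, "RRR",
            float(np.exp(beta)) if estimable else float("nan"),
            float(np.exp(beta - z * se)) if estimable else float("nan"),
            float(np.exp(beta + z * se)) if estimable else float("nan"),
            float(2 * sps.norm.sf(abs(beta) / se)) if estimable else float("nan"),
            n_used, list(covariates), cats[0], estimable=estimable))
    return out


def adjusted_residuals(table: np.ndarray) -> np.ndarray:
    """Adjusted standardized residuals of an r x c contingency table.

    R_ij = (O_ij - E_ij) / sqrt(E_ij (1 - row_i/N) (1 - col_j/N)); |R| > 2
    flags cells driving an omnibus chi-square result.
    """
    table = np.asarray(table, dtype=float)
    N = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / N
    denom = np.sqrt(expected * (1 - row / N) * (1 - col / N))
    return (table - expected) / denom


def compare_groups(frame: pd.DataFrame, variable: str,
                   kind: Literal["continuous", "categorical"] | None = None,
                   family_alpha: float = 0.05) -> GroupComparisonResult:
    """Five-group omnibus comparison of one risk factor.

    Continuous variables: one-way ANOVA plus all 10 pairwise two-sample
    t-tests with Bonferroni-multiplied p-values capped at 1. Binary
    variables: 2 x 5 chi-square plus per-group adjusted standardized
    residuals of the risk-factor-present row.
    """
    groups_present = [g for g in GROUP_ORDER if g in set(frame["group"])]
    col = frame[variable]
    if col.dtype == object:
        col = col.map(lambda v: np.nan if v is None else float(v))
    values = col.astype(float)
    if kind is None:
        kind = "categorical" if values.dropna().isin([0.0, 1.0]).all() else "continuous"

    if kind == "continuous":
        samples = [values[(frame["group"] == g) & values.notna()].to_numpy()
                   for g in groups_present]
        stat, p = sps.f_oneway(*samples)
        pairs = []
        n_pairs = len(groups_present) * (len(groups_present) - 1) // 2
        for (gi, xi), (gj, xj) in itertools.combinations(zip(groups_present, samples), 2):
            _, p_raw = sps.ttest_ind(xi, xj, equal_var=True)
            pairs.append((gi, gj, float(min(1.0, p_raw * n_pairs))))
        return GroupComparisonResult(
            variable, "anova", float(stat), float(p), pairwise=pairs,
            bonferroni_threshold=family_alpha)

    # categorical: 2 x g table of flag value by group
    table = np.array([
        [int(((frame["group"] == g) & (values == 1.0)).sum()) for g in groups_present],
        [int(((frame["group"] == g) & (values == 0.0)).sum()) for g in groups_present],
    ], dtype=float)
    warn = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warn.append("expected cell count below 1; chi-square approximation unreliable")
    resid = adjusted_residuals(table)
    return GroupComparisonResult(
        variable, "chi_square", float(chi2), float(p),
        adjusted_residuals={g: float(resid[0, i]) for i, g in enumerate(groups_present)},
        bonferroni_threshold=family_alpha, warnings=warn)
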