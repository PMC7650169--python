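"""Biomarker dichotomization thresholds.

CSF analytes (Aβ42, p-Tau) are dichotomized by fitting a two-component
univariate Gaussian mixture to the cohort's values and cutting either at the
density intersection of the two weighted components or at a component mean
± k standard deviations. Neurodegeneration (Scheltens medial-temporal-atrophy
score) uses age-decade-specific thresholds.

The EM fitter is deliberately self-contained: it exposes its per-iteration
log-likelihood trace (``MixtureFit.loglik_trace``) so the monotone-ascent
property of EM can be asserted directly, and supports multiple random
restarts with a quantile-split initial start.

Default "fixed" rules ship with the established CSF cut-offs for the Roche
Elecsys assay in this population — Aβ42 < 1025 pg/ml ⇒ A+ and
p-Tau > 24 pg/ml ⇒ T+ — so classification can run without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "MixtureFit",
    "CutoffRule",
    "InsufficientDataError",
    "DegenerateDataError",
    "NoIntersectionError",
    "fit_two_component_mixture",
    "intersection_cutoff",
    "mean_sd_cutoff",
    "scheltens_threshold",
    "default_abeta_rule",
    "default_ptau_rule",
    "ABETA42_CUTOFF",
    "PTAU_CUTOFF",
]

ABETA42_CUTOFF = 1025.0  # pg/ml, amyloid positivity strictly below
PTAU_CUTOFF = 24.0       # pg/ml, tau positivity strictly above

MIN_N = 20


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


class NoIntersectionError(RuntimeError):
    """The weighted component densities do not cross between the means."""


@dataclass
class MixtureFit:
    """A fitted two-component univariate Gaussian mixture.

    Components are ordered so ``mean_1 <= mean_2``. ``loglik_trace`` holds
    the EM log-likelihood after each iteration of the winning restart.
    """

    weight_1: float
    weight_2: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    log_likelihood: float
    converged: bool
    n_used: int
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def separation(self) -> float:
        """Component separation |μ2 − μ1| / pooled SD; near 0 ⇒ effectively unimodal."""
        pooled = math.sqrt(0.5 * (self.sd_1 ** 2 + self.sd_2 ** 2))
        return abs(self.mean_2 - self.mean_1) / pooled

    def density(self, x: np.ndarray | float) -> np.ndarray | float:
        return (self.weight_1 * norm.pdf(x, self.mean_1, self.sd_1)
                + self.weight_2 * norm.pdf(x, self.mean_2, self.sd_2))


@dataclass(frozen=True)
class CutoffRule:
    """Dichotomization rule for one analyte.

    ``positive_direction`` gives the side of ``threshold`` (strict
    inequality) that counts as biomarker-positive.
    """

    analyte: Literal["abeta42", "ptau"]
    threshold: float
    positive_direction: Literal["below", "above"]
    method: Literal["intersection", "mean_sd", "fixed"]
    k_sd: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def is_positive(self, value: float | None) -> bool | None:
        """Apply the rule; ``None`` propagates missingness."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if self.positive_direction == "below":
            return value < self.threshold
        return value > self.threshold


def default_abeta_rule() -> CutoffRule:
    return CutoffRule("abeta42", ABETA42_CUTOFF, "below", "fixed")


def default_ptau_rule() -> CutoffRule:
    return CutoffRule("ptau", PTAU_CUTOFF, "above", "fixed")


# ---------------------------------------------------------------------------
# EM for a two-component univariate Gaussian mixture

_SD_FLOOR_FRAC = 1e-4  # floor component SDs at this fraction of the data SD


def _em_run(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray,
            tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, list[float]]:
    n = x.size
    sd_floor = _SD_FLOOR_FRAC * x.std()
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step via log densities for numerical stability
        log_comp = np.log(w)[None, :] + norm.logpdf(x[:, None], mu[None, :], sd[None, :])
        m = log_comp.max(axis=1, keepdims=True)
        log_mix = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        new_loglik = float(log_mix.sum())
        resp = np.exp(log_comp - log_mix[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        trace.append(new_loglik)
        if np.isfinite(loglik):
            denom = max(abs(loglik), 1.0)
            if (new_loglik - loglik) / denom < tol:
                loglik = new_loglik
                converged = True
                break
        loglik = new_loglik
    return w, mu, sd, loglik, converged, it, trace


def fit_two_component_mixture(values: Sequence[float] | np.ndarray, seed: int = 0,
                              n_starts: int = 10, tol: float = 1e-8,
                              max_iter: int = 500) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM, best of ``n_starts`` restarts.

    The first start splits the data at the median (a quantile analogue of
    k-means initialization); the remaining starts perturb means and weights
    randomly. Missing values are dropped. Requires at least 20 finite values
    and positive sample variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_N:
        raise InsufficientDataError(
            f"need at least {MIN_N} non-missing values, got {x.size}")
    if x.std() == 0:
        raise DegenerateDataError("values have zero variance")

    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for start in range(max(1, n_starts)):
        if start == 0:
            med = np.median(x)
            lo, hi = x[x <= med], x[x > med]
            mu0 = np.array([lo.mean(), hi.mean()])
            sd0 = np.array([max(lo.std(), 1e-3 * x.std()),
                            max(hi.std(), 1e-3 * x.std())])
            w0 = np.array([0.5, 0.5])
        else:
            mu0 = np.sort(rng.choice(x, size=2, replace=False))
            sd0 = np.full(2, x.std() * rng.uniform(0.3, 1.0))
            p = rng.uniform(0.2, 0.8)
            w0 = np.array([p, 1 - p])
        result = _em_run(x, w0, mu0, sd0, tol, max_iter)
        if best is None or result[3] > best[3]:
            best = result
    w, mu, sd, loglik, converged, n_iter, trace = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    return MixtureFit(
        weight_1=float(w[0]), weight_2=float(w[1]),
        mean_1=float(mu[0]), mean_2=float(mu[1]),
        sd_1=float(sd[0]), sd_2=float(sd[1]),
        log_likelihood=loglik, converged=converged,
        n_used=int(x.size), n_iter=n_iter, loglik_trace=trace)


def intersection_cutoff(fit: MixtureFit, analyte: Literal["abeta42", "ptau"] = "abeta42",
                        positive_direction: Literal["below", "above"] | None = None) -> CutoffRule:
    """Cut at the x between the means where the weighted densities are equal.

    Solves ``w1·φ(x; μ1, σ1) = w2·φ(x; μ2, σ2)`` in closed form — a quadratic
    in x when σ1 ≠ σ2, linear when equal — and selects the root inside
    (μ1, μ2). Raises :class:`NoIntersectionError` if no root lies strictly
    between the means (possible under extreme weight imbalance), in which
    case :func:`mean_sd_cutoff` is the fallback.
    """
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    if not fit.mean_1 < fit.mean_2:
        raise ValueError("component means must be distinct with mean_1 < mean_2")
    w1, w2 = fit.weight_1, fit.weight_2
    m1, m2 = fit.mean_1, fit.mean_2
    s1, s2 = fit.sd_1, fit.sd_2

    # equal log weighted densities:
    # (x-m2)^2/(2 s2^2) - (x-m1)^2/(2 s1^2) + log(w1 s2 / (w2 s1)) = 0
    c = math.log((w1 * s2) / (w2 * s1))
    if math.isclose(s1, s2, rel_tol=1e-12, abs_tol=1e-12):
        # linear: (m1 - m2) x + (m2^2 - m1^2)/2 + s^2 c = 0
        x = ((m2 ** 2 - m1 ** 2) / 2 + s1 ** 2 * c) / (m2 - m1)
        roots = [x]
    else:
        a2 = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
        a1 = m1 / s1 ** 2 - m2 / s2 ** 2
        a0 = m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2) + c
        disc = a1 ** 2 - 4 * a2 * a0
        if disc < 0:
            raise NoIntersectionError(
                "no density intersection between the component means; "
                "use mean_sd_cutoff instead")
        sq = math.sqrt(disc)
        roots = [(-a1 - sq) / (2 * a2), (-a1 + sq) / (2 * a2)]
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        raise NoIntersectionError(
            "no density intersection between the component means; "
            "use mean_sd_cutoff instead")
    x = inside[0]
    # verify: both weighted densities agree at the root
    d1 = w1 * norm.pdf(x, m1, s1)
    d2 = w2 * norm.pdf(x, m2, s2)
    if abs(d1 - d2) > 1e-8 * max(d1, d2):
        raise NoIntersectionError("intersection verification failed")
    if positive_direction is None:
        positive_direction = "below" if analyte == "abeta42" else "above"
    return CutoffRule(analyte, float(x), positive_direction, "intersection")


def mean_sd_cutoff(fit: MixtureFit, component: Literal["lower", "upper"] = "lower",
                   k_sd: float = 2.0, analyte: Literal["abeta42", "ptau"] = "abeta42",
                   positive_direction: Literal["below", "above"] | None = None) -> CutoffRule:
    """Cut at a component mean ± k·SD, moving toward the other component."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    if component == "lower":
        threshold = fit.mean_1 + k_sd * fit.sd_1
    else:
        threshold = fit.mean_2 - k_sd * fit.sd_2
    if positive_direction is None:
        positive_direction = "below" if analyte == "abeta42" else "above"
    return CutoffRule(analyte, float(threshold), positive_direction, "mean_sd", k_sd=k_sd)


def scheltens_threshold(age: float) -> float:
    """Age-specific Scheltens MTA threshold: N+ is a score strictly above it.

    1.0 under age 65, 1.5 for 65–74, and 2.0 from 75 up (age exactly 75
    falls in the oldest band).
    """
    if age <= 0:
        raise ValueError("age must be positive")
    if age < 65:
        return 1.0
    if age < 75:
        return 1.5
    return 2.0
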