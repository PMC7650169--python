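import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from atnpredict import atn, stats, synthetic
from atnpredict.stats import (
    NonEstimableError, adjusted_residuals, bonferroni_threshold,
    build_analysis_frame, compare_groups, fit_multinomial,
    fit_pathology_logistic, interaction_scan,
)


def model_frame(seed, n, intercepts, coefficients, covariates, categories=None,
                outcome="multinomial"):
    mode = synthetic.ModelMode(
        outcome=outcome, covariates=covariates, intercepts=intercepts,
        coefficients=coefficients,
        categories=categories or list(stats.GROUP_ORDER))
    config = synthetic.CohortConfig(
        seed=seed, model_mode=mode,
        combination_counts={(False, False, False): n})
    records = synthetic.generate_from_model(config)
    return build_analysis_frame(records, atn.classify_cohort(records))


class TestBonferroni:
    def test_published_footnote_arithmetic(self):
        assert bonferroni_threshold(0.5, 21) == pytest.approx(0.0238, abs=5e-4)

    def test_identity_and_division(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 84) == pytest.approx(0.05 / 84)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


class TestPathologyLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # 2x2 table: exposed cases 30, exposed controls 20,
        # unexposed cases 10, unexposed controls 40 -> OR = 30*40/(20*10) = 6
        rows = ([{"x": 1.0, "y": 1.0}] * 30 + [{"x": 1.0, "y": 0.0}] * 20
                + [{"x": 0.0, "y": 1.0}] * 10 + [{"x": 0.0, "y": 0.0}] * 40)
        frame = pd.DataFrame(rows).rename(columns={"x": "apoe4_carrier",
                                                   "y": "a_pos"})
        result = fit_pathology_logistic(frame, "a_pos", "apoe4_carrier",
                                        covariates=())
        assert result.estimate == pytest.approx(6.0, rel=1e-4)

    def test_null_exposure_recovers_unity(self):
        frame = model_frame(
            seed=40, n=50000, intercepts=[-0.8],
            coefficients={"apoe4_carrier": [0.0], "age": [0.0]},
            covariates={"apoe4_carrier": ("bernoulli", 0.4),
                        "age": ("normal", 64.0, 7.0)},
            outcome="binary")
        result = fit_pathology_logistic(frame, "a_pos", "apoe4_carrier",
                                        covariates=("age",))
        assert 0.95 <= result.estimate <= 1.05

    def test_adjusted_coefficient_recovery(self):
        beta_age, beta_apoe = math.log(1.03), math.log(2.24)
        frame = model_frame(
            seed=41, n=100000,
            intercepts=[math.log(0.3 / 0.7) - beta_age * 64.6 - beta_apoe * 0.375],
            coefficients={"age": [beta_age], "sex_female": [0.0],
                          "apoe4_carrier": [beta_apoe]},
            covariates={"age": ("normal", 64.6, 6.8),
                        "sex_female": ("bernoulli", 0.59),
                        "apoe4_carrier": ("bernoulli", 0.375)},
            outcome="binary")
        result = fit_pathology_logistic(frame, "a_pos", "apoe4_carrier")
        assert abs(result.estimate - 2.24) / 2.24 < 0.05
        assert result.ci_low < result.estimate < result.ci_high

    def test_complete_separation_reported_not_crashed(self):
        frame = pd.DataFrame({
            "apoe4_carrier": [0.0] * 20 + [1.0] * 20,
            "a_pos": [0.0] * 20 + [1.0] * 20})
        result = fit_pathology_logistic(frame, "a_pos", "apoe4_carrier",
                                        covariates=())
        assert not result.estimable

    def test_too_few_rows_raise(self):
        frame = pd.DataFrame({"apoe4_carrier": [0.0, 1.0], "a_pos": [0.0, 1.0],
                              "age": [60.0, 61.0], "sex_female": [1.0, 0.0]})
        with pytest.raises(NonEstimableError):
            fit_pathology_logistic(frame, "a_pos", "apoe4_carrier")


class TestMultinomial:
    def test_binary_reduction_matches_logistic(self, analysis_frame):
        sub = analysis_frame[analysis_frame["group"].isin(
            ["normal_ad_biomarkers", "alzheimers_disease"])]
        multi = fit_multinomial(sub, "apoe4_carrier", include_site=False)
        assert len(multi) == 1
        # same data, same model: the AD-contrast RRR equals the logistic OR
        sub3 = sub.copy()
        sub3["a_pos"] = (sub3["group"] == "alzheimers_disease").astype(float)
        binary = fit_pathology_logistic(sub3, "a_pos", "apoe4_carrier")
        assert multi[0].estimate == pytest.approx(binary.estimate, rel=1e-6)
        assert multi[0].p_value == pytest.approx(binary.p_value, rel=1e-4, abs=1e-12)

    def test_reference_category_is_normal_group(self, analysis_frame):
        results = fit_multinomial(analysis_frame, "apoe4_carrier")
        assert all(r.reference_category == "normal_ad_biomarkers" for r in results)
        assert len(results) == 4

    def test_generating_rrr_recovered(self):
        shares = np.array([567, 211, 67, 31, 134]) / 1010
        log_rrr = np.log([1.93, 6.48, 1.09, 1.27])
        frame = model_frame(
            seed=42, n=60000,
            intercepts=list(np.log(shares[1:] / shares[0]) - log_rrr * 0.375),
            coefficients={"apoe4_carrier": list(log_rrr),
                          "age": [0.0] * 4, "sex_female": [0.0] * 4},
            covariates={"apoe4_carrier": ("bernoulli", 0.375),
                        "age": ("normal", 64.6, 6.8),
                        "sex_female": ("bernoulli", 0.59)})
        results = {r.outcome: r for r in fit_multinomial(frame, "apoe4_carrier")}
        ad = results["alzheimers_disease"]
        assert abs(ad.estimate - 6.48) / 6.48 < 0.10

    def test_missing_reference_group_raises(self, analysis_frame):
        sub = analysis_frame[analysis_frame["group"] != "normal_ad_biomarkers"]
        with pytest.raises(NonEstimableError):
            fit_multinomial(sub, "apoe4_carrier")


class TestInteractionScan:
    def test_constant_moderator_non_estimable(self, analysis_frame):
        frame = analysis_frame.copy()
        frame["apoe4_carrier"] = True
        with pytest.raises(NonEstimableError):
            interaction_scan(frame, "bmi", "apoe4_carrier")

    def test_null_product_term_p_values_are_uniform(self):
        """With no generated interaction, product-term p-values follow U(0,1)."""
        pvals = []
        for seed in range(60):
            frame = model_frame(
                seed=500 + seed, n=900, intercepts=[-0.8, -1.4],
                coefficients={"bmi": [0.05, 0.02], "apoe4_carrier": [0.5, 0.9]},
                covariates={"bmi": ("normal", 26.4, 4.3),
                            "apoe4_carrier": ("bernoulli", 0.375)},
                categories=["normal_ad_biomarkers",
                            "alzheimers_pathologic_change",
                            "alzheimers_disease"])
            res = interaction_scan(frame, "bmi", "apoe4_carrier",
                                   covariates=())
            pvals.extend(r.p_value for r in res if r.estimable)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_generated_interaction_recovered(self):
        gamma = 0.3
        rng = np.random.default_rng(77)
        n = 60000
        bmi_c = rng.normal(0.0, 4.3, n)  # centred exposure keeps conditioning sane
        apoe = (rng.random(n) < 0.375).astype(float)
        eta = -1.0 + 0.02 * bmi_c + 0.4 * apoe + gamma * bmi_c * apoe
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        frame = pd.DataFrame({
            "bmi": bmi_c, "apoe4_carrier": apoe,
            "group": np.where(y, "alzheimers_pathologic_change",
                              "normal_ad_biomarkers")})
        res = interaction_scan(frame, "bmi", "apoe4_carrier", covariates=())
        est = [r for r in res if r.estimable][0]
        assert abs(math.log(est.estimate) - gamma) / gamma < 0.10


class TestCompareGroups:
    def test_residuals_zero_on_exact_independence(self):
        # observed == expected in every cell of a 2x5 table
        table = np.outer([40, 60], [10, 20, 30, 25, 15])
        assert np.allclose(adjusted_residuals(table / 100.0), 0.0)

    def test_residuals_match_direct_formula(self):
        table = np.array([[12, 7, 30, 4, 9], [88, 43, 170, 27, 41]], dtype=float)
        resid = adjusted_residuals(table)
        N = table.sum()
        for i in range(2):
            for j in range(5):
                expected = table[i].sum() * table[:, j].sum() / N
                denom = math.sqrt(expected * (1 - table[i].sum() / N)
                                  * (1 - table[:, j].sum() / N))
                assert resid[i, j] == pytest.approx(
                    (table[i, j] - expected) / denom)

    def test_continuous_variable_uses_anova_with_capped_pairs(self, analysis_frame):
        result = compare_groups(analysis_frame, "age")
        assert result.test == "anova"
        assert len(result.pairwise) == 10
        assert all(0 < p <= 1 for _, _, p in result.pairwise)

    def test_categorical_variable_uses_chi_square_with_residuals(self, analysis_frame):
        result = compare_groups(analysis_frame, "apoe4_carrier")
        assert result.test == "chi_square"
        assert set(result.adjusted_residuals) == set(stats.GROUP_ORDER)
        # APOE4 enrichment in the AD group is the hallmark subgroup effect
        assert result.adjusted_residuals["alzheimers_disease"] > 2
        assert result.adjusted_residuals["normal_ad_biomarkers"] < -2

    def test_null_omnibus_rarely_significant(self):
        """Identical group distributions: ANOVA p exceeds alpha in >=94/100 seeds."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            frame = pd.DataFrame({
                "group": np.repeat(list(stats.GROUP_ORDER), 40),
                "age": rng.normal(65, 7, 200)})
            if compare_groups(frame, "age").omnibus_p <= 0.05:
                hits += 1
        assert hits <= 6
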