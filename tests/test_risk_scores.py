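import dataclasses

import numpy as np
import pytest

from atnpredict import risk_scores
from atnpredict.risk_scores import (
    Band, Component, ScoringTable, TableValidationError, caide_score,
    framingham_cvd_score, framingham_stroke_score, load_default_table,
    score_record, standardize,
)

from conftest import make_record


@pytest.fixture(scope="module")
def caide_table():
    return load_default_table("caide")


@pytest.fixture(scope="module")
def cvd_table():
    return load_default_table("framingham_cvd")


@pytest.fixture(scope="module")
def stroke_table():
    return load_default_table("framingham_stroke")


class TestTableValidation:
    @pytest.mark.parametrize("name", ["caide", "framingham_cvd", "framingham_stroke"])
    def test_default_tables_load_with_valid_band_partitions(self, name):
        table = load_default_table(name)  # validate() runs in __post_init__
        assert table.score_name == name

    def test_band_gap_rejected(self):
        comp = Component("x", "bmi", "both", "numeric",
                         bands=(Band(0, 20, 0), Band(25, 100, 2)),
                         range=(0.0, 100.0))
        with pytest.raises(TableValidationError, match="gap or overlap"):
            ScoringTable("bad", False, [comp])

    def test_band_overlap_rejected(self):
        comp = Component("x", "bmi", "both", "numeric",
                         bands=(Band(0, 30, 0), Band(25, 100, 2)),
                         range=(0.0, 100.0))
        with pytest.raises(TableValidationError):
            ScoringTable("bad", False, [comp])

    def test_incomplete_coverage_rejected(self):
        comp = Component("x", "bmi", "both", "numeric",
                         bands=(Band(0, 30, 0),), range=(0.0, 100.0))
        with pytest.raises(TableValidationError):
            ScoringTable("bad", False, [comp])

    def test_sex_specific_table_must_cover_both_sexes(self):
        comp = Component("x", "bmi", "female", "numeric",
                         bands=(Band(0, 100, 0),), range=(0.0, 100.0))
        with pytest.raises(TableValidationError, match="both sexes"):
            ScoringTable("bad", True, [comp])


class TestCaide:
    def test_cholesterol_flag_adds_exactly_two_points(self, caide_table):
        low = caide_score(make_record(high_cholesterol=False), caide_table)
        high = caide_score(make_record(high_cholesterol=True), caide_table)
        assert high.raw_points - low.raw_points == 2

    def test_minimum_risk_profile_scores_zero(self, caide_table):
        rec = make_record(age=45.0, sex_female=True, education_years=16.0,
                          systolic_bp=120.0, bmi=24.0, high_cholesterol=False,
                          physical_inactivity=False)
        assert caide_score(rec, caide_table).raw_points == 0

    def test_worked_profile_matches_hand_sum(self, caide_table):
        # 66-y male, 8 y education, SBP 150, BMI 32, cholesterol, inactive:
        # age 4 + sex 1 + education 2 + SBP 2 + BMI 2 + chol 2 + inactivity 1 = 14
        rec = make_record(age=66.0, sex_female=False, education_years=8.0,
                          systolic_bp=150.0, bmi=32.0, high_cholesterol=True,
                          physical_inactivity=True)
        assert caide_score(rec, caide_table).raw_points == 14

    def test_score_bounded_by_table_maximum(self, caide_table):
        assert caide_table.max_points == 15
        rng = np.random.default_rng(0)
        for i in range(200):
            rec = make_record(age=float(rng.uniform(20, 90)),
                              sex_female=bool(rng.integers(2)),
                              education_years=float(rng.uniform(0, 25)),
                              systolic_bp=float(rng.uniform(90, 200)),
                              bmi=float(rng.uniform(15, 45)),
                              high_cholesterol=bool(rng.integers(2)),
                              physical_inactivity=bool(rng.integers(2)))
            points = caide_score(rec, caide_table).raw_points
            assert 0 <= points <= 15


class TestFraminghamCvd:
    def test_sex_subtables_differ(self, cvd_table):
        # a 66-y smoker: female age 10 + smoke 3 = 13; male age 12 + smoke 4 = 16
        female = framingham_cvd_score(
            make_record(sex_female=True, age=66.0, ever_smoked=True), cvd_table)
        male = framingham_cvd_score(
            make_record(sex_female=False, age=66.0, ever_smoked=True), cvd_table)
        assert female.raw_points == 13
        assert male.raw_points == 16

    @pytest.mark.parametrize("female,diabetes_points", [(True, 4), (False, 3)])
    def test_cholesterol_scores_sex_specific_diabetes_points(
            self, cvd_table, female, diabetes_points):
        base = make_record(sex_female=female, high_cholesterol=False)
        flagged = make_record(sex_female=female, high_cholesterol=True)
        delta = (framingham_cvd_score(flagged, cvd_table).raw_points
                 - framingham_cvd_score(base, cvd_table).raw_points)
        assert delta == diabetes_points

    def test_treated_bp_bands_differ_from_untreated(self, cvd_table):
        untreated = make_record(sex_female=True, systolic_bp=135.0,
                                bp_medication=False)
        treated = make_record(sex_female=True, systolic_bp=135.0,
                              bp_medication=True)
        delta = (framingham_cvd_score(treated, cvd_table).raw_points
                 - framingham_cvd_score(untreated, cvd_table).raw_points)
        assert delta == 2  # women 130-139 mmHg: treated 3 vs untreated 1

    def test_all_lowest_band_profile_is_table_minimum(self, cvd_table):
        # young never-smoker, SBP < 120 untreated: women score the -3 SBP band
        rec = make_record(sex_female=True, age=30.0, systolic_bp=110.0)
        assert framingham_cvd_score(rec, cvd_table).raw_points == -3

    def test_missing_sex_is_incomplete(self, cvd_table):
        result = framingham_cvd_score(make_record(sex_female=None), cvd_table)
        assert result.incomplete and result.raw_points is None


class TestFraminghamStroke:
    def test_prior_cvd_toggle_adds_encoded_points(self, stroke_table):
        for female, pts in ((True, 2), (False, 4)):
            base = make_record(sex_female=female, prior_cvd=False)
            cvd = make_record(sex_female=female, prior_cvd=True)
            delta = (framingham_stroke_score(cvd, stroke_table).raw_points
                     - framingham_stroke_score(base, stroke_table).raw_points)
            assert delta == pts

    def test_all_lowest_band_profile_is_minimum(self, stroke_table):
        rec = make_record(sex_female=True, age=50.0, systolic_bp=100.0)
        assert framingham_stroke_score(rec, stroke_table).raw_points == 0

    def test_missing_component_field_is_incomplete(self, stroke_table):
        result = framingham_stroke_score(
            make_record(atrial_fibrillation=None), stroke_table)
        assert result.incomplete and result.raw_points is None

    def test_lvh_defaults_to_absent(self, stroke_table):
        rec = make_record()
        assert rec.left_ventricular_hypertrophy is False
        assert not framingham_stroke_score(rec, stroke_table).incomplete


class TestMonotonicity:
    def test_worsening_a_component_never_decreases_total(self, cvd_table):
        worsenings = [
            ("age", [30.0, 40.0, 52.0, 66.0, 80.0]),
            ("systolic_bp", [110.0, 125.0, 135.0, 145.0, 170.0]),
        ]
        for sex_female in (True, False):
            for field_name, values in worsenings:
                points = [framingham_cvd_score(
                    make_record(sex_female=sex_female, **{field_name: v}),
                    cvd_table).raw_points for v in values]
                assert points == sorted(points)


class TestStandardize:
    def make_results(self, values):
        return [risk_scores.CompositeResult("caide", f"P{i}", v)
                for i, v in enumerate(values)]

    def test_mean_zero_sd_one(self):
        results = standardize(self.make_results([2, 5, 7, 11, 3]))
        z = np.array([r.z_score for r in results])
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_two_values_sample_sd_convention(self):
        results = standardize(self.make_results([4, 6]))
        # sample SD of {4, 6} is sqrt(2); z = ±1/sqrt(2)
        assert results[0].z_score == pytest.approx(-0.7071067811865475)
        assert results[1].z_score == pytest.approx(+0.7071067811865475)

    def test_incomplete_results_excluded(self):
        results = self.make_results([1, 2, 3, 4])
        results.append(risk_scores.CompositeResult("caide", "P9", None,
                                                   incomplete=True))
        standardize(results)
        complete_z = [r.z_score for r in results if not r.incomplete]
        assert all(z is not None for z in complete_z)
        assert results[-1].z_score is None
        # z computed from the four complete values only
        vals = np.array([1, 2, 3, 4], dtype=float)
        expected = (vals - vals.mean()) / vals.std(ddof=1)
        assert np.allclose(complete_z, expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize(self.make_results([5, 5, 5]))
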