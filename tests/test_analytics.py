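"""Fit-scoring, star-plot and gap-query tests, including brute-force
equivalence and monotonicity properties."""

import math

import pytest

from semcds import analytics, cohorts, fixtures
from semcds.analytics import GapFilter, GapQuerySpec
from semcds.cohorts import CohortGrid
from semcds.errors import ValidationError, VocabularyError


@pytest.fixture(scope="module")
def lexicon():
    return cohorts.default_lexicon()


def simple_model(eligibility=None):
    grid = CohortGrid(
        study_id="s1",
        cells=(
            ("Characteristic", "Metformin (n=342)"),
            ("Age (years)", "55.0 ± 10.0"),
            ("Systolic blood pressure (mmHg)", "130.0 ± 15.0"),
            ("HbA1c (%)", "7.5 ± 1.0"),
            ("Diabetes duration (years)", "8.0 [5.0–12.0]"),
            ("African American", "40 (11.7%)"),
        ),
        eligibility=eligibility,
    )
    return cohorts.assemble_cohort(grid)


class TestFitPatient:
    def test_patient_at_arm_center_scores_one(self):
        model = simple_model()
        patient = {"record_id": "p", "age": 55.0, "sbp": 130.0, "hba1c": 7.5}
        report = analytics.fit_patient(patient, model, "Metformin",
                                       ["age", "sbp", "hba1c"])
        assert report.fit_score == 1.0
        assert report.evaluated_n == 3 and report.skipped == ()

    def test_score_is_fraction_in_range(self):
        model = simple_model()
        patient = {"record_id": "p", "age": 80.0, "sbp": 130.0, "hba1c": 7.0}
        report = analytics.fit_patient(patient, model, "Metformin",
                                       ["age", "sbp", "hba1c"])
        recount = sum(1 for f in report.features if f.in_range)
        assert report.fit_score == recount / report.evaluated_n == 2 / 3

    def test_iqr_band_used_for_median_statistics(self):
        model = simple_model()
        inside = analytics.fit_patient(
            {"record_id": "p", "dm_duration": 6.0}, model, "Metformin",
            ["dm_duration"])
        outside = analytics.fit_patient(
            {"record_id": "p", "dm_duration": 13.0}, model, "Metformin",
            ["dm_duration"])
        assert inside.fit_score == 1.0 and outside.fit_score == 0.0

    def test_sd_multiplier_widens_band(self):
        model = simple_model()
        patient = {"record_id": "p", "age": 70.0}
        narrow = analytics.fit_patient(patient, model, "Metformin", ["age"])
        wide = analytics.fit_patient(patient, model, "Metformin", ["age"],
                                     sd_multiplier=2.0)
        assert narrow.fit_score == 0.0 and wide.fit_score == 1.0

    def test_eligibility_age_range_takes_precedence(self):
        model = simple_model(eligibility={"age_min": 50, "age_max": 75})
        patient = {"record_id": "p", "age": 48.0}  # inside mean±SD, below floor
        report = analytics.fit_patient(patient, model, "Metformin", ["age"])
        assert report.fit_score == 0.0
        assert report.features[0].arm_low == 50

    def test_categorical_representation(self, lexicon):
        model = simple_model()
        report = analytics.fit_patient(
            {"record_id": "p", "race": "African American"}, model, "Metformin",
            ["race"], lexicon=lexicon)
        assert report.features[0].in_range

    def test_missing_features_are_skipped_not_failed(self):
        model = simple_model()
        report = analytics.fit_patient(
            {"record_id": "p", "age": 55.0}, model, "Metformin",
            ["age", "bmi", "egfr"])
        assert report.evaluated_n == 1
        assert set(report.skipped) == {"bmi", "egfr"}
        assert report.evaluated_n + len(report.skipped) == 3

    def test_no_comparable_features_is_an_error(self):
        model = simple_model()
        with pytest.raises(ValidationError, match="none of"):
            analytics.fit_patient({"record_id": "p", "egfr": 60.0}, model,
                                  "Metformin", ["egfr"])

    def test_fit_score_monotonic_under_feature_append(self):
        model = simple_model()
        base = {"record_id": "p", "age": 55.0, "sbp": 300.0}
        features = ["sbp"]
        report = analytics.fit_patient(base, model, "Metformin", features)
        appended_in = analytics.fit_patient(base, model, "Metformin",
                                            features + ["age"])
        assert appended_in.fit_score >= report.fit_score
        high = {"record_id": "p", "age": 55.0, "sbp": 130.0, "hba1c": 20.0}
        report2 = analytics.fit_patient(high, model, "Metformin", ["age", "sbp"])
        appended_out = analytics.fit_patient(high, model, "Metformin",
                                             ["age", "sbp", "hba1c"])
        assert appended_out.fit_score <= report2.fit_score

    def test_bruteforce_recount_on_random_pairs(self, lexicon):
        features = ["age", "sbp", "dbp", "hba1c", "bmi"]
        patients, _ = fixtures.gen_patients(20, seed=23)
        specs = [fixtures.random_cohort_spec(f"bf{i}", seed=100 + i) for i in range(5)]
        models = [cohorts.assemble_cohort(fixtures.gen_cohort_grid(s)[0], lexicon)
                  for s in specs]
        n_pairs = 0
        for model in models:
            for patient in patients:
                report = analytics.fit_patient(patient, model,
                                               model.arms[0].arm_name, features)
                expected_hits = 0
                for f in report.features:
                    assert f.arm_low <= f.arm_high
                    if f.arm_low <= f.patient_value <= f.arm_high:
                        expected_hits += 1
                assert math.isclose(report.fit_score,
                                    expected_hits / report.evaluated_n)
                n_pairs += 1
        assert n_pairs == 100


class TestStarPlot:
    def report(self, n=4):
        model = simple_model()
        patient = {"record_id": "p", "age": 55.0, "sbp": 120.0, "hba1c": 9.0,
                   "dm_duration": 8.0}
        return analytics.fit_patient(
            patient, model, "Metformin", ["age", "sbp", "hba1c", "dm_duration"][:n])

    def test_four_features_give_right_angles(self):
        data = analytics.star_plot_data(self.report(4))
        assert data.angles_deg == (0.0, 90.0, 180.0, 270.0)

    def test_patient_at_center_lies_mid_band(self):
        model = simple_model()
        patient = {"record_id": "p", "age": 55.0, "sbp": 130.0, "hba1c": 7.5}
        report = analytics.fit_patient(patient, model, "Metformin",
                                       ["age", "sbp", "hba1c"])
        data = analytics.star_plot_data(report)
        for p, lo, hi in zip(data.patient, data.band_low, data.band_high):
            assert lo < p < hi and math.isclose(p, 0.5)

    def test_normalized_values_within_unit_interval(self):
        data = analytics.star_plot_data(self.report(4))
        for seq in (data.patient, data.band_low, data.band_high):
            assert all(0.0 <= v <= 1.0 for v in seq)

    def test_fewer_than_three_features_rejected(self):
        with pytest.raises(ValidationError, match="≥3"):
            analytics.star_plot_data(self.report(2))

    def test_permuting_features_permutes_axes(self):
        model = simple_model()
        patient = {"record_id": "p", "age": 60.0, "sbp": 120.0, "hba1c": 9.0}
        fwd = analytics.star_plot_data(
            analytics.fit_patient(patient, model, "Metformin",
                                  ["age", "sbp", "hba1c"]))
        rev = analytics.star_plot_data(
            analytics.fit_patient(patient, model, "Metformin",
                                  ["hba1c", "sbp", "age"]))
        assert fwd.features == tuple(reversed(rev.features))
        assert fwd.patient == tuple(reversed(rev.patient))

    def test_plot_renders_to_file(self, tmp_path):
        data = analytics.star_plot_data(self.report(4))
        out = tmp_path / "star.png"
        analytics.plot_star(data, str(out), title="patient vs arm")
        assert out.stat().st_size > 0


class TestGapQueries:
    def four_study_corpus(self, lexicon):
        """Four studies, three with nonzero African-American representation."""
        models = []
        for i in range(4):
            rows = [("Age (years)", "55.0 ± 8.0"), ("Female", "50 (50%)")]
            if i < 3:
                rows.append(("African American", "20 (20%)"))
            cells = [("Characteristic", "Arm A (n=100)")] + \
                [(label, value) for label, value in rows]
            grid = CohortGrid(study_id=f"s{i}", cells=tuple(cells))
            models.append(cohorts.assemble_cohort(grid, lexicon))
        return models

    def test_three_of_four_represented_studies_is_75_percent(self, lexicon):
        corpus = self.four_study_corpus(lexicon)
        spec = GapQuerySpec("study_match",
                            (GapFilter("african_american", "present"),
                             GapFilter("female", "present")))
        result = analytics.run_gap_query(corpus, spec, lexicon=lexicon)
        assert result.percentage == 75.0
        assert set(result.matches) == {"s0", "s1", "s2"}

    def test_limitation_empty_when_subgroup_everywhere(self, lexicon):
        corpus = self.four_study_corpus(lexicon)[:3]
        spec = GapQuerySpec("study_limitation",
                            (GapFilter("african_american", "present"),))
        result = analytics.run_gap_query(corpus, spec, lexicon=lexicon)
        assert result.matches == () and result.percentage == 0.0

    def test_limitation_flags_under_represented_arms(self, lexicon):
        grid = CohortGrid(
            "s",
            cells=(("Characteristic", "A (n=100)", "B (n=100)"),
                   ("African American", "2 (2%)", "30 (30%)")),
        )
        corpus = [cohorts.assemble_cohort(grid, lexicon)]
        spec = GapQuerySpec("study_limitation",
                            (GapFilter("african_american", "present"),),
                            representation_threshold=5.0)
        result = analytics.run_gap_query(corpus, spec, lexicon=lexicon)
        assert result.matches == ("s/A",)

    def test_quality_query_equals_bruteforce_scan(self, lexicon):
        models, _ = fixtures.gen_corpus(n_studies=50, seed=29)
        spec = GapQuerySpec("study_quality", size_threshold=1000,
                            arm_fraction=1 / 3)
        result = analytics.run_gap_query(models, spec, lexicon=lexicon)
        expected = {
            m.study_id for m in models
            if m.total_size >= 1000
            and any(a.size >= m.total_size / 3 for a in m.arms)
        }
        assert set(result.matches) == expected

    def test_match_query_equals_bruteforce_scan(self, lexicon):
        models, truth = fixtures.gen_corpus(n_studies=40, seed=31)
        spec = GapQuerySpec("study_match",
                            (GapFilter("african_american", "present"),))
        result = analytics.run_gap_query(models, spec, lexicon=lexicon)
        assert sorted(result.matches) == sorted(truth["represented"])

    def test_unknown_feature_code_rejected(self, lexicon):
        corpus = self.four_study_corpus(lexicon)
        spec = GapQuerySpec("study_match", (GapFilter("zorkness", "present"),))
        with pytest.raises(VocabularyError, match="zorkness"):
            analytics.run_gap_query(corpus, spec, lexicon=lexicon)

    def test_empty_corpus_rejected(self):
        spec = GapQuerySpec("study_match", (GapFilter("age", "ge", 70),))
        with pytest.raises(ValidationError, match="empty corpus"):
            analytics.run_gap_query([], spec)

    def test_match_and_limitation_require_filters(self):
        with pytest.raises(ValidationError, match="filter"):
            GapQuerySpec("study_match")


class TestCorpusSummary:
    def test_empty_spec_list_gives_empty_table(self, lexicon):
        models, _ = fixtures.gen_corpus(n_studies=4, seed=1)
        table = analytics.corpus_summary(models, [], lexicon=lexicon)
        assert len(table) == 0

    def test_duplicate_specs_give_identical_rows(self, lexicon):
        models, _ = fixtures.gen_corpus(n_studies=8, seed=2)
        spec = GapQuerySpec("study_match",
                            (GapFilter("african_american", "present"),))
        table = analytics.corpus_summary(models, [spec, spec], lexicon=lexicon)
        assert len(table) == 2
        assert table.iloc[0].equals(table.iloc[1])

    def test_planted_prevalences_recovered(self, lexicon):
        models, truth = fixtures.gen_corpus(n_studies=20, seed=11)
        specs = [
            GapQuerySpec("study_match", (GapFilter("african_american", "present"),)),
            GapQuerySpec("study_match", (GapFilter("age", "ge", 70),)),
            GapQuerySpec("study_quality", size_threshold=1000, arm_fraction=1 / 3),
        ]
        table = analytics.corpus_summary(models, specs, lexicon=lexicon)
        assert list(table["percentage"]) == [
            truth["prevalences"]["representation"],
            truth["prevalences"]["over70"],
            truth["prevalences"]["quality"],
        ]
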