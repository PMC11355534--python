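"""Cohort filtering, sensitive-attribute splits, baseline tables."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from equiflow.cohort import (CohortSpec, apply_cohort_spec, baseline_table,
                             round_half_away, split_by_attribute, yates_chi2_2x2)
from equiflow.errors import ConfigError

from conftest import build_log


def _toy_cohort():
    mk = lambda cid, age, comorb, sex, lang: {
        "case_id": cid, "adm": 0, "dis": 24,
        "attrs": {"age": str(age), "sex": sex, "language": lang, "diagnosis": "sepsis"},
        "comorbidities": comorb,
    }
    return build_log([
        mk("p1", 70, {"chf"}, "F", "ENGLISH"),
        mk("p2", 45, {"chf"}, "M", "ENGLISH"),
        mk("p3", 60, set(), "F", "SPANISH"),
        mk("p4", 17, set(), "M", "ENGLISH"),
        mk("p5", 80, set(), "F", "ENGLISH"),
    ])


class TestApplyCohortSpec:
    def test_comorbidity_any_of(self):
        log = _toy_cohort()
        out, flow = apply_cohort_spec(
            log, CohortSpec(required_comorbidities={"chf", "mi", "copd"}))
        assert sorted(p.case_id for p in out.patients) == ["p1", "p2"]
        assert flow.stages == [("comorbidity", 3, 2)]

    def test_empty_spec_is_identity(self):
        log = _toy_cohort()
        out, flow = apply_cohort_spec(log, CohortSpec())
        assert out == log
        assert flow.stages == []

    def test_min_age_excludes_minor_and_counts_it(self):
        out, flow = apply_cohort_spec(_toy_cohort(), CohortSpec(min_age=18))
        assert "p4" not in {p.case_id for p in out.patients}
        assert flow.stages == [("age", 1, 4)]

    def test_stage_conjunction_is_order_independent(self):
        log = _toy_cohort()
        full = CohortSpec(required_diagnosis={"sepsis"}, min_age=18,
                          required_comorbidities={"chf"})
        out, _ = apply_cohort_spec(log, full)
        # intersect single-filter cohorts by hand
        ids = set(p.case_id for p in log.patients)
        for spec in (CohortSpec(required_diagnosis={"sepsis"}),
                     CohortSpec(min_age=18),
                     CohortSpec(required_comorbidities={"chf"})):
            sub, _ = apply_cohort_spec(log, spec)
            ids &= {p.case_id for p in sub.patients}
        assert {p.case_id for p in out.patients} == ids

    def test_unknown_attribute_is_config_error(self):
        with pytest.raises(ConfigError):
            apply_cohort_spec(_toy_cohort(),
                              CohortSpec(required_diagnosis={"sepsis"},
                                         diagnosis_attribute="icd_code"))


class TestSplitByAttribute:
    def test_sex_split_partitions_cohort(self):
        split = split_by_attribute(_toy_cohort(), "sex")
        assert set(split.groups) == {"F", "M"}
        assert len(split.groups["F"]) + len(split.groups["M"]) == 5

    def test_language_level_map(self):
        split = split_by_attribute(_toy_cohort(), "language",
                                   level_map={"ENGLISH": "ESP"},
                                   default_level="non-ESP")
        assert len(split.groups["ESP"]) == 4
        assert split.groups["non-ESP"] == {"p3"}

    def test_missing_values_form_explicit_group_excluded_from_tests(self):
        log = _toy_cohort()
        log.patients[0].attributes["language"] = None
        split = split_by_attribute(log, "language")
        assert split.missing_group == "missing"
        assert split.groups["missing"] == {"p1"}
        assert "missing" not in split.test_groups()
        assert sum(len(v) for v in split.test_groups().values()) == 4


class TestBaselineTable:
    def _printed_language_cohort(self):
        # cell counts of the published sex x English-proficiency table
        cases = []
        i = 0
        for lang, sex, n in (("ESP", "M", 5573), ("ESP", "F", 4043),
                             ("non-ESP", "M", 578), ("non-ESP", "F", 438)):
            for _ in range(n):
                i += 1
                cases.append({"case_id": f"p{i}", "adm": 0, "dis": 1,
                              "attrs": {"language": lang, "sex": sex}})
        return build_log(cases)

    def test_male_percentages_by_language(self):
        log = self._printed_language_cohort()
        split = split_by_attribute(log, "language")
        table = baseline_table(split, log.patients_frame(), categorical=["sex"])
        block = table.blocks[0]
        assert block.cells["M"]["ESP"] == (5573, 58)
        assert block.cells["M"]["non-ESP"] == (578, 57)

    def test_sex_by_language_p_value_rounds_to_053(self):
        log = self._printed_language_cohort()
        split = split_by_attribute(log, "language")
        table = baseline_table(split, log.patients_frame(), categorical=["sex"])
        block = table.blocks[0]
        assert block.test_name == "chi-square (Yates)"
        assert round(block.p_value, 2) == 0.53

    def test_identical_groups_give_null_statistics(self):
        cases = []
        for g in ("A", "B"):
            for i in range(30):
                cases.append({"case_id": f"{g}{i}", "adm": 0, "dis": 1,
                              "attrs": {"grp": g, "sex": "F" if i < 12 else "M",
                                        "age": str(50 + i % 5)}})
        log = build_log(cases)
        split = split_by_attribute(log, "grp")
        table = baseline_table(split, log.patients_frame(),
                               categorical=["sex"], numeric=["age"])
        assert table.blocks[0].statistic == pytest.approx(0.0)
        assert table.blocks[0].p_value == pytest.approx(1.0)

    def test_numeric_attribute_reports_median_iqr_and_rank_test(self):
        cases = [{"case_id": f"a{i}", "adm": 0, "dis": 1,
                  "attrs": {"grp": "A", "age": str(a)}}
                 for i, a in enumerate([60, 62, 64, 66, 68])]
        cases += [{"case_id": f"b{i}", "adm": 0, "dis": 1,
                   "attrs": {"grp": "B", "age": str(a)}}
                  for i, a in enumerate([70, 72, 74, 76, 80])]
        log = build_log(cases)
        table = baseline_table(split_by_attribute(log, "grp"),
                               log.patients_frame(), numeric=["age"])
        block = table.blocks[0]
        assert block.cells["A"] == (64.0, 4.0)
        assert block.cells["B"] == (74.0, 4.0)
        assert block.test_name == "Mann-Whitney U"
        assert block.p_value < 0.05

    def test_percentage_blocks_sum_to_about_100(self):
        log = self._printed_language_cohort()
        split = split_by_attribute(log, "language")
        table = baseline_table(split, log.patients_frame(), categorical=["sex"])
        for g in ("ESP", "non-ESP"):
            total = sum(cell[g][1] for cell in table.blocks[0].cells.values())
            assert abs(total - 100) <= 1  # integer rounding slack


def test_yates_statistic_matches_hand_formula():
    rng = np.random.default_rng(42)
    for _ in range(50):
        a, b, c, d = rng.integers(5, 2000, size=4)
        n = a + b + c + d
        stat, _ = yates_chi2_2x2(a, b, c, d)
        num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 * n
        den = float((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(num / den, abs=1e-10)


@pytest.mark.parametrize("x,expected", [(0.5, 1), (1.49, 1), (2.5, 3), (-0.5, -1)])
def test_round_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


def test_yates_wrapper_agrees_with_reference_contingency_test():
    stat, p = yates_chi2_2x2(5573, 4043, 578, 438)
    ref = chi2_contingency(np.array([[5573, 4043], [578, 438]]), correction=True)
    assert stat == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue))
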