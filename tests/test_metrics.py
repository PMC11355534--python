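"""Single- and multiple-step disparity metrics and the bootstrap machinery."""

import numpy as np
import pytest

from equiflow.cohort import split_by_attribute
from equiflow.errors import DataContractError
from equiflow.eventlog import to_cases
from equiflow.metrics import (bootstrap_ci, build_variant_panel, cis_disjoint,
                              inter_step_time, outcome_stats, sofa_at_start,
                              step_duration)

from conftest import build_log


def _vent_case(cid, start, end, sofa=None, attrs=None, outcomes=None, dis=100):
    return {"case_id": cid, "adm": 0, "dis": dis,
            "events": [("ventilation", start, end, sofa)],
            "attrs": {"grp": "A", **(attrs or {})},
            "outcomes": outcomes or {}}


class TestStepDuration:
    def test_mean_of_two_durations(self):
        log = build_log([_vent_case("p1", 2, 50), _vent_case("p2", 2, 52)])
        split = split_by_attribute(log, "grp")
        out = step_duration(to_cases(log), "ventilation", 0, split, seed=1)
        assert out["A"].estimate == pytest.approx(49.0)
        assert out["A"].n == 2
        assert out["A"].unit == "hours"

    def test_constant_durations_degenerate_interval(self):
        log = build_log([_vent_case(f"p{i}", 2, 50) for i in range(5)])
        split = split_by_attribute(log, "grp")
        m = step_duration(to_cases(log), "ventilation", 0, split, seed=1)["A"]
        assert m.ci_low == m.ci_high == pytest.approx(48.0)

    def test_bad_occurrence_index_is_contract_error(self):
        log = build_log([_vent_case("p1", 2, 50)])
        with pytest.raises(DataContractError):
            step_duration(to_cases(log), "ventilation", 1, None)

    def test_mixed_variants_rejected(self):
        log = build_log([_vent_case("p1", 2, 50),
                         {"case_id": "p2", "adm": 0, "dis": 100,
                          "events": [("vasopressor", 1, 4, None)],
                          "attrs": {"grp": "A"}}])
        with pytest.raises(DataContractError):
            step_duration(to_cases(log), "ventilation", 0, None)


class TestSofaAtStart:
    def _log(self, sofa_first, sofa_second):
        return build_log([{
            "case_id": "p1", "adm": 0, "dis": 100,
            "events": [("ventilation", 2, 50, sofa_first),
                       ("vasopressor", 5, 30, sofa_second)],
            "attrs": {"grp": "A"}}])

    def test_present_value_used(self):
        out = sofa_at_start(to_cases(self._log(8, 6)), "ventilation", 0, None, seed=1)
        assert out["all"].estimate == pytest.approx(8.0)

    def test_missing_value_falls_back_to_next_available(self):
        out = sofa_at_start(to_cases(self._log(None, 6)), "ventilation", 0, None, seed=1)
        assert out["all"].estimate == pytest.approx(6.0)
        assert out["all"].n_excluded == 0

    def test_no_sofa_anywhere_excluded_and_counted(self):
        cases = to_cases(build_log([
            {"case_id": "p1", "adm": 0, "dis": 100,
             "events": [("ventilation", 2, 50, None), ("vasopressor", 5, 30, None)],
             "attrs": {"grp": "A"}},
            {"case_id": "p2", "adm": 0, "dis": 100,
             "events": [("ventilation", 2, 50, 7), ("vasopressor", 5, 30, 5)],
             "attrs": {"grp": "A"}}]))
        out = sofa_at_start(cases, "ventilation", 0, None, seed=1)
        assert out["all"].n == 1
        assert out["all"].n_excluded == 1
        assert out["all"].estimate == pytest.approx(7.0)


class TestInterStepTime:
    def test_time_to_first_treatment(self):
        log = build_log([_vent_case("p1", 3, 50)])
        out = inter_step_time(to_cases(log), 0, None, seed=1)
        assert out["all"].estimate == pytest.approx(3.0)

    def test_zero_gap_for_simultaneous_adjacent_tokens(self):
        # ventilation ends exactly when vasopressor starts
        log = build_log([{"case_id": "p1", "adm": 0, "dis": 100,
                          "events": [("ventilation", 2, 10, None),
                                     ("vasopressor", 10, 30, None)]}])
        out = inter_step_time(to_cases(log), 2, None, seed=1)  # end:vent -> start:vaso
        assert out["all"].estimate == pytest.approx(0.0)

    def test_index_out_of_range(self):
        log = build_log([_vent_case("p1", 2, 50)])
        with pytest.raises(DataContractError):
            inter_step_time(to_cases(log), 5, None)


class TestOutcomeStats:
    def test_mortality_proportion(self):
        log = build_log([
            {**_vent_case(f"p{i}", 2, 50), "outcomes": {"mortality": i < 3,
                                                        "length_of_stay": 100.0}}
            for i in range(10)])
        out = outcome_stats(to_cases(log), None, seed=1)
        assert out["mortality"]["all"].estimate == pytest.approx(0.3)
        assert out["length_of_stay"]["all"].estimate == pytest.approx(100.0)

    def test_all_survive_degenerate_interval(self):
        log = build_log([
            {**_vent_case(f"p{i}", 2, 50), "outcomes": {"mortality": False}}
            for i in range(4)])
        m = outcome_stats(to_cases(log), None, seed=1)["mortality"]["all"]
        assert (m.estimate, m.ci_low, m.ci_high) == (0.0, 0.0, 0.0)

    def test_missing_outcomes_excluded_with_count(self):
        log = build_log([
            {**_vent_case("p1", 2, 50), "outcomes": {"mortality": True}},
            {**_vent_case("p2", 2, 50), "outcomes": {}}])
        m = outcome_stats(to_cases(log), None, seed=1)["mortality"]["all"]
        assert m.n == 1 and m.n_excluded == 1


class TestBootstrapCI:
    def test_constant_sequence(self):
        assert bootstrap_ci([3.0] * 10, seed=0) == (3.0, 3.0)

    def test_same_seed_reproduces_interval(self):
        x = np.random.default_rng(9).normal(size=40)
        assert bootstrap_ci(x, seed=123) == bootstrap_ci(x, seed=123)
        assert bootstrap_ci(x, seed=123) != bootstrap_ci(x, seed=124)

    def test_single_observation_warns_and_degenerates(self):
        with pytest.warns(UserWarning):
            assert bootstrap_ci([5.0]) == (5.0, 5.0)

    def test_interval_brackets_mean_and_shrinks_with_n(self):
        rng = np.random.default_rng(7)
        big = rng.normal(size=1000)
        small = big[:50]
        lo_b, hi_b = bootstrap_ci(big, B=1000, seed=1)
        lo_s, hi_s = bootstrap_ci(small, B=1000, seed=1)
        assert lo_b <= big.mean() <= hi_b
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_empty_input_rejected(self):
        with pytest.raises(DataContractError):
            bootstrap_ci([])


class TestVariantPanel:
    def _two_group_log(self, shift_b=0.0):
        cases = []
        rng = np.random.default_rng(11)
        for g, n in (("A", 40), ("B", 40)):
            for i in range(n):
                t0 = 3.0 + (shift_b if g == "B" else 0.0) + rng.uniform(0, 0.5)
                cases.append({
                    "case_id": f"{g}{i}", "adm": 0, "dis": 90,
                    "events": [("ventilation", t0, t0 + 40, 8),
                               ("vasopressor", t0 + 2, t0 + 20, 7)],
                    "attrs": {"grp": g},
                    "outcomes": {"mortality": i % 5 == 0, "length_of_stay": 90.0}})
        return build_log(cases)

    def test_panel_covers_every_token_pair_and_step(self):
        log = self._two_group_log()
        split = split_by_attribute(log, "grp")
        panel = build_variant_panel(to_cases(log), split, B=200, seed=2)
        assert len(panel.signature) == 6
        assert len(panel.gaps) == 5  # every adjacent token pair exactly once
        assert set(panel.durations) == {"ventilation", "vasopressor"}
        assert set(panel.sofa) == {"ventilation", "vasopressor"}
        assert set(panel.outcomes) == {"mortality", "length_of_stay"}
        for d in panel.gaps:
            assert set(d) == {"A", "B"}

    def test_duplicated_groups_have_equal_estimates(self):
        log = self._two_group_log(shift_b=0.0)
        # make B an exact copy of A's clinical data
        cases = []
        rng = np.random.default_rng(11)
        for g in ("A", "B"):
            for i in range(40):
                t0 = 3.0 + 0.01 * i
                cases.append({
                    "case_id": f"{g}{i}", "adm": 0, "dis": 90,
                    "events": [("ventilation", t0, t0 + 40, 8)],
                    "attrs": {"grp": g},
                    "outcomes": {"mortality": i % 4 == 0, "length_of_stay": 90.0}})
        log = build_log(cases)
        split = split_by_attribute(log, "grp")
        panel = build_variant_panel(to_cases(log), split, B=200, seed=2)
        for d in panel.gaps + list(panel.durations.values()) + \
                list(panel.sofa.values()) + list(panel.outcomes.values()):
            assert d["A"].estimate == pytest.approx(d["B"].estimate)

    def test_all_gaps_and_durations_nonnegative(self, demo_log):
        from equiflow.variants import compute_variants, filter_variants
        split = split_by_attribute(demo_log, "language")
        cases = to_cases(demo_log)
        table = filter_variants(compute_variants(cases, split), 30)
        case_map = {c.case_id: c for c in cases}
        row = table.rows[0]
        panel = build_variant_panel([case_map[c] for c in row.case_ids],
                                    split, B=100, seed=3)
        for m in panel.all_metrics():
            if m.unit == "hours":
                assert m.estimate >= 0.0 and m.ci_low >= 0.0
            assert m.ci_low <= m.estimate <= m.ci_high

    def test_injected_shift_moves_only_first_gap(self):
        log0 = self._two_group_log(0.0)
        log2 = self._two_group_log(4.0)
        for log, expect in ((log0, False), (log2, True)):
            split = split_by_attribute(log, "grp")
            panel = build_variant_panel(to_cases(log), split, B=500, seed=4)
            first = panel.gaps[0]
            assert cis_disjoint(first["A"], first["B"]) is expect
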