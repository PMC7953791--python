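"""Validation harness: filtering, hits, reports, chi-square, splitting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcbayes import (
    ArgumentError,
    DegenerateTableError,
    HitRateReport,
    RankerConfig,
    UnknownDiseaseError,
    ValidationCase,
    compare_error_rates,
    evaluate_dataset,
    filter_cases,
    is_hit,
    load_cases,
    pearson_chi_square,
    rank_diagnoses,
    split_dataset,
)
from ihcbayes.evaluation import (
    REASON_INCONCLUSIVE,
    REASON_NO_DIAGNOSTIC,
    REASON_TOO_FEW,
    CategoryCounts,
)
from ihcbayes.ranker import CasePanel

from conftest import make_kb


def closed_form_chi2(a, b, c, d):
    """Independent 2x2 Pearson statistic: n(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestFilterCases:
    def make_case(self, panel, case_id="c1", truth="D1"):
        return ValidationCase(case_id=case_id, panel=panel, true_disease_id=truth)

    def test_prognostic_strip_can_drop_below_minimum(self, registry):
        case = self.make_case({"CK7": True, "TTF-1": True, "p53": True})
        retained, excluded = filter_cases([case], registry)
        assert retained == []
        assert excluded == [("c1", REASON_TOO_FEW)]

    def test_adequate_panel_passes_through(self, registry):
        case = self.make_case({"CK7": True, "TTF-1": True, "CK20": False,
                               "CDX2": False})
        retained, excluded = filter_cases([case], registry)
        assert excluded == []
        assert retained[0].panel == case.panel

    def test_all_prognostic_is_no_diagnostic_markers(self, registry):
        case = self.make_case({"EGFR": True, "p53": False})
        _, excluded = filter_cases([case], registry)
        assert excluded == [("c1", REASON_NO_DIAGNOSTIC)]

    def test_inconclusive_result_excludes(self, registry):
        case = self.make_case({"CK7": True, "TTF-1": None, "CK20": False,
                               "CDX2": True})
        _, excluded = filter_cases([case], registry)
        assert excluded == [("c1", REASON_INCONCLUSIVE)]

    def test_prognostic_markers_are_stripped_from_retained_panels(self, registry):
        case = self.make_case({"CK7": True, "TTF-1": True, "CK20": False,
                               "p53": True})
        retained, excluded = filter_cases([case], registry)
        assert excluded == []
        assert "p53" not in retained[0].panel
        assert len(retained[0].panel) == 3


class TestIsHit:
    @pytest.fixture
    def gist_kb(self):
        return make_kb(
            {
                "GIST-stomach": {"A": 0.95, "B": 0.9, "C": 0.1},
                "GIST-small-intestine": {"A": 0.95, "B": 0.9, "C": 0.1},
                "leiomyoma": {"A": 0.1, "B": 0.2, "C": 0.9},
            },
            equivalence={"GIST-stomach": "GIST", "GIST-small-intestine": "GIST"},
        )

    def test_direct_inclusion(self, gist_kb):
        ranked = rank_diagnoses(gist_kb, CasePanel({"A": True, "B": True,
                                                    "C": False}), RankerConfig())
        assert is_hit("GIST-stomach", ranked, gist_kb, k=10)

    def test_location_equivalent_counts_as_hit(self, gist_kb):
        ranked = rank_diagnoses(gist_kb, CasePanel({"A": True, "B": True,
                                                    "C": False}),
                                RankerConfig(top_k=1))
        only = ranked[0].disease_id
        other = ("GIST-stomach" if only == "GIST-small-intestine"
                 else "GIST-small-intestine")
        assert is_hit(other, ranked, gist_kb, k=1)

    def test_outside_window_is_miss(self, gist_kb):
        ranked = rank_diagnoses(gist_kb, CasePanel({"A": True, "B": True,
                                                    "C": False}), RankerConfig())
        assert not is_hit("leiomyoma", ranked, gist_kb, k=1)
        assert is_hit("leiomyoma", ranked, gist_kb, k=3)

    def test_window_monotonicity(self, gist_kb):
        ranked = rank_diagnoses(gist_kb, CasePanel({"A": False, "B": False,
                                                    "C": True}), RankerConfig())
        for k in range(1, len(ranked)):
            if is_hit("GIST-stomach", ranked, gist_kb, k=k):
                assert is_hit("GIST-stomach", ranked, gist_kb, k=k + 1)

    def test_unknown_disease_raises(self, gist_kb):
        ranked = rank_diagnoses(gist_kb, CasePanel({"A": True}), RankerConfig())
        with pytest.raises(UnknownDiseaseError):
            is_hit("nonexistent", ranked, gist_kb, k=10)


class TestReports:
    def test_perfectly_separable_dataset_hits_100(self):
        kb = make_kb({
            "D1": {"A": 0.95, "B": 0.0, "C": 0.0},
            "D2": {"A": 0.0, "B": 0.95, "C": 0.0},
            "D3": {"A": 0.0, "B": 0.0, "C": 0.95},
        })
        cases = [
            ValidationCase("c1", {"A": True, "B": False, "C": False}, "D1",
                           category="primary carcinoma"),
            ValidationCase("c2", {"A": False, "B": True, "C": False}, "D2",
                           category="primary carcinoma"),
            ValidationCase("c3", {"A": False, "B": False, "C": True}, "D3",
                           category="metastatic carcinoma"),
        ]
        report = evaluate_dataset(cases, kb, RankerConfig(top_k=1))
        assert report.total.n_cases == 3
        assert report.total.hit_rate_pct == pytest.approx(100.0)

    def test_category_counts_conserve_totals(self):
        report = HitRateReport(per_category={
            "primary carcinoma": CategoryCounts(232, 190),
            "metastatic carcinoma": CategoryCounts(151, 112),
            "benign (normal) lesion": CategoryCounts(33, 29),
        })
        t = report.total
        assert t.n_cases == 232 + 151 + 33
        assert t.n_accurate == 190 + 112 + 29
        for c in report.per_category.values():
            assert c.n_accurate + c.n_error == c.n_cases

    def test_printed_count_arithmetic(self):
        # archive tallies: 441/562, 298/382, 146/164, overall 885/1108
        assert HitRateReport.from_counts(441, 121).total.hit_rate_pct == \
            pytest.approx(78.5, abs=0.05)
        assert HitRateReport.from_counts(298, 84).total.hit_rate_pct == \
            pytest.approx(78.0, abs=0.05)
        assert HitRateReport.from_counts(146, 18).total.hit_rate_pct == \
            pytest.approx(89.0, abs=0.05)
        table = HitRateReport.from_counts(885, 223).to_table()
        assert "\t79.9\t" in table

    def test_empty_dataset_rejected(self, toy_kb):
        with pytest.raises(ArgumentError):
            evaluate_dataset([], toy_kb)


class TestChiSquare:
    def test_training_vs_validation_table(self):
        result = pearson_chi_square([[441, 121], [298, 84]])
        assert result.degrees_of_freedom == 1
        assert result.p_value == pytest.approx(0.866, abs=1e-3)

    def test_identical_proportions(self):
        result = pearson_chi_square([[50, 50], [50, 50]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        result = pearson_chi_square([[10, 0], [0, 10]])
        assert result.statistic == pytest.approx(20.0, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square([[5, 0], [7, 0]])

    @settings(max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_matches_closed_form(self, counts):
        a, b, c, d = counts
        result = pearson_chi_square([[a, b], [c, d]])
        assert result.statistic == pytest.approx(closed_form_chi2(a, b, c, d),
                                                 abs=1e-9)

    def test_compare_error_rates_from_totals(self):
        res = compare_error_rates(HitRateReport.from_counts(441, 121),
                                  HitRateReport.from_counts(298, 84))
        assert res.p_value == pytest.approx(0.866, abs=1e-3)

    def test_compare_identical_reports(self):
        r = HitRateReport.from_counts(90, 10)
        assert compare_error_rates(r, r).p_value == pytest.approx(1.0)

    def test_compare_is_symmetric(self):
        ra = HitRateReport.from_counts(90, 10)
        rb = HitRateReport.from_counts(10, 90)
        ab = compare_error_rates(ra, rb)
        ba = compare_error_rates(rb, ra)
        assert ab.statistic == pytest.approx(ba.statistic, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)
        assert ab.statistic == pytest.approx(128.0, abs=1e-9)
        assert ab.p_value < 0.001


class TestSplit:
    def _cases(self, n):
        return [ValidationCase(f"c{i}", {"A": True}, "D1") for i in range(n)]

    def test_sixty_forty(self):
        a, b = split_dataset(self._cases(100), (0.6, 0.4), seed=3)
        assert (len(a), len(b)) == (60, 40)

    def test_deterministic_under_seed(self):
        cases = self._cases(37)
        a1, b1 = split_dataset(cases, seed=11)
        a2, b2 = split_dataset(cases, seed=11)
        assert [c.case_id for c in a1] == [c.case_id for c in a2]
        assert [c.case_id for c in b1] == [c.case_id for c in b2]

    def test_partition_property(self):
        cases = self._cases(53)
        a, b = split_dataset(cases, (0.6, 0.4), seed=5)
        ids = {c.case_id for c in a} | {c.case_id for c in b}
        assert len(a) + len(b) == 53
        assert ids == {c.case_id for c in cases}

    def test_degenerate_ratio(self):
        a, b = split_dataset(self._cases(10), (1.0, 0.0), seed=0)
        assert len(a) == 10 and b == []

    def test_bad_inputs(self):
        with pytest.raises(ArgumentError):
            split_dataset([], seed=0)
        with pytest.raises(ArgumentError):
            split_dataset(self._cases(5), (0.7, 0.7), seed=0)


WIDE_CASES = """case_id\ttrue_disease_id\tcategory\torgan\tCK7\tTTF-1\tCK20\tCDX2
c1\tD1\tprimary carcinoma\tlung\t+\t+\t-\t
c2\tD2\tmetastatic carcinoma\tstomach\t-\t\t+\tpos
c3\tD1\tprimary carcinoma\tlung\t+\tequivocal\t-\t-
"""

LONG_CASES = """case_id\ttrue_disease_id\tcategory\torgan\tantibody\tresult
c1\tD1\tprimary carcinoma\tlung\tCK7\t+
c1\tD1\tprimary carcinoma\tlung\tTTF1\tpositive
c2\tD2\tmetastatic carcinoma\tstomach\tCK20\t1
"""


class TestCaseIO:
    def test_wide_dialect(self, tmp_path, registry):
        path = tmp_path / "cases.tsv"
        path.write_text(WIDE_CASES, encoding="utf-8")
        cases = {c.case_id: c for c in load_cases(path, registry)}
        assert cases["c1"].panel == {"CK7": True, "TTF-1": True, "CK20": False}
        assert cases["c2"].panel == {"CK7": False, "CK20": True, "CDX2": True}
        # unparseable token survives as None for the filter to report
        assert cases["c3"].panel["TTF-1"] is None

    def test_long_dialect_resolves_aliases(self, tmp_path, registry):
        path = tmp_path / "cases.tsv"
        path.write_text(LONG_CASES, encoding="utf-8")
        cases = {c.case_id: c for c in load_cases(path, registry)}
        assert cases["c1"].panel == {"CK7": True, "TTF-1": True}
        assert cases["c2"].panel == {"CK20": True}

    def test_missing_meta_columns_rejected(self, tmp_path, registry):
        path = tmp_path / "cases.tsv"
        path.write_text("case_id\tCK7\nc1\t+\n", encoding="utf-8")
        from ihcbayes.errors import LoadError

        with pytest.raises(LoadError):
            load_cases(path, registry)
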