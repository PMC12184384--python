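"""Positive-signal intersection, expectedness, overlap, priority scoring."""

import math

import pytest

from pvsignal.classify import (
    PriorityScore,
    cross_database_overlap,
    fatality_fraction,
    flag_unexpected,
    intersect_signals,
    score_priority,
    sensitivity_monotherapy,
    soc_composition_test,
)
from pvsignal.disproportionality import DisproMetrics
from pvsignal.model import AdverseEvent, DrugEntry, SafetyReport

TARGET = "IRINOTECAN"


def _metrics(term="t", flags=(True, True, True, True), a=50):
    return DisproMetrics(
        term=term, level="PT", a=a,
        flag_ror=flags[0], flag_prr=flags[1], flag_bcpnn=flags[2], flag_mgps=flags[3],
    )


class TestIntersection:
    @pytest.mark.parametrize(
        "flags, positive",
        [
            ((True, True, True, False), False),
            ((True, True, True, True), True),
            ((False, False, False, False), False),
        ],
    )
    def test_all_four_required(self, flags, positive):
        [s] = intersect_signals([_metrics(flags=flags)])
        assert s.positive is positive


class TestUnexpected:
    LABEL = ["Diarrhoea", "Neutropenia", "Thrombocytopenia", "Stomatitis", "Enteritis"]

    def test_label_terms_are_expected(self):
        signals = intersect_signals([_metrics("Diarrhoea"), _metrics("Hiccups")])
        signals = flag_unexpected(signals, self.LABEL)
        by_term = {s.term: s for s in signals}
        assert not by_term["Diarrhoea"].unexpected
        assert by_term["Hiccups"].unexpected

    def test_negative_terms_never_unexpected(self):
        signals = intersect_signals([_metrics("Hiccups", flags=(True, False, True, True))])
        signals = flag_unexpected(signals, self.LABEL)
        assert not signals[0].unexpected

    def test_empty_label_list_warns(self):
        signals = intersect_signals([_metrics("Anything")])
        with pytest.warns(UserWarning):
            flag_unexpected(signals, [])
        assert signals[0].unexpected


class TestOverlap:
    def _sigs(self, terms):
        return intersect_signals([_metrics(t) for t in terms])

    def test_partial_disjoint_identical(self):
        assert cross_database_overlap(self._sigs("xy"), self._sigs("yz"))["overlap"] == ["y"]
        assert cross_database_overlap(self._sigs("ab"), self._sigs("cd"))["overlap"] == []
        both = cross_database_overlap(self._sigs("ab"), self._sigs("ab"))
        assert both["overlap"] == ["a", "b"] and both["a_only"] == [] and both["b_only"] == []

    def test_overlap_bounded_by_smaller_set(self):
        out = cross_database_overlap(self._sigs("abcde"), self._sigs("cd"))
        assert len(out["overlap"]) <= 2


class TestPriority:
    IME = ["Sepsis", "Febrile neutropenia"]
    DME = ["Hepatic failure", "Agranulocytosis"]

    def test_high_medium_low_bands(self):
        # hepatic-failure-like: rare (<1%), all four detectors, >50% fatal, DME
        high = score_priority("Hepatic failure", 0.16, 4, 0.6, self.IME, self.DME)
        assert high.total == 6 and high.category == "high"
        # febrile-neutropenia-like: common, all four detectors, 25-50% fatal, IME
        medium = score_priority("Febrile neutropenia", 1.2, 4, 0.3, self.IME, self.DME)
        assert medium.total == 5 and medium.category == "medium"
        # dehydration-like: rare, all four detectors, low fatality, unlisted
        low = score_priority("Dehydration", 0.9, 4, 0.1, self.IME, self.DME)
        assert low.total == 2 and low.category == "low"

    @pytest.mark.parametrize(
        "rate, expected", [(15.0, 2), (10.0, 1), (1.0, 1), (0.9, 0)]
    )
    def test_rate_points(self, rate, expected):
        s = score_priority("x", rate, 0, 0.0, [], [])
        assert s.rate_points == expected

    @pytest.mark.parametrize("n_alg, expected", [(4, 2), (3, 2), (2, 1), (1, 0), (0, 0)])
    def test_stability_points(self, n_alg, expected):
        assert score_priority("x", 0.0, n_alg, 0.0, [], []).stability_points == expected

    @pytest.mark.parametrize(
        "frac, expected", [(0.6, 2), (0.5, 1), (0.25, 1), (0.2, 0)]
    )
    def test_fatality_points(self, frac, expected):
        assert score_priority("x", 0.0, 0, frac, [], []).fatality_points == expected

    def test_dme_beats_ime_when_on_both_lists(self):
        s = score_priority("Sepsis", 0.0, 0, 0.0, ["Sepsis"], ["Sepsis"])
        assert s.relevance_points == 2

    def test_category_monotone_in_each_criterion(self):
        order = {"low": 0, "medium": 1, "high": 2}
        base = PriorityScore(1, 1, 1, 1)
        for bump in range(4):
            pts = [1, 1, 1, 1]
            pts[bump] = 2
            assert order[PriorityScore(*pts).category] >= order[base.category]


class TestFatality:
    def _r(self, rid, pts, outcomes):
        return SafetyReport(
            report_id=rid, case_id=rid, source_db="FAERS",
            drugs=[DrugEntry(TARGET, "PS")],
            events=[AdverseEvent(p) for p in pts], outcomes=outcomes,
        )

    def test_report_level_denominator(self):
        reports = [
            self._r("1", ["Sepsis"], ["DE"]),
            self._r("2", ["Sepsis", "Nausea"], ["HO"]),
            self._r("3", ["Nausea"], ["DE"]),
        ]
        assert fatality_fraction(reports, "Sepsis") == 0.5
        assert fatality_fraction(reports, "Absent term") == 0.0

    def test_jader_death_vocabulary(self):
        reports = [self._r("1", ["Sepsis"], ["死亡"])]
        assert fatality_fraction(reports, "Sepsis") == 1.0


class TestSocComposition:
    def test_proportional_vectors_are_null(self):
        stat, p = soc_composition_test([50, 50], [500, 500])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_expanded_example(self):
        stat, p = soc_composition_test([50, 50], [90, 10])
        assert stat == pytest.approx(38.095, abs=1e-2)
        assert p < 1e-8

    def test_absent_soc_in_one_cohort_no_crash(self):
        stat, p = soc_composition_test([50, 0, 50], [40, 10, 50])
        assert math.isfinite(stat) and 0 <= p <= 1

    def test_errors(self):
        with pytest.raises(ValueError):
            soc_composition_test([1, 2], [1])
        with pytest.raises(ValueError):
            soc_composition_test([5], [3])


class TestMonotherapy:
    def _r(self, rid, drugs):
        return SafetyReport(
            report_id=rid, case_id=rid, source_db="FAERS",
            drugs=drugs, events=[AdverseEvent("Diarrhoea")],
        )

    def test_concomitant_reports_excluded(self):
        mono = self._r("1", [DrugEntry(TARGET, "PS")])
        combo = self._r("2", [DrugEntry(TARGET, "PS"), DrugEntry("OXALIPLATIN", "C")])
        background = [mono, combo, self._r("3", [DrugEntry("CETUXIMAB", "PS")])]
        kept, metrics = sensitivity_monotherapy([mono, combo], background, [TARGET])
        assert [r.report_id for r in kept] == ["1"]
        assert metrics  # recomputed through the shared code path

    def test_empty_stratum_is_error(self):
        combo = self._r("1", [DrugEntry(TARGET, "PS"), DrugEntry("OXALIPLATIN", "C")])
        with pytest.raises(ValueError):
            sensitivity_monotherapy([combo], [combo], [TARGET])

    def test_subset_never_larger(self, planted_cleaned):
        target, background, _ = planted_cleaned
        kept, _ = sensitivity_monotherapy(target, background, [TARGET])
        assert len(kept) <= len(target)
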