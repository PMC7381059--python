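"""Gold standards, record-level metrics, serology audit, specificity
estimator."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from privlink import (
    GoldStandard,
    LinkageResult,
    TestRecord,
    build_gold_registry,
    build_gold_specimen,
    estimate_specificity,
    score_linkage,
    serology_audit,
)
from privlink.evaluation import EvalReport, SerologyAuditReport

from conftest import brute_force_score, make_record


def result_from(clusters: dict, approach="accept_all") -> LinkageResult:
    return LinkageResult(accepted_pairs=(), clusters=clusters, approach=approach)


class TestGoldRegistry:
    def test_28_pairs_among_3700_records(self):
        ids = [f"r{i}" for i in range(3700)]
        registry = [(f"p{i}", f"r{2 * i}") for i in range(28)] + [
            (f"p{i}", f"r{2 * i + 1}") for i in range(28)
        ]
        gold = build_gold_registry(ids, registry)
        assert len(gold.linked_ids) == 56
        assert len(gold.unlinked_ids) == 3644
        assert len({gold.clusters[r] for r in gold.linked_ids}) == 28

    def test_empty_registry_all_singletons(self):
        gold = build_gold_registry(["a", "b"], [])
        assert gold.linked_ids == frozenset()
        assert gold.unlinked_ids == {"a", "b"}

    def test_one_person_three_records(self):
        gold = build_gold_registry(["a", "b", "c", "d"], [("p", "a"), ("p", "b"), ("p", "c")])
        assert gold.linked_ids == {"a", "b", "c"}
        assert len({gold.clusters[r] for r in "abc"}) == 1

    def test_conflicting_rows_error(self):
        with pytest.raises(ValueError, match="conflicting"):
            build_gold_registry(["a"], [("p1", "a"), ("p2", "a")])

    def test_unknown_record_error(self):
        with pytest.raises(ValueError, match="unknown record"):
            build_gold_registry(["a"], [("p1", "zz")])


class TestGoldSpecimen:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["record_id", "specimen_id", "birth_year", "test_date"])

    def test_seven_day_difference_matches(self):
        clinic = self.frame([("c1", "s1", 1980, "2015-01-01")])
        lab = self.frame([("l1", "s1", 1980, "2015-01-08")])
        gold = build_gold_specimen(clinic, lab)
        assert gold.clusters["c1"] == gold.clusters["l1"]

    def test_eight_day_difference_excluded(self):
        clinic = self.frame([("c1", "s1", 1980, "2015-01-01")])
        lab = self.frame([("l1", "s1", 1980, "2015-01-09")])
        assert build_gold_specimen(clinic, lab).clusters == {}

    def test_different_birth_year_excluded(self):
        clinic = self.frame([("c1", "s1", 1980, "2015-01-01")])
        lab = self.frame([("l1", "s1", 1981, "2015-01-01")])
        assert build_gold_specimen(clinic, lab).clusters == {}

    def test_transitive_union_and_exclusion_of_unmatched(self):
        clinic = self.frame(
            [("c1", "s1", 1980, "2015-01-01"), ("c2", "s2", 1980, "2015-02-01"),
             ("c3", "s9", 1980, "2015-03-01")]
        )
        lab = self.frame(
            [("l1", "s1", 1980, "2015-01-02"), ("l1", "s2", 1980, "2015-02-02")]
        )
        gold = build_gold_specimen(clinic, lab)
        # l1 ties c1 and c2 together; c3's specimen never reached a lab
        assert gold.clusters["c1"] == gold.clusters["c2"] == gold.clusters["l1"]
        assert "c3" not in gold.clusters


class TestScoreLinkage:
    def prepx_like(self, n_pairs=28, n_single=3644, miss=1):
        """Registry-style instance: n_pairs true pairs, n_single singletons,
        the tool missing `miss` of the pairs."""
        ids = [f"p{i}a" for i in range(n_pairs)] + [f"p{i}b" for i in range(n_pairs)]
        singles = [f"s{i}" for i in range(n_single)]
        gold = GoldStandard(
            clusters={**{f"p{i}a": f"g{i}" for i in range(n_pairs)},
                      **{f"p{i}b": f"g{i}" for i in range(n_pairs)},
                      **{s: s for s in singles}}
        )
        tool = {}
        for i in range(n_pairs):
            if i < miss:
                tool[f"p{i}a"], tool[f"p{i}b"] = f"p{i}a", f"p{i}b"
            else:
                tool[f"p{i}a"] = tool[f"p{i}b"] = f"p{i}a"
        tool.update({s: s for s in singles})
        return result_from(tool), gold

    def test_one_missed_pair_of_28(self):
        result, gold = self.prepx_like(miss=1)
        rep = score_linkage(result, gold)
        assert (rep.n_correctly_linked, rep.n_gold_linked) == (54, 56)
        assert rep.sensitivity_pct == 96.43  # prints as 96% at table precision
        assert rep.specificity_pct == 100.0
        assert rep.ppv_pct == 100.0
        assert rep.n_tool_unlinked_correct == 3644 and rep.n_tool_unlinked == 3646

    def test_tool_links_nothing(self):
        result, gold = self.prepx_like(n_pairs=5, n_single=10, miss=5)
        rep = score_linkage(result, gold)
        assert rep.sensitivity_pct == 0.0
        assert rep.specificity_pct == 100.0
        assert rep.ppv_pct is None  # no tool-linked records: not estimable

    def test_record_set_mismatch_errors(self):
        result, gold = self.prepx_like(n_pairs=2, n_single=2)
        result = result_from({**dict(result.clusters), "extra": "extra"})
        with pytest.raises(ValueError, match="record sets differ"):
            score_linkage(result, gold)

    def test_correctly_linked_needs_only_one_true_comember(self):
        gold = GoldStandard(clusters={"a": "g", "b": "g", "c": "g"})
        tool = result_from({"a": "a", "b": "a", "c": "c"})
        rep = score_linkage(tool, gold)
        assert rep.n_correctly_linked == 2  # a and b; c missed
        strict = score_linkage(tool, gold, require_all_comembers=True)
        assert strict.n_correctly_linked == 0

    def test_false_link_counts(self):
        gold = GoldStandard(clusters={"a": "a", "b": "b"})
        tool = result_from({"a": "a", "b": "a"})
        rep = score_linkage(tool, gold)
        assert rep.specificity_pct == 0.0
        assert rep.ppv_pct == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scorer(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        ids = [f"r{i}" for i in range(n)]
        gold_c = {r: f"g{int(rng.integers(0, n // 3 + 1))}" for r in ids}
        tool_c = {r: f"t{int(rng.integers(0, n // 3 + 1))}" for r in ids}
        rep = score_linkage(result_from(tool_c), GoldStandard(clusters=gold_c))
        expected = brute_force_score(tool_c, gold_c)
        for field, value in expected.items():
            assert getattr(rep, field) == value, field


def days(n: int) -> dt.date:
    return dt.date(2015, 1, 1) + dt.timedelta(days=n)


def rec_with_tests(rid, tests):
    return make_record(rid, tests=[TestRecord(rid, a, r, d) for a, r, d in tests])


class TestSerologyAudit:
    def linked(self, *rids):
        label = min(rids)
        return result_from({r: label for r in rids})

    def test_negative_ten_days_after_positive_is_discordant(self):
        a = rec_with_tests("a", [("HIV_WB", "positive", days(0)),
                                 ("HIV_AB", "positive", days(5))])
        b = rec_with_tests("b", [("HIV_AB", "negative", days(10))])
        rep = serology_audit([a, b], self.linked("a", "b"), "HIV")
        assert rep.n_discordant_clusters == 1
        assert rep.n_retained == 2 and rep.n_concordant == 1
        assert rep.incorrect_record_ids == ("b",)
        assert rep.ppv_pct == 50.0

    def test_negative_three_days_after_positive_within_window(self):
        a = rec_with_tests("a", [("HIV_WB", "positive", days(0))])
        b = rec_with_tests("b", [("HIV_AB", "negative", days(3))])
        rep = serology_audit([a, b], self.linked("a", "b"), "HIV")
        assert rep.n_discordant_clusters == 0
        assert rep.n_retained == 2 and rep.ppv_pct == 100.0

    def test_majority_negative_flags_the_positives(self):
        a = rec_with_tests("a", [("HCV_AB", "positive", days(0))])
        b = rec_with_tests("b", [("HCV_AB", "negative", days(30)),
                                 ("HCV_AB", "negative", days(60)),
                                 ("HCV_AB", "negative", days(90))])
        rep = serology_audit([a, b], self.linked("a", "b"), "HCV")
        assert rep.n_discordant_clusters == 1
        assert rep.incorrect_record_ids == ("a",)  # the lone positive is the intruder

    def test_own_history_discordance_excluded_before_linkage(self):
        # record a is internally discordant; its discordance must not be
        # attributed to the (clean) link with b
        a = rec_with_tests("a", [("HIV_WB", "positive", days(0)),
                                 ("HIV_AB", "negative", days(20))])
        b = rec_with_tests("b", [("HIV_AB", "negative", days(40))])
        rep = serology_audit([a, b], self.linked("a", "b"), "HIV")
        assert rep.n_retained == 0  # a excluded; cluster no longer auditable

    def test_cluster_without_initial_positive_not_retained(self):
        a = rec_with_tests("a", [("HIV_AB", "negative", days(0))])
        b = rec_with_tests("b", [("HIV_AB", "negative", days(5))])
        rep = serology_audit([a, b], self.linked("a", "b"), "HIV")
        assert rep.n_retained == 0 and rep.ppv_pct is None

    def test_hiv_requires_western_blot_as_initial_positive(self):
        # a positive HIV antibody alone does not start the HIV clock
        a = rec_with_tests("a", [("HIV_AB", "positive", days(0))])
        b = rec_with_tests("b", [("HIV_AB", "negative", days(30))])
        rep = serology_audit([a, b], self.linked("a", "b"), "HIV")
        assert rep.n_retained == 0

    def test_unknown_analyte_class_errors(self):
        with pytest.raises(ValueError, match="analyte class"):
            serology_audit([], result_from({}), "HBV")

    def test_unlinked_records_not_audited(self):
        a = rec_with_tests("a", [("HIV_WB", "positive", days(0))])
        b = rec_with_tests("b", [("HIV_AB", "negative", days(30))])
        rep = serology_audit([a, b], result_from({"a": "a", "b": "b"}), "HIV")
        assert rep.n_retained == 0


class TestEstimateSpecificity:
    def test_perfect_linkage(self):
        assert estimate_specificity(1.0, 1.0, 0.3) == 1.0

    def test_roundtrip_inverse_of_forward_identity(self):
        se, sp, pi = 0.9, 0.95, 0.3
        ppv = se * pi / (se * pi + (1 - sp) * (1 - pi))
        assert abs(estimate_specificity(ppv, se, pi) - sp) < 1e-10

    @pytest.mark.parametrize("bad", [
        dict(ppv=0.0, sensitivity=0.9, prevalence=0.3),
        dict(ppv=0.9, sensitivity=1.2, prevalence=0.3),
        dict(ppv=0.9, sensitivity=0.9, prevalence=1.0),
        dict(ppv=0.9, sensitivity=0.9, prevalence=0.0),
    ])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            estimate_specificity(**bad)

    def test_clamped_to_unit_interval(self):
        assert estimate_specificity(0.01, 1.0, 0.9) == 0.0


def test_report_from_counts_percentages():
    rep = EvalReport.from_counts("accept_all", 56, 54, 3644, 3644, 54, 54, 3646, 3644)
    assert rep.sensitivity_pct == 96.43
    assert rep.specificity_pct == 100.0
    assert rep.ppv_pct == 100.0
    assert rep.npv_pct == 99.95


def test_audit_report_estimated_specificity_consistency():
    rep = SerologyAuditReport.from_counts("accept_all", "HIV", 1245, 1427)
    assert rep.ppv_pct == 87.25
    sp = rep.estimated_specificity_pct(sensitivity=0.9515, prevalence=0.5)
    # inverse identity at the same prevalence reproduces the PPV
    se, pi = 0.9515, 0.5
    ppv_back = se * pi / (se * pi + (1 - sp / 100) * (1 - pi))
    assert abs(ppv_back - 0.8725) < 1e-3
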