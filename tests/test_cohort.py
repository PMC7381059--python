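"""Synthetic cohort generator: determinism, truth consistency, serology
validity, corruption rates, false-link injection."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from privlink import (
    CohortConfig,
    SiteConfig,
    build_gold_registry,
    generate_cohort,
    inject_false_links,
    make_deid_table,
    deid_table_to_records,
    run_linkage,
    score_linkage,
    serology_audit,
)
from privlink.cohort import build_discordant_scenario
from privlink.linker import LinkageResult


def clean_clinic_sites(n=4, p=0.3):
    return tuple(
        SiteConfig(f"c{i}", "clinic", visit_probability=p, medicare_missing_rate=0.0,
                   name_typo_rate=0.0, nickname_rate=0.0, dob_transpose_rate=0.0,
                   partial_dob_rate=0.0)
        for i in range(n)
    )


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(n_persons=400, rng_seed=42))


def test_byte_identical_reproducibility(cohort):
    again = generate_cohort(CohortConfig(n_persons=400, rng_seed=42))
    for name in ("identified", "truth", "tests", "registry", "persons"):
        assert getattr(cohort, name).to_csv(index=False) == getattr(again, name).to_csv(index=False)
    other = generate_cohort(CohortConfig(n_persons=400, rng_seed=43))
    assert other.identified.to_csv(index=False) != cohort.identified.to_csv(index=False)


def test_truth_covers_every_record_exactly_once(cohort):
    assert sorted(cohort.truth["record_id"]) == sorted(cohort.identified["record_id"])
    assert cohort.truth["record_id"].is_unique


def test_every_person_attends_at_least_one_clinic(cohort):
    clinic_records = cohort.identified[cohort.identified["site_type"] == "clinic"]
    persons_with_clinic = set(
        cohort.truth.set_index("record_id").loc[clinic_records["record_id"], "person_id"]
    )
    assert persons_with_clinic == set(cohort.persons["person_id"])


def test_specimen_flow_one_clinic_one_or_more_lab_records(cohort):
    site_type = dict(zip(cohort.identified["record_id"], cohort.identified["site_type"]))
    by_specimen = defaultdict(lambda: {"clinic": 0, "laboratory": 0})
    for row in cohort.tests.itertuples(index=False):
        by_specimen[row.specimen_id][site_type[row.record_id]] += 1
    for spec, counts in by_specimen.items():
        assert counts["clinic"] == 1, spec
        assert counts["laboratory"] >= 1, spec


def test_serology_valid_within_person(cohort):
    """No negative result postdates a positive within one person, so any
    post-linkage discordance is attributable to wrong links."""
    person_of = dict(zip(cohort.truth["record_id"], cohort.truth["person_id"]))
    tests = cohort.tests.assign(
        person=[person_of[r] for r in cohort.tests["record_id"]],
        date=pd.to_datetime(cohort.tests["test_date"]),
        cls=cohort.tests["analyte"].str[:3],
    )
    for (_, _), grp in tests.groupby(["person", "cls"]):
        pos = grp.loc[grp["result"] == "positive", "date"]
        neg = grp.loc[grp["result"] == "negative", "date"]
        if len(pos) and len(neg):
            assert neg.max() < pos.min()


def test_clean_data_limit_recovers_truth_exactly(key_config):
    cfg = CohortConfig(n_persons=150, rng_seed=5, sites=clean_clinic_sites(),
                       duplicate_emr_rate=0.0)
    c = generate_cohort(cfg)
    deid = make_deid_table(c.identified, key_config)
    records = deid_table_to_records(deid)
    gold = build_gold_registry(c.truth["record_id"], c.registry)
    rep = score_linkage(run_linkage(records, "accept_all"), gold)
    assert rep.sensitivity_pct == 100.0
    assert rep.specificity_pct == 100.0
    assert rep.ppv_pct == 100.0 and rep.npv_pct == 100.0


def test_medicare_missing_rate_respected(key_config):
    sites = clean_clinic_sites(2) + (
        SiteConfig("lab_poor", "laboratory", medicare_missing_rate=0.9),
    )
    c = generate_cohort(CohortConfig(n_persons=500, rng_seed=9, sites=sites))
    lab = c.identified[c.identified["site_id"] == "lab_poor"]
    frac_missing = (lab["medicare_number"] == "").mean()
    n = len(lab)
    se = np.sqrt(0.9 * 0.1 / n)
    assert abs(frac_missing - 0.9) < 3 * se
    # records without Medicare carry only the name-based key
    deid = make_deid_table(c.identified, key_config)
    no_med = deid[deid["record_id"].isin(lab.loc[lab["medicare_number"] == "", "record_id"])]
    assert (no_med["key1"] == "").all() and (no_med["key2"] == "").all() and (
        no_med["key4"] == ""
    ).all()


def test_distinct_persons_do_not_cross_link(key_config):
    """Two persons may share a surname and birth date, yet their records
    never merge on clean data (distinct first names / Medicare)."""
    cfg = CohortConfig(n_persons=200, rng_seed=21, sites=clean_clinic_sites(),
                       duplicate_emr_rate=0.0)
    c = generate_cohort(cfg)
    deid = make_deid_table(c.identified, key_config)
    res = run_linkage(deid_table_to_records(deid), "accept_all")
    person_of = dict(zip(c.truth["record_id"], c.truth["person_id"]))
    for pair in res.accepted_pairs:
        assert person_of[pair.record_id_a] == person_of[pair.record_id_b]


class TestInjectFalseLinks:
    def truth_clusters(self, n=200):
        return {f"r{i}": f"p{i}" for i in range(n)}

    def test_rate_zero_is_identity(self):
        truth = self.truth_clusters()
        clusters, injected = inject_false_links(truth, 0.0, rng_seed=1)
        assert injected == []
        assert len(set(clusters.values())) == len(truth)

    def test_injected_count_binomial(self):
        truth = self.truth_clusters(1000)
        counts = [len(inject_false_links(truth, 0.1, rng_seed=s)[1]) for s in range(10)]
        mean = np.mean(counts)
        assert abs(mean - 100) < 3 * np.sqrt(1000 * 0.1 * 0.9 / 10)

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            inject_false_links(self.truth_clusters(), 0.7, rng_seed=1)

    def test_injected_pairs_cross_person(self):
        truth = {f"r{i}": f"p{i // 2}" for i in range(100)}
        clusters, injected = inject_false_links(truth, 0.2, rng_seed=3)
        for a, b in injected:
            assert truth[a] != truth[b]
            assert clusters[a] == clusters[b]


def test_discordant_scenario_detected_by_audit():
    """An injected serodiscordant intruder is flagged by the audit."""
    c = generate_cohort(
        CohortConfig(n_persons=400, rng_seed=77, sites=clean_clinic_sites(p=0.4),
                     hiv_prevalence=0.4, tests_per_person_range=(3, 5))
    )
    clusters, injected = build_discordant_scenario(c, n_false_links=5, rng_seed=1)
    assert len(injected) == 5
    from privlink.pipeline import tests_by_record
    from conftest import make_record

    by_rec = tests_by_record(c.tests)
    records = [
        make_record(rid, tests=by_rec.get(rid, ()))
        for rid in c.truth["record_id"]
    ]
    result = LinkageResult(accepted_pairs=(), clusters=clusters, approach="synthetic")
    rep = serology_audit(records, result, "HIV")
    assert set(rep.incorrect_record_ids) == set(injected)
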