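"""Reproducible evaluation experiments on synthetic cohorts.

Each function sets up one study condition, runs the full pipeline
(identity preparation, key generation, linkage, scoring/audit) and returns
the measured quantities. They are the package's own validation
experiments:

* the clean-data limit — complete, uncorrupted identifiers: every
  acceptance approach must recover the truth exactly;
* the Medicare-missingness response — one laboratory records almost no
  Medicare numbers, so its records carry only the name-based key and
  approaches that require two key types lose the matches involving it;
* estimator recovery — a linkage with known injected serodiscordant false
  links, against which the discordance-audit PPV and the Bayes-inversion
  specificity estimate are compared with directly measured truth.

All randomness flows from the seed arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import (
    CohortConfig,
    CohortData,
    SiteConfig,
    build_discordant_scenario,
    generate_cohort,
)
from .evaluation import (
    EvalReport,
    build_gold_registry,
    estimate_specificity,
    score_linkage,
    serology_audit,
)
from .keys import KeyGenConfig
from .linker import APPROACHES, LinkageResult, run_linkage
from .pipeline import deid_table_to_records, make_deid_table

__all__ = [
    "clean_clinic_sites",
    "run_clean_limit",
    "run_missingness_response",
    "run_estimator_recovery",
    "inversion_roundtrip_max_error",
]

_KEYCFG = KeyGenConfig(secret_seed=b"privlink-experiments")


def clean_clinic_sites(n: int = 4, visit_probability: float = 0.3) -> tuple[SiteConfig, ...]:
    """Clinics with complete, uncorrupted identifier recording."""
    return tuple(
        SiteConfig(
            f"clinic{i}", "clinic", visit_probability=visit_probability,
            medicare_missing_rate=0.0, name_typo_rate=0.0, nickname_rate=0.0,
            dob_transpose_rate=0.0, partial_dob_rate=0.0,
        )
        for i in range(1, n + 1)
    )


def _deid_records(cohort: CohortData):
    deid = make_deid_table(cohort.identified, _KEYCFG)
    return deid, deid_table_to_records(deid, cohort.tests)


def run_clean_limit(n_persons: int = 1000, seed: int = 0) -> dict[str, EvalReport]:
    """Score all six approaches on a clean clinic-only cohort.

    With complete identifiers and no shared identities, every approach
    should achieve 100% sensitivity, specificity, PPV and NPV.
    """
    cohort = generate_cohort(
        CohortConfig(
            n_persons=n_persons, rng_seed=seed, sites=clean_clinic_sites(),
            duplicate_emr_rate=0.0,
        )
    )
    _, records = _deid_records(cohort)
    gold = build_gold_registry(cohort.truth["record_id"], cohort.registry)
    return {a: score_linkage(run_linkage(records, a), gold) for a in APPROACHES}


@dataclass(frozen=True)
class MissingnessResult:
    site_id: str
    n_site_records: int
    frac_key3_only: float
    configured_rate: float
    site_sensitivity: dict[str, float]  # approach -> % among gold-linked records at the site


def run_missingness_response(
    n_persons: int = 2000, seed: int = 0, missing_rate: float = 0.97
) -> MissingnessResult:
    """One laboratory blanks the Medicare number at *missing_rate*.

    Measures (a) the fraction of that site's records carrying only key
    type 3, and (b) the sensitivity restricted to gold-linked records at
    that site, per approach — requiring two or more matching key types
    must lose matches there, since those records have only one key.
    """
    lab = SiteConfig(
        "lab_missing", "laboratory", medicare_missing_rate=missing_rate,
        name_typo_rate=0.0, nickname_rate=0.0, dob_transpose_rate=0.0,
        partial_dob_rate=0.0,
    )
    cohort = generate_cohort(
        CohortConfig(
            n_persons=n_persons, rng_seed=seed,
            sites=clean_clinic_sites() + (lab,), duplicate_emr_rate=0.0,
        )
    )
    deid, records = _deid_records(cohort)
    site_ids = set(deid.loc[deid["site_id"] == "lab_missing", "record_id"])
    key3_only = deid.loc[
        deid["record_id"].isin(site_ids)
        & (deid["key3"] != "")
        & (deid["key1"] == "") & (deid["key2"] == "") & (deid["key4"] == ""),
        "record_id",
    ]
    gold = build_gold_registry(cohort.truth["record_id"], cohort.registry)
    gold_members = gold.members()
    site_gold_linked = [r for r in gold.linked_ids if r in site_ids]

    site_sens: dict[str, float] = {}
    for approach in APPROACHES:
        result = run_linkage(records, approach)
        members = result.cluster_members()
        n_correct = 0
        for rid in site_gold_linked:
            mates = set(members[result.clusters[rid]]) - {rid}
            true_mates = gold_members[gold.clusters[rid]] - {rid}
            if mates & true_mates:
                n_correct += 1
        site_sens[approach] = 100.0 * n_correct / len(site_gold_linked)
    return MissingnessResult(
        site_id="lab_missing",
        n_site_records=len(site_ids),
        frac_key3_only=len(key3_only) / len(site_ids),
        configured_rate=missing_rate,
        site_sensitivity=site_sens,
    )


@dataclass(frozen=True)
class EstimatorRecoveryResult:
    n_records: int
    n_false_links: int
    prevalence: float  # of truly-linked records
    measured: EvalReport  # direct scoring against truth
    audit_ppv_pct: float
    audit_n_retained: int
    estimated_specificity_pct: float
    ppv_tolerance_pct: float  # 2 Monte-Carlo SEs on the audit PPV
    specificity_tolerance_pct: float  # 2 SEs on specificity, plus propagated PPV error


def run_estimator_recovery(
    n_persons: int = 6000, seed: int = 0, n_false_links: int = 60
) -> EstimatorRecoveryResult:
    """Validate the audit PPV and the specificity estimator on known truth.

    Builds a tool clustering whose errors are fully known: auditable true
    clusters are kept, other true links are treated as missed, and
    *n_false_links* serodiscordant intruders are attached to retained
    clusters. Scoring is restricted to the serology-bearing subpopulation
    (records carrying at least one HIV result): the audit can only ever
    see those records, and within that universe the audit PPV estimates
    the linkage PPV directly and the Bayes identity relating PPV,
    sensitivity, prevalence and specificity is exact. The audit PPV should
    match the directly measured PPV, and the inversion applied to
    (audit PPV, measured sensitivity, true prevalence) should match the
    directly measured specificity, both within Monte-Carlo error.
    """
    cohort = generate_cohort(
        CohortConfig(
            n_persons=n_persons, rng_seed=seed,
            sites=clean_clinic_sites(visit_probability=0.4),
            duplicate_emr_rate=0.0, hiv_prevalence=0.4,
            tests_per_person_range=(3, 5),
        )
    )
    clusters, injected = build_discordant_scenario(
        cohort, n_false_links=n_false_links, rng_seed=seed + 1
    )
    result = LinkageResult(accepted_pairs=(), clusters=clusters, approach="synthetic")

    # serology-bearing subpopulation: the audit's visible universe
    hiv_tests = cohort.tests[cohort.tests["analyte"].isin(["HIV_WB", "HIV_AB"])]
    subpop = set(hiv_tests["record_id"])
    sub_result = LinkageResult(
        accepted_pairs=(),
        clusters={r: c for r, c in clusters.items() if r in subpop},
        approach="synthetic",
    )
    sub_registry = cohort.registry[cohort.registry["record_id"].isin(subpop)]
    gold = build_gold_registry(sorted(subpop), sub_registry)
    measured = score_linkage(sub_result, gold)

    _, records = _deid_records(cohort)
    audit = serology_audit(records, result, "HIV")

    n_all = len(sub_result.clusters)
    prevalence = measured.n_gold_linked / n_all
    se_frac = measured.sensitivity_pct / 100.0
    est_sp = estimate_specificity(audit.ppv_pct / 100.0, se_frac, prevalence)

    p = audit.ppv_pct / 100.0
    se_ppv = math.sqrt(max(p * (1 - p), 1e-12) / audit.n_retained)
    sp = measured.specificity_pct / 100.0
    se_sp = math.sqrt(max(sp * (1 - sp), 1e-12) / measured.n_gold_unlinked)
    # sensitivity of the inversion to PPV error: dSp/dPPV = Se*pi/(PPV^2 (1-pi))
    dsp_dppv = se_frac * prevalence / (p**2 * (1 - prevalence))
    return EstimatorRecoveryResult(
        n_records=n_all,
        n_false_links=len(injected),
        prevalence=prevalence,
        measured=measured,
        audit_ppv_pct=audit.ppv_pct,
        audit_n_retained=audit.n_retained,
        estimated_specificity_pct=100.0 * est_sp,
        ppv_tolerance_pct=100.0 * 2 * se_ppv,
        specificity_tolerance_pct=100.0 * (2 * se_sp + dsp_dppv * 2 * se_ppv),
    )


def inversion_roundtrip_max_error(grid_points: int = 9) -> float:
    """Max |inverted - true| specificity over a (Se, Sp, prevalence) grid,
    passing the forward PPV identity through the inversion."""
    worst = 0.0
    values = [0.1 + 0.8 * i / (grid_points - 1) for i in range(grid_points)]
    for se in values:
        for sp in values:
            for pi in values:
                ppv = se * pi / (se * pi + (1 - sp) * (1 - pi))
                worst = max(worst, abs(estimate_specificity(ppv, se, pi) - sp))
    return worst
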