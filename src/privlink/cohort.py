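"""Seeded synthetic multi-site EMR cohorts with ground truth.

The generator emulates the data conditions a sentinel-surveillance linkage
system faces, so that key generation, linkage and evaluation can be
exercised end-to-end without any real data:

* duplicate identities — one person owns records at several clinics (and
  possibly several records at one site);
* per-site identifier quality — each site has its own rates of missing
  Medicare numbers, name typos, nickname use, day/month transposition and
  year-only dates of birth (public laboratories in particular may record
  almost no Medicare numbers);
* clinic-to-laboratory specimen flows — every clinic test is mirrored to a
  laboratory record sharing the specimen ID, with the recorded date
  jittered by up to a configurable number of days;
* longitudinal HIV / hepatitis C serology consistent with each person's
  true status: every antibody test after infection is positive, every test
  before it (and every test of an uninfected person) is negative, with no
  assay errors. Any discordance observed after linkage is therefore
  attributable to wrong links.

Name typos come in two regimes: phonetic-preserving edits (the misspelling
keeps its double-metaphone code, so the name-based key still matches) and
phonetic-breaking edits (the code changes and the key is lost). The split
is configurable; both are needed to exercise sensitivity loss.

All outputs are plain tables, byte-reproducible from the seed.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .identity import canonicalize_dob, default_nickname_table, _load_lines
from .phonetics import double_metaphone

__all__ = [
    "SiteConfig",
    "CohortConfig",
    "CohortData",
    "default_sites",
    "generate_cohort",
    "inject_false_links",
    "build_discordant_scenario",
]

_STUDY_START = dt.date(2010, 1, 1)
_STUDY_END = dt.date(2018, 4, 30)
_CONSONANTS = "BCDFGHJKLMNPQRSTVWXZ"
_VOWELS = "AEIOU"


@dataclass(frozen=True)
class SiteConfig:
    """Identifier-quality profile of one site."""

    site_id: str
    site_type: str  # "clinic" | "laboratory"
    visit_probability: float = 0.3  # clinics only
    medicare_missing_rate: float = 0.05
    name_typo_rate: float = 0.02
    nickname_rate: float = 0.05
    dob_transpose_rate: float = 0.01
    partial_dob_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.site_type not in ("clinic", "laboratory"):
            raise ValueError(f"unknown site_type {self.site_type!r}")
        for name in (
            "visit_probability",
            "medicare_missing_rate",
            "name_typo_rate",
            "nickname_rate",
            "dob_transpose_rate",
            "partial_dob_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def default_sites() -> tuple[SiteConfig, ...]:
    """A default site mix: seven general clinics with near-complete
    Medicare recording, one sexual-health clinic recording it for roughly
    half of its patients, and four laboratories whose Medicare completeness
    spans near-complete to almost absent (public laboratories often receive
    requests without the number)."""
    clinics = [
        SiteConfig(f"clinic{i}", "clinic", visit_probability=p, medicare_missing_rate=m)
        for i, (p, m) in enumerate(
            [(0.30, 0.03), (0.35, 0.05), (0.20, 0.01), (0.40, 0.03),
             (0.15, 0.01), (0.20, 0.07), (0.25, 0.03)],
            start=1,
        )
    ]
    clinics.append(
        SiteConfig("clinic_sh", "clinic", visit_probability=0.35, medicare_missing_rate=0.54)
    )
    labs = [
        SiteConfig("lab1", "laboratory", medicare_missing_rate=0.10),
        SiteConfig("lab2", "laboratory", medicare_missing_rate=0.97),
        SiteConfig("lab3", "laboratory", medicare_missing_rate=0.45),
        SiteConfig("lab4", "laboratory", medicare_missing_rate=0.04),
    ]
    return tuple(clinics + labs)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_persons: int
    rng_seed: int
    sites: tuple[SiteConfig, ...] = field(default_factory=default_sites)
    duplicate_emr_rate: float = 0.02
    hiv_prevalence: float = 0.05
    hcv_prevalence: float = 0.03
    tests_per_person_range: tuple[int, int] = (1, 4)
    specimen_date_jitter_days: int = 2
    typo_phonetic_break_share: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.n_persons <= 100_000:
            raise ValueError("n_persons must be in 1..100000")
        if not self.sites:
            raise ValueError("at least one site is required")
        if not any(s.site_type == "clinic" for s in self.sites):
            raise ValueError("at least one clinic site is required")
        if not 0 <= self.specimen_date_jitter_days <= 7:
            raise ValueError("specimen_date_jitter_days must be in 0..7")
        for name in ("duplicate_emr_rate", "hiv_prevalence", "hcv_prevalence",
                     "typo_phonetic_break_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.tests_per_person_range
        if not (1 <= lo <= hi):
            raise ValueError("tests_per_person_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class CohortData:
    """Generated cohort tables (all plain string/int columns).

    identified — one row per EMR with as-recorded identifiers;
    truth      — record_id -> person_id;
    tests      — serology results per record, with specimen IDs;
    registry   — (person_id, record_id) auxiliary registry rows;
    persons    — person-level truth (serostatus and infection dates).
    """

    identified: pd.DataFrame
    truth: pd.DataFrame
    tests: pd.DataFrame
    registry: pd.DataFrame
    persons: pd.DataFrame


def _rand_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _typo(
    rng: np.random.Generator, name: str, break_phonetic: bool, max_tries: int = 12
) -> str:
    """Single-character edit that preserves or breaks the phonetic code."""
    target = double_metaphone(name)[0]
    for _ in range(max_tries):
        kind = rng.integers(0, 3)
        i = int(rng.integers(0, len(name)))
        if kind == 0 and len(name) > 3:  # deletion
            cand = name[:i] + name[i + 1 :]
        elif kind == 1:  # substitution
            pool = _VOWELS if name[i] in _VOWELS and not break_phonetic else _CONSONANTS
            c = pool[int(rng.integers(0, len(pool)))]
            if c == name[i]:
                continue
            cand = name[:i] + c + name[i + 1 :]
        else:  # duplication
            cand = name[:i] + name[i] + name[i:]
        changed = double_metaphone(cand)[0] != target
        if cand != name and changed == break_phonetic:
            return cand
    return name  # no suitable edit found; leave unchanged


class _IdentityCorruptor:
    def __init__(self, rng: np.random.Generator, break_share: float):
        self.rng = rng
        self.break_share = break_share
        nick = default_nickname_table()
        self.nicknames_of: dict[str, list[str]] = defaultdict(list)
        for n, canon in sorted(nick.items()):
            self.nicknames_of[canon].append(n)

    def record_fields(self, person: dict, site: SiteConfig) -> dict:
        rng = self.rng
        first, last = person["first_name"], person["last_name"]
        day, month, year = person["birth_day"], person["birth_month"], person["birth_year"]
        medicare = person["medicare_number"]

        if self.nicknames_of.get(first) and rng.random() < site.nickname_rate:
            opts = self.nicknames_of[first]
            first = opts[int(rng.integers(0, len(opts)))]
        if rng.random() < site.name_typo_rate:
            breaking = rng.random() < self.break_share
            if rng.random() < 0.5:
                first = _typo(rng, first, breaking)
            else:
                last = _typo(rng, last, breaking)
        if rng.random() < site.dob_transpose_rate and day <= 12 and month <= 12 and day != month:
            day, month = month, day
        if rng.random() < site.partial_dob_rate:
            day = month = None
        if rng.random() < site.medicare_missing_rate:
            medicare = ""
        return {
            "first_name": first,
            "last_name": last,
            "birth_day": day,
            "birth_month": month,
            "birth_year": year,
            "sex": person["sex"],
            "postcode": person["postcode"],
            "medicare_number": medicare,
        }


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate a cohort under the given study conditions.

    Every person attends at least one clinic; corruption is drawn
    independently per record, so two records of one person may disagree in
    exactly the ways real duplicate EMRs do. Fully reproducible from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    firsts = _load_lines("first_names.txt")
    lasts = _load_lines("last_names.txt")
    corruptor = _IdentityCorruptor(rng, config.typo_phonetic_break_share)
    clinics = [s for s in config.sites if s.site_type == "clinic"]
    labs = [s for s in config.sites if s.site_type == "laboratory"]

    # Distinct persons carry distinct Medicare cards; assigning distinct
    # 5-digit prefixes reflects that (family card sharing is out of scope).
    medicare5_pool = rng.permutation(100_000)[: config.n_persons]

    persons = []
    seen_signatures: set[tuple] = set()
    for i in range(config.n_persons):
        # Resample identities whose phonetic-name + canonical-DOB signature
        # collides with an earlier person: synthetic persons are distinct
        # individuals, and a chance signature clash would make them
        # indistinguishable to any linkage, corrupting the ground truth.
        for _ in range(100):
            first = firsts[int(rng.integers(0, len(firsts)))]
            last = lasts[int(rng.integers(0, len(lasts)))]
            year = int(rng.integers(1950, 2001))
            month = int(rng.integers(1, 13))
            day = int(rng.integers(1, 29))
            _, dob_t3 = canonicalize_dob(day, month, year)
            sig = (double_metaphone(first)[0], double_metaphone(last)[0], dob_t3)
            if sig not in seen_signatures:
                seen_signatures.add(sig)
                break
        hiv = bool(rng.random() < config.hiv_prevalence)
        hcv = bool(rng.random() < config.hcv_prevalence)
        persons.append(
            {
                "person_id": f"P{i:06d}",
                "first_name": first,
                "last_name": last,
                "birth_day": day,
                "birth_month": month,
                "birth_year": year,
                "sex": "M" if rng.random() < 0.5 else "F",
                "postcode": f"{int(rng.integers(3000, 4000)):04d}",
                "medicare_number": f"{int(medicare5_pool[i]):05d}"
                + "".join(str(int(d)) for d in rng.integers(0, 10, size=5)),
                "hiv_positive": hiv,
                "hiv_infection_date": _rand_date(rng, dt.date(2010, 6, 1), dt.date(2015, 12, 31))
                if hiv
                else None,
                "hcv_positive": hcv,
                "hcv_infection_date": _rand_date(rng, dt.date(2010, 6, 1), dt.date(2015, 12, 31))
                if hcv
                else None,
            }
        )

    id_rows: list[dict] = []
    truth_rows: list[dict] = []
    test_rows: list[dict] = []
    registry_rows: list[dict] = []
    record_counter = 0
    specimen_counter = 0

    def new_record(person: dict, site: SiteConfig) -> str:
        nonlocal record_counter
        rid = f"R{record_counter:07d}"
        record_counter += 1
        fields = corruptor.record_fields(person, site)
        id_rows.append(
            {"record_id": rid, "site_id": site.site_id, "site_type": site.site_type, **fields}
        )
        truth_rows.append({"record_id": rid, "person_id": person["person_id"]})
        registry_rows.append({"person_id": person["person_id"], "record_id": rid})
        return rid

    for person in persons:
        visited = [c for c in clinics if rng.random() < c.visit_probability]
        if not visited:
            visited = [clinics[int(rng.integers(0, len(clinics)))]]
        clinic_records: list[str] = []
        for site in visited:
            clinic_records.append(new_record(person, site))
            if rng.random() < config.duplicate_emr_rate:
                clinic_records.append(new_record(person, site))

        lab_records: dict[str, str] = {}  # lab site_id -> record_id (one EMR per lab)

        def add_test(analyte: str, result: str, date: dt.date) -> None:
            nonlocal specimen_counter
            clinic_rid = clinic_records[int(rng.integers(0, len(clinic_records)))]
            specimen = f"SP{specimen_counter:07d}"
            specimen_counter += 1
            test_rows.append(
                {
                    "record_id": clinic_rid,
                    "analyte": analyte,
                    "result": result,
                    "test_date": date.isoformat(),
                    "specimen_id": specimen,
                }
            )
            if labs:
                lab = labs[int(rng.integers(0, len(labs)))]
                if lab.site_id not in lab_records:
                    lab_records[lab.site_id] = new_record(person, lab)
                lab_date = date + dt.timedelta(
                    days=int(rng.integers(0, config.specimen_date_jitter_days + 1))
                )
                test_rows.append(
                    {
                        "record_id": lab_records[lab.site_id],
                        "analyte": analyte,
                        "result": result,
                        "test_date": lab_date.isoformat(),
                        "specimen_id": specimen,
                    }
                )

        lo, hi = config.tests_per_person_range
        for disease, wb in (("hiv", True), ("hcv", False)):
            n_tests = int(rng.integers(lo, hi + 1))
            dates = sorted(
                _rand_date(rng, _STUDY_START, _STUDY_END) for _ in range(n_tests)
            )
            infected = person[f"{disease}_positive"]
            infection = person[f"{disease}_infection_date"]
            ab = "HIV_AB" if disease == "hiv" else "HCV_AB"
            if infected:
                # guarantee at least one post-infection result
                if all(d < infection for d in dates):
                    dates[-1] = infection + dt.timedelta(days=int(rng.integers(14, 200)))
                    dates.sort()
                first_pos_emitted = False
                for d in dates:
                    if d < infection:
                        add_test(ab, "negative", d)
                    elif disease == "hiv" and not first_pos_emitted:
                        add_test("HIV_WB", "positive", d)
                        first_pos_emitted = True
                    else:
                        add_test(ab, "positive", d)
            else:
                for d in dates:
                    add_test(ab, "negative", d)

    identified = pd.DataFrame(
        id_rows,
        columns=[
            "record_id", "site_id", "site_type", "first_name", "last_name",
            "birth_day", "birth_month", "birth_year", "sex", "postcode",
            "medicare_number",
        ],
    )
    # all-string columns ('' = missing): matches the CSV convention and
    # keeps output byte-identical across runs
    for col in ("birth_day", "birth_month", "birth_year"):
        identified[col] = identified[col].map(
            lambda v: "" if v is None or pd.isna(v) else str(int(v))
        )
    persons_df = pd.DataFrame(persons)[
        ["person_id", "hiv_positive", "hiv_infection_date", "hcv_positive", "hcv_infection_date"]
    ]
    return CohortData(
        identified=identified,
        truth=pd.DataFrame(truth_rows, columns=["record_id", "person_id"]),
        tests=pd.DataFrame(
            test_rows, columns=["record_id", "analyte", "result", "test_date", "specimen_id"]
        ),
        registry=pd.DataFrame(registry_rows, columns=["person_id", "record_id"]),
        persons=persons_df,
    )


def inject_false_links(
    truth_clusters: Mapping[str, str],
    rate: float,
    rng_seed: int,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Union cross-person record pairs into a clustering at the given rate.

    Each record is, with probability *rate*, linked to one record of a
    different person (so the injected pair count is Binomial(n, rate)).
    Returns the perturbed record_id -> cluster_id mapping together with the
    injected pairs, for testing the discordance audit and the specificity
    estimator against known truth.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError("rate must be in [0, 0.5]")
    rng = np.random.default_rng(rng_seed)
    ids = sorted(truth_clusters)
    person_of = dict(truth_clusters)
    parent = {r: r for r in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    injected: list[tuple[str, str]] = []
    for rid in ids:
        if rng.random() >= rate:
            continue
        for _ in range(20):
            other = ids[int(rng.integers(0, len(ids)))]
            if person_of[other] != person_of[rid]:
                break
        else:
            continue
        injected.append((min(rid, other), max(rid, other)))
        ra, rb = find(rid), find(other)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    # merge true clusters too
    by_person: dict[str, list[str]] = defaultdict(list)
    for rid in ids:
        by_person[person_of[rid]].append(rid)
    for members in by_person.values():
        for other in members[1:]:
            ra, rb = find(members[0]), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    return {rid: find(rid) for rid in ids}, injected


def build_discordant_scenario(
    cohort: CohortData,
    n_false_links: int,
    rng_seed: int,
    analyte_class: str = "HIV",
    window_days: int = 7,
) -> tuple[dict[str, str], list[str]]:
    """Construct a tool clustering with known, serologically detectable
    false links, for validating the discordance audit and the specificity
    estimator against ground truth.

    The identifiability conditions of the audit-based PPV are built in:
    the tool clustering keeps exactly those true clusters that the audit
    can retain (seropositive persons with an initial positive and at least
    two later positive antibody results, spread over at least two
    records); all other true links are treated as missed matches. Each
    injected false link attaches the record of a seronegative
    single-record person to one retained cluster, choosing intruders whose
    negative antibody results are at least *window_days* after the
    cluster's initial positive and fewer than the cluster's later
    positives (so the majority rule attributes the error to the intruder).
    Under these conditions the audit's concordant/retained ratio estimates
    the linkage PPV without bias.

    Returns ``(clusters, injected_record_ids)`` where *clusters* maps every
    record_id to a tool cluster label.
    """
    if analyte_class == "HIV":
        index_analytes, ab = {"HIV_WB"}, "HIV_AB"
        pos_col, date_col = "hiv_positive", "hiv_infection_date"
    elif analyte_class == "HCV":
        index_analytes, ab = {"HCV_AB"}, "HCV_AB"
        pos_col, date_col = "hcv_positive", "hcv_infection_date"
    else:
        raise ValueError(f"unknown analyte class {analyte_class!r}")

    rng = np.random.default_rng(rng_seed)
    person_of = dict(zip(cohort.truth["record_id"], cohort.truth["person_id"]))
    records_of: dict[str, list[str]] = defaultdict(list)
    for rid, pid in sorted(person_of.items()):
        records_of[pid].append(rid)
    positive = dict(zip(cohort.persons["person_id"], cohort.persons[pos_col]))

    tests = cohort.tests.copy()
    tests["test_date"] = pd.to_datetime(tests["test_date"]).dt.date
    tests_of_record: dict[str, list[tuple[str, str, dt.date]]] = defaultdict(list)
    for row in tests.itertuples(index=False):
        tests_of_record[str(row.record_id)].append(
            (str(row.analyte), str(row.result), row.test_date)
        )

    def person_tests(pid: str) -> list[tuple[str, str, dt.date]]:
        return [t for rid in records_of[pid] for t in tests_of_record[rid]]

    # retained clusters: multi-record seropositive persons with an
    # auditable history spread over >= 2 records
    retained: list[tuple[str, dt.date, int]] = []  # (person, initial_pos, n_later_pos_ab)
    for pid, rids in records_of.items():
        if len(rids) < 2 or not positive.get(pid, False):
            continue
        ts = person_tests(pid)
        pos_idx = [d for a, r, d in ts if a in index_analytes and r == "positive"]
        if not pos_idx:
            continue
        initial = min(pos_idx)
        later_pos_ab = sum(1 for a, r, d in ts if a == ab and r == "positive" and d > initial)
        relevant = index_analytes | {ab}
        records_with_tests = sum(
            1 for rid in rids if any(a in relevant for a, _, _ in tests_of_record[rid])
        )
        if later_pos_ab >= 2 and records_with_tests >= 2:
            retained.append((pid, initial, later_pos_ab))

    # candidate intruders: single-record seronegative persons whose
    # negative antibody results can postdate an initial positive
    intruders: list[tuple[str, list[dt.date]]] = []
    for pid, rids in records_of.items():
        if len(rids) != 1 or positive.get(pid, False):
            continue
        neg_dates = [d for a, r, d in tests_of_record[rids[0]] if a == ab and r == "negative"]
        if neg_dates:
            intruders.append((rids[0], neg_dates))

    clusters: dict[str, str] = {rid: rid for rid in person_of}
    for pid, _, _ in retained:
        label = min(records_of[pid])
        for rid in records_of[pid]:
            clusters[rid] = label

    injected: list[str] = []
    used: set[str] = set()
    intruder_order = [intruders[int(i)] for i in rng.permutation(len(intruders))]
    for c_idx in rng.permutation(len(retained)):  # at most one intruder per cluster
        if len(injected) >= n_false_links:
            break
        pid, initial, n_later_pos = retained[int(c_idx)]
        for rid, neg_dates in intruder_order:
            if rid in used:
                continue
            post_initial = [d for d in neg_dates if d > initial]
            qualifying = [d for d in post_initial if (d - initial).days >= window_days]
            # detectable, and outnumbered by the cluster's own later
            # positives so the majority rule blames the intruder
            if qualifying and len(post_initial) < n_later_pos:
                clusters[rid] = min(records_of[pid])
                injected.append(rid)
                used.add(rid)
                break
    if len(injected) < n_false_links:
        raise ValueError(
            f"only {len(injected)} of {n_false_links} requested false links could be "
            "placed; enlarge the cohort or its seropositive fraction"
        )
    return clusters, injected
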