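"""Linkage-quality evaluation.

Two gold-standard builders provide ground-truth clusterings against which a
linkage result is scored record-by-record:

* a **registry** gold standard, from an auxiliary person identifier
  (e.g. a study enrolment ID) recorded alongside each record;
* a **specimen** gold standard, matching clinic and laboratory records on
  laboratory specimen ID, year of birth, and test date within a tolerance
  (default 7 days, because the recorded date for one specimen commonly
  differs between clinic and laboratory systems). Only matched records
  enter this gold standard — unmatched records cannot be verified as
  belonging to different people, so specificity is not directly measurable
  from it.

Scoring is at the record (EMR) level: a truly-linked record counts as
correctly linked when the tool places it with at least one true co-member;
a truly-single record counts as correctly unlinked when the tool links it
to nothing.

Where specificity cannot be measured directly, it is estimated via a
serology audit: within one person, an HIV or hepatitis C antibody test
after infection can never revert to negative, so a negative antibody
result at least ``window_days`` after a positive result inside one linked
cluster is evidence of a wrong link. The audit yields a PPV, and
specificity follows from PPV, sensitivity and prevalence by inverting the
Bayes identity PPV = Se·pi / (Se·pi + (1 - Sp)(1 - pi)).
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .linker import DeidRecord, LinkageResult
from .util import percentage, round_half_up

__all__ = [
    "GoldStandard",
    "TestRecord",
    "EvalReport",
    "SerologyAuditReport",
    "build_gold_registry",
    "build_gold_specimen",
    "score_linkage",
    "serology_audit",
    "estimate_specificity",
]

ANALYTES = ("HIV_WB", "HIV_AB", "HCV_AB")


@dataclass(frozen=True)
class TestRecord:
    """One serology result attached to a record."""

    __test__ = False  # not a pytest class, despite the name

    record_id: str
    analyte: str  # HIV_WB | HIV_AB | HCV_AB
    result: str  # positive | negative
    test_date: dt.date
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.result not in ("positive", "negative"):
            raise ValueError(f"unknown result {self.result!r}")


@dataclass(frozen=True)
class GoldStandard:
    """Ground-truth clustering of record IDs."""

    clusters: Mapping[str, str]  # record_id -> gold_id

    @property
    def linked_ids(self) -> frozenset[str]:
        sizes: dict[str, int] = defaultdict(int)
        for gid in self.clusters.values():
            sizes[gid] += 1
        return frozenset(r for r, g in self.clusters.items() if sizes[g] >= 2)

    @property
    def unlinked_ids(self) -> frozenset[str]:
        return frozenset(self.clusters) - self.linked_ids

    def members(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for rid, gid in self.clusters.items():
            out[gid].add(rid)
        return {g: frozenset(m) for g, m in out.items()}


@dataclass(frozen=True)
class EvalReport:
    """Record-level evaluation of one linkage approach against a gold
    standard; percentages to 2 decimals, None where not estimable."""

    approach: str
    n_gold_linked: int
    n_correctly_linked: int
    sensitivity_pct: float | None
    n_gold_unlinked: int
    n_correctly_unlinked: int
    specificity_pct: float | None
    n_tool_linked: int
    n_tool_linked_correct: int
    ppv_pct: float | None
    n_tool_unlinked: int
    n_tool_unlinked_correct: int
    npv_pct: float | None

    @classmethod
    def from_counts(
        cls,
        approach: str,
        n_gold_linked: int,
        n_correctly_linked: int,
        n_gold_unlinked: int,
        n_correctly_unlinked: int,
        n_tool_linked: int,
        n_tool_linked_correct: int,
        n_tool_unlinked: int,
        n_tool_unlinked_correct: int,
    ) -> "EvalReport":
        return cls(
            approach=approach,
            n_gold_linked=n_gold_linked,
            n_correctly_linked=n_correctly_linked,
            sensitivity_pct=percentage(n_correctly_linked, n_gold_linked),
            n_gold_unlinked=n_gold_unlinked,
            n_correctly_unlinked=n_correctly_unlinked,
            specificity_pct=percentage(n_correctly_unlinked, n_gold_unlinked),
            n_tool_linked=n_tool_linked,
            n_tool_linked_correct=n_tool_linked_correct,
            ppv_pct=percentage(n_tool_linked_correct, n_tool_linked),
            n_tool_unlinked=n_tool_unlinked,
            n_tool_unlinked_correct=n_tool_unlinked_correct,
            npv_pct=percentage(n_tool_unlinked_correct, n_tool_unlinked),
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class SerologyAuditReport:
    """Discordant-serology audit of linked clusters for one analyte class."""

    approach: str
    analyte_class: str  # HIV | HCV
    n_retained: int  # linked EMRs with an antibody result after an initial positive
    n_concordant: int
    n_discordant_clusters: int
    ppv_pct: float | None
    incorrect_record_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_concordant > self.n_retained:
            raise ValueError("concordant count cannot exceed retained count")

    @classmethod
    def from_counts(
        cls, approach: str, analyte_class: str, n_concordant: int, n_retained: int
    ) -> "SerologyAuditReport":
        return cls(
            approach=approach,
            analyte_class=analyte_class,
            n_retained=n_retained,
            n_concordant=n_concordant,
            n_discordant_clusters=0,
            ppv_pct=percentage(n_concordant, n_retained),
        )

    def estimated_specificity_pct(
        self, sensitivity: float, prevalence: float
    ) -> float | None:
        """Specificity implied by this audit's PPV at the given linkage
        sensitivity and prevalence of truly-linked records (proportions)."""
        if self.ppv_pct is None:
            return None
        sp = estimate_specificity(self.ppv_pct / 100.0, sensitivity, prevalence)
        return round_half_up(100.0 * sp)


def build_gold_registry(
    record_ids: Iterable[str],
    registry: Iterable[tuple[str, str]] | pd.DataFrame,
) -> GoldStandard:
    """Gold standard from an auxiliary person-ID registry.

    *registry* holds (person_id, record_id) rows; records sharing a person
    ID form one gold cluster and every other record is a singleton. A
    record registered under two different person IDs is an error.
    """
    if isinstance(registry, pd.DataFrame):
        rows = list(zip(registry["person_id"].astype(str), registry["record_id"].astype(str)))
    else:
        rows = [(str(p), str(r)) for p, r in registry]
    known = set(map(str, record_ids))
    assigned: dict[str, str] = {}
    for person_id, record_id in rows:
        if record_id not in known:
            raise ValueError(f"registry references unknown record {record_id!r}")
        prev = assigned.get(record_id)
        if prev is not None and prev != person_id:
            raise ValueError(
                f"conflicting registry rows for record {record_id!r}: {prev!r} vs {person_id!r}"
            )
        assigned[record_id] = person_id
    clusters = {
        rid: (f"G:{assigned[rid]}" if rid in assigned else f"S:{rid}") for rid in known
    }
    return GoldStandard(clusters=clusters)


def build_gold_specimen(
    clinic_tests: pd.DataFrame,
    lab_tests: pd.DataFrame,
    date_tolerance_days: int = 7,
) -> GoldStandard:
    """Gold standard from clinic-to-laboratory specimen flows.

    Both inputs need columns ``record_id``, ``specimen_id``, ``birth_year``
    and ``test_date``. A clinic record and a laboratory record are
    gold-matched iff they share the specimen ID and year of birth and their
    test dates differ by at most *date_tolerance_days* (inclusive). Matches
    are merged transitively; only matched records enter the gold standard,
    since unmatched ones cannot be verified.
    """

    def norm(df: pd.DataFrame) -> pd.DataFrame:
        df = df.loc[df["specimen_id"].notna() & (df["specimen_id"] != "")].copy()
        df["test_date"] = pd.to_datetime(df["test_date"]).dt.date
        return df

    clinic = norm(clinic_tests)
    lab = norm(lab_tests)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    lab_by_spec: dict[tuple[str, int], list[tuple[str, dt.date]]] = defaultdict(list)
    for row in lab.itertuples(index=False):
        lab_by_spec[(str(row.specimen_id), int(row.birth_year))].append(
            (str(row.record_id), row.test_date)
        )
    for row in clinic.itertuples(index=False):
        key = (str(row.specimen_id), int(row.birth_year))
        for lab_rid, lab_date in lab_by_spec.get(key, ()):
            if abs((row.test_date - lab_date).days) <= date_tolerance_days:
                union(str(row.record_id), lab_rid)
    clusters = {rid: f"G:{find(rid)}" for rid in parent}
    return GoldStandard(clusters=clusters)


def score_linkage(
    result: LinkageResult,
    gold: GoldStandard,
    require_all_comembers: bool = False,
) -> EvalReport:
    """Score a linkage result against a gold standard, record by record.

    A gold-linked record is correctly linked when the tool clusters it with
    at least one of its true co-members (or, with
    ``require_all_comembers=True``, with all of them). A gold-unlinked
    record is correctly unlinked when the tool links it to no other record.
    PPV and NPV condition on the tool's output instead: among tool-linked
    (tool-unlinked) records, the fraction whose gold status agrees.

    The record sets of *result* and *gold* must coincide.
    """
    if set(result.clusters) != set(gold.clusters):
        raise ValueError(
            f"record sets differ: result has {len(result.clusters)}, gold has "
            f"{len(gold.clusters)} records, {len(set(result.clusters) ^ set(gold.clusters))} not shared"
        )
    tool_members: dict[str, set[str]] = defaultdict(set)
    for rid, lid in result.clusters.items():
        tool_members[lid].add(rid)
    gold_members = gold.members()

    gold_linked = gold.linked_ids
    gold_unlinked = gold.unlinked_ids
    tool_linked = {rid for rid in result.clusters if len(tool_members[result.clusters[rid]]) >= 2}

    def linked_correctly(rid: str) -> bool:
        mates = tool_members[result.clusters[rid]] - {rid}
        true_mates = gold_members[gold.clusters[rid]] - {rid}
        if require_all_comembers:
            return true_mates <= mates
        return bool(mates & true_mates)

    n_correct_linked = sum(1 for rid in gold_linked if linked_correctly(rid))
    n_correct_unlinked = sum(1 for rid in gold_unlinked if rid not in tool_linked)
    n_tool_linked_correct = sum(
        1 for rid in tool_linked if rid in gold_linked and linked_correctly(rid)
    )
    tool_unlinked = set(result.clusters) - tool_linked
    n_tool_unlinked_correct = sum(1 for rid in tool_unlinked if rid in gold_unlinked)
    return EvalReport.from_counts(
        approach=result.approach,
        n_gold_linked=len(gold_linked),
        n_correctly_linked=n_correct_linked,
        n_gold_unlinked=len(gold_unlinked),
        n_correctly_unlinked=n_correct_unlinked,
        n_tool_linked=len(tool_linked),
        n_tool_linked_correct=n_tool_linked_correct,
        n_tool_unlinked=len(tool_unlinked),
        n_tool_unlinked_correct=n_tool_unlinked_correct,
    )


def _analyte_sets(analyte_class: str) -> tuple[set[str], set[str]]:
    """(index analytes whose positive starts the clock, antibody analytes)."""
    if analyte_class == "HIV":
        return {"HIV_WB"}, {"HIV_AB"}
    if analyte_class == "HCV":
        return {"HCV_AB"}, {"HCV_AB"}
    raise ValueError(f"unknown analyte class {analyte_class!r}; expected HIV or HCV")


def _own_history_discordant(
    tests: Sequence[TestRecord], antibodies: set[str], window_days: int
) -> bool:
    pos_dates = [t.test_date for t in tests if t.result == "positive"]
    neg_ab = [t.test_date for t in tests if t.analyte in antibodies and t.result == "negative"]
    return any(
        (nd - pd_).days >= window_days for pd_ in pos_dates for nd in neg_ab
    )


def serology_audit(
    records: Sequence[DeidRecord],
    result: LinkageResult,
    analyte_class: str,
    window_days: int = 7,
) -> SerologyAuditReport:
    """Audit linked clusters for biologically impossible serology.

    Procedure:

    1. records whose *own* test history is discordant (a negative antibody
       at least *window_days* after a positive, within the one record) are
       excluded up front — their discordance predates linkage;
    2. only linked clusters containing an antibody result dated after an
       initial positive (HIV: first positive western blot; HCV: first
       positive antibody) are retained — discordance is only observable
       after a positive;
    3. a retained cluster is discordant if any negative antibody result in
       it occurs at least *window_days* after any positive result;
    4. within a discordant cluster the records carrying the offending
       negative antibody results are counted incorrectly matched — unless a
       strict majority of the antibody results after the initial positive
       are negative, in which case the positive-result records are the
       incorrect ones (the lone positive among negatives is then the
       intruder).

    PPV is the percentage of retained records not counted incorrect.
    """
    index_analytes, antibodies = _analyte_sets(analyte_class)
    relevant = index_analytes | antibodies

    by_id = {r.record_id: r for r in records}
    tests_by_record: dict[str, list[TestRecord]] = {}
    for r in records:
        own = [t for t in r.tests if t.analyte in relevant]
        if own:
            tests_by_record[r.record_id] = sorted(own, key=lambda t: t.test_date)

    # step 1: drop records already discordant on their own
    eligible = {
        rid
        for rid, ts in tests_by_record.items()
        if not _own_history_discordant(ts, antibodies, window_days)
    }

    clusters: dict[str, list[str]] = defaultdict(list)
    for rid, lid in result.clusters.items():
        if rid in by_id:
            clusters[lid].append(rid)

    n_retained = 0
    n_incorrect = 0
    n_discordant_clusters = 0
    incorrect_ids: list[str] = []

    for lid, members in clusters.items():
        members = [m for m in members if m in eligible]
        if len(members) < 2:
            continue  # not linked (or nothing auditable survives step 1)
        cluster_tests = [
            (rid, t) for rid in members for t in tests_by_record.get(rid, ())
        ]
        if not cluster_tests:
            continue
        # step 2: initial positive on the index analyte, then any later antibody
        pos_index = [
            t.test_date for _, t in cluster_tests if t.analyte in index_analytes and t.result == "positive"
        ]
        if not pos_index:
            continue
        initial_pos = min(pos_index)
        later_ab = [
            (rid, t)
            for rid, t in cluster_tests
            if t.analyte in antibodies and t.test_date > initial_pos
        ]
        if not later_ab:
            continue
        n_retained += len(members)

        # step 3: discordance classification with the 7-day window
        pos_dates = [t.test_date for _, t in cluster_tests if t.result == "positive"]
        offending = {
            rid
            for rid, t in cluster_tests
            if t.analyte in antibodies
            and t.result == "negative"
            and any((t.test_date - pd_).days >= window_days for pd_ in pos_dates)
        }
        if not offending:
            continue
        n_discordant_clusters += 1

        # step 4: majority rule
        n_later_neg = sum(1 for _, t in later_ab if t.result == "negative")
        if 2 * n_later_neg > len(later_ab):
            bad = {
                rid
                for rid, t in cluster_tests
                if t.result == "positive"
            }
        else:
            bad = offending
        n_incorrect += len(bad)
        incorrect_ids.extend(sorted(bad))

    return SerologyAuditReport(
        approach=result.approach,
        analyte_class=analyte_class,
        n_retained=n_retained,
        n_concordant=n_retained - n_incorrect,
        n_discordant_clusters=n_discordant_clusters,
        ppv_pct=percentage(n_retained - n_incorrect, n_retained),
        incorrect_record_ids=tuple(incorrect_ids),
    )


def estimate_specificity(ppv: float, sensitivity: float, prevalence: float) -> float:
    """Specificity implied by PPV and sensitivity at a given prevalence.

    Inverts PPV = Se·pi / (Se·pi + (1 - Sp)(1 - pi)) to

        Sp = 1 - Se·pi·(1 - PPV) / (PPV·(1 - pi))

    where pi is the prevalence of truly-linked records. All arguments are
    proportions; PPV and sensitivity must lie in (0, 1], prevalence in
    (0, 1). The result is clamped to [0, 1].
    """
    for name, v in (("ppv", ppv), ("sensitivity", sensitivity)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    sp = 1.0 - sensitivity * prevalence * (1.0 - ppv) / (ppv * (1.0 - prevalence))
    return min(1.0, max(0.0, sp))
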