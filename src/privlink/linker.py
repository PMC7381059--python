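"""Three-step linkage of deidentified records.

Records carry only hashed linkage keys plus a few retained demographics
(sex, year of birth), so linkage proceeds by exact key equality:

1. **find pairs** — every pair of records sharing at least one linkage key
   (of the same type) becomes a candidate pair, annotated with the set of
   key types that matched. An inverted index per key type makes this
   near-linear in the number of records; the output is identical to
   comparing all pairs.
2. **accept pairs** — one of six acceptance approaches filters the
   candidate pairs using the retained demographics (e.g. require matching
   year of birth, or two or more matching key types).
3. **assign link IDs** — accepted pairs are merged transitively; every
   connected component receives one link ID (the smallest record ID in the
   component), labelling all its records as one individual.

Under the filtering approaches a pair with missing sex or year of birth is
rejected by default (strict policy, favouring specificity); set
``strict_missing=False`` to let missing values pass.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .keys import KEY_TYPES, LinkageKeySet

__all__ = [
    "DeidRecord",
    "CandidatePair",
    "LinkageResult",
    "APPROACHES",
    "find_candidate_pairs",
    "accept_pairs",
    "assign_link_ids",
    "run_linkage",
]


@dataclass(frozen=True)
class DeidRecord:
    """The privacy-preserving unit of linkage: hashed keys plus the
    demographics retained for match acceptance."""

    record_id: str
    site_id: str
    site_type: str  # "clinic" or "laboratory"
    keyset: LinkageKeySet
    sex: str | None = None
    birth_year: int | None = None
    tests: tuple = ()


@dataclass(frozen=True)
class CandidatePair:
    """A pair of records sharing at least one linkage key."""

    record_id_a: str
    record_id_b: str
    matched_types: frozenset[int]

    def __post_init__(self) -> None:
        if self.record_id_a >= self.record_id_b:
            raise ValueError("pair must be ordered: record_id_a < record_id_b")
        if not self.matched_types:
            raise ValueError("matched_types must be non-empty")


@dataclass(frozen=True)
class LinkageResult:
    """Accepted pairs and the transitive link-ID clustering they induce."""

    accepted_pairs: tuple[CandidatePair, ...]
    clusters: Mapping[str, str]  # record_id -> link_id
    approach: str

    def cluster_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = defaultdict(list)
        for rid, lid in self.clusters.items():
            members[lid].append(rid)
        return {lid: sorted(ms) for lid, ms in members.items()}

    def linked_ids(self) -> set[str]:
        """Records placed in a cluster with at least one other record."""
        sizes: dict[str, int] = defaultdict(int)
        for lid in self.clusters.values():
            sizes[lid] += 1
        return {rid for rid, lid in self.clusters.items() if sizes[lid] >= 2}


def find_candidate_pairs(records: Sequence[DeidRecord]) -> list[CandidatePair]:
    """All record pairs agreeing on at least one linkage key type.

    Missing keys never match. Duplicate record IDs are a hard error.
    Output is sorted by (record_id_a, record_id_b) for determinism.
    """
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record_id: {r.record_id!r}")
        seen.add(r.record_id)

    matched: dict[tuple[str, str], set[int]] = defaultdict(set)
    for t in KEY_TYPES:
        buckets: dict[str, list[str]] = defaultdict(list)
        for r in records:
            k = r.keyset.key(t)
            if k is not None:
                buckets[k].append(r.record_id)
        for ids in buckets.values():
            if len(ids) < 2:
                continue
            ids = sorted(ids)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    matched[(a, b)].add(t)
    return [
        CandidatePair(a, b, frozenset(types))
        for (a, b), types in sorted(matched.items())
    ]


def _demog_equal(
    a: DeidRecord, b: DeidRecord, attr: str, strict_missing: bool
) -> bool:
    va, vb = getattr(a, attr), getattr(b, attr)
    if va is None or vb is None:
        return not strict_missing
    return va == vb


def _make_approaches() -> dict[str, Callable[[CandidatePair, DeidRecord, DeidRecord, bool], bool]]:
    def accept_all(p, a, b, strict):
        return True

    def yob_match(p, a, b, strict):
        return _demog_equal(a, b, "birth_year", strict)

    def sex_match(p, a, b, strict):
        return _demog_equal(a, b, "sex", strict)

    def yob_sex_match(p, a, b, strict):
        return yob_match(p, a, b, strict) and sex_match(p, a, b, strict)

    def two_or_more_keys(p, a, b, strict):
        return len(p.matched_types) >= 2

    def key3_plus_sex(p, a, b, strict):
        return 3 in p.matched_types and sex_match(p, a, b, strict)

    return {
        "accept_all": accept_all,
        "yob_match": yob_match,
        "sex_match": sex_match,
        "yob_sex_match": yob_sex_match,
        "two_or_more_keys": two_or_more_keys,
        "key3_plus_sex": key3_plus_sex,
    }


#: The six match-acceptance approaches, in reporting order.
APPROACHES = _make_approaches()


def accept_pairs(
    pairs: Iterable[CandidatePair],
    records: Sequence[DeidRecord] | Mapping[str, DeidRecord],
    approach: str,
    strict_missing: bool = True,
) -> list[CandidatePair]:
    """Filter candidate pairs under one of the six acceptance approaches."""
    if approach not in APPROACHES:
        raise ValueError(
            f"unknown approach {approach!r}; expected one of {sorted(APPROACHES)}"
        )
    by_id = (
        records
        if isinstance(records, Mapping)
        else {r.record_id: r for r in records}
    )
    pred = APPROACHES[approach]
    out = []
    for p in pairs:
        a, b = by_id[p.record_id_a], by_id[p.record_id_b]
        if pred(p, a, b, strict_missing):
            out.append(p)
    return out


def assign_link_ids(
    records: Sequence[DeidRecord] | Iterable[str],
    accepted_pairs: Iterable[CandidatePair],
    approach: str = "",
) -> LinkageResult:
    """Transitive closure of accepted pairs into link-ID clusters.

    Every record appears in the result; records in no accepted pair form
    singleton clusters. The link ID of a cluster is its smallest record ID,
    which makes labels independent of input order.
    """
    ids = [r.record_id if isinstance(r, DeidRecord) else r for r in records]
    accepted = tuple(accepted_pairs)
    known = set(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for p in accepted:
        if p.record_id_a not in known or p.record_id_b not in known:
            raise ValueError(f"pair references unknown record: {p}")
        g.add_edge(p.record_id_a, p.record_id_b)
    clusters: dict[str, str] = {}
    for comp in nx.connected_components(g):
        link_id = min(comp)
        for rid in comp:
            clusters[rid] = link_id
    return LinkageResult(accepted_pairs=accepted, clusters=clusters, approach=approach)


def run_linkage(
    records: Sequence[DeidRecord],
    approach: str = "accept_all",
    strict_missing: bool = True,
) -> LinkageResult:
    """Find, accept and transitively merge pairs in one call."""
    pairs = find_candidate_pairs(records)
    accepted = accept_pairs(pairs, records, approach, strict_missing=strict_missing)
    return assign_link_ids(records, accepted, approach=approach)
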