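"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
import pytest

from privlink import DeidRecord, KeyGenConfig, LinkageKeySet, PrepConfig
from privlink.keys import KEY_TYPES


@pytest.fixture(scope="session")
def key_config() -> KeyGenConfig:
    return KeyGenConfig(secret_seed=b"unit-test-secret-seed")

@pytest.fixture(scope="session")
def prep_config() -> PrepConfig:
    return PrepConfig.default()


def make_record(record_id, site_id="s1", site_type="clinic", keys=None, sex=None,
                birth_year=None, tests=()):
    """Terse DeidRecord builder: keys={1: "h1", 3: "h3"}."""
    keys = keys or {}
    return DeidRecord(
        record_id=record_id,
        site_id=site_id,
        site_type=site_type,
        keyset=LinkageKeySet(record_id=record_id, **{f"key{t}": keys.get(t) for t in KEY_TYPES}),
        sex=sex,
        birth_year=birth_year,
        tests=tuple(tests),
    )


def brute_force_pairs(records):
    """All-pairs oracle for candidate-pair generation."""
    out = []
    for a, b in itertools.combinations(sorted(records, key=lambda r: r.record_id), 2):
        types = frozenset(
            t
            for t in KEY_TYPES
            if a.keyset.key(t) is not None and a.keyset.key(t) == b.keyset.key(t)
        )
        if types:
            out.append((a.record_id, b.record_id, types))
    return out


def brute_force_score(tool_clusters, gold_clusters):
    """Explicit-enumeration scorer: returns the eight raw counts.

    Works directly over co-membership sets, independent of the scoring
    implementation's cluster bookkeeping.
    """
    def comember_sets(clusters):
        groups = defaultdict(set)
        for rid, cid in clusters.items():
            groups[cid].add(rid)
        return {rid: groups[cid] - {rid} for rid, cid in clusters.items()}

    tool = comember_sets(tool_clusters)
    gold = comember_sets(gold_clusters)
    ids = set(gold_clusters)
    gold_linked = {r for r in ids if gold[r]}
    gold_unlinked = ids - gold_linked
    tool_linked = {r for r in ids if tool[r]}
    correct_linked = {r for r in gold_linked if tool[r] & gold[r]}
    return {
        "n_gold_linked": len(gold_linked),
        "n_correctly_linked": len(correct_linked),
        "n_gold_unlinked": len(gold_unlinked),
        "n_correctly_unlinked": len(gold_unlinked - tool_linked),
        "n_tool_linked": len(tool_linked),
        "n_tool_linked_correct": len(tool_linked & correct_linked),
        "n_tool_unlinked": len(ids - tool_linked),
        "n_tool_unlinked_correct": len((ids - tool_linked) & gold_unlinked),
    }


def random_keyed_records(rng: np.random.Generator, n: int, n_key_values: int = 12,
                         missing_rate: float = 0.35):
    """Random records over a small key-value pool, to force collisions."""
    records = []
    for i in range(n):
        keys = {}
        for t in KEY_TYPES:
            if rng.random() >= missing_rate:
                keys[t] = f"t{t}v{int(rng.integers(0, n_key_values))}"
        records.append(
            make_record(
                f"r{i:04d}",
                keys=keys,
                sex=("M", "F", None)[int(rng.integers(0, 3))],
                birth_year=int(rng.integers(1960, 1965)) if rng.random() < 0.9 else None,
            )
        )
    return records
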