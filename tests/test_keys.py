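"""Linkage-key hashing: determinism, missingness, invariances, privacy."""

from __future__ import annotations

import numpy as np
import pytest

from privlink import (
    KeyGenConfig,
    LinkageKeySet,
    PreparedIdentity,
    RawIdentity,
    generate_keyset,
    key_availability_summary,
    make_key,
    prepare_identity,
)
from privlink.identity import _load_lines
from privlink.phonetics import double_metaphone


def prep(first="WILLIAM", last="OBRIEN", day=3, month=5, year=1985, sex="M",
         postcode="3000", medicare="2123456701", prep_config=None, **over):
    from privlink.identity import PrepConfig

    raw = RawIdentity(
        first_name=over.get("first_name", first),
        last_name=over.get("last_name", last),
        birth_day=day, birth_month=month, birth_year=year,
        sex=sex, postcode=postcode, medicare_number=medicare,
    )
    return prepare_identity(raw, prep_config or PrepConfig.default())


class TestMakeKey:
    def test_deterministic(self, key_config):
        assert make_key(["A", "B"], key_config) == make_key(["A", "B"], key_config)

    def test_seed_dependence(self, key_config):
        other = KeyGenConfig(secret_seed=b"another-seed")
        assert make_key(["A", "B"], key_config) != make_key(["A", "B"], other)

    def test_separator_prevents_concatenation_ambiguity(self, key_config):
        assert make_key(["AB", "C"], key_config) != make_key(["A", "BC"], key_config)

    def test_missing_component_never_hashed(self, key_config):
        with pytest.raises(ValueError):
            make_key(["A", ""], key_config)
        with pytest.raises(ValueError):
            make_key(["A", None], key_config)

    def test_digest_length(self):
        cfg = KeyGenConfig(secret_seed=b"s", digest_len=16)
        k = make_key(["A"], cfg)
        assert len(k) == 16 and all(c in "0123456789abcdef" for c in k)


class TestGenerateKeyset:
    def test_complete_identity_yields_four_keys(self, key_config):
        ks = generate_keyset(prep(), key_config, "r1")
        assert ks.present_types == (1, 2, 3, 4)

    def test_no_medicare_yields_only_key3(self, key_config):
        ks = generate_keyset(prep(medicare=""), key_config, "r1")
        assert ks.present_types == (3,)

    def test_keyset_at_most_key3_without_medicare(self, key_config):
        # even with other fields also missing, never more than key3
        ks = generate_keyset(prep(medicare="", postcode=""), key_config, "r1")
        assert set(ks.present_types) <= {3}

    def test_name_order_swap_preserves_keys_3_and_4(self, key_config):
        a = generate_keyset(prep(first="JOHN", last="SMITH"), key_config, "a")
        b = generate_keyset(prep(first="SMITH", last="JOHN"), key_config, "b")
        assert a.key3 == b.key3 and a.key4 == b.key4

    def test_year_only_dob_drops_keys_1_and_3(self, key_config):
        p = prep(day=None, month=None)
        ks = generate_keyset(p, key_config, "r1")
        assert ks.key1 is None and ks.key3 is None
        assert ks.key2 is not None and ks.key4 is not None  # year of birth suffices for key2

    def test_key3_invariances(self, key_config):
        base = generate_keyset(prep(first="WILLIAM", last="SMITH", day=3, month=5),
                               key_config, "x")
        nickname = generate_keyset(prep(first="Bill", last="SMITH", day=3, month=5),
                                   key_config, "x")
        transposed = generate_keyset(prep(first="WILLIAM", last="SMITH", day=5, month=3),
                                     key_config, "x")
        misspelled = generate_keyset(prep(first="WILLIAM", last="SMYTH", day=3, month=5),
                                     key_config, "x")
        assert base.key3 == nickname.key3 == transposed.key3 == misspelled.key3

    def test_different_identities_different_keys(self, key_config):
        a = generate_keyset(prep(), key_config, "a")
        b = generate_keyset(prep(first="ROBERT"), key_config, "b")
        assert a.key2 != b.key2 and a.key3 != b.key3 and a.key4 != b.key4
        assert a.key1 == b.key1  # same Medicare + DOB + sex: first name not in key 1


def test_no_identifier_substrings_in_keys(key_config):
    """Privacy proxy: emitted key strings never contain the raw components."""
    p = prep()
    ks = generate_keyset(p, key_config, "r1")
    for key in filter(None, [ks.key1, ks.key2, ks.key3, ks.key4]):
        up = key.upper()
        assert "WILLIAM" not in up and "OBRIEN" not in up
        assert p.medicare5 not in key
        assert "1985-05-03" not in key and "19850503" not in key


def test_collision_sanity_100k_distinct_identities(key_config):
    """No full-keyset collision across 10^5 distinct identities.

    Identities are built directly as prepared components (names from the
    bundled pools, distinct Medicare prefixes), isolating the hashing
    layer from the preparation layer.
    """
    rng = np.random.default_rng(1234)
    firsts = _load_lines("first_names.txt")
    lasts = _load_lines("last_names.txt")
    codes_f = {n: double_metaphone(n)[0] for n in firsts}
    codes_l = {n: double_metaphone(n)[0] for n in lasts}
    seen = set()
    n = 100_000
    fi = rng.integers(0, len(firsts), size=n)
    li = rng.integers(0, len(lasts), size=n)
    years = rng.integers(1940, 2010, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    sexes = rng.integers(0, 2, size=n)
    for i in range(n):
        first, last = firsts[fi[i]], lasts[li[i]]
        y, m, d = int(years[i]), int(months[i]), int(days[i])
        p = PreparedIdentity(
            first_canon=first,
            last_canon=last,
            first_phonetic=codes_f[first],
            last_phonetic=codes_l[last],
            dob_iso=(y, m, d),
            dob_t3=(y, max(m, d), min(m, d)) if d <= 12 and m <= 12 else (y, m, d),
            sex_norm="M" if sexes[i] else "F",
            postcode_norm="3000",
            medicare5=f"{i % 100_000:05d}",
        )
        ks = generate_keyset(p, key_config, f"r{i}")
        sig = (ks.key1, ks.key2, ks.key3, ks.key4)
        assert sig not in seen, f"full-keyset collision at identity {i}"
        seen.add(sig)


class TestKeyAvailabilitySummary:
    def toy_keyset(self, rid, present):
        return LinkageKeySet(
            record_id=rid, **{f"key{t}": (f"h{t}" if t in present else None) for t in (1, 2, 3, 4)}
        )

    def test_all_keys_present(self):
        table = key_availability_summary(
            {"site": [self.toy_keyset(f"r{i}", {1, 2, 3, 4}) for i in range(10)]}
        )
        site_row = table[table["site"] == "site"].iloc[0]
        for t in (1, 2, 3, 4):
            assert site_row[f"key{t}_n"] == 10 and site_row[f"key{t}_pct"] == 100.0
        assert site_row["no_keys_n"] == 0

    def test_printed_ratio_roundtrip(self):
        # 215 of 8124 records with key type 1 -> 2.65%
        keysets = [self.toy_keyset(f"r{i}", {1, 3} if i < 215 else {3}) for i in range(8124)]
        table = key_availability_summary({"lab": keysets})
        row = table[table["site"] == "lab"].iloc[0]
        assert row["key1_pct"] == 2.65
        assert row["key3_pct"] == 100.0

    def test_empty_input(self):
        assert key_availability_summary({}).empty

    def test_no_keys_counted(self):
        table = key_availability_summary(
            {"s": [self.toy_keyset("a", set()), self.toy_keyset("b", {3})]}
        )
        row = table.iloc[0]
        assert row["no_keys_n"] == 1 and row["no_keys_pct"] == 50.0
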