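"""Irreversible hashed linkage keys.

Each medical record yields up to four linkage keys, each a keyed
cryptographic hash (HMAC-SHA256 under a secret seed) of a fixed combination
of canonical identifier components:

* type 1 — 5 Medicare digits; full date of birth; sex
* type 2 — 5 Medicare digits; postcode; first three characters of the
  (cleaned, nickname-resolved) first name; year of birth
* type 3 — phonetic codes of first and last name as an unordered pair;
  transposition-canonical date of birth
* type 4 — phonetic codes of first and last name as an unordered pair;
  5 Medicare digits

A key is generated only when *every* component it needs is present; a hash
of partial input is never emitted. Only type 3 survives a missing Medicare
number. Because hashing is keyed by a secret seed, records hashed at
different sites link only when the sites share the seed, and the keys are
irreversible without it.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .identity import PreparedIdentity
from .util import percentage

__all__ = [
    "KeyGenConfig",
    "LinkageKeySet",
    "KEY_TYPES",
    "make_key",
    "generate_keyset",
    "key_availability_summary",
]

KEY_TYPES = (1, 2, 3, 4)

# Unit separator: cannot occur in canonical components (uppercase letters,
# digits, '-'), so joined component lists are unambiguous.
_SEP = b"\x1f"


@dataclass(frozen=True)
class KeyGenConfig:
    """Secret seed and digest parameters for key hashing.

    The seed is never emitted in any output; repr masks it.
    """

    secret_seed: bytes
    digest_len: int = 64
    medicare_digit_offset: int = 0

    def __post_init__(self) -> None:
        if not self.secret_seed:
            raise ValueError("secret_seed must be non-empty")
        if not 1 <= self.digest_len <= 64:
            raise ValueError("digest_len must be in 1..64 (hex characters of SHA-256)")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"KeyGenConfig(secret_seed=<{len(self.secret_seed)} bytes>, "
            f"digest_len={self.digest_len}, medicare_digit_offset={self.medicare_digit_offset})"
        )


@dataclass(frozen=True)
class LinkageKeySet:
    """The up-to-four hashed linkage keys of one record."""

    record_id: str
    key1: str | None = None
    key2: str | None = None
    key3: str | None = None
    key4: str | None = None

    def key(self, key_type: int) -> str | None:
        return getattr(self, f"key{key_type}")

    @property
    def present_types(self) -> tuple[int, ...]:
        return tuple(t for t in KEY_TYPES if self.key(t) is not None)


def make_key(components: Sequence[str], config: KeyGenConfig) -> str:
    """Keyed hash of an ordered component list.

    Components are joined with a separator byte that cannot occur in them,
    so ("A", "B") and ("AB", "") can never collide. Raises ``ValueError``
    if any component is missing or empty — callers must withhold the key
    instead of hashing partial input.
    """
    if not components:
        raise ValueError("empty component list")
    encoded = []
    for comp in components:
        if comp is None or comp == "":
            raise ValueError("missing component: no key may be generated")
        data = str(comp).encode("utf-8")
        if _SEP in data:
            raise ValueError("component contains the reserved separator byte")
        encoded.append(data)
    digest = hmac.new(config.secret_seed, _SEP.join(encoded), hashlib.sha256).hexdigest()
    return digest[: config.digest_len]


def _fmt_date(ymd: tuple[int, int, int]) -> str:
    y, m, d = ymd
    return f"{y:04d}-{m:02d}-{d:02d}"


def generate_keyset(
    p: PreparedIdentity, config: KeyGenConfig, record_id: str
) -> LinkageKeySet:
    """Generate all linkage keys a prepared identity supports.

    The phonetic name pair is sorted before hashing, which makes first/last
    name order irrelevant for key types 3 and 4; the transposition-canonical
    date makes day/month swaps irrelevant for type 3.
    """

    def try_key(components: Sequence[str | None]) -> str | None:
        if any(c is None or c == "" for c in components):
            return None
        return make_key([str(c) for c in components], config)

    full_dob = _fmt_date(p.dob_iso) if p.dob_iso is not None and len(p.dob_iso) == 3 else None
    birth_year = f"{p.dob_iso[0]:04d}" if p.dob_iso is not None else None
    first3 = p.first_canon[:3] if p.first_canon else None
    if p.first_phonetic is not None and p.last_phonetic is not None:
        pho_a, pho_b = sorted((p.first_phonetic, p.last_phonetic))
    else:
        pho_a = pho_b = None
    dob_t3 = _fmt_date(p.dob_t3) if p.dob_t3 is not None else None

    return LinkageKeySet(
        record_id=record_id,
        key1=try_key(["K1", p.medicare5, full_dob, p.sex_norm]),
        key2=try_key(["K2", p.medicare5, p.postcode_norm, first3, birth_year]),
        key3=try_key(["K3", pho_a, pho_b, dob_t3]),
        key4=try_key(["K4", pho_a, pho_b, p.medicare5]),
    )


def key_availability_summary(
    keysets_by_site: Mapping[str, Iterable[LinkageKeySet]],
) -> pd.DataFrame:
    """Per-site counts and percentages of records carrying each key type.

    Returns one row per site plus a ``Total`` row, with columns
    ``n_records``, ``no_keys_n``/``no_keys_pct`` and, for each key type t,
    ``key{t}_n``/``key{t}_pct``. Percentages are reported to 2 decimals
    (half-up). Empty input yields an empty table.
    """
    rows = []
    totals = {"n_records": 0, "no_keys_n": 0, **{f"key{t}_n": 0 for t in KEY_TYPES}}
    for site, keysets in keysets_by_site.items():
        counts = {"n_records": 0, "no_keys_n": 0, **{f"key{t}_n": 0 for t in KEY_TYPES}}
        for ks in keysets:
            counts["n_records"] += 1
            present = ks.present_types
            if not present:
                counts["no_keys_n"] += 1
            for t in present:
                counts[f"key{t}_n"] += 1
        row = {"site": site, **counts}
        for name in ("no_keys", *[f"key{t}" for t in KEY_TYPES]):
            row[f"{name}_pct"] = percentage(counts[f"{name}_n"], counts["n_records"])
        rows.append(row)
        for k in totals:
            totals[k] += counts[k]
    if not rows:
        return pd.DataFrame(
            columns=["site", "n_records", "no_keys_n", "no_keys_pct"]
            + [c for t in KEY_TYPES for c in (f"key{t}_n", f"key{t}_pct")]
        )
    total_row = {"site": "Total", **totals}
    for name in ("no_keys", *[f"key{t}" for t in KEY_TYPES]):
        total_row[f"{name}_pct"] = percentage(totals[f"{name}_n"], totals["n_records"])
    rows.append(total_row)
    cols = ["site", "n_records", "no_keys_n", "no_keys_pct"] + [
        c for t in KEY_TYPES for c in (f"key{t}_n", f"key{t}_pct")
    ]
    return pd.DataFrame(rows, columns=cols)
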