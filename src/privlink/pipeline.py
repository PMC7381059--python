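"""Table-level glue between the modules.

The library modules operate on domain objects; real runs move CSV tables.
These helpers convert between the two: identified table -> deidentified
key table (the only step that ever sees identifiers), and deidentified
table (+ optional tests table) -> linkage records.
"""

from __future__ import annotations

from collections import defaultdict
import datetime as dt

import pandas as pd

from .evaluation import TestRecord
from .identity import PrepConfig, RawIdentity, prepare_identity
from .keys import KeyGenConfig, LinkageKeySet, generate_keyset
from .linker import DeidRecord

__all__ = [
    "row_to_raw_identity",
    "make_deid_table",
    "tests_by_record",
    "deid_table_to_records",
]


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    if not s:
        return None
    return int(float(s)) if "." in s else int(s)


def row_to_raw_identity(row) -> RawIdentity:
    """Build a RawIdentity from one identified-table row ('' = missing)."""
    get = row.get if hasattr(row, "get") else lambda k, d="": getattr(row, k, d)
    return RawIdentity(
        first_name=str(get("first_name", "") or ""),
        last_name=str(get("last_name", "") or ""),
        birth_day=_opt_int(get("birth_day", "")),
        birth_month=_opt_int(get("birth_month", "")),
        birth_year=_opt_int(get("birth_year", "")),
        sex=str(get("sex", "") or ""),
        postcode=str(get("postcode", "") or ""),
        medicare_number=str(get("medicare_number", "") or ""),
    )


def make_deid_table(
    identified: pd.DataFrame,
    key_config: KeyGenConfig,
    prep_config: PrepConfig | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Deidentify an identified-records table.

    Produces one row per record with the hashed keys and the retained
    demographics (normalized sex, birth year) — nothing else survives.
    """
    prep_config = prep_config if prep_config is not None else PrepConfig.default(
        medicare_digit_offset=key_config.medicare_digit_offset
    )
    rows = []
    for rec in identified.to_dict("records"):
        rid = str(rec["record_id"])
        row_log: list[str] = []
        prepared = prepare_identity(row_to_raw_identity(rec), prep_config, log=row_log)
        if log is not None:
            log.extend(f"record {rid}: {msg}" for msg in row_log)
        ks = generate_keyset(prepared, key_config, rid)
        rows.append(
            {
                "record_id": rid,
                "site_id": str(rec.get("site_id", "")),
                "site_type": str(rec.get("site_type", "")),
                "key1": ks.key1 or "",
                "key2": ks.key2 or "",
                "key3": ks.key3 or "",
                "key4": ks.key4 or "",
                "sex": prepared.sex_norm or "",
                "birth_year": str(prepared.dob_iso[0]) if prepared.dob_iso else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["record_id", "site_id", "site_type", "key1", "key2", "key3", "key4",
                 "sex", "birth_year"],
    )


def tests_by_record(tests: pd.DataFrame) -> dict[str, tuple[TestRecord, ...]]:
    """Group a tests table into TestRecord tuples per record."""
    grouped: dict[str, list[TestRecord]] = defaultdict(list)
    for rec in tests.to_dict("records"):
        rid = str(rec["record_id"])
        spec = str(rec.get("specimen_id", "") or "")
        grouped[rid].append(
            TestRecord(
                record_id=rid,
                analyte=str(rec["analyte"]),
                result=str(rec["result"]),
                test_date=dt.date.fromisoformat(str(rec["test_date"])),
                specimen_id=spec or None,
            )
        )
    return {rid: tuple(ts) for rid, ts in grouped.items()}


def deid_table_to_records(
    deid: pd.DataFrame, tests: pd.DataFrame | None = None
) -> list[DeidRecord]:
    """Materialize linkage records from a deidentified table."""
    by_record = tests_by_record(tests) if tests is not None else {}
    records = []
    for rec in deid.to_dict("records"):
        rid = str(rec["record_id"])
        records.append(
            DeidRecord(
                record_id=rid,
                site_id=str(rec.get("site_id", "")),
                site_type=str(rec.get("site_type", "")),
                keyset=LinkageKeySet(
                    record_id=rid,
                    **{
                        f"key{t}": (str(rec[f"key{t}"]) or None)
                        if str(rec.get(f"key{t}", "")) != ""
                        else None
                        for t in (1, 2, 3, 4)
                    },
                ),
                sex=str(rec.get("sex", "")) or None,
                birth_year=_opt_int(rec.get("birth_year", "")),
                tests=by_record.get(rid, ()),
            )
        )
    return records
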