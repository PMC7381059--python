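"""CSV schemas, validation, and run manifests.

One convention everywhere: files are UTF-8 CSV, missing values are empty
fields, dates are ISO-8601. Schema validation is run at every pipeline
boundary, and deidentified stages refuse files that still carry identifier
columns — a privacy guard against accidentally feeding identified data
into a linkage step.
"""

from __future__ import annotations

import datetime as dt
import json
import platform
from pathlib import Path

import pandas as pd

__all__ = [
    "SCHEMAS",
    "IDENTIFIER_COLUMNS",
    "read_csv",
    "write_csv",
    "validate_schema",
    "write_manifest",
]

SCHEMAS: dict[str, list[str]] = {
    "identified": [
        "record_id", "site_id", "site_type", "first_name", "last_name",
        "birth_day", "birth_month", "birth_year", "sex", "postcode",
        "medicare_number",
    ],
    "deid": [
        "record_id", "site_id", "site_type", "key1", "key2", "key3", "key4",
        "sex", "birth_year",
    ],
    "links": ["record_id", "link_id", "approach"],
    "pairs": ["record_id_a", "record_id_b", "matched_types"],
    "tests": ["record_id", "analyte", "result", "test_date", "specimen_id"],
    "gold": ["record_id", "gold_id"],
    "truth": ["record_id", "person_id"],
    "registry": ["person_id", "record_id"],
}

#: Columns that must never appear in any artifact after deidentification.
IDENTIFIER_COLUMNS = frozenset(
    {"first_name", "last_name", "birth_day", "birth_month", "postcode", "medicare_number"}
)

_INT_COLUMNS = {"birth_day", "birth_month", "birth_year"}
_DATE_COLUMNS = {"test_date"}


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV with all columns as strings and '' = missing."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline CSV ('' = missing, no index)."""
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v)) else v)
    out.to_csv(path, index=False)


def validate_schema(
    source: str | Path | pd.DataFrame,
    schema: str,
    forbid_identifiers: bool = False,
) -> list[str]:
    """Check a file (or frame) against a named schema.

    Returns a list of human-readable violations (empty = ok): header
    mismatches by column name, type violations by line number, and — with
    ``forbid_identifiers`` — any identifier column leaking into a
    post-deidentification stage.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = source if isinstance(source, pd.DataFrame) else read_csv(source)
    expected = SCHEMAS[schema]
    violations: list[str] = []
    have = list(df.columns)
    for col in expected:
        if col not in have:
            violations.append(f"missing column: {col!r}")
    for col in have:
        if col not in expected:
            violations.append(f"unexpected column: {col!r}")
            if forbid_identifiers and col in IDENTIFIER_COLUMNS:
                violations.append(
                    f"identifier column {col!r} is forbidden after deidentification"
                )
    if violations and any(v.startswith("missing") for v in violations):
        return violations

    def check(col: str, ok, desc: str) -> None:
        if col not in df.columns:
            return
        for i, v in enumerate(df[col]):
            s = "" if v is None else str(v)
            if s == "":
                continue
            if not ok(s):
                violations.append(f"line {i + 2}: column {col!r}: {desc}: {s!r}")

    for col in _INT_COLUMNS & set(expected):
        check(col, lambda s: s.lstrip("-").isdigit(), "not an integer")
    for col in _DATE_COLUMNS & set(expected):
        def is_date(s: str) -> bool:
            try:
                dt.date.fromisoformat(s)
                return True
            except ValueError:
                return False
        check(col, is_date, "not an ISO-8601 date")
    if schema in ("deid",):
        check("sex", lambda s: s in ("M", "F", "X"), "not one of M/F/X")
    if schema == "tests":
        check("analyte", lambda s: s in ("HIV_WB", "HIV_AB", "HCV_AB"), "unknown analyte")
        check("result", lambda s: s in ("positive", "negative"), "unknown result")
    return violations


def write_manifest(
    path: str | Path,
    command: str,
    inputs: dict[str, str | None],
    outputs: dict[str, str | None],
    parameters: dict,
    counts: dict[str, int],
) -> None:
    """Write a reproducibility manifest for one pipeline run.

    Records inputs, outputs, parameters (never the secret seed itself),
    row counts and versions; together with the input files this suffices
    to reproduce the run bit-identically.
    """
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "python_version": platform.python_version(),
        "inputs": {k: str(v) if v is not None else None for k, v in inputs.items()},
        "outputs": {k: str(v) if v is not None else None for k, v in outputs.items()},
        "parameters": parameters,
        "counts": counts,
    }
    if any("secret" in str(k).lower() and "file" not in str(k).lower() for k in parameters):
        raise ValueError("refusing to write secret material into a manifest")
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
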