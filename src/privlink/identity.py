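"""Normalization and canonicalization of raw patient identifiers.

Hashed linkage keys can only ever be compared for exact equality, so every
tolerance the linkage offers — misspellings, nicknames, swapped name order,
transposed day/month of birth — must be realized *before* hashing, by
mapping variant identifier spellings onto one canonical form. This module
turns the as-recorded identifiers of one medical record (a
:class:`RawIdentity`) into those canonical components (a
:class:`PreparedIdentity`):

* names are cleaned (case, punctuation, titles), nickname-resolved against
  an editable nickname table, and phonetically encoded (double metaphone);
* the date of birth is validated and, for the name-based key, brought to a
  transposition-canonical form in which 03/05 and 05/03 are identical;
* sex is mapped to {M, F, X}; the Medicare number is validated and reduced
  to the five digits used as a key component.

Missing values are represented as ``None`` throughout — never as sentinel
strings — and every derived component is ``None`` whenever its inputs are.
"""

from __future__ import annotations

import calendar
import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

from .phonetics import double_metaphone

__all__ = [
    "RawIdentity",
    "PreparedIdentity",
    "PrepConfig",
    "clean_name",
    "resolve_nickname",
    "phonetic_encode",
    "canonicalize_dob",
    "normalize_sex",
    "extract_medicare5",
    "prepare_identity",
    "default_stop_words",
    "default_nickname_table",
]


@dataclass(frozen=True)
class RawIdentity:
    """As-recorded patient identifiers attached to one medical record.

    Any field may be missing: empty string for the free-text fields,
    ``None`` for the date-of-birth components.
    """

    first_name: str = ""
    last_name: str = ""
    birth_day: int | None = None
    birth_month: int | None = None
    birth_year: int | None = None
    sex: str = ""
    postcode: str = ""
    medicare_number: str = ""


@dataclass(frozen=True)
class PreparedIdentity:
    """Canonical identifier components feeding linkage-key hashing.

    ``dob_iso`` is ``(year, month, day)`` when the full date is valid,
    ``(year,)`` when only the year is usable, else ``None``. ``dob_t3`` is
    the transposition-canonical full date used by the name-based key, and
    is present only when the full date is.
    """

    first_canon: str | None = None
    last_canon: str | None = None
    first_phonetic: str | None = None
    last_phonetic: str | None = None
    dob_iso: tuple[int, ...] | None = None
    dob_t3: tuple[int, int, int] | None = None
    sex_norm: str | None = None
    postcode_norm: str | None = None
    medicare5: str | None = None

    def __post_init__(self) -> None:
        assert (self.first_phonetic is None) == (self.first_canon is None)
        assert (self.last_phonetic is None) == (self.last_canon is None)
        if self.dob_t3 is not None:
            assert self.dob_iso is not None and len(self.dob_iso) == 3


def _load_lines(name: str) -> list[str]:
    text = resources.files("privlink.data").joinpath(name).read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def default_stop_words() -> frozenset[str]:
    """Titles and honorifics stripped from name fields (editable list)."""
    return frozenset(_load_lines("stop_words.txt"))


def default_nickname_table() -> dict[str, str]:
    """Bundled nickname -> canonical given-name map (editable list)."""
    text = resources.files("privlink.data").joinpath("nicknames.csv").read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    return {row["nickname"]: row["canonical"] for row in reader}


@dataclass(frozen=True)
class PrepConfig:
    """Configuration for identifier preparation.

    stop_words and nickname_table are data, not code: site deployments can
    substitute their own lists without touching the pipeline.
    """

    stop_words: frozenset[str]
    nickname_table: Mapping[str, str]
    medicare_digit_offset: int = 0

    @classmethod
    def default(cls, medicare_digit_offset: int = 0) -> "PrepConfig":
        return cls(
            stop_words=default_stop_words(),
            nickname_table=default_nickname_table(),
            medicare_digit_offset=medicare_digit_offset,
        )


def clean_name(raw: str, stop_words: Iterable[str] = ()) -> str | None:
    """Clean a free-text name into one canonical uppercase token.

    Whitespace separates tokens; within a token, non-alphabetic characters
    (hyphens, apostrophes) join name pieces, so O'Brien-Smith becomes
    OBRIENSMITH. Stop words (titles such as DR, MRS) are removed; of the
    remaining tokens the longest is kept (ties broken by first occurrence).
    Returns ``None`` when nothing survives cleaning.
    """
    if raw is None:
        return None
    stop = {w.upper() for w in stop_words}
    tokens = []
    for ws_tok in raw.upper().split():
        tok = "".join(c for c in ws_tok if "A" <= c <= "Z")
        if tok and tok not in stop:
            tokens.append(tok)
    if not tokens:
        return None
    return max(tokens, key=len)


def resolve_nickname(token: str, nickname_table: Mapping[str, str]) -> str:
    """Map a cleaned name token to its canonical form, if it is a known
    nickname; unknown tokens and canonical forms pass through unchanged."""
    return nickname_table.get(token, token)


def phonetic_encode(token: str) -> str:
    """Primary double-metaphone code of a cleaned uppercase token."""
    primary, _ = double_metaphone(token)
    return primary


def _valid_year(year: int | None) -> bool:
    return year is not None and 1000 <= year <= 9999


def canonicalize_dob(
    day: int | None,
    month: int | None,
    year: int | None,
    log: list[str] | None = None,
) -> tuple[tuple[int, ...] | None, tuple[int, int, int] | None]:
    """Validate and canonicalize a date of birth.

    Returns ``(dob_iso, dob_t3)``. ``dob_iso`` is the full ``(y, m, d)``
    when all components form a valid calendar date, ``(y,)`` when only the
    year is usable, else ``None``. ``dob_t3`` is the transposition-
    canonical date for the name-based linkage key: when both day and month
    are <= 12 (and unequal), the smaller value is placed in the day slot, so
    3/5 and 5/3 canonicalize identically. Invalid calendar combinations
    (e.g. 31 February) are treated as a missing day and noted in *log*.
    """
    if month is not None and not 1 <= month <= 12:
        if log is not None:
            log.append(f"invalid birth month {month}: treated as missing")
        month = None
    if day is not None and not 1 <= day <= 31:
        if log is not None:
            log.append(f"invalid birth day {day}: treated as missing")
        day = None
    year_ok = _valid_year(year)
    if day is not None and month is not None and year_ok:
        if day > calendar.monthrange(year, month)[1]:
            if log is not None:
                log.append(
                    f"invalid calendar date {day:02d}/{month:02d}/{year}: day treated as missing"
                )
            day = None
    if day is not None and month is not None and year_ok:
        dob_iso: tuple[int, ...] | None = (year, month, day)
        if day <= 12 and month <= 12 and day != month:
            lo, hi = sorted((day, month))
            dob_t3: tuple[int, int, int] | None = (year, hi, lo)
        else:
            dob_t3 = (year, month, day)
        return dob_iso, dob_t3
    if year_ok:
        return (year,), None
    return None, None


_SEX_MAP = {"M": "M", "MALE": "M", "F": "F", "FEMALE": "F"}


def normalize_sex(raw: str) -> str | None:
    """Map free-text sex to M / F / X (any other non-empty value)."""
    if raw is None:
        return None
    token = raw.strip().upper()
    if not token:
        return None
    return _SEX_MAP.get(token, "X")


def extract_medicare5(raw: str, offset: int = 0) -> str | None:
    """Validate a Medicare number and return the 5 digits used for keying.

    Strips non-digits; a number with fewer than 10 digits fails validation
    and yields ``None``. The 5 digits are taken at *offset* into the card
    number (default: the first five).
    """
    if raw is None:
        return None
    digits = "".join(c for c in raw if c.isdigit())
    if len(digits) < 10:
        return None
    five = digits[offset : offset + 5]
    return five if len(five) == 5 else None


def _normalize_postcode(raw: str) -> str | None:
    if raw is None:
        return None
    digits = "".join(c for c in raw if c.isdigit())
    return digits or None


def prepare_identity(
    raw: RawIdentity,
    config: PrepConfig | None = None,
    log: list[str] | None = None,
) -> PreparedIdentity:
    """Compose cleaning, nickname resolution, phonetic encoding, date and
    Medicare validation into the canonical components used for hashing.

    Fully deterministic given the configuration.
    """
    cfg = config if config is not None else PrepConfig.default()
    first = clean_name(raw.first_name, cfg.stop_words)
    last = clean_name(raw.last_name, cfg.stop_words)
    if first is not None:
        first = resolve_nickname(first, cfg.nickname_table)
    if last is not None:
        last = resolve_nickname(last, cfg.nickname_table)
    dob_iso, dob_t3 = canonicalize_dob(raw.birth_day, raw.birth_month, raw.birth_year, log=log)
    medicare5 = extract_medicare5(raw.medicare_number, cfg.medicare_digit_offset)
    if raw.medicare_number and medicare5 is None and log is not None:
        log.append(f"medicare number failed 10-digit validation: {'*' * len(raw.medicare_number)}")
    return PreparedIdentity(
        first_canon=first,
        last_canon=last,
        first_phonetic=phonetic_encode(first) if first else None,
        last_phonetic=phonetic_encode(last) if last else None,
        dob_iso=dob_iso,
        dob_t3=dob_t3,
        sex_norm=normalize_sex(raw.sex),
        postcode_norm=_normalize_postcode(raw.postcode),
        medicare5=medicare5,
    )
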