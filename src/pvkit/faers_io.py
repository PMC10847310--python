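"""Readers for FAERS-style quarterly ASCII tables and auxiliary dictionaries.

The FDA Adverse Event Reporting System distributes quarterly snapshots as
'$'-delimited ASCII tables (DEMO, DRUG, REAC, OUTC, THER).  This module
parses those tables into typed :class:`pandas.DataFrame` collections,
handles the partial dates FAERS uses (4, 6 or 8 digits), and provides the
two auxiliary lookups every analysis needs: a preferred-term -> system organ
class vocabulary and a drug synonym dictionary mapping trade/generic names
back to canonical active ingredients.
"""

from __future__ import annotations

import datetime
import functools
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PartialDate",
    "parse_partial_date",
    "ParseLog",
    "ParsedTable",
    "SchemaError",
    "SCHEMAS",
    "parse_table",
    "write_table",
    "Vocabulary",
    "load_vocabulary",
    "DrugDictionary",
    "load_drug_dictionary",
    "match_drug",
    "normalize_name",
]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
AGE_UNITS = frozenset({"YR", "MON", "WK", "DY", "HR", "DEC"})

#: divisors converting an age in the given FAERS unit into years
AGE_TO_YEARS = {
    "YR": 1.0,
    "DEC": 0.1,          # decades: multiply by 10 == divide by 0.1
    "MON": 12.0,
    "WK": 52.18,
    "DY": 365.25,
    "HR": 365.25 * 24.0,
}


@functools.total_ordering
@dataclass(frozen=True, slots=True)
class PartialDate:
    """A possibly incomplete calendar date as found in FAERS date columns.

    FAERS stores dates as 4 (year), 6 (year+month) or 8 (full) digit
    strings.  Missing components order as smallest, giving a deterministic
    total order used by report deduplication.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= 2100:
            raise ValueError(f"year {self.year} outside 1900-2100")
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} invalid")
        if self.day is not None:
            # raises ValueError for calendar-invalid combinations
            datetime.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def __lt__(self, other: "PartialDate") -> bool:
        if not isinstance(other, PartialDate):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    @property
    def is_full(self) -> bool:
        return self.day is not None

    def to_date(self, impute_day: int | None = None) -> datetime.date | None:
        """Concrete :class:`datetime.date`, optionally imputing a missing day.

        Returns None when the month is missing (year-only precision is too
        coarse for interval arithmetic) or the day is missing and no
        imputation was requested.
        """
        if self.month is None:
            return None
        day = self.day
        if day is None:
            if impute_day is None:
                return None
            day = impute_day
        return datetime.date(self.year, self.month, day)

    def compact(self) -> str:
        """FAERS wire format: YYYY, YYYYMM or YYYYMMDD."""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.compact()


def parse_partial_date(text: object) -> PartialDate | None:
    """Parse a FAERS date field; total over all inputs (never raises).

    8 digits -> full date, 6 -> year+month, 4 -> year only; anything else,
    including calendar-invalid dates, yields None.
    """
    if text is None:
        return None
    s = str(text).strip()
    if not re.fullmatch(r"\d{4}|\d{6}|\d{8}", s):
        return None
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else None
    day = int(s[6:8]) if len(s) == 8 else None
    try:
        return PartialDate(year, month, day)
    except ValueError:
        return None


# --------------------------------------------------------------------------
# table schemas and parsing

class SchemaError(ValueError):
    """A required column is absent from a table header."""


@dataclass
class ParseLog:
    """Counts of rows kept and dropped while parsing one table."""

    n_rows: int = 0
    n_dropped: int = 0
    reasons: Counter = field(default_factory=Counter)

    def drop(self, reason: str) -> None:
        self.n_dropped += 1
        self.reasons[reason] += 1


@dataclass
class ParsedTable:
    """A parsed FAERS table plus its parse log."""

    schema: str
    records: pd.DataFrame
    log: ParseLog


@dataclass(frozen=True)
class _TableSchema:
    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...]

    @property
    def columns(self) -> tuple[str, ...]:
        return self.required + self.optional


SCHEMAS: dict[str, _TableSchema] = {
    "DEMO": _TableSchema(
        "DEMO",
        required=("primaryid", "caseid", "fda_dt"),
        optional=("event_dt", "age", "age_cod", "sex", "country"),
    ),
    "DRUG": _TableSchema(
        "DRUG",
        required=("primaryid", "drug_seq", "role_cod", "drugname"),
        optional=("prod_ai",),
    ),
    "REAC": _TableSchema("REAC", required=("primaryid", "pt"), optional=()),
    "OUTC": _TableSchema("OUTC", required=("primaryid", "outc_cod"), optional=()),
    "THER": _TableSchema(
        "THER",
        required=("primaryid", "dsg_drug_seq"),
        optional=("start_dt", "end_dt"),
    ),
}

_INT_COLUMNS = {"primaryid", "caseid", "drug_seq", "dsg_drug_seq"}
_DATE_COLUMNS = {"fda_dt", "event_dt", "start_dt", "end_dt"}


def _convert_demo(row: dict, log: ParseLog) -> dict | None:
    if row["fda_dt"] is None:
        log.drop("missing fda_dt")
        return None
    age = row.get("age")
    try:
        row["age"] = float(age) if age not in (None, "") else None
    except (TypeError, ValueError):
        row["age"] = None
    cod = (row.get("age_cod") or "").strip().upper()
    row["age_cod"] = cod if cod in AGE_UNITS else None
    sex = (row.get("sex") or "").strip().upper()
    row["sex"] = sex if sex in ("F", "M") else "unknown"
    row["country"] = (row.get("country") or "").strip() or None
    return row


def _convert_drug(row: dict, log: ParseLog) -> dict | None:
    role = (row["role_cod"] or "").strip().upper()
    if role not in ROLE_CODES:
        log.drop("invalid role_cod")
        return None
    row["role_cod"] = role
    if not (row["drugname"] or "").strip():
        log.drop("empty drugname")
        return None
    row["drugname"] = row["drugname"].strip()
    prod_ai = (row.get("prod_ai") or "").strip()
    row["prod_ai"] = prod_ai or None
    return row


def _convert_reac(row: dict, log: ParseLog) -> dict | None:
    pt = (row["pt"] or "").strip()
    if not pt:
        log.drop("empty pt")
        return None
    row["pt"] = pt
    return row


def _convert_outc(row: dict, log: ParseLog) -> dict | None:
    cod = (row["outc_cod"] or "").strip().upper()
    if cod not in OUTCOME_CODES:
        log.drop("invalid outc_cod")
        return None
    row["outc_cod"] = cod
    return row


def _convert_ther(row: dict, log: ParseLog) -> dict | None:
    start, end = row.get("start_dt"), row.get("end_dt")
    if (
        start is not None
        and end is not None
        and start.is_full
        and end.is_full
        and end < start
    ):
        log.drop("end before start")
        return None
    return row


_CONVERTERS = {
    "DEMO": _convert_demo,
    "DRUG": _convert_drug,
    "REAC": _convert_reac,
    "OUTC": _convert_outc,
    "THER": _convert_ther,
}


def parse_table(path: str | Path, schema: str, delimiter: str = "$") -> ParsedTable:
    """Parse one FAERS-style ASCII table into a typed DataFrame.

    The first line must be a delimited header containing the schema's
    required columns (case-insensitive; extra columns are ignored).  Data
    lines with the wrong field count are dropped and counted in the parse
    log, as are rows violating a schema invariant (e.g. an unknown
    ``role_cod``).  Unparseable optional fields become missing values.
    """
    spec = SCHEMAS[schema.upper()]
    path = Path(path)
    text = path.read_text()
    log = ParseLog()
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        warnings.warn(f"{path}: empty {spec.name} file", stacklevel=2)
        return ParsedTable(spec.name, _empty_frame(spec), log)

    header = [h.strip().lower() for h in lines[0].split(delimiter)]
    for col in spec.required:
        if col not in header:
            raise SchemaError(f"{path}: {spec.name} table missing required column {col!r}")
    positions = {col: header.index(col) for col in spec.columns if col in header}
    n_fields = len(header)
    convert = _CONVERTERS[spec.name]

    rows: list[dict] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split(delimiter)
        if len(parts) != n_fields:
            log.drop("wrong field count")
            continue
        row: dict = {}
        bad = False
        for col in spec.columns:
            idx = positions.get(col)
            raw = parts[idx].strip() if idx is not None else ""
            if col in _INT_COLUMNS:
                try:
                    row[col] = int(raw)
                except ValueError:
                    bad = True
                    break
            elif col in _DATE_COLUMNS:
                row[col] = parse_partial_date(raw) if raw else None
            else:
                row[col] = raw or None
        if bad:
            log.drop("unparseable identifier")
            continue
        converted = convert(row, log)
        if converted is not None:
            rows.append(converted)
            log.n_rows += 1

    if not rows:
        return ParsedTable(spec.name, _empty_frame(spec), log)
    frame = pd.DataFrame(rows, columns=list(spec.columns))
    if spec.name == "DEMO" and frame["primaryid"].duplicated().any():
        dupes = frame.loc[frame["primaryid"].duplicated(), "primaryid"].tolist()
        raise SchemaError(f"{path}: duplicate primaryid values in DEMO: {dupes[:5]}")
    return ParsedTable(spec.name, frame, log)


def _empty_frame(spec: _TableSchema) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in spec.columns})


def write_table(
    records: pd.DataFrame, path: str | Path, schema: str, delimiter: str = "$"
) -> Path:
    """Serialize a record collection back to the FAERS ASCII dialect.

    Inverse of :func:`parse_table`: writing then re-parsing yields the same
    records.
    """
    spec = SCHEMAS[schema.upper()]
    path = Path(path)
    lines = [delimiter.join(spec.columns)]
    for row in records.itertuples(index=False):
        fields = []
        for col in spec.columns:
            value = getattr(row, col, None)
            if value is None or (isinstance(value, float) and pd.isna(value)):
                fields.append("")
            elif isinstance(value, PartialDate):
                fields.append(value.compact())
            elif isinstance(value, float) and value.is_integer():
                fields.append(str(int(value)))
            else:
                fields.append(str(value))
        lines.append(delimiter.join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# vocabulary (PT -> SOC)

class Vocabulary:
    """Mapping of MedDRA preferred terms to their primary system organ class.

    Lookups are case-insensitive; each PT maps to exactly one SOC (the
    primary-SOC convention).
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._by_folded: dict[str, tuple[str, str]] = {}
        for pt, soc in mapping.items():
            key = pt.strip().casefold()
            if key in self._by_folded and self._by_folded[key][1] != soc.strip():
                raise ValueError(f"PT {pt!r} mapped to conflicting SOCs")
            self._by_folded[key] = (pt.strip(), soc.strip())

    def soc_of(self, pt: str) -> str | None:
        entry = self._by_folded.get(pt.strip().casefold())
        return entry[1] if entry else None

    def __contains__(self, pt: str) -> bool:
        return pt.strip().casefold() in self._by_folded

    def __len__(self) -> int:
        return len(self._by_folded)

    def pts(self) -> list[str]:
        return [pt for pt, _ in self._by_folded.values()]

    def pts_in(self, soc: str) -> list[str]:
        want = soc.strip().casefold()
        return [pt for pt, s in self._by_folded.values() if s.casefold() == want]

    def socs(self) -> list[str]:
        return sorted({s for _, s in self._by_folded.values()})


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a two-column tab-separated PT -> SOC table.

    Duplicate identical rows collapse to one entry; a PT mapped to two
    different SOCs is a validation error naming the PT.
    """
    entries: dict[str, tuple[str, str]] = {}
    conflicts: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        pt, soc = parts[0].strip(), parts[1].strip()
        key = pt.casefold()
        prior = entries.get(key)
        if prior is not None and prior[1] != soc:
            conflicts.add(pt)
        entries[key] = (pt, soc)
    if conflicts:
        raise ValueError(f"conflicting SOC mappings for PTs: {sorted(conflicts)}")
    return Vocabulary({pt: soc for pt, soc in entries.values()})


# --------------------------------------------------------------------------
# drug synonym dictionary

_PUNCT_RE = re.compile(r"[^0-9a-z]+")


@functools.lru_cache(maxsize=65536)
def normalize_name(name: str) -> str:
    """Case-fold, strip punctuation, and collapse whitespace in a drug name."""
    return _PUNCT_RE.sub(" ", name.casefold()).strip()


class DrugDictionary:
    """Canonical active ingredients and their trade/generic synonyms.

    Matching is whole-string after normalization (case-folded,
    punctuation-stripped); substring matching is deliberately avoided so
    that e.g. a bare antibody name does not swallow its drug conjugates.
    Synonym sets must be pairwise disjoint after normalization.
    """

    def __init__(self, synonyms: Mapping[str, Iterable[str]]):
        self._canonical: dict[str, str] = {}
        self._synonyms: dict[str, set[str]] = {}
        for canonical, names in synonyms.items():
            canonical = canonical.strip()
            pool = set(names) | {canonical}
            self._synonyms[canonical] = set()
            for name in pool:
                key = normalize_name(name)
                if not key:
                    continue
                owner = self._canonical.get(key)
                if owner is not None and owner != canonical:
                    raise ValueError(
                        f"synonym {name!r} claimed by both {owner!r} and {canonical!r}"
                    )
                self._canonical[key] = canonical
                self._synonyms[canonical].add(name.strip())

    @property
    def ingredients(self) -> list[str]:
        return list(self._synonyms)

    def synonyms_of(self, canonical: str) -> set[str]:
        return set(self._synonyms[canonical])

    def lookup(self, name: str | None) -> str | None:
        if not name:
            return None
        return self._canonical.get(normalize_name(name))

    def match(self, drugname: str | None, prod_ai: str | None = None) -> str | None:
        """Canonical ingredient for a DRUG row, or None.

        The reported drug name takes precedence; the active-ingredient
        string (present in FAERS quarters after 2014) is the fallback.
        """
        return self.lookup(drugname) or self.lookup(prod_ai)


def match_drug(
    drugname: str | None, prod_ai: str | None, dictionary: DrugDictionary
) -> str | None:
    """Functional form of :meth:`DrugDictionary.match`."""
    return dictionary.match(drugname, prod_ai)


def load_drug_dictionary(path: str | Path) -> DrugDictionary:
    """Load a two-column TSV (canonical ingredient, synonym), one per row."""
    table: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        table.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return DrugDictionary(table)
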