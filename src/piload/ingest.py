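"""Read, validate and type registry records from flattened dump files.

Two on-disk layouts are accepted, selected by file extension: delimited
tables (``.csv`` comma, ``.tsv``/``.txt`` tab) and newline-delimited JSON
(``.jsonl``/``.ndjson``). A ``schema_map`` maps the pipeline's canonical
field names to the dump's column names, absorbing whatever header naming a
particular export used.

Dates follow the day-first convention the Indian registry renders
(DD/MM/YYYY, DD-MM-YYYY); ISO dates are also accepted. ``NA`` and
``Not Applicable`` are absent-value sentinels throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .model import CalendarDuration, PIContact, RawTrialRecord


class IngestError(Exception):
    """Fatal ingest failure (unreadable file, duplicate registry IDs)."""


class DuplicateRegistryIdError(IngestError):
    def __init__(self, ids: list[str]):
        self.ids = ids
        super().__init__(f"duplicate registry_id values: {sorted(set(ids))}")


class DateParseError(ValueError):
    """Raised for non-empty, non-sentinel text that is not a valid date."""

    def __init__(self, text: str, reason: str = "unparseable date"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


class DurationParseError(ValueError):
    def __init__(self, text: str, reason: str = "unparseable duration"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


#: canonical field name -> description; keys double as the default column names
CANONICAL_FIELDS = (
    "registry_id",
    "type_of_trial",
    "types_of_study",
    "post_graduate_thesis",
    "countries_of_recruitment",
    "pi_name",
    "pi_email",
    "pi_phone",
    "pi_fax",
    "pi_affiliation",
    "pi_address",
    "pi_postal_code",
    "date_first_enrollment",
    "estimated_duration",
    "date_study_completion",
)

#: fields a schema_map must cover; the rest default to their canonical names
REQUIRED_FIELDS = (
    "registry_id",
    "type_of_trial",
    "types_of_study",
    "countries_of_recruitment",
    "pi_name",
)

DEFAULT_SCHEMA_MAP: dict[str, str] = {f: f for f in CANONICAL_FIELDS}

_NA_SENTINELS = {"", "na", "n/a", "not applicable", "nil", "none"}

_DATE_PATTERNS = (
    re.compile(r"^(?P<d>\d{1,2})[/-](?P<m>\d{1,2})[/-](?P<y>\d{4})$"),  # day-first
    re.compile(r"^(?P<y>\d{4})-(?P<m>\d{1,2})-(?P<d>\d{1,2})$"),  # ISO
)

_DURATION_UNIT = re.compile(
    r"(?P<n>\d+)\s*(?P<u>years?|yrs?|y|months?|mos?|m|days?|d)\b", re.IGNORECASE
)


def _is_na(text: str | None) -> bool:
    return text is None or text.strip().lower() in _NA_SENTINELS


def parse_ctri_date(text: str | None) -> date | None:
    """Parse a registry date string; absent sentinels return ``None``.

    Unparseable non-empty text raises :class:`DateParseError` rather than
    silently becoming absent — a malformed date is a data-quality event the
    load report must surface.
    """
    if _is_na(text):
        return None
    s = text.strip()
    for pat in _DATE_PATTERNS:
        m = pat.match(s)
        if m:
            try:
                return date(int(m["y"]), int(m["m"]), int(m["d"]))
            except ValueError as exc:
                raise DateParseError(s, str(exc)) from exc
    raise DateParseError(s)


def parse_duration(
    text: str | None, default_unit: str = "months"
) -> CalendarDuration | None:
    """Parse an *Estimated Duration of Trial* string.

    Handles "1 Years 6 Months 0 Days" style strings, single-unit forms
    ("18 Months") and bare numbers (interpreted in ``default_unit``). Zero
    durations parse to a zero :class:`CalendarDuration`, never to absent:
    the zero case drives an exclusion rule downstream.
    """
    if _is_na(text):
        return None
    s = text.strip()
    if re.fullmatch(r"\d+", s):
        return CalendarDuration(**{default_unit: int(s)})
    parts: dict[str, int] = {}
    matched_len = 0
    for m in _DURATION_UNIT.finditer(s):
        unit = m["u"].lower()
        key = "years" if unit[0] == "y" else "months" if unit[0] == "m" else "days"
        if key in parts:
            raise DurationParseError(s, f"repeated {key} component")
        parts[key] = int(m["n"])
        matched_len += len(m.group(0))
    leftover = _DURATION_UNIT.sub("", s).strip(" ,;")
    if not parts or leftover:
        raise DurationParseError(s)
    return CalendarDuration(**parts)


def _split_multivalue(text: str | None) -> frozenset[str]:
    if _is_na(text):
        return frozenset()
    return frozenset(p.strip() for p in re.split(r"[,;]", text) if p.strip())


@dataclass
class Rejection:
    row_index: int
    registry_id: str | None
    reason: str


@dataclass
class LoadReport:
    """Accounting sidecar for one load: rows in = records out + rejections."""

    rows_read: int = 0
    rejections: list[Rejection] = field(default_factory=list)
    field_missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejections)

    @property
    def records_returned(self) -> int:
        return self.rows_read - self.rows_rejected

    def missingness(self) -> dict[str, float]:
        """Per-field fraction of accepted rows with an absent value."""
        n = self.records_returned
        if n == 0:
            return {f: 0.0 for f in self.field_missing_counts}
        return {f: c / n for f, c in self.field_missing_counts.items()}

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "records_returned": self.records_returned,
            "rows_rejected": self.rows_rejected,
            "rejections": [vars(r) for r in self.rejections],
            "field_missing_counts": dict(self.field_missing_counts),
        }


def _read_rows(path: Path) -> list[dict]:
    ext = path.suffix.lower()
    try:
        if ext in {".jsonl", ".ndjson"}:
            rows = []
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        rows.append(json.loads(line))
            return rows
        sep = "," if ext == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        return df.to_dict(orient="records")
    except (OSError, ValueError, json.JSONDecodeError) as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc


def _build_record(raw: dict, schema: dict[str, str]) -> RawTrialRecord:
    def get(f: str) -> str | None:
        v = raw.get(schema.get(f, f))
        if v is None:
            return None
        v = str(v).strip()
        return v if v else None

    rid = get("registry_id")
    if rid is None:
        raise ValueError("missing registry_id")
    pi = PIContact(
        name_raw=get("pi_name") or "",
        email=get("pi_email"),
        phone=get("pi_phone"),
        fax=get("pi_fax"),
        affiliation=get("pi_affiliation"),
        address=get("pi_address"),
        postal_code=get("pi_postal_code"),
    )
    return RawTrialRecord(
        registry_id=rid,
        type_of_trial=get("type_of_trial") or "",
        types_of_study=_split_multivalue(get("types_of_study")),
        # "NA" is a meaningful registry value here (kept by the filter), so only
        # a truly blank field maps to absent
        post_graduate_thesis=get("post_graduate_thesis"),
        countries_of_recruitment=_split_multivalue(get("countries_of_recruitment")),
        pi=pi,
        date_first_enrollment=parse_ctri_date(get("date_first_enrollment")),
        estimated_duration=parse_duration(get("estimated_duration")),
        date_study_completion=parse_ctri_date(get("date_study_completion")),
    )


_MISSING_TRACKED = (
    "pi_email",
    "pi_phone",
    "pi_fax",
    "pi_affiliation",
    "pi_postal_code",
    "date_first_enrollment",
    "estimated_duration",
    "date_study_completion",
)


def read_records(
    source: str | Path, schema_map: dict[str, str] | None = None
) -> tuple[list[RawTrialRecord], LoadReport]:
    """Load a registry dump into typed records plus a load report.

    Malformed rows are rejected with a reason (never silently dropped);
    duplicate registry IDs abort the load.
    """
    schema = dict(DEFAULT_SCHEMA_MAP)
    if schema_map:
        schema.update(schema_map)
    missing_keys = [f for f in REQUIRED_FIELDS if f not in schema]
    if missing_keys:
        raise IngestError(f"schema_map missing required fields: {missing_keys}")

    path = Path(source)
    rows = _read_rows(path)
    report = LoadReport(rows_read=len(rows))
    report.field_missing_counts = {f: 0 for f in _MISSING_TRACKED}
    records: list[RawTrialRecord] = []
    for i, raw in enumerate(rows):
        try:
            rec = _build_record(raw, schema)
        except (ValueError, DateParseError, DurationParseError) as exc:
            rid = raw.get(schema["registry_id"])
            report.rejections.append(
                Rejection(row_index=i, registry_id=str(rid) if rid else None, reason=str(exc))
            )
            continue
        records.append(rec)
        for f in _MISSING_TRACKED:
            v = raw.get(schema.get(f, f))
            if _is_na(None if v is None else str(v)):
                report.field_missing_counts[f] += 1

    ids = [r.registry_id for r in records]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for rid in ids:
            if rid in seen:
                dups.append(rid)
            seen.add(rid)
        raise DuplicateRegistryIdError(dups)
    return records, report
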