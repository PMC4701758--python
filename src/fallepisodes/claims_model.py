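"""Normalized claims data model and person-day expansion.

The grouper consumes a single normalized line-item schema, one row per
billed service line, regardless of whether the source was fee-for-service
Medicare (MedPAR/Carrier/Outpatient extracts) or a Medicare Advantage plan
export: that upstream merge is out of scope and is abstracted into the
``setting_hint`` field (which stands in for the MedPAR short-stay/long-stay/
SNF indicator and plan-specific inpatient identification).

The algorithm reasons in whole calendar days.  :func:`expand_to_person_days`
turns validated claim lines into one :class:`PersonDay` per (patient, date)
covered by any claim's inclusive service span; diagnosis and setting
information from a multi-day claim applies to every covered day, and flags
on a day are the union over all contributing lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ClaimLine",
    "EnrollmentSpan",
    "PersonDay",
    "SchemaConfigError",
    "RowValidationError",
    "DEFAULT_SCHEMA",
    "load_claims",
    "load_enrollment",
    "expand_to_person_days",
    "person_days_to_frame",
]

logger = logging.getLogger("fallepisodes")

SETTING_HINTS = ("inpatient", "snf", "other", "unknown")

#: default column mapping for the normalized delimited schema.  Diagnosis
#: codes may come either as one delimited field (``dx_mode: delimited``)
#: or as wide columns dx1..dxN (``dx_mode: wide``); position 1 is primary.
DEFAULT_SCHEMA: dict = {
    "sep": ",",
    "dx_mode": "delimited",
    "dx_column": "diagnosis_codes",
    "dx_delimiter": ";",
    "dx_columns": None,  # used when dx_mode == "wide", e.g. ["dx1", "dx2"]
    "columns": {
        "patient_id": "patient_id",
        "claim_id": "claim_id",
        "start_date": "start_date",
        "end_date": "end_date",
        "procedure_code": "procedure_code",
        "betos_code": "betos_code",
        "pos_code": "pos_code",
        "revenue_code": "revenue_code",
        "setting_hint": "setting_hint",
        "paid_amount": "paid_amount",
        "payment_year": "payment_year",
    },
}


class SchemaConfigError(ValueError):
    """A required column is missing or the schema config is invalid."""


class RowValidationError(ValueError):
    """One or more input rows failed validation.

    Carries ``errors``: a list of (row_number, message) pairs, row numbers
    0-based over the data rows.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        preview = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid claim rows: {preview}{more}")


@dataclass(frozen=True)
class ClaimLine:
    """One billed service line — the atomic input record."""

    patient_id: str
    claim_id: str
    start_date: date
    end_date: date
    diagnosis_codes: tuple[str, ...] = ()  # position 1 = primary
    procedure_code: str | None = None
    betos_code: str | None = None
    pos_code: str | None = None
    revenue_code: str | None = None
    setting_hint: str = "unknown"
    paid_amount: float = 0.0
    payment_year: int = 2009

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(
                f"claim {self.claim_id}: end_date {self.end_date} before "
                f"start_date {self.start_date}"
            )
        if self.paid_amount < 0:
            raise ValueError(f"claim {self.claim_id}: negative paid_amount")
        if self.setting_hint not in SETTING_HINTS:
            raise ValueError(
                f"claim {self.claim_id}: setting_hint {self.setting_hint!r} "
                f"not in {SETTING_HINTS}"
            )

    @property
    def primary_diagnosis(self) -> str | None:
        return self.diagnosis_codes[0] if self.diagnosis_codes else None

    def service_days(self) -> Iterable[date]:
        d = self.start_date
        while d <= self.end_date:
            yield d
            d += timedelta(days=1)


@dataclass(frozen=True)
class EnrollmentSpan:
    """A coverage span; spans for one patient are non-overlapping."""

    patient_id: str
    span_start: date
    span_end: date

    def __post_init__(self) -> None:
        if self.span_end < self.span_start:
            raise ValueError(
                f"enrollment span for {self.patient_id}: end before start"
            )


@dataclass
class PersonDay:
    """A patient calendar day with derived flags.

    Setting flags are filled by the setting-detection step, injury and
    procedure annotations by the encounter engine; every flag is traceable
    to at least one contributing claim line in ``claim_refs``.
    """

    patient_id: str
    date: date
    is_inpatient: bool = False
    is_snf: bool = False
    is_ed: bool = False
    # (injury_type, body_site) pairs present on this day
    injury_sites: set[tuple[str, str]] = field(default_factory=set)
    has_primary_fall_dx: dict[str, bool] = field(default_factory=dict)
    has_secondary_fall_dx: dict[str, bool] = field(default_factory=dict)
    procedure_classes: set[str] = field(default_factory=set)
    repair_sites: set[str] = field(default_factory=set)
    imaging_sites: set[str] = field(default_factory=set)
    has_cast_appropriate_dx: bool = False
    has_disqualifying_ecode: bool = False
    claim_refs: list[str] = field(default_factory=list)

    @property
    def injury_flags(self) -> set[str]:
        """The injury types present on this day."""
        return {t for t, _ in self.injury_sites}


def _parse_date(value, row: int, col: str, errors: list[tuple[int, str]]):
    try:
        if isinstance(value, date):
            return value
        return date.fromisoformat(str(value).strip())
    except (ValueError, TypeError):
        errors.append((row, f"unparseable date {value!r} in column {col}"))
        return None


def _clean_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _read_table(source, sep: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, sep=sep, dtype=str, keep_default_na=True)


def load_claims(
    table_source, schema_config: Mapping | None = None
) -> list[ClaimLine]:
    """Read and validate a delimited claims table into :class:`ClaimLine`s.

    ``table_source`` is a path, file handle, or DataFrame; ``schema_config``
    follows :data:`DEFAULT_SCHEMA` (unspecified keys default).  Rows failing
    validation are never silently dropped: a :class:`RowValidationError`
    listing every offending row number and value is raised.
    """
    cfg = dict(DEFAULT_SCHEMA)
    if schema_config:
        cfg.update(schema_config)
        if "columns" in schema_config:
            cols = dict(DEFAULT_SCHEMA["columns"])
            cols.update(schema_config["columns"])
            cfg["columns"] = cols
    df = _read_table(table_source, cfg["sep"])
    colmap = cfg["columns"]

    required = ["patient_id", "claim_id", "start_date", "end_date"]
    for key in required:
        if colmap[key] not in df.columns:
            raise SchemaConfigError(
                f"required column {colmap[key]!r} (field {key}) missing from input"
            )
    if cfg["dx_mode"] == "delimited":
        if cfg["dx_column"] not in df.columns:
            raise SchemaConfigError(
                f"diagnosis column {cfg['dx_column']!r} missing from input"
            )
    elif cfg["dx_mode"] == "wide":
        dx_cols = cfg["dx_columns"] or [c for c in df.columns if c.startswith("dx")]
        if not dx_cols:
            raise SchemaConfigError("dx_mode 'wide' but no dx columns found")
        cfg["dx_columns"] = dx_cols
    else:
        raise SchemaConfigError(f"unknown dx_mode {cfg['dx_mode']!r}")

    if df.empty:
        logger.warning("claims input has 0 data rows")
        return []

    claims: list[ClaimLine] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        start = _parse_date(row[colmap["start_date"]], i, colmap["start_date"], errors)
        end = _parse_date(row[colmap["end_date"]], i, colmap["end_date"], errors)
        if start is None or end is None:
            continue
        if cfg["dx_mode"] == "delimited":
            raw = _clean_str(row.get(cfg["dx_column"]))
            dx = tuple(
                c.strip() for c in raw.split(cfg["dx_delimiter"]) if c.strip()
            ) if raw else ()
        else:
            dx = tuple(
                c for c in (_clean_str(row.get(col)) for col in cfg["dx_columns"]) if c
            )
        try:
            paid = row.get(colmap["paid_amount"])
            year = row.get(colmap["payment_year"])
            claims.append(
                ClaimLine(
                    patient_id=str(row[colmap["patient_id"]]),
                    claim_id=str(row[colmap["claim_id"]]),
                    start_date=start,
                    end_date=end,
                    diagnosis_codes=dx,
                    procedure_code=_clean_str(row.get(colmap["procedure_code"])),
                    betos_code=_clean_str(row.get(colmap["betos_code"])),
                    pos_code=_clean_str(row.get(colmap["pos_code"])),
                    revenue_code=_clean_str(row.get(colmap["revenue_code"])),
                    setting_hint=_clean_str(row.get(colmap["setting_hint"]))
                    or "unknown",
                    paid_amount=float(paid) if _clean_str(paid) is not None else 0.0,
                    payment_year=int(float(year))
                    if _clean_str(year) is not None
                    else start.year,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise RowValidationError(errors)
    logger.info("loaded %d claim lines", len(claims))
    return claims


def load_enrollment(
    table_source, schema_config: Mapping | None = None
) -> list[EnrollmentSpan]:
    """Read an enrollment table (patient_id, span_start, span_end).

    Overlapping or adjacent spans of one patient are merged so downstream
    person-year arithmetic never double counts coverage.
    """
    cfg = {
        "sep": ",",
        "columns": {
            "patient_id": "patient_id",
            "span_start": "span_start",
            "span_end": "span_end",
        },
    }
    if schema_config:
        if "sep" in schema_config:
            cfg["sep"] = schema_config["sep"]
        cfg["columns"].update(schema_config.get("columns", {}))
    df = _read_table(table_source, cfg["sep"])
    colmap = cfg["columns"]
    for key, col in colmap.items():
        if col not in df.columns:
            raise SchemaConfigError(f"required column {col!r} (field {key}) missing")
    errors: list[tuple[int, str]] = []
    raw: dict[str, list[tuple[date, date]]] = {}
    for i, row in enumerate(df.to_dict("records")):
        s = _parse_date(row[colmap["span_start"]], i, colmap["span_start"], errors)
        e = _parse_date(row[colmap["span_end"]], i, colmap["span_end"], errors)
        if s is None or e is None:
            continue
        if e < s:
            errors.append((i, f"span end {e} before start {s}"))
            continue
        raw.setdefault(str(row[colmap["patient_id"]]), []).append((s, e))
    if errors:
        raise RowValidationError(errors)
    spans: list[EnrollmentSpan] = []
    for pid, intervals in raw.items():
        intervals.sort()
        merged: list[list[date]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1] + timedelta(days=1):
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        spans.extend(EnrollmentSpan(pid, s, e) for s, e in merged)
    return spans


def expand_to_person_days(
    claims: Sequence[ClaimLine],
) -> dict[tuple[str, date], PersonDay]:
    """Expand claim lines into one :class:`PersonDay` per covered date.

    A claim covers every date in [start_date, end_date] inclusive; two
    claims touching the same (patient, date) contribute to a single
    PersonDay whose ``claim_refs`` lists both.  The expansion is a pure
    union, hence idempotent and independent of input order.
    """
    out: dict[tuple[str, date], PersonDay] = {}
    for claim in claims:
        for d in claim.service_days():
            key = (claim.patient_id, d)
            pday = out.get(key)
            if pday is None:
                pday = out[key] = PersonDay(patient_id=claim.patient_id, date=d)
            pday.claim_refs.append(claim.claim_id)
    for pday in out.values():
        pday.claim_refs.sort()
    return out


def person_days_to_frame(
    person_days: Mapping[tuple[str, date], PersonDay]
) -> pd.DataFrame:
    """Flatten person-days to a table (for CSV audit output)."""
    rows = []
    for (pid, d), p in sorted(person_days.items()):
        rows.append(
            {
                "patient_id": pid,
                "date": d.isoformat(),
                "is_inpatient": p.is_inpatient,
                "is_snf": p.is_snf,
                "is_ed": p.is_ed,
                "injury_types": ";".join(sorted(p.injury_flags)),
                "injury_sites": ";".join(
                    f"{t}:{s}" for t, s in sorted(p.injury_sites)
                ),
                "primary_fall_dx": ";".join(
                    sorted(t for t, v in p.has_primary_fall_dx.items() if v)
                ),
                "procedure_classes": ";".join(sorted(p.procedure_classes)),
                "has_disqualifying_ecode": p.has_disqualifying_ecode,
                "claim_refs": ";".join(p.claim_refs),
            }
        )
    return pd.DataFrame(rows)
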