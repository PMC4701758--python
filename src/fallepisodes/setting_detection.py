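"""Step 1 — mark person-days as inpatient/SNF and flag ED activity.

A day is inpatient if any contributing claim line either carries an
inpatient setting hint (the normalized stand-in for the MedPAR short-stay/
long-stay indicator) or bills an inpatient evaluation-and-management CPT
code; SNF analogously.  A day may carry both flags (e.g. a same-day
transfer) — downstream encounter typing treats "inpatient or SNF" jointly,
and only the duration accounting gives inpatient precedence.

A line indicates emergency-department activity if any one of three criteria
holds: its BETOS code is "M3" (emergency room visit) or starts with "I"
(imaging); its place-of-service code is the emergency-room code (default
23); or its revenue-center code is 0450-0459 or 0981.  The ED flag is kept
even on days concurrent with an inpatient stay, since ED visits resulting
in admission are often not billed separately and reveal themselves only
through ED-related line items.

Both operations only ever turn flags on: adding claim lines is monotone.
"""

from __future__ import annotations

from datetime import date
from typing import Mapping, Sequence

from .claims_model import ClaimLine, PersonDay
from .code_config import CodeTables, normalize_revenue

__all__ = [
    "line_is_inpatient",
    "line_is_snf",
    "line_is_ed",
    "flag_inpatient_snf",
    "flag_ed_activity",
]


def _cpt(line: ClaimLine) -> str | None:
    return line.procedure_code.strip().upper() if line.procedure_code else None


def line_is_inpatient(line: ClaimLine, tables: CodeTables) -> bool:
    return line.setting_hint == "inpatient" or _cpt(line) in tables.inpatient_cpt


def line_is_snf(line: ClaimLine, tables: CodeTables) -> bool:
    return line.setting_hint == "snf" or _cpt(line) in tables.snf_cpt


def line_is_ed(line: ClaimLine, tables: CodeTables) -> bool:
    """Any of the three ED criteria: BETOS, place of service, revenue code."""
    if line.betos_code:
        betos = line.betos_code.strip().upper()
        if betos in tables.ed_betos_exact:
            return True
        if any(betos.startswith(p.upper()) for p in tables.ed_betos_prefixes):
            return True
    if line.pos_code and line.pos_code.strip().lstrip("0") in {
        c.lstrip("0") for c in tables.ed_pos_codes
    }:
        return True
    if line.revenue_code:
        if normalize_revenue(line.revenue_code) in tables.ed_revenue_codes:
            return True
    return False


def _index_claims(claims: Sequence[ClaimLine]) -> dict[str, list[ClaimLine]]:
    by_id: dict[str, list[ClaimLine]] = {}
    for c in claims:
        by_id.setdefault(c.claim_id, []).append(c)
    return by_id


def flag_inpatient_snf(
    person_days: Mapping[tuple[str, date], PersonDay],
    claims: Sequence[ClaimLine],
    tables: CodeTables,
) -> Mapping[tuple[str, date], PersonDay]:
    """Set is_inpatient / is_snf on each day from its contributing lines."""
    for claim in claims:
        inp = line_is_inpatient(claim, tables)
        snf = line_is_snf(claim, tables)
        if not (inp or snf):
            continue
        for d in claim.service_days():
            pday = person_days.get((claim.patient_id, d))
            if pday is None:
                continue
            pday.is_inpatient = pday.is_inpatient or inp
            pday.is_snf = pday.is_snf or snf
    return person_days


def flag_ed_activity(
    person_days: Mapping[tuple[str, date], PersonDay],
    claims: Sequence[ClaimLine],
    tables: CodeTables,
) -> Mapping[tuple[str, date], PersonDay]:
    """Set is_ed on each day with at least one ED-qualifying line."""
    for claim in claims:
        if not line_is_ed(claim, tables):
            continue
        for d in claim.service_days():
            pday = person_days.get((claim.patient_id, d))
            if pday is not None:
                pday.is_ed = True
    return person_days
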