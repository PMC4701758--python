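"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from fallepisodes import ClaimLine, PersonDay, default_code_tables
from fallepisodes.encounter_engine import Encounter


@pytest.fixture(scope="session")
def tables():
    return default_code_tables()


def make_claim(
    pid="P1",
    cid="C1",
    start="2007-03-01",
    end=None,
    dx=(),
    proc=None,
    betos=None,
    pos=None,
    revenue=None,
    setting="unknown",
    paid=0.0,
    year=None,
):
    start_d = date.fromisoformat(start)
    end_d = date.fromisoformat(end) if end else start_d
    return ClaimLine(
        patient_id=pid,
        claim_id=cid,
        start_date=start_d,
        end_date=end_d,
        diagnosis_codes=tuple(dx),
        procedure_code=proc,
        betos_code=betos,
        pos_code=pos,
        revenue_code=revenue,
        setting_hint=setting,
        paid_amount=paid,
        payment_year=year if year is not None else start_d.year,
    )


def make_person_day(
    pid="P1",
    day="2007-03-01",
    inpatient=False,
    snf=False,
    ed=False,
    injury_sites=(),
    primary=(),
    secondary=(),
    procedure_classes=(),
    repair_sites=(),
    imaging_sites=(),
    cast_ok=False,
    disqualifying=False,
):
    return PersonDay(
        patient_id=pid,
        date=date.fromisoformat(day) if isinstance(day, str) else day,
        is_inpatient=inpatient,
        is_snf=snf,
        is_ed=ed,
        injury_sites=set(injury_sites),
        has_primary_fall_dx={t: True for t in primary},
        has_secondary_fall_dx={t: True for t in secondary},
        procedure_classes=set(procedure_classes),
        repair_sites=set(repair_sites),
        imaging_sites=set(imaging_sites),
        has_cast_appropriate_dx=cast_ok,
        has_disqualifying_ecode=disqualifying,
        claim_refs=["C"],
    )


def make_encounter(
    pid="P1",
    etype=6,
    start=0,
    end=None,
    origin=date(2007, 1, 1),
    injuries=("fall_ecode",),
    inpatient=False,
    snf=False,
    ed=False,
    disqualifying=False,
):
    """Encounter spanning day offsets [start, end] from an origin date."""
    end = start if end is None else end
    days = [origin + timedelta(days=d) for d in range(start, end + 1)]
    return Encounter(
        patient_id=pid,
        encounter_type=etype,
        member_days=days,
        injury_types=set(injuries),
        body_sites=set(),
        involves_inpatient=inpatient,
        involves_snf=snf,
        involves_ed=ed,
        has_disqualifying_ecode=disqualifying,
    )
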