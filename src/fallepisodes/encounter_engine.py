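"""Steps 2-3 — fall-incident annotation and six-type encounter classification.

Step 2 walks every claim line contributing to a person-day and records the
fall-related evidence present on that day: injury diagnoses classified into
five types (hip fracture, other fracture, head injury, joint dislocation,
accidental-fall E code) with body sites and primary/secondary position,
procedure classes (repair / cast-splint / imaging with body sites), and any
disqualifying external-cause code.

Step 3 assigns each fall-incident day to at most one *encounter*, typed on
a six-level hierarchy where lower numbers carry higher certainty:

1. inpatient fall-related injury            (inpatient/SNF day, primary dx)
2. probable inpatient fall-related injury   (inpatient/SNF day, secondary dx)
3. probable outpatient fall-related injury  (repair + fall dx, or general
                                             cast/splint + appropriate dx)
4. outpatient fracture repair procedure     (site-specific repair, no dx)
5. possible outpatient fall-related injury  (days chained by same site/type
                                             diagnoses within a 10-day
                                             forward window)
6. fall-related use of medical care         (accidental-fall E code only)

Types 1-4 and 6 are single-day encounters; type 5 spans every day reachable
through the chaining relation.  Each injury type participates only at the
certainty levels where the evidence is clinically interpretable: hip and
other fractures at 1-4 (other fractures at body sites with an associated
imaging-code list additionally at 5), joint dislocations at 1-5, head
injuries at 1-2 only (head codes are examined solely in the inpatient/SNF
setting), and fall E codes at 1-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

from .claims_model import ClaimLine, PersonDay
from .code_config import (
    CodeTables,
    _prefix_match,
    classify_diagnosis,
    classify_procedure,
    is_disqualifying_ecode,
    normalize_dx,
)

__all__ = ["Encounter", "annotate_fall_incidents", "classify_encounters"]

ENCOUNTER_TYPE_LABELS = {
    1: "inpatient fall-related injury",
    2: "probable inpatient fall-related injury",
    3: "probable outpatient fall-related injury",
    4: "outpatient fracture repair procedure",
    5: "possible outpatient fall-related injury",
    6: "fall-related use of medical care",
}


@dataclass
class Encounter:
    """A maximal set of connected person-days with one encounter type."""

    patient_id: str
    encounter_type: int
    member_days: list[date]
    injury_types: set[str] = field(default_factory=set)
    body_sites: set[str] = field(default_factory=set)
    involves_inpatient: bool = False
    involves_snf: bool = False
    involves_ed: bool = False
    has_disqualifying_ecode: bool = False

    @property
    def start_date(self) -> date:
        return min(self.member_days)

    @property
    def end_date(self) -> date:
        return max(self.member_days)

    @property
    def type_label(self) -> str:
        return ENCOUNTER_TYPE_LABELS[self.encounter_type]


def annotate_fall_incidents(
    person_days: Mapping[tuple[str, date], PersonDay],
    claims: Sequence[ClaimLine],
    tables: CodeTables,
) -> Mapping[tuple[str, date], PersonDay]:
    """Step 2: record injury/procedure evidence on every person-day.

    All listed diagnoses are used — primary and secondary, including E
    codes — and evidence from a multi-day claim applies to each covered
    day.  Requires setting flags to have been filled already only insofar
    as callers usually run step 1 first; the annotation itself is
    independent of the setting flags.
    """
    for claim in claims:
        dx_class = [
            (
                pos,
                classify_diagnosis(dx, tables),
                is_disqualifying_ecode(dx, tables),
                _cast_appropriate(dx, tables),
            )
            for pos, dx in enumerate(claim.diagnosis_codes, start=1)
        ]
        proc_class, proc_site = classify_procedure(claim.procedure_code, tables)
        if proc_class == "other" and not any(
            pairs or disq for _, pairs, disq, _app in dx_class
        ):
            continue
        for d in claim.service_days():
            pday = person_days.get((claim.patient_id, d))
            if pday is None:
                continue
            for pos, pairs, disq, appropriate in dx_class:
                pday.injury_sites |= pairs
                for etype, _site in pairs:
                    if pos == 1:
                        pday.has_primary_fall_dx[etype] = True
                    else:
                        pday.has_secondary_fall_dx[etype] = True
                if pairs and appropriate:
                    pday.has_cast_appropriate_dx = True
                if disq:
                    pday.has_disqualifying_ecode = True
            if proc_class != "other":
                pday.procedure_classes.add(proc_class)
                if proc_class == "repair" and proc_site:
                    pday.repair_sites.add(proc_site)
                elif proc_class == "imaging" and proc_site:
                    pday.imaging_sites.add(proc_site)
    return person_days


def _type5_dx_keys(pday: PersonDay, tables: CodeTables) -> set[tuple[str, str]]:
    """Chaining keys contributed by this day's *diagnoses*.

    A key is ("type", injury_type) or ("site", body_site), restricted to
    the injury types eligible for type-5 encounters: joint dislocations,
    other fractures at imaging-list body sites, and accidental-fall E
    codes (whose "site" is the mechanism category).
    """
    keys: set[tuple[str, str]] = set()
    t5_sites = tables.type5_fracture_sites()
    for etype, site in pday.injury_sites:
        if etype == "joint_dislocation" or etype == "fall_ecode":
            keys.add(("type", etype))
            keys.add(("site", site))
        elif etype == "other_fracture" and site in t5_sites:
            keys.add(("type", etype))
            keys.add(("site", site))
    return keys


def _has_fall_dx(pday: PersonDay) -> bool:
    return bool(pday.injury_sites)


def _has_primary_fall_dx(pday: PersonDay) -> bool:
    return any(pday.has_primary_fall_dx.values())


def _make_single_day(pday: PersonDay, etype: int) -> Encounter:
    return Encounter(
        patient_id=pday.patient_id,
        encounter_type=etype,
        member_days=[pday.date],
        injury_types=set(pday.injury_flags),
        body_sites={s for _, s in pday.injury_sites},
        involves_inpatient=pday.is_inpatient,
        involves_snf=pday.is_snf,
        involves_ed=pday.is_ed,
        has_disqualifying_ecode=pday.has_disqualifying_ecode,
    )


def classify_encounters(
    person_days: Mapping[tuple[str, date], PersonDay],
    tables: CodeTables,
    window_days: int = 10,
) -> list[Encounter]:
    """Step 3: assign every fall-incident day to at most one encounter.

    The decision order follows the published flow exactly: inpatient/SNF
    test, site-specific repair test, general cast/splint test, forward
    chaining of diagnosis/imaging days into a type-5 encounter, and
    finally the accidental-fall E-code test.  On a day eligible for more
    than one type the best-ranked (lowest) number wins.

    Chaining looks forward up to ``window_days`` calendar days (a gap of
    exactly ``window_days`` connects) for a later day carrying a diagnosis
    on the same body site or injury type, then repeats from each newly
    connected day; imaging evidence can seed a chain but only a diagnosis
    can extend one.  The result equals the connected components of the
    day-pair connection graph.  Output is sorted and independent of input
    order.
    """
    if window_days < 0:
        raise ValueError(f"window_days must be >= 0, got {window_days}")

    by_patient: dict[str, list[PersonDay]] = {}
    for (pid, _d), pday in person_days.items():
        by_patient.setdefault(pid, []).append(pday)

    encounters: list[Encounter] = []
    for pid in sorted(by_patient):
        days = sorted(by_patient[pid], key=lambda p: p.date)
        chain_candidates: list[tuple[PersonDay, set, set]] = []
        for pday in days:
            if pday.is_inpatient or pday.is_snf:
                if _has_fall_dx(pday):
                    etype = 1 if _has_primary_fall_dx(pday) else 2
                    encounters.append(_make_single_day(pday, etype))
                continue
            # outpatient day
            if pday.repair_sites:
                etype = 3 if _has_fall_dx(pday) else 4
                enc = _make_single_day(pday, etype)
                enc.body_sites |= pday.repair_sites
                encounters.append(enc)
                continue
            if "cast_splint" in pday.procedure_classes and pday.has_cast_appropriate_dx:
                encounters.append(_make_single_day(pday, 3))
                continue
            dx_keys = _type5_dx_keys(pday, tables)
            img_keys = {("site", s) for s in pday.imaging_sites}
            if dx_keys or img_keys:
                chain_candidates.append((pday, dx_keys, img_keys))
            # E-code fallback handled after chaining below

        encounters.extend(
            _chain_type5(pid, chain_candidates, window_days, tables)
        )
    encounters.sort(key=lambda e: (e.patient_id, e.start_date, e.encounter_type))
    return encounters


def _cast_appropriate(dx_code: str, tables: CodeTables) -> bool:
    """Is this a diagnosis for which a cast or splint would be appropriate?

    Configured as dx-code prefixes; the default set covers all fracture
    and dislocation codes and excludes head injuries.
    """
    try:
        code = normalize_dx(dx_code)
    except Exception:
        return False
    return _prefix_match(code, tables.cast_appropriate_dx) is not None


def _chain_type5(
    patient_id: str,
    candidates: list[tuple[PersonDay, set, set]],
    window_days: int,
    tables: CodeTables,
) -> list[Encounter]:
    """Resolve chaining candidates into type-5 (or fallback) encounters."""
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    connected = [False] * n
    for i in range(n):
        pday_i, dx_i, img_i = candidates[i]
        keys_i = dx_i | img_i
        if not keys_i:
            continue
        for j in range(n):
            if i == j:
                continue
            pday_j, dx_j, _img_j = candidates[j]
            gap = (pday_j.date - pday_i.date).days
            if gap <= 0 or gap > window_days:
                continue
            if keys_i & dx_j:  # later day must connect via a diagnosis
                union(i, j)
                connected[i] = connected[j] = True

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    out: list[Encounter] = []
    for members in comps.values():
        if len(members) >= 2:
            pdays = [candidates[i][0] for i in members]
            enc = Encounter(
                patient_id=patient_id,
                encounter_type=5,
                member_days=sorted(p.date for p in pdays),
            )
            for p in pdays:
                enc.injury_types |= p.injury_flags
                enc.body_sites |= {s for _, s in p.injury_sites}
                enc.body_sites |= p.imaging_sites
                enc.involves_inpatient = enc.involves_inpatient or p.is_inpatient
                enc.involves_snf = enc.involves_snf or p.is_snf
                enc.involves_ed = enc.involves_ed or p.is_ed
                enc.has_disqualifying_ecode = (
                    enc.has_disqualifying_ecode or p.has_disqualifying_ecode
                )
            out.append(enc)
        else:
            pday = candidates[members[0]][0]
            if ("fall_ecode" in pday.injury_flags):
                out.append(_make_single_day(pday, 6))
            # else: isolated imaging/diagnosis day with no connection and no
            # E code — an invalid case, no encounter
    return out
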