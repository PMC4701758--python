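"""Step 4 — chain encounters into episodes of care and categorize them.

An episode of care is a set of encounters clustered closely enough in time
to believably stem from one underlying injury.  Episode construction has
two phases:

**Start identification.**  An encounter begins a new episode iff (a) it
carries no disqualifying external-cause code; (b) no encounter of any type
ends within the 30-day lookback before its start (so it is not the tail of
an earlier episode); and (c) if it involves a SNF stay it must also involve
an ED visit or inpatient stay, and the most recent prior encounter (at any
lag) must not involve SNF — blocking episodes that would "start" inside a
continuing SNF residence.

**Forward chaining.**  From a valid start, each subsequent encounter whose
start falls within 30 days (inclusive) of the latest connected encounter's
end is connected; meeting an encounter with a disqualifying E code stops
the chain and excludes that encounter from any episode.  The episode ends
on the latest connected encounter's last day.

Episodes are finally sorted into three mutually exclusive hierarchies: the
six-level certainty category (best encounter type present), the service
category (inpatient/SNF > ED visit > non-ED outpatient only), and the
injury category (hip fracture > non-hip fracture > non-fracture injury).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

from .claims_model import PersonDay
from .encounter_engine import Encounter

__all__ = [
    "Episode",
    "EpisodeAudit",
    "find_episode_starts",
    "chain_episode",
    "categorize_episode",
    "build_episodes",
]

logger = logging.getLogger("fallepisodes")

SERVICE_CATEGORIES = ("inpatient_or_snf", "ed_visit", "outpatient_only")
INJURY_CATEGORIES = ("hip_fracture", "non_hip_fracture", "non_fracture_injury")


@dataclass
class Episode:
    """A chained set of encounters with category labels and costs."""

    patient_id: str
    start_date: date
    end_date: date
    encounter_refs: list[Encounter]
    episode_category: int | None = None
    service_category: str | None = None
    injury_category: str | None = None
    ed_days: int = 0
    inpatient_days: int = 0
    snf_days: int = 0
    total_cost_2009: float | None = None
    attributable_cost_2009: float | None = None

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class EpisodeAudit:
    """Bookkeeping of encounters that formed no episode, for audit logs."""

    rejected_starts: list[Encounter] = field(default_factory=list)
    disqualified: list[Encounter] = field(default_factory=list)


def _by_patient(encounters: Sequence[Encounter]) -> dict[str, list[Encounter]]:
    out: dict[str, list[Encounter]] = {}
    for e in encounters:
        out.setdefault(e.patient_id, []).append(e)
    for encs in out.values():
        encs.sort(key=lambda e: (e.start_date, e.encounter_type))
    return out


def _is_start(
    enc: Encounter, patient_encs: Sequence[Encounter], lookback_days: int
) -> bool:
    if enc.has_disqualifying_ecode:
        return False
    prior = [e for e in patient_encs if e is not enc and e.start_date < enc.start_date]
    horizon = enc.start_date - timedelta(days=lookback_days)
    if any(e.end_date >= horizon for e in prior):
        return False
    if enc.involves_snf:
        if not (enc.involves_ed or enc.involves_inpatient):
            return False
        if prior:
            most_recent = max(prior, key=lambda e: (e.end_date, e.start_date))
            if most_recent.involves_snf:
                return False
    return True


def find_episode_starts(
    encounters: Sequence[Encounter], lookback_days: int = 30
) -> list[Encounter]:
    """Return the encounters that qualify as episode starts.

    The lookback is inclusive: an encounter ending exactly ``lookback_days``
    before a candidate's start blocks it.
    """
    if lookback_days < 1:
        raise ValueError(f"lookback_days must be >= 1, got {lookback_days}")
    out = []
    for patient_encs in _by_patient(encounters).values():
        out.extend(
            e for e in patient_encs if _is_start(e, patient_encs, lookback_days)
        )
    return out


def chain_episode(
    start_encounter: Encounter,
    encounters: Sequence[Encounter],
    window_days: int = 30,
) -> tuple[Episode, Encounter | None]:
    """Greedily chain subsequent encounters onto a qualified start.

    Returns the episode and, when the chain was terminated by an encounter
    carrying a disqualifying E code, that (excluded) encounter.  A gap of
    exactly ``window_days`` between the latest connected encounter's end
    and a candidate's start still connects.
    """
    patient_encs = [
        e
        for e in encounters
        if e.patient_id == start_encounter.patient_id
        and e.start_date > start_encounter.start_date
    ]
    patient_encs.sort(key=lambda e: (e.start_date, e.encounter_type))
    members = [start_encounter]
    latest_end = start_encounter.end_date
    stopper: Encounter | None = None
    for cand in patient_encs:
        if (cand.start_date - latest_end).days > window_days:
            break
        if cand.has_disqualifying_ecode:
            stopper = cand
            break
        members.append(cand)
        latest_end = max(latest_end, cand.end_date)
    episode = Episode(
        patient_id=start_encounter.patient_id,
        start_date=start_encounter.start_date,
        end_date=latest_end,
        encounter_refs=members,
    )
    return episode, stopper


def categorize_episode(episode: Episode) -> Episode:
    """Assign the three hierarchical, mutually exclusive category labels.

    The certainty category is the best (lowest) encounter type present:
    e.g. an episode holding both an inpatient fall-related injury (1) and
    an outpatient fracture repair (4) is an episode of (1).
    """
    encs = episode.encounter_refs
    episode.episode_category = min(e.encounter_type for e in encs)
    if any(e.involves_inpatient or e.involves_snf for e in encs):
        episode.service_category = "inpatient_or_snf"
    elif any(e.involves_ed for e in encs):
        episode.service_category = "ed_visit"
    else:
        episode.service_category = "outpatient_only"
    injuries = set().union(*(e.injury_types for e in encs))
    if "hip_fracture" in injuries:
        episode.injury_category = "hip_fracture"
    elif "other_fracture" in injuries:
        episode.injury_category = "non_hip_fracture"
    else:
        episode.injury_category = "non_fracture_injury"
    return episode


def _fill_duration_components(
    episode: Episode, person_days: Mapping[tuple[str, date], PersonDay]
) -> None:
    """Count ED / inpatient / SNF days inside the episode window.

    A day that is both inpatient and SNF counts as inpatient only; the ED
    flag is counted regardless of concurrent stays (ED activity during a
    hospitalization is real ED use).
    """
    ed = inp = snf = 0
    d = episode.start_date
    while d <= episode.end_date:
        pday = person_days.get((episode.patient_id, d))
        if pday is not None:
            if pday.is_ed:
                ed += 1
            if pday.is_inpatient:
                inp += 1
            elif pday.is_snf:
                snf += 1
        d += timedelta(days=1)
    episode.ed_days, episode.inpatient_days, episode.snf_days = ed, inp, snf


def build_episodes(
    encounters: Sequence[Encounter],
    lookback_days: int = 30,
    window_days: int = 30,
    person_days: Mapping[tuple[str, date], PersonDay] | None = None,
) -> tuple[list[Episode], EpisodeAudit]:
    """Construct and categorize all episodes for a cohort of encounters.

    Encounters are examined per patient in chronological order; each valid
    start is chained forward, consuming its members, and every encounter
    belongs to at most one episode.  Encounters that never qualify (e.g.
    SNF-only starts, disqualified chain stoppers) are reported in the audit
    rather than silently dropped.
    """
    if lookback_days < 1:
        raise ValueError(f"lookback_days must be >= 1, got {lookback_days}")
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    episodes: list[Episode] = []
    audit = EpisodeAudit()
    for pid, patient_encs in sorted(_by_patient(encounters).items()):
        consumed: set[int] = set()
        for enc in patient_encs:
            if id(enc) in consumed:
                continue
            if not _is_start(enc, patient_encs, lookback_days):
                if not enc.has_disqualifying_ecode:
                    audit.rejected_starts.append(enc)
                continue
            episode, stopper = chain_episode(enc, patient_encs, window_days)
            consumed.update(id(e) for e in episode.encounter_refs)
            if stopper is not None:
                audit.disqualified.append(stopper)
                consumed.add(id(stopper))
            categorize_episode(episode)
            if person_days is not None:
                _fill_duration_components(episode, person_days)
            episodes.append(episode)
    logger.info(
        "built %d episodes (%d rejected starts, %d disqualified encounters)",
        len(episodes),
        len(audit.rejected_starts),
        len(audit.disqualified),
    )
    return episodes, audit
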