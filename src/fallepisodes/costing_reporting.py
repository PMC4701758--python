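"""Episode costing, CPI adjustment, and cohort summary tables.

Two costs are attached to every episode, both expressed in 2009 US dollars
via the medical-care component of the consumer price index:

* **total cost** — the paid amount of *every* claim line of the patient
  whose service dates overlap the episode window, fall-related or not (an
  upper bound on the true cost of the injury);
* **attributable cost** — the same sum restricted to lines carrying at
  least one fall-related diagnosis code (a lower bound).

A claim overlapping an episode boundary contributes its full paid amount
(no per-day proration).  Summaries reproduce the cohort descriptive tables:
episode counts, hierarchical mutually exclusive proportions by service
setting and by injury, rates per 1000 person-years from enrollment spans,
and mean durations, setting-specific day counts and costs conditional on
episode type.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_model import ClaimLine, EnrollmentSpan, expand_to_person_days
from .code_config import CodeTables, classify_diagnosis, default_code_tables
from .encounter_engine import annotate_fall_incidents, classify_encounters
from .episode_engine import Episode, build_episodes
from .setting_detection import flag_ed_activity, flag_inpatient_snf

__all__ = [
    "compute_episode_costs",
    "inpatient_snf_cost_share",
    "person_years",
    "summarize",
    "outpatient_ed_share",
    "run_pipeline",
    "episodes_to_frame",
]

logger = logging.getLogger("fallepisodes")


def _line_is_fall_related(line: ClaimLine, tables: CodeTables) -> bool:
    return any(classify_diagnosis(dx, tables) for dx in line.diagnosis_codes)


def compute_episode_costs(
    episode: Episode, claims: Sequence[ClaimLine], tables: CodeTables
) -> Episode:
    """Fill total and attributable cost (2009 USD) on an episode.

    Total sums the CPI-adjusted paid amount of all the patient's claim
    lines whose [start, end] service span overlaps the episode window;
    attributable restricts to lines with >= 1 fall-related diagnosis
    (primary or secondary, E codes included).
    """
    total = attributable = 0.0
    for line in claims:
        if line.patient_id != episode.patient_id:
            continue
        if line.start_date > episode.end_date or line.end_date < episode.start_date:
            continue
        adjusted = line.paid_amount * tables.cpi_factor(line.payment_year)
        total += adjusted
        if _line_is_fall_related(line, tables):
            attributable += adjusted
    episode.total_cost_2009 = total
    episode.attributable_cost_2009 = attributable
    return episode


def inpatient_snf_cost_share(
    episode: Episode, claims: Sequence[ClaimLine], tables: CodeTables
) -> float:
    """Share of episode total cost on inpatient/SNF facility claims.

    Facility lines are those whose setting hint marks an inpatient or SNF
    stay; physician lines billed with inpatient E&M CPT codes from a
    non-facility source count toward the denominator only.
    """
    num = den = 0.0
    for line in claims:
        if line.patient_id != episode.patient_id:
            continue
        if line.start_date > episode.end_date or line.end_date < episode.start_date:
            continue
        adjusted = line.paid_amount * tables.cpi_factor(line.payment_year)
        den += adjusted
        if line.setting_hint in ("inpatient", "snf"):
            num += adjusted
    if den == 0:
        logger.warning("episode has zero total cost; share undefined")
        return float("nan")
    return num / den


def person_years(
    enrollment: Sequence[EnrollmentSpan],
    study_window: tuple[date, date] | None = None,
) -> float:
    """Total person-years of coverage, optionally clipped to a window.

    Spans are inclusive on both ends; a year is 365.25 days.
    """
    total_days = 0
    for span in enrollment:
        s, e = span.span_start, span.span_end
        if study_window is not None:
            s, e = max(s, study_window[0]), min(e, study_window[1])
        if e >= s:
            total_days += (e - s).days + 1
    return total_days / 365.25


def summarize(
    episodes: Sequence[Episode],
    enrollment: Sequence[EnrollmentSpan],
    group_by: str = "service_category",
    study_window: tuple[date, date] | None = None,
    patient_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cohort summary by service category, injury category, medical group,
    or overall.

    Returns one row per group with episode counts, the proportion of all
    episodes (service/injury groups are hierarchical and mutually
    exclusive, so their proportions partition 100%), episodes per 1000
    person-years, and mean duration/day-count/cost statistics conditional
    on episode type.  ``group_by="medical_group"`` stratifies by a
    patient-id -> group mapping, with each stratum standardized by its own
    person-years; the other groupings use cohort person-years.
    """
    if group_by not in ("service_category", "injury_category", "medical_group", "none"):
        raise ValueError(f"unsupported group_by {group_by!r}")
    rows = []
    group_py: dict[str, float] | None = None
    if group_by == "none":
        groups = {"all": list(episodes)}
        order = ["all"]
    elif group_by == "medical_group":
        if patient_groups is None:
            raise ValueError("group_by='medical_group' requires patient_groups")
        order = sorted(set(patient_groups.values()))
        groups = {g: [] for g in order}
        for ep in episodes:
            groups[patient_groups[ep.patient_id]].append(ep)
        group_py = {g: 0.0 for g in order}
        for span in enrollment:
            g = patient_groups.get(span.patient_id)
            if g is not None:
                group_py[g] += person_years([span], study_window)
    else:
        order = list(
            SERVICE_ORDER if group_by == "service_category" else INJURY_ORDER
        )
        groups = {g: [] for g in order}
        for ep in episodes:
            groups[getattr(ep, group_by)].append(ep)
    cohort_py = person_years(enrollment, study_window)
    if cohort_py == 0:
        logger.warning("zero person-years; standardized rates undefined")
    n_all = len(episodes)
    for g in order:
        eps = groups[g]
        n = len(eps)
        py = group_py[g] if group_py is not None else cohort_py
        if py == 0 and group_py is not None:
            logger.warning("zero person-years in group %s; rate undefined", g)

        def mean(attr: str) -> float:
            vals = [getattr(e, attr) for e in eps if getattr(e, attr) is not None]
            return float(np.mean(vals)) if vals else float("nan")

        rows.append(
            {
                "group": g,
                "n_episodes": n,
                "proportion": n / n_all if n_all else float("nan"),
                "episodes_per_1000py": 1000.0 * n / py if py > 0 else float("nan"),
                "mean_duration_days": mean("duration_days"),
                "mean_ed_days": mean("ed_days"),
                "mean_inpatient_days": mean("inpatient_days"),
                "mean_snf_days": mean("snf_days"),
                "mean_total_cost_2009": mean("total_cost_2009"),
                "mean_attributable_cost_2009": mean("attributable_cost_2009"),
            }
        )
    return pd.DataFrame(rows)


SERVICE_ORDER = ("inpatient_or_snf", "ed_visit", "outpatient_only")
INJURY_ORDER = ("hip_fracture", "non_hip_fracture", "non_fracture_injury")


def outpatient_ed_share(summary) -> float:
    """Among episodes without inpatient/SNF care, the share involving ED.

    ``summary`` is either the DataFrame from :func:`summarize`
    (group_by="service_category") or a mapping with keys ``ed_visit`` and
    ``outpatient_only`` holding proportions.  Returns ed / (ed + out);
    NaN with a warning when both are zero.
    """
    if isinstance(summary, pd.DataFrame):
        lookup = dict(zip(summary["group"], summary["proportion"]))
        ed = float(lookup.get("ed_visit", 0.0))
        out = float(lookup.get("outpatient_only", 0.0))
    else:
        ed = float(summary["ed_visit"])
        out = float(summary["outpatient_only"])
    if ed + out == 0:
        logger.warning("no non-inpatient episodes; outpatient ED share undefined")
        return float("nan")
    return ed / (ed + out)


def run_pipeline(
    claims: Sequence[ClaimLine],
    tables: CodeTables | None = None,
    connection_window: int = 10,
    episode_window: int = 30,
    lookback: int = 30,
    compute_costs: bool = True,
):
    """Run the full four-step grouper on validated claim lines.

    Returns ``(episodes, encounters, person_days, audit)``.  Steps: expand
    to person-days; flag settings and ED activity; annotate fall incidents;
    classify encounters (10-day connection window); build, categorize and
    cost episodes (30-day lookback and chaining windows).
    """
    if tables is None:
        tables = default_code_tables()
    person_days = expand_to_person_days(claims)
    logger.info("expanded %d claims to %d person-days", len(claims), len(person_days))
    flag_inpatient_snf(person_days, claims, tables)
    flag_ed_activity(person_days, claims, tables)
    annotate_fall_incidents(person_days, claims, tables)
    encounters = classify_encounters(person_days, tables, window_days=connection_window)
    logger.info("classified %d encounters", len(encounters))
    episodes, audit = build_episodes(
        encounters,
        lookback_days=lookback,
        window_days=episode_window,
        person_days=person_days,
    )
    if compute_costs:
        by_patient: dict[str, list[ClaimLine]] = {}
        for c in claims:
            by_patient.setdefault(c.patient_id, []).append(c)
        for ep in episodes:
            compute_episode_costs(ep, by_patient.get(ep.patient_id, ()), tables)
    return episodes, encounters, person_days, audit


def episodes_to_frame(episodes: Sequence[Episode]) -> pd.DataFrame:
    """Flatten episodes to a table (one row per episode) for CSV output."""
    rows = []
    for ep in episodes:
        rows.append(
            {
                "patient_id": ep.patient_id,
                "start_date": ep.start_date.isoformat(),
                "end_date": ep.end_date.isoformat(),
                "duration_days": ep.duration_days,
                "episode_category": ep.episode_category,
                "service_category": ep.service_category,
                "injury_category": ep.injury_category,
                "n_encounters": len(ep.encounter_refs),
                "encounter_types": ";".join(
                    str(e.encounter_type) for e in ep.encounter_refs
                ),
                "ed_days": ep.ed_days,
                "inpatient_days": ep.inpatient_days,
                "snf_days": ep.snf_days,
                "total_cost_2009": ep.total_cost_2009,
                "attributable_cost_2009": ep.attributable_cost_2009,
            }
        )
    return pd.DataFrame(rows)
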