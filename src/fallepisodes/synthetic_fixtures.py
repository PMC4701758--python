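"""Seeded synthetic claims cohorts with planted ground-truth episodes.

The generator emulates the structure of merged fee-for-service Medicare and
Medicare Advantage claims for an older, high-fall-risk population observed
over a multi-year window: multi-day inpatient and SNF facility claims with
primary and secondary ICD-9-CM diagnoses, single-day ED lines with
emergency-room revenue-center codes, outpatient repair/imaging lines,
accidental-fall E codes, background non-fall "noise" claims, and paid
amounts by setting.  Each planted episode is recorded in a ground-truth
table (boundaries, category labels, planted fall-claim cost), so grouper
output can be checked exactly — including how a chain must truncate when a
disqualifying external-cause code is injected into it.

Defaults mirror the study conditions the tool targets: 500 patients over
2005-2009, an episode rate of 0.144 per person-year, an injury mixture of
18% hip fracture / 35% other fracture / 47% non-fracture, and a service
mixture of 43% inpatient-or-SNF / 49% ED / 8% outpatient-only.  Planted
episodes are separated by a minimum 61-day quiet gap so that, absent
injected disqualifiers, recovery must be exact.

The generator emits the same normalized CSV schema the loader consumes,
so the pipeline is closed under its own fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "SpecError", "generate_cohort", "figure3_fixture"]


class SpecError(ValueError):
    """Raised for an internally inconsistent cohort specification."""


_INJURY_DX = {
    "hip_fracture": [("hip", "820.21"), ("hip", "820.8")],
    "other_fracture": [
        ("humerus", "812.21"),
        ("radius_ulna", "813.42"),
        ("ankle", "824.8"),
        ("hand", "815.00"),
        ("femur_tibia_fibula", "823.20"),
        ("clavicle", "810.02"),
        ("pelvis", "808.2"),
    ],
    "head_injury": [("head_trauma", "850.0"), ("head_fracture", "801.25")],
    "joint_dislocation": [
        ("shoulder", "831.00"),
        ("knee", "836.50"),
        ("wrist", "833.00"),
    ],
    "fall_ecode": [(None, None)],
}

_FALL_ECODES = ["E888.9", "E885.9", "E880.9", "E884.9", "E886.0"]
_DISQUALIFYING_ECODE = "E812.0"  # motor-vehicle traffic accident
_REPAIR_BY_SITE = {
    "hip": "27236",
    "humerus": "24505",
    "radius_ulna": "25505",
    "ankle": "27766",
    "hand": "26605",
    "femur_tibia_fibula": "27506",
    "clavicle": "23505",
    "pelvis": "27216",
    "shoulder": "23650",
    "knee": "27550",
    "wrist": "25660",
}
_NOISE_DX = ["250.00", "401.9", "428.0", "496", "715.90"]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_patients: int = 500
    study_start: date = date(2005, 1, 1)
    study_end: date = date(2009, 12, 31)
    #: planted episode rate per person-year of enrollment
    fall_rate_per_py: float = 0.144
    injury_mix: dict[str, float] = field(
        default_factory=lambda: {
            "hip_fracture": 0.18,
            "other_fracture": 0.35,
            "head_injury": 0.05,
            "joint_dislocation": 0.05,
            "fall_ecode": 0.37,
        }
    )
    service_mix: dict[str, float] = field(
        default_factory=lambda: {
            "inpatient_or_snf": 0.43,
            "ed_visit": 0.49,
            "outpatient_only": 0.08,
        }
    )
    #: minimum quiet days between one planted episode's end and the next's
    #: start; must exceed the grouper's episode window for exact recovery
    min_gap_days: int = 61
    extra_gap_mean_days: float = 120.0
    #: probability an ED/outpatient episode has 2-3 encounter days
    multi_encounter_prob: float = 0.3
    #: day gaps between encounters inside a planted multi-encounter episode;
    #: kept above the 10-day connection window so each day stays a distinct
    #: encounter, and at or below 30 so episode chaining must join them
    encounter_gap_range: tuple[int, int] = (11, 25)
    #: probability an ED/outpatient episode's first day carries a
    #: site-specific repair procedure
    repair_prob: float = 0.3
    inpatient_cost_mean: float = 20000.0
    ed_cost_mean: float = 1100.0
    outpatient_cost_mean: float = 700.0
    cost_sigma: float = 0.5
    #: probability a multi-encounter planted episode gets a disqualifying
    #: E code injected on an interior encounter day
    disqualify_rate: float = 0.0
    #: background non-fall claims per person-year
    noise_rate_per_py: float = 4.0
    seed: int = 0
    episode_window_days: int = 30  # the grouper window recovery assumes

    def validate(self) -> None:
        for name, mix in (("injury_mix", self.injury_mix), ("service_mix", self.service_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise SpecError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise SpecError(f"{name} probabilities must be nonnegative")
        if self.min_gap_days <= self.episode_window_days:
            raise SpecError(
                "min_gap_days must exceed the episode window "
                f"({self.min_gap_days} <= {self.episode_window_days}): planted "
                "episodes would merge"
            )
        lo, hi = self.encounter_gap_range
        if not (10 < lo <= hi <= self.episode_window_days):
            raise SpecError(
                "encounter_gap_range must lie in (10, episode_window]: gaps "
                "<= 10 days merge into one chained encounter, gaps > the "
                "episode window break the planted episode apart"
            )
        if self.study_end < self.study_start:
            raise SpecError("study_end before study_start")
        if self.fall_rate_per_py < 0 or self.noise_rate_per_py < 0:
            raise SpecError("rates must be nonnegative")


def _draw(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]


def _cost(rng: np.random.Generator, mean: float, sigma: float) -> float:
    # lognormal with the requested mean
    mu = np.log(mean) - sigma**2 / 2
    return float(np.round(rng.lognormal(mu, sigma), 2))


class _Emitter:
    def __init__(self) -> None:
        self.rows: list[dict] = []
        self._n = 0

    def claim(
        self,
        pid: str,
        start: date,
        end: date,
        dx: Sequence[str],
        paid: float,
        *,
        proc: str | None = None,
        betos: str | None = None,
        pos: str | None = None,
        revenue: str | None = None,
        setting: str = "other",
    ) -> None:
        self._n += 1
        self.rows.append(
            {
                "patient_id": pid,
                "claim_id": f"{pid}-C{self._n:05d}",
                "start_date": start.isoformat(),
                "end_date": end.isoformat(),
                "diagnosis_codes": ";".join(dx),
                "procedure_code": proc or "",
                "betos_code": betos or "",
                "pos_code": pos or "",
                "revenue_code": revenue or "",
                "setting_hint": setting,
                "paid_amount": paid,
                "payment_year": start.year,
            }
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _plant_episode(
    em: _Emitter,
    rng: np.random.Generator,
    spec: CohortSpec,
    pid: str,
    start: date,
    cpi: dict[int, float],
) -> dict:
    """Emit the claims of one planted episode; return its ground truth."""
    injury = _draw(rng, spec.injury_mix)
    service = _draw(rng, spec.service_mix)
    if injury == "head_injury":
        # head codes are only interpretable in the inpatient/SNF setting
        service = "inpatient_or_snf"
    site, dx_code = _INJURY_DX[injury][rng.integers(len(_INJURY_DX[injury]))]
    ecode = _FALL_ECODES[rng.integers(len(_FALL_ECODES))]
    adj = lambda amount, d: amount * cpi[d.year]

    planted_cost = 0.0
    if service == "inpatient_or_snf":
        inp_len = int(rng.integers(3, 9))
        snf_len = int(rng.integers(0, 15)) if rng.random() < 0.5 else 0
        dx = [dx_code, ecode] if dx_code else [ecode]
        paid = _cost(rng, spec.inpatient_cost_mean, spec.cost_sigma)
        inp_end = start + timedelta(days=inp_len - 1)
        em.claim(pid, start, inp_end, dx, paid, setting="inpatient")
        planted_cost += adj(paid, start)
        end = inp_end
        if snf_len:
            snf_start = inp_end + timedelta(days=1)
            end = inp_end + timedelta(days=snf_len)
            paid_snf = _cost(rng, spec.inpatient_cost_mean / 2, spec.cost_sigma)
            em.claim(pid, snf_start, end, dx, paid_snf, setting="snf")
            planted_cost += adj(paid_snf, snf_start)
        if rng.random() < 0.5:  # ED line on admission day
            paid_ed = _cost(rng, spec.ed_cost_mean, spec.cost_sigma)
            em.claim(pid, start, start, dx, paid_ed, revenue="0450")
            planted_cost += adj(paid_ed, start)
        category = 1
        n_encounter_days = (end - start).days + 1
        truth_end = end
        disqualified = False
    else:
        n_days = 1
        if rng.random() < spec.multi_encounter_prob:
            n_days = int(rng.integers(2, 4))
        gaps = [
            int(rng.integers(spec.encounter_gap_range[0], spec.encounter_gap_range[1] + 1))
            for _ in range(n_days - 1)
        ]
        days = [start]
        for g in gaps:
            days.append(days[-1] + timedelta(days=g))
        with_repair = rng.random() < spec.repair_prob and site is not None
        inject_at = None
        if n_days >= 2 and rng.random() < spec.disqualify_rate:
            inject_at = int(rng.integers(1, n_days))
        mean = spec.ed_cost_mean if service == "ed_visit" else spec.outpatient_cost_mean
        types = []
        for i, d in enumerate(days):
            dx = [dx_code, ecode] if dx_code else [ecode]
            if inject_at is not None and i == inject_at:
                dx = dx + [_DISQUALIFYING_ECODE]
            paid = _cost(rng, mean, spec.cost_sigma)
            kw: dict = {}
            if service == "ed_visit":
                kw["revenue"] = "0450"
                kw["pos"] = "23"
            else:
                kw["pos"] = "11"
            proc = None
            if with_repair and i == 0:
                proc = _REPAIR_BY_SITE[site]
            em.claim(pid, d, d, dx, paid, proc=proc, **kw)
            types.append(3 if (with_repair and i == 0) else 6)
            if inject_at is None or i < inject_at:
                planted_cost += adj(paid, d)
        if inject_at is not None:
            kept = list(range(inject_at))
            disqualified = True
        else:
            kept = list(range(n_days))
            disqualified = False
        truth_end = days[kept[-1]]
        category = min(types[i] for i in kept)
        n_encounter_days = len(kept)
        end = days[-1]  # physical extent, for spacing the next episode

    injury_cat = (
        "hip_fracture"
        if injury == "hip_fracture"
        else "non_hip_fracture"
        if injury == "other_fracture"
        else "non_fracture_injury"
    )
    return {
        "patient_id": pid,
        "start_date": start.isoformat(),
        "end_date": truth_end.isoformat(),
        "episode_category": category,
        "service_category": service,
        "injury_category": injury_cat,
        "n_encounters": n_encounter_days,
        "planted_cost_2009": round(planted_cost, 2),
        "disqualified_truncation": disqualified,
        "_physical_end": end,
    }


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (claims, enrollment, ground-truth episodes) tables.

    Output is deterministic for a fixed ``spec.seed``.  Claims use the
    normalized delimited schema of :mod:`fallepisodes.claims_model`; the
    ground-truth table lists each planted episode's boundaries, category
    labels, encounter count and CPI-adjusted planted fall-claim cost, with
    boundaries already truncated where a disqualifying code was injected.
    """
    spec.validate()
    # default CPI deflators; imported lazily to keep the generator emitting
    # costs consistent with the pipeline's default tables
    from .code_config import default_code_tables

    cpi = default_code_tables().cpi_factors
    for y in range(spec.study_start.year, spec.study_end.year + 1):
        cpi.setdefault(y, 1.0)
    em = _Emitter()
    truth_rows: list[dict] = []
    enroll_rows: list[dict] = []
    window_days = (spec.study_end - spec.study_start).days + 1
    years = window_days / 365.25

    for p in range(spec.n_patients):
        # independent substreams per patient, and for planting vs noise, so
        # changing the noise rate never perturbs the planted episodes
        rng = np.random.default_rng([spec.seed, 2 * p])
        noise_rng = np.random.default_rng([spec.seed, 2 * p + 1])
        pid = f"P{p + 1:05d}"
        enroll_rows.append(
            {
                "patient_id": pid,
                "span_start": spec.study_start.isoformat(),
                "span_end": spec.study_end.isoformat(),
            }
        )
        # planted fall episodes, spaced by a quiet gap
        n_episodes = rng.poisson(spec.fall_rate_per_py * years)
        cursor = spec.study_start + timedelta(days=int(rng.integers(0, 90)))
        for _ in range(n_episodes):
            # an episode needs headroom for its span (<= ~60 days)
            if cursor > spec.study_end - timedelta(days=70):
                break
            truth = _plant_episode(em, rng, spec, pid, cursor, cpi)
            physical_end = truth.pop("_physical_end")
            truth_rows.append(truth)
            gap = spec.min_gap_days + int(
                rng.exponential(spec.extra_gap_mean_days)
            )
            cursor = physical_end + timedelta(days=gap)
        # background non-fall noise claims
        n_noise = noise_rng.poisson(spec.noise_rate_per_py * years)
        offsets = sorted(int(o) for o in noise_rng.integers(0, window_days, n_noise)) if n_noise else []
        for o in offsets:
            d = spec.study_start + timedelta(days=o)
            em.claim(
                pid,
                d,
                d,
                [_NOISE_DX[noise_rng.integers(len(_NOISE_DX))]],
                _cost(noise_rng, 120.0, spec.cost_sigma),
                proc="99213",
                pos="11",
            )

    claims = em.frame()
    if claims.empty:
        claims = pd.DataFrame(
            columns=[
                "patient_id", "claim_id", "start_date", "end_date",
                "diagnosis_codes", "procedure_code", "betos_code", "pos_code",
                "revenue_code", "setting_hint", "paid_amount", "payment_year",
            ]
        )
    enrollment = pd.DataFrame(enroll_rows)
    truth = pd.DataFrame(truth_rows)
    if truth.empty:
        truth = pd.DataFrame(
            columns=[
                "patient_id", "start_date", "end_date", "episode_category",
                "service_category", "injury_category", "n_encounters",
                "planted_cost_2009", "disqualified_truncation",
            ]
        )
    return claims, enrollment, truth


def figure3_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged worked-example fixture: one patient, two episodes.

    Encodes, as a claims table, the published day grid of a representative
    43-day hip-fracture episode: an inpatient stay on days 1-6 (primary
    hip-fracture diagnosis 820.21, secondary tibia/fibula fracture 823.20,
    accidental-fall E code E888.9), one SNF day (day 7), a second inpatient
    spell on days 8-14, and SNF care through day 43; ED-related chest and
    musculoskeletal X-ray lines early in the stay; facility (inpatient+SNF)
    paid amounts summing to $38,854 of a $41,963 episode total.  Four
    months earlier the patient has a single-day outpatient visit with a
    shoulder X-ray and a same-level-tripping fall code (E885.9), which the
    grouper must recover as a separate one-day episode.

    The split of the two printed facility/total sums across individual
    claim lines is not published; this fixture's per-line amounts are one
    consistent choice.
    """
    em = _Emitter()
    pid = "FIG3"
    day1 = date(2009, 6, 1)

    def day(n: int) -> date:
        return day1 + timedelta(days=n - 1)

    # earlier episode: single-day outpatient shoulder imaging, 4 months prior
    em.claim(
        pid, date(2009, 2, 1), date(2009, 2, 1), ["E885.9"], 171.0,
        proc="73030", pos="11",
    )
    # inpatient days 1-6
    em.claim(
        pid, day(1), day(6), ["820.21", "823.20", "E888.9"], 14000.0,
        setting="inpatient",
    )
    # SNF day 7
    em.claim(pid, day(7), day(7), ["820.21", "E888.9"], 854.0, setting="snf")
    # inpatient days 8-14
    em.claim(pid, day(8), day(14), ["820.21"], 12000.0, setting="inpatient")
    # SNF days 15-43
    em.claim(pid, day(15), day(43), ["820.21"], 12000.0, setting="snf")
    # ED-related imaging early in the stay (BETOS imaging criterion)
    em.claim(pid, day(1), day(1), [], 409.0, proc="71020", betos="I1B")
    em.claim(pid, day(2), day(2), [], 350.0, proc="73510", betos="I2B")
    # inpatient physician visit billed from the carrier file
    em.claim(pid, day(3), day(3), ["820.21"], 2350.0, proc="99232")

    enrollment = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "span_start": "2009-01-01",
                "span_end": "2009-12-31",
            }
        ]
    )
    return em.frame(), enrollment
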