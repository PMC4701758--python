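# fallepisodes

An episode-of-care grouper for fall-related injuries in Medicare-style
administrative claims.

Falls are the leading cause of injury in older adults, but tracking actual
falls requires chart review or patient self-report. Claims data offer a
cheaper alternative — if the scattered line items a fall generates
(ambulance, ED visit, X-rays, fracture repair, hospitalization, skilled
nursing care) can be reassembled into coherent *episodes of care* whose
duration is driven by the actual pattern of claims rather than a fixed
window. `fallepisodes` implements a four-step grouper that does exactly
that for normalized fee-for-service Medicare / Medicare Advantage line
items, for researchers studying the frequency, duration and cost of
fall-related injuries.

## The algorithm

Working entirely at the granularity of patient calendar days:

1. **Setting detection.** Each person-day is flagged as inpatient and/or
   skilled-nursing-facility (SNF) care (from a setting indicator or
   inpatient/SNF evaluation-and-management CPT codes, e.g. 99217–99223 and
   99301–99313), and as involving emergency-department (ED) activity
   (BETOS code M3 or I\*, ED place-of-service, or revenue-center code
   0450–0459/0981).
2. **Fall-incident identification.** All primary and secondary ICD-9-CM
   diagnoses, accidental-fall external-cause codes (E880–E888), and
   repair/cast/splint/imaging CPT codes are classified into five injury
   types: hip fracture, other fracture, head injury, joint dislocation,
   and fall E codes.
3. **Encounter typing.** Every day of fall-related care is assigned one of
   six hierarchical encounter types, from *(1) inpatient fall-related
   injury* (inpatient/SNF day with a primary fall diagnosis) down to
   *(6) fall-related use of medical care* (an isolated fall E code).
   Ambiguous outpatient evidence (a diagnosis or site-specific imaging) is
   chained forward: any later day within 10 days carrying a diagnosis on
   the same body site or injury type is connected, repeatedly, and the
   connected days form one *(5) possible outpatient fall-related injury*.
4. **Episode construction.** An encounter starts a new episode when no
   encounter of any type ends in the preceding 30 days, it carries no
   disqualifying E code (mechanisms incompatible with a fall, e.g.
   motor-vehicle accidents), and — if it involves SNF — it also involves
   ED/inpatient care and does not continue a prior SNF residence.
   Subsequent encounters within 30 days of the latest connected encounter
   are chained on; a disqualifying encounter stops the chain. Episodes get
   three mutually exclusive hierarchical labels (certainty category 1–6,
   service setting, injury type) and two costs in CPI-adjusted 2009
   dollars: **total** (all claims during the episode, an upper bound) and
   **attributable** (claims carrying a fall-related diagnosis, a lower
   bound).

All code lists are table-driven (`fallepisodes export-codes` writes them as
editable CSVs; `--codes-dir` loads replacements), and a seeded synthetic
cohort generator with planted ground-truth episodes makes the whole
pipeline testable without any data access.

## Worked example

The packaged fixture encodes, as a claims table, the day grid of a
representative 43-day hip-fracture episode — inpatient days 1–6 (primary
diagnosis 820.21, secondary 823.20, fall code E888.9), one SNF day, a
second week-long inpatient spell, then SNF through day 43, with ED-related
chest/musculoskeletal X-rays early in the stay — plus a single-day
outpatient fall visit (shoulder X-ray, E885.9) four months earlier.

```python
from fallepisodes import (figure3_fixture, load_claims, run_pipeline,
                          inpatient_snf_cost_share, default_code_tables)

claims_df, enrollment_df = figure3_fixture()
claims = load_claims(claims_df)
episodes, encounters, person_days, audit = run_pipeline(claims)
for ep in episodes:
    print(ep.start_date, ep.duration_days, ep.episode_category,
          ep.injury_category, round(ep.total_cost_2009))
major = max(episodes, key=lambda e: e.duration_days)
print(round(inpatient_snf_cost_share(major, claims, default_code_tables()), 3))
```

prints

```
2009-02-01 1 6 non_fracture_injury 171
2009-06-01 43 1 hip_fracture 41963
0.926
```

Two episodes are recovered. The major one spans 43 days, is categorized
*(1) inpatient fall-related injury* with injury category *hip fracture*,
costs $41,963 in total, and 92.6% (≈93%, $38,854/$41,963) of that total
sits on inpatient/SNF facility claims. The earlier one-day outpatient
visit forms its own category-6 episode, as it should: nothing connects it
to care four months later.

The same pipeline is available from the shell:

```bash
fallepisodes fixture fig3 --out fix/
fallepisodes run --claims fix/claims.csv --enrollment fix/enrollment.csv --out out/
fallepisodes report --episodes out/episodes.csv --enrollment fix/enrollment.csv
fallepisodes simulate --seed 3 --out sim/   # synthetic cohort + ground truth
```

## Documentation

See `docs/methods.md` for the model, its assumptions, the default code
tables and their provenance, the synthetic-data generator's design, and
known limitations.
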