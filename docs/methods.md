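# Methods

## Scope and data model

`fallepisodes` operates on a *normalized* line-item schema: one row per
billed service line with patient id, inclusive service dates, an ordered
ICD-9-CM diagnosis list (first position = primary; E codes anywhere), an
optional HCPCS/CPT-4 procedure code, BETOS / place-of-service /
revenue-center codes, a `setting_hint` in {inpatient, snf, other, unknown},
a paid amount and its payment year. Upstream extraction and merging of
fee-for-service files (MedPAR, Carrier, Outpatient) and plan-specific
Medicare Advantage exports is deliberately out of scope; `setting_hint`
abstracts both the MedPAR short-stay/long-stay/SNF indicator and whatever
plan-specific logic identified inpatient care upstream.

All temporal reasoning is in whole calendar days, inclusive on both ends.
A multi-day claim contributes its diagnoses and setting to *every* covered
day: no within-claim date attribution exists in claims data, and the union
is the conservative choice that makes a day-by-day grid of an inpatient
stay reconstructible from facility claims.

## Encounter typing (the six-level hierarchy)

Each day with fall-related evidence is assigned at most one encounter type;
lower numbers mean higher certainty, and on a day eligible for several
types the lowest wins. The decision order is fixed: inpatient/SNF test →
site-specific repair test → general cast/splint test → forward chaining →
E-code fallback.

Design choices where the flow leaves room:

- **Primary vs. secondary.** An inpatient/SNF day with both a primary and
  a secondary fall diagnosis (possibly of different injury types) yields a
  single type-1 encounter whose `injury_types` records every contributing
  type. Episode categorization only needs the best type and the injury
  set, so nothing is lost by merging at the day level.
- **Chaining keys.** "A diagnosis code on the same body site or type of
  injury" is implemented as key overlap, where a day contributes a key per
  eligible injury *type* and per body *site* (for E codes the mechanism
  category plays the site role). Site keys let an ankle fracture connect
  to ankle imaging; type keys let two dislocations at different sites
  connect. Imaging contributes site keys and can seed a chain, but only a
  day with a diagnosis can extend one; a seed day that does connect is
  included in the encounter's member days.
- **Window boundaries.** "Up to 10 days after" means a strictly later day
  with (later − current) ≤ 10: day 10 connects, day 11 does not. A
  connection window of 0 is accepted and degenerates to no multi-day
  encounters, which is a useful limit check; negative windows are errors.
- **Eligibility matrix.** Hip and other fractures participate at types
  1–4; other fractures at body sites carrying an imaging list (by default
  navicular/scaphoid, hand, ankle — the sites where an outpatient X-ray
  trail is diagnostic) and joint dislocations at 1–5; head injuries at 1–2
  only, because outpatient head-injury codes are too unreliable outside
  the inpatient/SNF setting; fall E codes at 1–6.
- Days that reach the end of the flow without qualifying (e.g. an isolated
  outpatient humerus-fracture day with no repair, cast or E code) form no
  encounter.

The chained result provably equals the connected components of the
day-pair graph (later day within window, keys overlap, later day has a
diagnosis); the test suite checks this against a brute-force transitive
closure on randomized instances.

## Episode construction

- **Lookback.** Inclusive at 30 days, measured from the candidate's start
  date against every prior encounter's end date: a prior encounter ending
  exactly 30 days before blocks a start (the candidate may be the tail of
  that earlier episode). Chaining is likewise inclusive: a subsequent
  encounter starting exactly 30 days after the latest connected
  encounter's end still connects. Both windows are exposed
  (`--lookback`, `--episode-window`) for robustness checks.
- **SNF entry rule.** An encounter involving SNF starts an episode only if
  it also involves ED or inpatient care and the most recent prior
  encounter — at any lag, since the lookback already guarantees a 30-day
  quiet gap — does not involve SNF. This blocks "new" episodes that merely
  continue a SNF residence.
- **Disqualifying E codes** (default: the transport-accident chapter
  E800–E848) mark mechanisms incompatible with a fall as primary cause.
  Such an encounter never starts an episode, and meeting one stops a chain
  and excludes it from any episode; encounters after it may start fresh if
  they independently satisfy the start rules (in practice the disqualified
  encounter itself blocks starts for the next 30 days via the lookback).
- An encounter rejected as a start (e.g. SNF-only) is not dropped: it can
  still be chained into an episode begun by an earlier valid start, and
  otherwise appears in the audit output.
- **Duration components.** Within an episode window, a day that is both
  inpatient and SNF counts as inpatient; the ED-day count is independent
  of concurrent stays, because ED activity during a hospitalization
  (visible only through ED-related line items, since ED visits ending in
  admission are not billed separately) is real ED use.

## Costing

Costs are adjusted to 2009 dollars with annual multiplicative deflators
from the medical-care component of the CPI-U (defaults cover 2005–2009;
2009 ≡ 1.0). Total cost sums every claim line of the patient whose service
span overlaps the episode; attributable cost restricts to lines carrying at
least one fall-related diagnosis (primary or secondary, E codes included;
V-code aftercare is deliberately not captured). A claim overlapping the
episode boundary contributes its full amount — claims data give no
defensible per-day proration, and this keeps the total an honest upper
bound. The facility cost share used in the worked example counts lines
whose `setting_hint` is inpatient/snf, i.e. facility claims; physician
E&M lines billed from carrier files with inpatient CPT codes land in the
denominator only.

Person-years come from enrollment spans (overlaps merged, days inclusive,
365.25 days/year), optionally clipped to a study window. Summary tables
group episodes by service setting or injury with hierarchical mutually
exclusive rows, so proportions partition 100%.

## Default code tables

The inpatient/SNF CPT ranges (99217–99223, 99231–99236, 99238–99239,
99251–99255, 99261–99263, 99291–99292, 99356–99357; 99301–99313,
99315–99316, 99318) and the three ED criteria (BETOS M3/I\*, ED place of
service 23, revenue 0450–0459/0981) are complete. The injury, procedure
and disqualifying lists are **structural defaults** built from the
ICD-9-CM chapter layout — hip fracture 820.x; other fractures 800–829
minus skull and hip, split by reported body site with navicular (814.01,
814.11) carved out of the carpal range by longest-prefix matching; head
injury 800–804 and 850–854; dislocations 831/832/833/836; fall E codes
E880–E888 by mechanism — plus small, representative CPT sets for
site-specific repairs, casting/splinting (29000–29599 by prefix) and
site-mapped X-rays. They are clinically reasonable but not authoritative;
every list is editable CSV (`export-codes` / `--codes-dir`) and
substituting a study-specific list changes no code. Matching is by prefix
on normalized codes (decimal stripped; revenue codes zero-padded to four
digits per UB-04), accommodating 3–5-digit dialects across plans.

## Synthetic cohorts

The generator plants ground-truth episodes and emits the same normalized
CSV schema the loader consumes. Defaults describe the conditions the tool
targets: 500 patients enrolled continuously over 2005–2009, 0.144 planted
episodes per person-year, injury mixture 18% hip fracture / 35% other
fracture / 5% head injury / 5% dislocation / 37% E-code-only, service
mixture 43% inpatient-or-SNF / 49% ED / 8% outpatient-only, and four
background non-fall claims per person-year. Planted structure:

- inpatient episodes are a 3–8-day facility claim (primary injury
  diagnosis + fall E code), optionally followed by a contiguous SNF claim
  and accompanied by an admission-day ED line;
- ED/outpatient episodes are one to three single-day claims, each with an
  injury diagnosis and a fall E code, gapped 11–25 days — above the 10-day
  connection window (so each day stays its own encounter) and inside the
  30-day episode window (so chaining must join them); a configurable
  fraction carry a site-specific repair on the first day;
- head-injury episodes are forced inpatient, since outpatient head codes
  are undetectable by design;
- episodes are separated by a quiet gap of at least 61 days, so recovery
  must be exact: count, boundaries, and all three category labels;
- optional injection of a motor-vehicle E code on an interior encounter
  day lets tests verify the chain-stop rule against generator bookkeeping;
- noise claims are office visits with chronic-disease diagnoses: they add
  total cost but can never add encounters or attributable cost.

Per-patient, per-purpose RNG substreams make output byte-identical for a
fixed seed and keep planted episodes invariant under noise-rate changes.

What the generator does *not* emulate — and what passing recovery tests
therefore do not show — includes coding error and E-code under-reporting,
episodes closer together than the episode window, claims spanning episode
boundaries, realistic heavy-tailed Medicare cost distributions, and
enrollment churn. The generator validates its own feasibility constraints
(mixtures sum to one, gaps compatible with the windows) and rejects
infeasible specifications.

## Problem sizes in the shipped checks

The packaged worked example is one patient and eight claims and runs in
milliseconds. Oracle-equivalence checks use 1,000 randomized instances of
up to 50 days (chaining) and 1,000 cohorts of up to 10 encounters
(episode construction); parameter recovery uses 500 patients over five
years (~10,000 claim lines) plus a 200-patient cohort with disqualifier
injection. The full suite completes in a few seconds on one CPU.

## Known limitations

- The five-type injury classification and the encounter eligibility matrix
  encode clinical judgment; with the default (structural) code lists the
  pipeline is faithful in mechanism but not authoritative in content.
- Whether a fall caused the episode or was itself the manifestation of an
  acute illness cannot be decided from claims alone.
- Costs are taken at face value per line; capitated-plan shadow pricing and
  charge-to-cost conversion are out of scope.
- ICD-9-CM only; ICD-10 use requires replacing the diagnosis tables.
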