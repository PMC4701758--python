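"""Steps 2-3: incident annotation and six-type encounter classification."""

import random
from datetime import date, timedelta

import pytest

from fallepisodes import (
    annotate_fall_incidents,
    classify_encounters,
    expand_to_person_days,
    flag_inpatient_snf,
)

from conftest import make_claim, make_person_day

ORIGIN = date(2007, 3, 1)


def iso(offset: int) -> str:
    return (ORIGIN + timedelta(days=offset)).isoformat()


def annotate(claims, tables):
    pdays = expand_to_person_days(claims)
    flag_inpatient_snf(pdays, claims, tables)
    annotate_fall_incidents(pdays, claims, tables)
    return pdays


# -- step 2: annotation ---------------------------------------------------


def test_primary_hip_dx_annotated(tables):
    pdays = annotate([make_claim(dx=["820.21", "E888.9"])], tables)
    d = pdays[("P1", ORIGIN)]
    assert ("hip_fracture", "hip") in d.injury_sites
    assert d.has_primary_fall_dx.get("hip_fracture")
    assert not d.has_secondary_fall_dx.get("hip_fracture")
    assert d.has_secondary_fall_dx.get("fall_ecode")


def test_secondary_ecode_only(tables):
    pdays = annotate([make_claim(dx=["250.00", "E888.9"])], tables)
    d = pdays[("P1", ORIGIN)]
    assert d.injury_flags == {"fall_ecode"}
    assert not d.has_primary_fall_dx


def test_multi_day_claim_propagates_dx_to_all_days(tables):
    pdays = annotate([make_claim(dx=["820.21"], end=iso(5))], tables)
    assert all(("hip_fracture", "hip") in p.injury_sites for p in pdays.values())


def test_no_fall_codes_no_flags(tables):
    pdays = annotate([make_claim(dx=["250.00"], proc="99213")], tables)
    d = pdays[("P1", ORIGIN)]
    assert not d.injury_sites and not d.procedure_classes


def test_disqualifying_ecode_flagged(tables):
    pdays = annotate([make_claim(dx=["820.21", "E810.0"])], tables)
    assert pdays[("P1", ORIGIN)].has_disqualifying_ecode


# -- step 3: the classification flow --------------------------------------


def classify(claims, tables, window=10):
    return classify_encounters(annotate(claims, tables), tables, window)


def test_inpatient_primary_hip_is_type_1(tables):
    encs = classify(
        [make_claim(dx=["820.21"], setting="inpatient")], tables
    )
    assert [e.encounter_type for e in encs] == [1]
    assert encs[0].involves_inpatient


def test_inpatient_secondary_dx_is_type_2(tables):
    encs = classify(
        [make_claim(dx=["250.00", "820.21"], setting="inpatient")], tables
    )
    assert [e.encounter_type for e in encs] == [2]


def test_outpatient_repair_with_dx_is_type_3_without_is_type_4(tables):
    hip_repair = sorted(tables.repair_cpt["hip"])[0]
    encs = classify([make_claim(dx=["820.21"], proc=hip_repair)], tables)
    assert [e.encounter_type for e in encs] == [3]
    encs = classify([make_claim(proc=hip_repair)], tables)
    assert [e.encounter_type for e in encs] == [4]


def test_cast_with_appropriate_dx_is_type_3_head_injury_not(tables):
    encs = classify([make_claim(dx=["824.8"], proc="29405")], tables)
    assert [e.encounter_type for e in encs] == [3]
    # cast with head-injury dx only: not cast-appropriate, no encounter
    encs = classify([make_claim(dx=["850.0"], proc="29405")], tables)
    assert encs == []


def test_outpatient_head_injury_yields_no_encounter(tables):
    """Head codes are examined only in the inpatient/SNF setting."""
    assert classify([make_claim(dx=["850.0"])], tables) == []
    encs = classify([make_claim(dx=["850.0"], setting="inpatient")], tables)
    assert [e.encounter_type for e in encs] == [1]


def test_isolated_ecode_day_is_type_6(tables):
    encs = classify([make_claim(dx=["E888.9"])], tables)
    assert [e.encounter_type for e in encs] == [6]


def test_type5_chain_from_imaging_seed(tables):
    """Knee imaging, same-site dx 7 days later, another 9 days after that:
    one type-5 encounter with three member days."""
    knee_imaging = sorted(tables.imaging_cpt["knee"])[0]
    claims = [
        make_claim(cid="C1", start=iso(0), proc=knee_imaging),
        make_claim(cid="C2", start=iso(7), dx=["836.50"]),
        make_claim(cid="C3", start=iso(16), dx=["836.50"]),
    ]
    encs = classify(claims, tables)
    assert [e.encounter_type for e in encs] == [5]
    assert len(encs[0].member_days) == 3
    assert encs[0].start_date == ORIGIN and encs[0].end_date == ORIGIN + timedelta(16)


def test_type5_window_boundary_day_10_connects_day_11_does_not(tables):
    def chain(gap):
        claims = [
            make_claim(cid="C1", start=iso(0), dx=["836.50"]),
            make_claim(cid="C2", start=iso(gap), dx=["836.50"]),
        ]
        return classify(claims, tables)

    assert [e.encounter_type for e in chain(10)] == [5]
    # beyond the window: two isolated dislocation days, no E code -> nothing
    assert chain(11) == []


def test_window_zero_eliminates_multiday_type5(tables):
    claims = [
        make_claim(cid="C1", start=iso(0), dx=["836.50", "E888.9"]),
        make_claim(cid="C2", start=iso(5), dx=["836.50", "E888.9"]),
    ]
    encs = classify(claims, tables, window=0)
    assert [e.encounter_type for e in encs] == [6, 6]


def test_imaging_cannot_extend_a_chain(tables):
    """A later imaging-only day is not 'a day with a diagnosis code'."""
    knee_imaging = sorted(tables.imaging_cpt["knee"])[0]
    claims = [
        make_claim(cid="C1", start=iso(0), dx=["836.50"]),
        make_claim(cid="C2", start=iso(7), proc=knee_imaging),
    ]
    assert classify(claims, tables) == []


def test_plain_fracture_dx_cannot_chain(tables):
    """Humerus fractures carry no imaging list: eligible for types 1-4 only."""
    claims = [
        make_claim(cid="C1", start=iso(0), dx=["812.21"]),
        make_claim(cid="C2", start=iso(7), dx=["812.21"]),
    ]
    assert classify(claims, tables) == []


def test_hierarchy_best_type_wins_on_one_day(tables):
    """Inpatient day with primary fall dx and a repair code: type 1."""
    hip_repair = sorted(tables.repair_cpt["hip"])[0]
    encs = classify(
        [make_claim(dx=["820.21"], proc=hip_repair, setting="inpatient")], tables
    )
    assert [e.encounter_type for e in encs] == [1]


def test_mixed_primary_secondary_types_merge_at_type_1(tables):
    """A day with primary hip dx and secondary dislocation dx yields one
    type-1 encounter recording both injury types."""
    encs = classify(
        [make_claim(dx=["820.21", "831.00"], setting="inpatient")], tables
    )
    (e,) = encs
    assert e.encounter_type == 1
    assert e.injury_types == {"hip_fracture", "joint_dislocation"}


def test_no_type_3_to_6_encounter_contains_inpatient_day(tables):
    claims = [
        make_claim(cid="C1", start=iso(0), dx=["836.50"]),
        make_claim(cid="C2", start=iso(5), dx=["836.50"], setting="inpatient"),
        make_claim(cid="C3", start=iso(9), dx=["836.50"]),
    ]
    encs = classify(claims, tables)
    for e in encs:
        if e.encounter_type >= 3:
            assert not e.involves_inpatient and not e.involves_snf
    # the inpatient day became its own type-1/2 encounter
    assert any(e.encounter_type in (1, 2) for e in encs)


def test_negative_window_rejected(tables):
    with pytest.raises(ValueError):
        classify_encounters({}, tables, window_days=-1)


def test_output_independent_of_input_order(tables):
    rnd = random.Random(7)
    claims = [
        make_claim(cid=f"C{i}", pid=f"P{i % 3}", start=iso(rnd.randrange(30)),
                   dx=[rnd.choice(["836.50", "E888.9", "820.21", "250.00"])])
        for i in range(40)
    ]
    def run(cs):
        return [
            (e.patient_id, e.encounter_type, e.start_date, tuple(e.member_days))
            for e in classify(cs, tables)
        ]
    shuffled = claims[:]
    rnd.shuffle(shuffled)
    assert run(claims) == run(shuffled)


# -- brute-force transitive-closure oracle ---------------------------------


def _oracle_components(days, window):
    """Independent oracle: reachability closure over day pairs.

    ``days`` is a list of (offset, dx_keys, img_keys); a pair (i, j) is
    directly connected when 0 < offset_j - offset_i <= window and the later
    day's diagnosis keys intersect the earlier day's full key set.  Type-5
    encounters are the undirected closure components of size >= 2.
    """
    n = len(days)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        oi, dxi, imi = days[i]
        for j in range(n):
            oj, dxj, _ = days[j]
            gap = oj - oi
            if 0 < gap <= window and (dxi | imi) & dxj:
                adj[i][j] = adj[j][i] = True
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(m for m in range(n) if adj[k][m] and m not in comp)
        seen |= comp
        if len(comp) >= 2:
            comps.append(frozenset(days[k][0] for k in comp))
    return set(comps)


DX_POOL = [
    ("836.50", {("type", "joint_dislocation"), ("site", "knee")}),
    ("831.00", {("type", "joint_dislocation"), ("site", "shoulder")}),
    ("824.8", {("type", "other_fracture"), ("site", "ankle")}),
    ("815.00", {("type", "other_fracture"), ("site", "hand")}),
    ("E888.9", {("type", "fall_ecode"), ("site", "other_and_unspecified")}),
    ("E885.9", {("type", "fall_ecode"), ("site", "same_level_tripping")}),
]
IMG_POOL = [("knee", {("site", "knee")}), ("hand", {("site", "hand")}),
            ("ankle", {("site", "ankle")}), ("shoulder", {("site", "shoulder")})]
IMG_CPT = {"knee": "73560", "hand": "73120", "ankle": "73600", "shoulder": "73020"}


def random_instance(rnd, max_days=50, span=60):
    offsets = sorted(rnd.sample(range(span), rnd.randint(2, min(max_days, span))))
    days = []
    for o in offsets:
        dx_keys, img_keys, dx, img = set(), set(), [], []
        for code, keys in DX_POOL:
            if rnd.random() < 0.25:
                dx.append(code)
                dx_keys |= keys
        if not dx and rnd.random() < 0.5:
            site, keys = rnd.choice(IMG_POOL)
            img.append(IMG_CPT[site])
            img_keys |= keys
        days.append((o, dx_keys, img_keys, dx, img))
    return days


def run_grouper_on_instance(days, tables, window=10):
    claims = []
    for i, (o, _dk, _ik, dx, img) in enumerate(days):
        claims.append(
            make_claim(cid=f"C{i}", start=iso(o), dx=dx, proc=img[0] if img else None)
        )
    encs = classify(claims, tables, window)
    return {
        frozenset((d - ORIGIN).days for d in e.member_days)
        for e in encs
        if e.encounter_type == 5
    }


@pytest.mark.parametrize("trial_seed", [0, 1, 2])
def test_type5_chaining_equals_transitive_closure(tables, trial_seed):
    rnd = random.Random(trial_seed)
    for _ in range(60):
        days = random_instance(rnd)
        expected = _oracle_components(
            [(o, dk, ik) for o, dk, ik, _, _ in days], 10
        )
        got = run_grouper_on_instance(days, tables)
        assert got == expected
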