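"""Configurable code tables for fall-related injury classification.

Every classification decision the episode grouper makes — which CPT codes
mark inpatient or skilled-nursing-facility (SNF) care, which ICD-9-CM
diagnosis codes count as fall-related injuries, which external-cause (E)
codes disqualify an encounter, which procedures are repairs, casts/splints,
or imaging — is table-driven through :class:`CodeTables`.  Swapping in a
different code list changes no pipeline code.

The CPT ranges for inpatient/SNF settings and the emergency-department
criteria (BETOS, place-of-service, revenue-center codes) are standard and
complete.  The injury, procedure, and disqualifying-E-code lists ship as
**structural defaults** derived from the ICD-9-CM chapter layout (fractures
800–829, intracranial injury 850–854, dislocations 830–839, accidental falls
E880–E888, transport accidents E800–E848): they are clinically reasonable
starting points, clearly intended to be replaced with a study-specific list
via :meth:`CodeTables.from_dir`.

Code matching is by prefix on *normalized* codes: ICD-9-CM codes have the
decimal point stripped ("820.21" -> "82021"; E codes keep the leading "E"),
and revenue-center codes are zero-padded to 4 digits per UB-04 convention
("450" -> "0450").  This accommodates the 3-, 4- and 5-digit dialects seen
across plans.  Within one injury type the *longest* matching site pattern
wins, so a specific site (navicular, 814.01) can be carved out of a broader
range (hand/wrist, 814–817).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CodeTables",
    "CodeConfigError",
    "ClassificationError",
    "INJURY_TYPES",
    "ECODE_CATEGORIES",
    "default_code_tables",
    "classify_diagnosis",
    "is_disqualifying_ecode",
    "classify_procedure",
    "normalize_dx",
    "normalize_revenue",
]

#: the five injury types of the grouper's classification
INJURY_TYPES = (
    "hip_fracture",
    "other_fracture",
    "head_injury",
    "joint_dislocation",
    "fall_ecode",
)

#: accidental-fall E-code mechanism categories
ECODE_CATEGORIES = (
    "stairs_or_steps",
    "ladders_or_scaffolding",
    "building_or_structure",
    "hole",
    "one_level_to_another",
    "same_level_tripping",
    "same_level_pushed",
    "other_and_unspecified",
)


class CodeConfigError(ValueError):
    """Raised for invalid or incomplete code-table configuration."""


class ClassificationError(ValueError):
    """Raised when a code string is malformed beyond classification."""


def normalize_dx(code: str) -> str:
    """Normalize an ICD-9-CM code: strip the decimal point, uppercase.

    "820.21" -> "82021"; "e885.9" -> "E8859".
    """
    if code is None:
        raise ClassificationError("diagnosis code is None")
    out = str(code).strip().upper().replace(".", "")
    if not out:
        raise ClassificationError("empty diagnosis code")
    return out


def normalize_revenue(code: str) -> str:
    """Normalize a revenue-center code to 4 digits ("450" -> "0450")."""
    out = str(code).strip()
    if out and out.isdigit() and len(out) < 4:
        out = out.zfill(4)
    return out


def _expand_range(lo: int, hi: int) -> set[str]:
    """Expand an inclusive numeric CPT range into 5-digit code strings."""
    return {f"{c:05d}" for c in range(lo, hi + 1)}


def _prefix_match(code: str, patterns: Iterable[str]) -> str | None:
    """Return the longest pattern that is a prefix of ``code``, or None."""
    best = None
    for pat in patterns:
        if code.startswith(pat) and (best is None or len(pat) > len(best)):
            best = pat
    return best


@dataclass
class CodeTables:
    """All configurable classification lists used by the pipeline.

    Attributes hold either plain sets of codes, mappings from a label
    (body site or E-code category) to pattern lists, or the annual CPI
    deflator table.  See :func:`default_code_tables` for defaults.
    """

    inpatient_cpt: set[str] = field(default_factory=set)
    snf_cpt: set[str] = field(default_factory=set)
    ed_betos_exact: set[str] = field(default_factory=set)
    ed_betos_prefixes: list[str] = field(default_factory=list)
    ed_pos_codes: set[str] = field(default_factory=set)
    ed_revenue_codes: set[str] = field(default_factory=set)
    # injury_type -> body_site -> list of normalized dx patterns
    injury_dx: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # e_category -> list of normalized E-code patterns (view into injury_dx
    # is NOT used; fall_ecodes is the authoritative mechanism table)
    fall_ecodes: dict[str, list[str]] = field(default_factory=dict)
    disqualifying_ecodes: list[str] = field(default_factory=list)
    repair_cpt: dict[str, set[str]] = field(default_factory=dict)
    cast_splint_cpt: list[str] = field(default_factory=list)
    imaging_cpt: dict[str, set[str]] = field(default_factory=dict)
    cast_appropriate_dx: list[str] = field(default_factory=list)
    cpi_factors: dict[int, float] = field(default_factory=dict)

    # -- derived helpers -------------------------------------------------

    def type5_fracture_sites(self) -> set[str]:
        """Body sites of "other fracture" eligible for multi-day chaining.

        These are the fracture sites that carry an associated imaging-code
        list; fractures elsewhere are only accepted as encounter types 1-4.
        """
        return set(self.imaging_cpt) & set(self.injury_dx.get("other_fracture", {}))

    def imaging_site(self, cpt_code: str | None) -> str | None:
        if not cpt_code:
            return None
        code = str(cpt_code).strip().upper()
        for site, codes in self.imaging_cpt.items():
            if code in codes:
                return site
        return None

    def repair_site(self, cpt_code: str | None) -> str | None:
        if not cpt_code:
            return None
        code = str(cpt_code).strip().upper()
        for site, codes in self.repair_cpt.items():
            if code in codes:
                return site
        return None

    def is_cast_splint(self, cpt_code: str | None) -> bool:
        if not cpt_code:
            return False
        code = str(cpt_code).strip().upper()
        return _prefix_match(code, self.cast_splint_cpt) is not None

    def cpi_factor(self, year: int) -> float:
        try:
            return self.cpi_factors[int(year)]
        except KeyError:
            raise CodeConfigError(
                f"no CPI deflator configured for payment year {year}"
            ) from None

    def validate(self) -> None:
        """Check structural invariants; raise :class:`CodeConfigError`."""
        for etype, sites in self.injury_dx.items():
            seen: dict[str, str] = {}
            for site, patterns in sites.items():
                for pat in patterns:
                    if not pat or not (pat[0].isdigit() or pat[0] == "E"):
                        raise CodeConfigError(
                            f"malformed pattern {pat!r} in injury_dx[{etype}][{site}]"
                        )
                    # longest-match-wins needs unambiguous equal-length patterns
                    if pat in seen and seen[pat] != site:
                        raise CodeConfigError(
                            f"pattern {pat!r} maps to two sites within {etype}: "
                            f"{seen[pat]} and {site}"
                        )
                    seen[pat] = site
        for cat in self.fall_ecodes:
            for pat in self.fall_ecodes[cat]:
                if not pat.startswith("E"):
                    raise CodeConfigError(f"fall E-code pattern {pat!r} must start with E")
        for pat in self.disqualifying_ecodes:
            if not pat.startswith("E"):
                raise CodeConfigError(
                    f"disqualifying E-code pattern {pat!r} must start with E"
                )

    # -- serialization ---------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write all tables as CSV files plus a manifest.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        for f in fields(self):
            name = f.name
            value = getattr(self, name)
            fname = f"{name}.csv"
            manifest[name] = fname
            if name == "cpi_factors":
                df = pd.DataFrame(
                    sorted(value.items()), columns=["year", "factor"]
                )
            elif name == "injury_dx":
                rows = [
                    (etype, site, pat)
                    for etype, sites in value.items()
                    for site, pats in sites.items()
                    for pat in pats
                ]
                df = pd.DataFrame(rows, columns=["injury_type", "site", "pattern"])
            elif isinstance(value, dict):
                rows = [(k, c) for k, codes in value.items() for c in sorted(codes)]
                df = pd.DataFrame(rows, columns=["label", "code"])
            else:
                df = pd.DataFrame({"code": sorted(value)})
            df.to_csv(path / fname, index=False)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "CodeTables":
        """Load tables previously written by :meth:`to_dir`."""
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        kwargs: dict = {}
        proto = cls()
        for f in fields(cls):
            name = f.name
            df = pd.read_csv(path / manifest[name], dtype=str)
            if name == "cpi_factors":
                kwargs[name] = {
                    int(y): float(v) for y, v in zip(df["year"], df["factor"])
                }
            elif name == "injury_dx":
                inj: dict[str, dict[str, list[str]]] = {}
                for etype, site, pat in df.itertuples(index=False):
                    inj.setdefault(etype, {}).setdefault(site, []).append(pat)
                kwargs[name] = inj
            elif "label" in df.columns:
                proto_val = getattr(proto, name)
                inner_set = not isinstance(proto_val, dict) or all(
                    isinstance(v, set) for v in proto_val.values()
                )
                mapping: dict[str, object] = {}
                for label, code in df.itertuples(index=False):
                    if name in ("repair_cpt", "imaging_cpt"):
                        mapping.setdefault(label, set()).add(code)
                    else:
                        mapping.setdefault(label, []).append(code)
                if name in ("fall_ecodes",):
                    mapping = {k: sorted(v) for k, v in mapping.items()}
                kwargs[name] = mapping
            else:
                codes = [] if df.empty else list(df["code"])
                if isinstance(getattr(proto, name), set):
                    kwargs[name] = set(codes)
                else:
                    kwargs[name] = sorted(codes)
            del name
        tables = cls(**kwargs)
        tables.validate()
        return tables

    def __eq__(self, other: object) -> bool:  # order-insensitive comparison
        if not isinstance(other, CodeTables):
            return NotImplemented

        def norm(v):
            if isinstance(v, dict):
                return {k: norm(x) for k, x in sorted(v.items())}
            if isinstance(v, (set, frozenset, list, tuple)):
                return tuple(sorted(v))
            return v

        return all(
            norm(getattr(self, f.name)) == norm(getattr(other, f.name))
            for f in fields(self)
        )


def default_code_tables() -> CodeTables:
    """Build the default :class:`CodeTables`.

    The inpatient/SNF CPT evaluation-and-management ranges and the three
    emergency-department criteria are complete as published for this
    algorithm.  The injury diagnosis, procedure and disqualifying-E-code
    lists are defaults derived from ICD-9-CM chapter structure — replace
    with study-specific lists when available.
    """
    inpatient_cpt = (
        _expand_range(99217, 99223)
        | _expand_range(99231, 99236)
        | _expand_range(99238, 99239)
        | _expand_range(99251, 99255)
        | _expand_range(99261, 99263)
        | _expand_range(99291, 99292)
        | _expand_range(99356, 99357)
    )
    snf_cpt = _expand_range(99301, 99313) | _expand_range(99315, 99316) | {"99318"}

    injury_dx = {
        "hip_fracture": {"hip": ["820"]},
        "other_fracture": {
            # fracture chapter 800-829 minus skull (800-804, head injury)
            # and hip (820); split by the body sites the grouper reports
            "pelvis": ["808"],
            "rib": ["8070", "8071"],
            "other_trunk": ["8072", "8073", "8074", "8075", "8076", "8078", "8079", "809"],
            "spine": ["805", "806"],
            "clavicle": ["810"],
            "scapula": ["811"],
            "humerus": ["812"],
            "radius_ulna": ["813"],
            # navicular (scaphoid) carved out of the carpal range by
            # longest-prefix-wins
            "navicular": ["81401", "81411"],
            "hand": ["814", "815", "816", "817"],
            "femur_tibia_fibula": ["821", "823"],
            "patella": ["822"],
            "ankle": ["824"],
            "foot": ["825", "826"],
            "other_limb": ["818", "819", "827", "828", "829"],
        },
        "head_injury": {
            "head_fracture": ["800", "801", "802", "803", "804"],
            "head_trauma": ["850", "851", "852", "853", "854"],
        },
        "joint_dislocation": {
            "shoulder": ["831"],
            "elbow": ["832"],
            "wrist": ["833"],
            "knee": ["836"],
        },
    }

    fall_ecodes = {
        "stairs_or_steps": ["E880"],
        "ladders_or_scaffolding": ["E881"],
        "building_or_structure": ["E882"],
        "hole": ["E883"],
        "one_level_to_another": ["E884"],
        "same_level_tripping": ["E885"],
        "same_level_pushed": ["E886"],
        "other_and_unspecified": ["E887", "E888"],
    }

    # mechanisms incompatible with a fall as primary cause: the transport
    # accident chapter (railway E800-E807, motor vehicle E810-E825, other
    # road E826-E829, water E830-E838, air/space E840-E845, other vehicle
    # E846-E848).  Default list; replace with a study-specific table.
    disqualifying_ecodes = ["E80", "E81", "E82", "E83"] + [
        f"E{c}" for c in range(840, 849)
    ]

    repair_cpt = {
        "hip": {"27125", "27130", "27235", "27236", "27244", "27245"},
        "femur_tibia_fibula": {"27506", "27507", "27756", "27758", "27759"},
        "pelvis": {"27216", "27217", "27218"},
        "rib": {"21811", "21812", "21813"},
        "clavicle": {"23505", "23515"},
        "humerus": {"23605", "24505", "24515"},
        "radius_ulna": {"25505", "25515", "25565", "25574"},
        "navicular": {"25622", "25624", "25628"},
        "hand": {"26605", "26615", "26725", "26735"},
        "patella": {"27520", "27524"},
        "ankle": {"27766", "27792", "27814"},
        "foot": {"28415", "28420", "28435", "28445"},
        "spine": {"22305", "22310", "22315"},
        # closed/open treatment of dislocations
        "shoulder": {"23650", "23655", "23660"},
        "elbow": {"24600", "24605", "24615"},
        "wrist": {"25660", "25670", "25675", "25680", "25690"},
        "knee": {"27550", "27552", "27556"},
    }

    # application of casts, splints and strapping (29000-29599), by prefix
    cast_splint_cpt = ["290", "291", "292", "293", "294", "295"]

    imaging_cpt = {
        "navicular": {"73100", "73110"},
        "hand": {"73120", "73130", "73140"},
        "ankle": {"73600", "73610"},
        "shoulder": {"73020", "73030"},
        "elbow": {"73070", "73080"},
        "wrist": {"73115"},
        "knee": {"73560", "73562", "73564", "73565"},
    }

    # a cast or splint is appropriate for any fracture or dislocation other
    # than skull fractures / intracranial injury
    cast_appropriate_dx = (
        ["805", "806", "807", "808", "809"]
        + ["81", "82"]
        + [f"83{d}" for d in range(10)]
    )

    # medical-care component of the CPI-U, expressed as multiplicative
    # deflators to 2009 USD (2009 factor exactly 1.0)
    cpi_factors = {2005: 1.162, 2006: 1.117, 2007: 1.070, 2008: 1.032, 2009: 1.0}

    tables = CodeTables(
        inpatient_cpt=inpatient_cpt,
        snf_cpt=snf_cpt,
        ed_betos_exact={"M3"},
        ed_betos_prefixes=["I"],
        ed_pos_codes={"23"},
        ed_revenue_codes={f"{c:04d}" for c in range(450, 460)} | {"0981"},
        injury_dx=injury_dx,
        fall_ecodes=fall_ecodes,
        disqualifying_ecodes=disqualifying_ecodes,
        repair_cpt=repair_cpt,
        cast_splint_cpt=cast_splint_cpt,
        imaging_cpt=imaging_cpt,
        cast_appropriate_dx=cast_appropriate_dx,
        cpi_factors=cpi_factors,
    )
    tables.validate()
    return tables


def classify_diagnosis(dx_code: str, tables: CodeTables) -> set[tuple[str, str]]:
    """Classify an ICD-9-CM code into (injury_type, body_site) pairs.

    Returns the empty set for non-injury codes.  Accidental-fall E codes
    map to ("fall_ecode", <mechanism category>).  Within one injury type
    the longest matching site pattern wins, so no code maps to two sites
    of the same type.
    """
    code = normalize_dx(dx_code)
    out: set[tuple[str, str]] = set()
    if code.startswith("E"):
        best_site, best_len = None, -1
        for cat, pats in tables.fall_ecodes.items():
            m = _prefix_match(code, pats)
            if m is not None and len(m) > best_len:
                best_site, best_len = cat, len(m)
        if best_site is not None:
            out.add(("fall_ecode", best_site))
        return out
    for etype, sites in tables.injury_dx.items():
        best_site, best_len = None, -1
        for site, pats in sites.items():
            m = _prefix_match(code, pats)
            if m is not None and len(m) > best_len:
                best_site, best_len = site, len(m)
        if best_site is not None:
            out.add((etype, best_site))
    return out


def is_disqualifying_ecode(dx_code: str, tables: CodeTables) -> bool:
    """True iff the code is an E code on the disqualifying-mechanism list."""
    try:
        code = normalize_dx(dx_code)
    except ClassificationError:
        return False
    if not code.startswith("E"):
        return False
    return _prefix_match(code, tables.disqualifying_ecodes) is not None


def classify_procedure(
    cpt_code: str | None, tables: CodeTables
) -> tuple[str, str | None]:
    """Classify a CPT/HCPCS code as (procedure_class, body_site or None).

    procedure_class is one of "repair", "cast_splint", "imaging", "other";
    repair and imaging carry the body site of the matched list.
    """
    if not cpt_code:
        return ("other", None)
    site = tables.repair_site(cpt_code)
    if site is not None:
        return ("repair", site)
    if tables.is_cast_splint(cpt_code):
        return ("cast_splint", None)
    site = tables.imaging_site(cpt_code)
    if site is not None:
        return ("imaging", site)
    return ("other", None)
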