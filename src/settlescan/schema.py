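"""Canonical survey data model.

One row per household (georeferenced, with raw dwelling/WASH attributes) and
one row per individual (the analysis unit).  Housing deprivation and WASH
binaries are *derived*, deterministically, from the raw categorical fields:

* ``inadequate_materials`` — any of wall/roof/floor made of non-durable
  materials (UN-Habitat housing-deprivation criterion);
* ``overcrowded`` — more than three household members per room;
* ``basic_water`` / ``basic_sanitation`` / ``basic_hygiene`` — facility code
  sits at rung "basic" or higher on the WHO/UNICEF JMP service ladder for
  that service.

The material vocabulary and the JMP ladder lookup ship as editable CSV tables
under ``settlescan/data`` so the durable/non-durable partition and the ladder
encoding can be adapted without touching code.

Missing values are carried as ``pandas.NA`` in nullable dtypes and are never
imputed; :func:`filter_complete_cases` is the only place rows are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .errors import DomainError, SchemaError

# ---------------------------------------------------------------------------
# column dictionaries

#: Raw household table columns (one row per household).
HOUSEHOLD_COLUMNS = [
    "household_id",
    "site_id",
    "lon",
    "lat",
    "wall_material",
    "roof_material",
    "floor_material",
    "n_rooms",
    "n_members",
    "indoor_cooking",
    "water_source_code",
    "sanitation_code",
    "hygiene_code",
    "water_constant_past_month",
    "head_secondary_education",
    "relatively_wealthy",
]

#: Individual roster columns (one row per person).
INDIVIDUAL_COLUMNS = ["person_id", "household_id", "under5", "female", "diarrhea_2wk"]

#: The seven model covariates, household-level by construction: every person
#: in a household shares them.  Codings are positive ("has the feature"),
#: except ``inadequate_materials`` which codes the deprivation itself.
MODEL_COVARIATES = [
    "indoor_cooking",
    "inadequate_materials",
    "water_constant",
    "basic_hygiene",
    "basic_sanitation",
    "head_secondary_education",
    "relatively_wealthy",
]

OUTCOME = "diarrhea_2wk"

#: Outcome + 7 covariates: a person enters a model only with valid answers to
#: all eight.
ANALYSIS_VARIABLES = [OUTCOME] + MODEL_COVARIATES

DERIVED_FLAGS = [
    "inadequate_materials",
    "overcrowded",
    "basic_water",
    "basic_sanitation",
    "basic_hygiene",
]

_BOOL_HH_COLUMNS = [
    "indoor_cooking",
    "water_constant_past_month",
    "head_secondary_education",
    "relatively_wealthy",
]
_BOOL_IND_COLUMNS = ["under5", "female", "diarrhea_2wk"]


# ---------------------------------------------------------------------------
# lookup tables

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("settlescan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class MaterialVocabulary:
    """Declared material codes partitioned into durable / non-durable."""

    durable: frozenset
    non_durable: frozenset

    @property
    def codes(self) -> frozenset:
        return self.durable | self.non_durable

    @classmethod
    def packaged(cls) -> "MaterialVocabulary":
        tab = _read_packaged("materials.csv")
        return cls(
            durable=frozenset(tab.loc[tab["durable"] == 1, "code"]),
            non_durable=frozenset(tab.loc[tab["durable"] == 0, "code"]),
        )


#: JMP ladder rungs from best to worst, per service.  "Basic" and anything
#: above it classify as at-least-basic.
JMP_RUNGS = {
    "water": ["safely_managed", "basic", "limited", "unimproved", "surface"],
    "sanitation": ["safely_managed", "basic", "limited", "unimproved", "open_defecation"],
    "hygiene": ["basic", "limited", "no_facility"],
}


@dataclass(frozen=True)
class JMPLadders:
    """Facility-code → ladder-rung lookup for the three JMP services."""

    table: dict  # (service, code) -> rung

    @classmethod
    def packaged(cls) -> "JMPLadders":
        tab = _read_packaged("jmp_ladders.csv")
        return cls(table={(r.service, r.code): r.rung for r in tab.itertuples()})

    def rung(self, code: str, service: str) -> str:
        if service not in JMP_RUNGS:
            raise SchemaError(f"unknown JMP service {service!r}")
        try:
            return self.table[(service, code)]
        except KeyError:
            raise SchemaError(
                f"facility code {code!r} is not mapped on the {service} ladder"
            ) from None


_DEFAULT_VOCAB = MaterialVocabulary.packaged()
_DEFAULT_LADDERS = JMPLadders.packaged()


# ---------------------------------------------------------------------------
# domain types

@dataclass
class StudySite:
    """A study settlement: identifier, name and WGS84 boundary polygon.

    ``boundary`` is stored in lon/lat; metric operations project it through a
    site-centered transverse Mercator (see :mod:`settlescan.spatial`), which
    ``crs_note`` records.
    """

    site_id: str
    name: str
    boundary: Polygon
    crs_note: str = "local spherical transverse Mercator centered on the site centroid"

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise SchemaError(f"site {self.site_id}: boundary must be simple with positive area")

    @property
    def origin(self) -> tuple:
        c = self.boundary.centroid
        return (c.x, c.y)


@dataclass
class Individual:
    person_id: str
    household_id: str
    under5: bool
    female: bool
    diarrhea_2wk: object  # bool or pd.NA


@dataclass
class Household:
    household_id: str
    site_id: str
    lon: float
    lat: float
    wall_material: str
    roof_material: str
    floor_material: str
    n_rooms: int
    n_members: int
    indoor_cooking: object
    water_source_code: str
    sanitation_code: str
    hygiene_code: str
    water_constant_past_month: object
    head_secondary_education: object
    relatively_wealthy: object
    members: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# derivations

def derive_inadequate_materials(wall, roof, floor, durable_set=None, known_codes=None):
    """True iff at least one of wall/roof/floor is made of non-durable material.

    Any missing surface code yields ``pd.NA`` (unknown adequacy), while an
    unrecognized code raises :class:`SchemaError` naming the code.
    """
    if durable_set is None:
        durable_set = _DEFAULT_VOCAB.durable
    if known_codes is None:
        known_codes = _DEFAULT_VOCAB.codes if durable_set is _DEFAULT_VOCAB.durable else None
    out = False
    missing = False
    for code in (wall, roof, floor):
        if pd.isna(code):
            missing = True
            continue
        if known_codes is not None and code not in known_codes:
            raise SchemaError(f"unknown material code {code!r}")
        if code not in durable_set:
            out = True
    if out:
        return True
    return pd.NA if missing else False


def derive_overcrowded(n_members: int, n_rooms: int):
    """True iff there are more than three members per room (strict)."""
    if pd.isna(n_members) or pd.isna(n_rooms):
        return pd.NA
    if n_rooms < 1:
        raise DomainError(f"n_rooms must be >= 1, got {n_rooms}")
    if n_members < 1:
        raise DomainError(f"n_members must be >= 1, got {n_members}")
    return n_members / n_rooms > 3


def classify_jmp_basic(facility_code, service: str, ladders: JMPLadders | None = None):
    """True iff the facility code sits at rung "basic" or better on the service ladder."""
    if ladders is None:
        ladders = _DEFAULT_LADDERS
    if pd.isna(facility_code):
        return pd.NA
    rungs = JMP_RUNGS[service] if service in JMP_RUNGS else None
    rung = ladders.rung(facility_code, service)
    return rungs.index(rung) <= rungs.index("basic")


def derive_flags(households: pd.DataFrame, vocab: MaterialVocabulary | None = None,
                 ladders: JMPLadders | None = None) -> pd.DataFrame:
    """Compute the five derived binaries for every household row.

    Pure function of the raw fields; returns a DataFrame indexed like the
    input with nullable-boolean columns ``inadequate_materials, overcrowded,
    basic_water, basic_sanitation, basic_hygiene``.
    """
    vocab = vocab or _DEFAULT_VOCAB
    ladders = ladders or _DEFAULT_LADDERS
    out = pd.DataFrame(index=households.index)
    out["inadequate_materials"] = [
        derive_inadequate_materials(w, r, f, vocab.durable, vocab.codes)
        for w, r, f in zip(
            households["wall_material"], households["roof_material"], households["floor_material"]
        )
    ]
    out["overcrowded"] = [
        derive_overcrowded(m, r)
        for m, r in zip(households["n_members"], households["n_rooms"])
    ]
    for flag, col, service in [
        ("basic_water", "water_source_code", "water"),
        ("basic_sanitation", "sanitation_code", "sanitation"),
        ("basic_hygiene", "hygiene_code", "hygiene"),
    ]:
        out[flag] = [classify_jmp_basic(c, service, ladders) for c in households[col]]
    return out.astype("boolean")


# ---------------------------------------------------------------------------
# expansion & complete cases

def expand_to_individuals(households: pd.DataFrame, individuals: pd.DataFrame,
                          flags: pd.DataFrame | None = None,
                          extra_flags: tuple = ()) -> pd.DataFrame:
    """One analysis row per person, inheriting household-level covariates.

    Output columns: identifiers (person_id, household_id, site_id), person
    attributes (under5, female), the outcome, and the seven model covariates.
    Row count equals the roster length.  ``extra_flags`` may name additional
    derived flags (e.g. ``basic_water``, ``overcrowded``) to carry along as
    screening candidates beyond the canonical eight variables.
    """
    extra = list(extra_flags)
    if individuals.empty or households.empty:
        return pd.DataFrame(
            columns=["person_id", "household_id", "site_id", "under5", "female"]
            + ANALYSIS_VARIABLES + extra
        )
    if flags is None:
        flags = derive_flags(households)
    hh = households[["household_id", "site_id", "indoor_cooking",
                     "water_constant_past_month", "head_secondary_education",
                     "relatively_wealthy"]].copy()
    hh = hh.join(flags[["inadequate_materials", "basic_sanitation", "basic_hygiene"]])
    hh = hh.join(flags[[f for f in extra if f in flags.columns]])
    hh = hh.rename(columns={"water_constant_past_month": "water_constant"})
    rows = individuals.merge(hh, on="household_id", how="left", validate="many_to_one")
    cols = ["person_id", "household_id", "site_id", "under5", "female"] + ANALYSIS_VARIABLES
    rows = rows[cols + extra]
    for c in ["under5", "female"] + ANALYSIS_VARIABLES + extra:
        rows[c] = rows[c].astype("boolean")
    return rows


def filter_complete_cases(rows: pd.DataFrame, required_vars=None):
    """Keep rows with valid answers to all required variables.

    Returns ``(kept, dropped_count)``; ``kept + dropped == len(rows)``.
    """
    if required_vars is None:
        required_vars = ANALYSIS_VARIABLES
    missing_cols = [v for v in required_vars if v not in rows.columns]
    if missing_cols:
        raise SchemaError(f"rows lack required variables: {missing_cols}")
    mask = rows[list(required_vars)].notna().all(axis=1)
    kept = rows.loc[mask].copy()
    return kept, int((~mask).sum())


def validate_households(households: pd.DataFrame, individuals: pd.DataFrame,
                        sites: list | None = None) -> None:
    """Enforce the core invariants; raises :class:`SchemaError` on violation."""
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in households.columns]
    if missing:
        raise SchemaError(f"household table missing columns: {missing}")
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in individuals.columns]
    if missing:
        raise SchemaError(f"individual table missing columns: {missing}")
    if households["household_id"].duplicated().any():
        raise SchemaError("duplicate household_id")
    if individuals["person_id"].duplicated().any():
        raise SchemaError("duplicate person_id")
    unknown = set(individuals["household_id"]) - set(households["household_id"])
    if unknown:
        raise SchemaError(f"individuals reference unknown households: {sorted(unknown)[:5]}")
    sizes = individuals.groupby("household_id").size()
    declared = households.set_index("household_id")["n_members"]
    mismatched = declared.reindex(sizes.index)
    bad = sizes[sizes != mismatched]
    if len(bad):
        raise SchemaError(f"n_members mismatch for households {list(bad.index[:5])}")
    if (households["n_rooms"] < 1).any() or (households["n_members"] < 1).any():
        raise SchemaError("n_rooms and n_members must be >= 1")
    if sites:
        by_id = {s.site_id: s for s in sites}
        for site_id, grp in households.groupby("site_id"):
            site = by_id.get(site_id)
            if site is None:
                raise SchemaError(f"household references unknown site {site_id!r}")
            # small tolerance: points must fall inside (or on) the boundary
            boundary = site.boundary.buffer(1e-9)
            outside = [
                hid for hid, x, y in zip(grp["household_id"], grp["lon"], grp["lat"])
                if not boundary.contains(Point(x, y))
            ]
            if outside:
                raise SchemaError(f"households outside site {site_id}: {outside[:5]}")
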