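"""Reading and writing the survey's standard file formats.

CSV: ``households.csv`` (one row per household) and ``individuals.csv`` (one
row per person), with the column dictionary of :mod:`settlescan.schema`.
Binary answers are stored as 0/1 with empty cells for missing; extra columns
round-trip untouched.

GeoJSON (RFC 7946): household point FeatureCollections carrying the
household attributes as properties, and site boundary polygons.  write∘read
is the identity on the data model, with coordinates kept to 7 decimal places
(~1 cm).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, mapping, shape

from .errors import ParseError
from .schema import (HOUSEHOLD_COLUMNS, INDIVIDUAL_COLUMNS, StudySite,
                     _BOOL_HH_COLUMNS, _BOOL_IND_COLUMNS)

_STR_HH_COLUMNS = ["household_id", "site_id", "wall_material", "roof_material",
                   "floor_material", "water_source_code", "sanitation_code",
                   "hygiene_code"]


def _booleans_to_int(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if c in out.columns:
            out[c] = out[c].astype("boolean").astype("Int64")
    return out


def _ints_to_boolean(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[c] = df[c].astype("Int64").astype("boolean")
    return df


def write_households_csv(households: pd.DataFrame, path) -> None:
    _booleans_to_int(households, _BOOL_HH_COLUMNS).to_csv(path, index=False)


def read_households_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: "string" for c in _STR_HH_COLUMNS})
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required household columns {missing}")
    df = _ints_to_boolean(df, _BOOL_HH_COLUMNS)
    for c in ("n_rooms", "n_members"):
        df[c] = df[c].astype("Int64")
    for c in _STR_HH_COLUMNS:
        df[c] = df[c].astype(object).where(df[c].notna(), pd.NA)
    return df


def write_individuals_csv(individuals: pd.DataFrame, path) -> None:
    _booleans_to_int(individuals, _BOOL_IND_COLUMNS).to_csv(path, index=False)


def read_individuals_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": "string", "household_id": "string"})
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required individual columns {missing}")
    df = _ints_to_boolean(df, _BOOL_IND_COLUMNS)
    for c in ("person_id", "household_id"):
        df[c] = df[c].astype(object)
    return df


# ---------------------------------------------------------------------------
# GeoJSON

def _jsonable(v):
    if pd.isna(v):
        return None
    if hasattr(v, "item"):
        return v.item()
    return v


def write_households_geojson(households: pd.DataFrame, path) -> None:
    features = []
    for _, row in households.iterrows():
        props = {c: _jsonable(row[c]) for c in households.columns if c not in ("lon", "lat")}
        features.append({
            "type": "Feature",
            "geometry": mapping(Point(round(float(row["lon"]), 7), round(float(row["lat"]), 7))),
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=None))


def read_households_geojson(path) -> pd.DataFrame:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON: {exc}") from None
    if doc.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ParseError(f"{path}: feature {i} has malformed geometry: {exc}") from None
        if geom.geom_type != "Point":
            raise ParseError(f"{path}: feature {i} is {geom.geom_type}, expected Point")
        rows.append({"lon": geom.x, "lat": geom.y, **feat.get("properties", {})})
    df = pd.DataFrame(rows)
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: household features lack properties {missing}")
    df = df[[c for c in HOUSEHOLD_COLUMNS if c in df.columns]
            + [c for c in df.columns if c not in HOUSEHOLD_COLUMNS]]
    for c in _BOOL_HH_COLUMNS:
        df[c] = pd.array([None if v is None else bool(v) for v in df[c]], dtype="boolean")
    for c in ("n_rooms", "n_members"):
        df[c] = df[c].astype("Int64")
    for c in _STR_HH_COLUMNS:
        df[c] = df[c].astype(object).where(pd.notna(df[c]), pd.NA)
    return df


def write_sites_geojson(sites, path) -> None:
    features = [{
        "type": "Feature",
        "geometry": mapping(s.boundary),
        "properties": {"site_id": s.site_id, "name": s.name, "crs_note": s.crs_note},
    } for s in sites]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_sites_geojson(path) -> list:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
    sites = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ParseError(f"{path}: feature {i} is {geom.geom_type}, expected Polygon")
        props = feat.get("properties", {})
        sites.append(StudySite(
            site_id=props["site_id"], name=props.get("name", props["site_id"]),
            boundary=geom,
            crs_note=props.get("crs_note", StudySite.__dataclass_fields__["crs_note"].default),
        ))
    return sites


def write_clusters_geojson(clusters: pd.DataFrame, households: pd.DataFrame, path) -> None:
    """Cluster results as a point FeatureCollection (one feature per focal household/layer)."""
    coords = households.set_index("household_id")[["lon", "lat"]]
    features = []
    for _, row in clusters.iterrows():
        lon, lat = coords.loc[row["household_id"]]
        features.append({
            "type": "Feature",
            "geometry": mapping(Point(round(float(lon), 7), round(float(lat), 7))),
            "properties": {
                "household_id": row["household_id"], "layer": row["layer"],
                "bb": int(row["bb"]), "pseudo_p": float(row["pseudo_p"]),
                "nperm": int(row["nperm"]), "significant": bool(row["significant"]),
            },
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
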