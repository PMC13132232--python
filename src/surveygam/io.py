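"""Survey data model: observations, transects, study areas.

Tables are plain pandas DataFrames with validated schemas; the study area
is a set of shapely polygons keyed by stratum.  All coordinates are planar
(an equal-area projection) in kilometres — the pipeline is
projection-agnostic, but geographic lon/lat input is rejected outright
because every downstream step (segment lengths, strip areas, grid cells)
assumes planar km.

Observation units follow aerial waterfowl survey convention:

* ``single_male`` — a lone drake; assumed to "indicate" a nesting female,
  so it counts as one indicated pair.
* ``pair`` — a male-female pair; one indicated pair.
* ``lone_female`` — a female outside a pair; dropped from analysis.
* ``open_group`` — group of unknown sex/pair status with a recorded size;
  size-1 groups are recoded to ``single_male``, larger ones are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape
from shapely import wkt as shapely_wkt

__all__ = [
    "VALID_UNITS",
    "StudyArea",
    "SchemaError",
    "ProjectionError",
    "read_observations",
    "read_transects",
    "read_study_area",
    "read_survey",
    "write_observations",
    "write_transects",
    "write_study_area",
    "apply_inclusion_rules",
    "indicated_units",
]

VALID_UNITS = ("single_male", "pair", "lone_female", "open_group")

OBS_COLUMNS = ("survey_id", "year", "x", "y", "unit", "on_transect")
TRANSECT_COLUMNS = ("transect_id", "survey_id", "year", "stratum", "geometry", "design_width")


class SchemaError(ValueError):
    """A required column is missing or a field fails validation."""


class ProjectionError(ValueError):
    """Coordinates look geographic (lon/lat) instead of planar km."""


@dataclass
class StudyArea:
    """Planar study-area polygons keyed by stratum label (areas in km²)."""

    polygons: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stratum, poly in self.polygons.items():
            if not poly.is_valid:
                raise ValueError(f"stratum {stratum!r} polygon is invalid (self-intersecting?)")
            if poly.area <= 0:
                raise ValueError(f"stratum {stratum!r} polygon has zero area")

    @property
    def stratum_areas(self) -> dict[str, float]:
        return {s: p.area for s, p in self.polygons.items()}

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.polygons.values())

    def union(self) -> Polygon:
        from shapely.ops import unary_union

        return unary_union(list(self.polygons.values()))


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required column(s): {missing}")


def _check_finite(df: pd.DataFrame, what: str) -> None:
    if len(df) == 0:
        return
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise SchemaError(f"{what} table has non-finite coordinates")


def _check_planar(df: pd.DataFrame, what: str) -> None:
    # All rows inside the lon/lat box is strong evidence of a geographic
    # CRS in a *file being read*; planar km coordinates of a real survey
    # exceed it.  Synthetic small-extent data can opt out (assume_planar).
    _check_finite(df, what)
    if len(df) == 0:
        return
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0):
        raise ProjectionError(
            f"{what} coordinates all lie within |x|<=180, |y|<=90 — this looks "
            "like lon/lat; supply planar equal-area coordinates in km"
        )


def validate_observations(df: pd.DataFrame, year_range: tuple[int, int] = (1950, 2100)) -> pd.DataFrame:
    _require_columns(df, OBS_COLUMNS, "observation")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    bad_years = df[(df["year"] < year_range[0]) | (df["year"] > year_range[1])]
    if len(bad_years):
        raise SchemaError(f"{len(bad_years)} observation year(s) outside {year_range}")
    _check_finite(df, "observation")
    bad_units = set(df["unit"]) - set(VALID_UNITS)
    if bad_units:
        raise SchemaError(f"unknown observation unit(s): {sorted(bad_units)}")
    if "group_size" not in df.columns:
        df["group_size"] = 1
    df["group_size"] = df["group_size"].fillna(1).astype(int)
    if (df.loc[df["unit"] == "open_group", "group_size"] < 1).any():
        raise SchemaError("open_group rows must have group_size >= 1")
    df["on_transect"] = df["on_transect"].astype(bool)
    return df


def read_observations(path, assume_planar: bool = False) -> pd.DataFrame:
    """Read and validate an observation CSV (planar km coordinates).

    ``assume_planar=True`` skips the lon/lat heuristic — needed for
    small-extent synthetic data whose km coordinates fit in the lon/lat box.
    """
    df = validate_observations(pd.read_csv(path))
    if not assume_planar:
        _check_planar(df, "observation")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _parse_geometry(value) -> LineString:
    geom = shapely_wkt.loads(value) if isinstance(value, str) else value
    if not isinstance(geom, LineString):
        raise SchemaError(f"transect geometry must be a LineString, got {geom.geom_type}")
    if len(geom.coords) < 2 or geom.length <= 0:
        raise SchemaError("transect geometry needs >= 2 vertices and positive length")
    return geom


def validate_transects(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, TRANSECT_COLUMNS, "transect")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["geometry"] = [_parse_geometry(g) for g in df["geometry"]]
    if (df["design_width"] <= 0).any():
        raise SchemaError("design_width must be positive")
    coords = pd.DataFrame(
        [(c[0], c[1]) for g in df["geometry"] for c in g.coords], columns=["x", "y"]
    )
    _check_finite(coords, "transect")
    return df


def read_transects(path, assume_planar: bool = False) -> pd.DataFrame:
    """Read and validate a transect CSV; ``geometry`` is WKT LINESTRING."""
    df = validate_transects(pd.read_csv(path))
    if not assume_planar:
        coords = pd.DataFrame(
            [(c[0], c[1]) for g in df["geometry"] for c in g.coords],
            columns=["x", "y"],
        )
        _check_planar(coords, "transect")
    return df


def write_transects(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["geometry"] = [g.wkt for g in out["geometry"]]
    out.to_csv(path, index=False)


def read_study_area(path, assume_planar: bool = False) -> StudyArea:
    """Read study-area polygons from GeoJSON with a ``stratum`` property.

    The GeoJSON must already be in the planar km CRS used everywhere else;
    lon/lat-looking coordinate ranges raise :class:`ProjectionError`
    (``assume_planar=True`` to skip, for small-extent synthetic areas).
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polygons: dict[str, Polygon] = {}
    all_xy = []
    for i, feat in enumerate(feats):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise SchemaError(f"study-area feature {i} is {geom.geom_type}, expected Polygon")
        stratum = str(feat.get("properties", {}).get("stratum", f"stratum_{i}"))
        polygons[stratum] = geom
        all_xy.extend(geom.exterior.coords)
    coords = pd.DataFrame(all_xy, columns=["x", "y"])
    if assume_planar:
        _check_finite(coords, "study-area")
    else:
        _check_planar(coords, "study-area")
    return StudyArea(polygons=polygons)


def write_study_area(area: StudyArea, path) -> None:
    feats = [
        {"type": "Feature", "properties": {"stratum": s}, "geometry": mapping(p)}
        for s, p in area.polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_survey(obs_path, transect_path, area_path, assume_planar: bool = False):
    """Read the three survey inputs: observations, transects, study area."""
    return (
        read_observations(obs_path, assume_planar),
        read_transects(transect_path, assume_planar),
        read_study_area(area_path, assume_planar),
    )


def apply_inclusion_rules(obs: pd.DataFrame, return_audit: bool = False):
    """Filter raw sightings down to the analysis set.

    Rules (idempotent):

    * drop lone females (only males/pairs index breeding pairs),
    * drop off-transect observations,
    * recode ``open_group`` of size 1 to ``single_male``,
    * reject ``open_group`` of size > 1 (no defensible recode).

    Returns the filtered table; with ``return_audit=True`` also a table of
    the rows dropped or recoded and the rule responsible.
    """
    obs = validate_observations(obs)
    big_open = obs[(obs["unit"] == "open_group") & (obs["group_size"] > 1)]
    if len(big_open):
        raise SchemaError(
            f"{len(big_open)} open_group observation(s) with size > 1: no supported recode"
        )
    audit_rows = []
    drop_female = obs["unit"] == "lone_female"
    drop_off = ~obs["on_transect"]
    recode = (obs["unit"] == "open_group") & (obs["group_size"] == 1) & ~drop_off
    for idx in obs.index[drop_female]:
        audit_rows.append({"row": idx, "action": "drop", "rule": "lone_female"})
    for idx in obs.index[drop_off & ~drop_female]:
        audit_rows.append({"row": idx, "action": "drop", "rule": "off_transect"})
    for idx in obs.index[recode]:
        audit_rows.append({"row": idx, "action": "recode_single_male", "rule": "open_group_size_1"})

    kept = obs[~(drop_female | drop_off)].copy()
    kept.loc[kept["unit"] == "open_group", "unit"] = "single_male"
    kept = kept.reset_index(drop=True)
    audit = pd.DataFrame(audit_rows, columns=["row", "action", "rule"])
    return (kept, audit) if return_audit else kept


def indicated_units(obs: pd.DataFrame) -> pd.DataFrame:
    """Attach the indicated-pair count: 1 per single male, 1 per pair.

    Expects inclusion rules to have been applied already (only
    ``single_male``/``pair`` rows remain); anything else is an error.
    Indicated *birds* are ``2 ×`` the pair count, computed downstream.
    """
    bad = set(obs["unit"]) - {"single_male", "pair"}
    if bad:
        raise SchemaError(
            f"unexpected unit(s) {sorted(bad)}: run apply_inclusion_rules first"
        )
    out = obs.copy()
    out["count"] = 1
    return out
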