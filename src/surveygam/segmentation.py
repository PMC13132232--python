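"""Transect segmentation and observation-to-segment assignment.

The density model's response rows are short transect segments (1 km for a
densely sampled area, 6 km for a sparse one): each carries a centroid, a
strip area (length × effective width), and the number of indicated pairs
assigned to it.  Transects are cut into consecutive segments of the target
length with one shorter remainder at the end; remainder segments keep
their smaller area, which flows into the model's log-area offset.

Observations are assigned to the nearest segment of their own survey-year
(perpendicular distance to the segment polyline); ties break to the
lexicographically smaller segment id, and observations farther than a
configurable gate from every candidate segment are excluded and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import substring

logger = logging.getLogger(__name__)

__all__ = ["segment_transects", "assign_counts"]

_MIN_TRANSECT_KM = 0.001  # 1 m


def segment_transects(
    transects: pd.DataFrame,
    target_length: float,
    effective_width: float,
    *,
    split_sides: bool = False,
) -> pd.DataFrame:
    """Cut each transect polyline into segments of ``target_length`` km.

    Parameters
    ----------
    transects
        Validated transect table (shapely ``geometry`` column).
    target_length
        Segment length in km; the last segment of each transect is the
        (shorter) remainder.
    effective_width
        Full strip width in km for pooled counting (two half-strips, e.g.
        0.4 for 200 m per side).
    split_sides
        Emit one row per side (left/right of the line) per segment, each
        with half the effective width — the observer-specific layout.

    Returns
    -------
    DataFrame with columns ``segment_id, transect_id, survey_id, year,
    stratum, x_c, y_c, length, area, count, geometry`` (+ ``side`` when
    ``split_sides``); ``count`` starts at 0.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    if effective_width <= 0:
        raise ValueError("effective_width must be positive")
    rows = []
    for tr in transects.itertuples(index=False):
        geom = tr.geometry
        total = geom.length
        if total < _MIN_TRANSECT_KM:
            logger.warning("transect %s shorter than 1 m; skipped", tr.transect_id)
            continue
        n_full = int(np.floor(total / target_length + 1e-12))
        cuts = [i * target_length for i in range(n_full + 1)]
        if total - cuts[-1] > 1e-12:
            cuts.append(total)
        for i in range(len(cuts) - 1):
            lo, hi = cuts[i], cuts[i + 1]
            piece = substring(geom, lo, hi)
            mid = piece.interpolate(piece.length / 2.0)
            length = hi - lo
            base = {
                "segment_id": f"{tr.transect_id}:{i:03d}",
                "transect_id": tr.transect_id,
                "survey_id": tr.survey_id,
                "year": tr.year,
                "stratum": tr.stratum,
                "x_c": mid.x,
                "y_c": mid.y,
                "length": length,
                "count": 0,
                "geometry": piece,
            }
            if split_sides:
                for side in ("left", "right"):
                    row = dict(base)
                    row["segment_id"] = f"{base['segment_id']}:{side[0]}"
                    row["side"] = side
                    row["area"] = length * effective_width / 2.0
                    rows.append(row)
            else:
                base["area"] = length * effective_width
                rows.append(base)
    cols = [
        "segment_id", "transect_id", "survey_id", "year", "stratum",
        "x_c", "y_c", "length", "area", "count", "geometry",
    ]
    if split_sides:
        cols.insert(5, "side")
    return pd.DataFrame(rows, columns=cols)


def assign_counts(
    segments: pd.DataFrame,
    obs: pd.DataFrame,
    *,
    gate_km: float = 1.0,
    return_orphans: bool = False,
):
    """Sum each observation's indicated-pair count into its nearest segment.

    Observations and segments are matched within (survey_id, year) [and
    ``side`` when both tables carry one]; every segment appears in the
    output, zero counts included.  Observations with no segment within
    ``gate_km`` are dropped with a warning (returned separately with
    ``return_orphans=True``).
    """
    out = segments.copy()
    out["count"] = 0
    if "count" not in obs.columns:
        raise ValueError("observation table lacks a 'count' column; run indicated_units")
    use_side = "side" in out.columns and "side" in obs.columns
    orphans = []
    key_cols = ["survey_id", "year"] + (["side"] if use_side else [])
    seg_groups = {k: g for k, g in out.groupby(key_cols)}
    # note: itertuples renames a 'count' column (namedtuple method clash),
    # so iterate with explicit column access instead
    for idx in obs.index:
        key = tuple(obs.at[idx, c] for c in key_cols)
        grp = seg_groups.get(key)
        if grp is None or len(grp) == 0:
            orphans.append(idx)
            continue
        pt = Point(obs.at[idx, "x"], obs.at[idx, "y"])
        dists = np.array([geom.distance(pt) for geom in grp["geometry"]])
        dmin = dists.min()
        if dmin > gate_km:
            orphans.append(idx)
            continue
        near = grp.index[np.abs(dists - dmin) <= 1e-9]
        chosen = min(near, key=lambda ix: out.at[ix, "segment_id"])
        out.at[chosen, "count"] += int(obs.at[idx, "count"])
    if orphans:
        logger.warning(
            "%d observation(s) farther than %.2f km from any segment of their "
            "survey-year; excluded", len(orphans), gate_km,
        )
    if return_orphans:
        return out, obs.loc[orphans]
    return out
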