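"""Floating catchments: nearest facility, per-IRIS accessibility radius, ZAP sets.

The catchment radius of an IRIS (the smallest French census unit) for a given
facility type is the longest travel time any of its residential areas needs to
reach its nearest facility of that type. That radius delimits each area's
potential accessibility zone (ZAP): every candidate facility whose cost from
the area is at or below the radius. By construction the ZAP always contains
the area's nearest facility, so it is never empty.
"""

from __future__ import annotations

from typing import Collection, Mapping

import numpy as np
import pandas as pd

from .errors import ScaleAccessError
from .travel_cost import ODMatrix


def _type_columns(od: ODMatrix, facilities: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Facility ids of the frame, sorted lexicographically, with OD column indices."""
    fac_ids = sorted(facilities["facility_id"])
    return fac_ids, od.column_indices(fac_ids)


def _masked_costs(od: ODMatrix, fac_ids: list[str], cols: np.ndarray,
                  area_ids: list[str],
                  candidates: Mapping[str, Collection[str]] | None,
                  impedance: str) -> np.ndarray:
    matrix = od.travel_time if impedance == "travel_time" else od.road_distance
    rows = np.array([od.row_index(a) for a in area_ids])
    costs = matrix[np.ix_(rows, cols)].astype(float)
    if candidates is not None:
        fac_pos = {f: j for j, f in enumerate(fac_ids)}
        for i, aid in enumerate(area_ids):
            allowed = candidates.get(aid)
            if allowed is None:
                raise ScaleAccessError(f"no candidate set for area {aid!r}")
            mask = np.ones(len(fac_ids), dtype=bool)
            for f in allowed:
                if f in fac_pos:
                    mask[fac_pos[f]] = False
            costs[i, mask] = np.inf
    return costs


def nearest_per_area(
    od: ODMatrix,
    facilities: pd.DataFrame,
    areas: pd.DataFrame,
    candidates: Mapping[str, Collection[str]] | None = None,
    impedance: str = "travel_time",
) -> pd.DataFrame:
    """Nearest facility of one type per residential area.

    ``facilities`` must hold a single facility type. Ties are broken by the
    lexicographically smallest facility_id so output is reproducible.
    ``candidates`` optionally restricts each area to a chunk-plan facility set.

    Returns columns ``area_id, facility_type, nearest_facility_id, nearest_cost``.
    """
    ftypes = facilities["facility_type"].unique()
    if len(ftypes) != 1:
        raise ScaleAccessError(f"nearest_per_area expects one facility type, got {list(ftypes)}")
    area_ids = list(areas["area_id"])
    fac_ids, cols = _type_columns(od, facilities)
    costs = _masked_costs(od, fac_ids, cols, area_ids, candidates, impedance)
    unreachable = ~np.isfinite(costs).any(axis=1)
    if unreachable.any():
        aid = area_ids[int(np.argmax(unreachable))]
        raise ScaleAccessError(
            f"area {aid!r} has no reachable candidate facility of type {ftypes[0]!r}"
        )
    best = np.argmin(costs, axis=1)  # first occurrence wins -> lexicographic tie-break
    return pd.DataFrame({
        "area_id": area_ids,
        "facility_type": ftypes[0],
        "nearest_facility_id": [fac_ids[j] for j in best],
        "nearest_cost": costs[np.arange(len(area_ids)), best],
    })


def iris_radius(nearest: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Per-IRIS catchment radius: the max nearest-facility cost over the IRIS's areas.

    Returns columns ``iris_id, facility_type, radius``.
    """
    merged = nearest.merge(areas[["area_id", "iris_id"]], on="area_id", validate="m:1")
    assert not merged["iris_id"].isna().any()
    out = (merged.groupby(["iris_id", "facility_type"], as_index=False)["nearest_cost"]
           .max().rename(columns={"nearest_cost": "radius"}))
    return out


def zap_members(
    od: ODMatrix,
    radii: pd.DataFrame,
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    candidates: Mapping[str, Collection[str]] | None = None,
    impedance: str = "travel_time",
) -> pd.DataFrame:
    """Potential accessibility zone per (area, facility type).

    Member set = all candidate facilities with cost <= the area's IRIS radius;
    the boundary is inclusive so the facility defining the radius is a member.

    Returns columns ``area_id, facility_type, radius, member_ids`` with
    member_ids a sorted tuple of facility ids (never empty).
    """
    ftypes = facilities["facility_type"].unique()
    if len(ftypes) != 1:
        raise ScaleAccessError(f"zap_members expects one facility type, got {list(ftypes)}")
    ftype = ftypes[0]
    radius_by_iris = (radii[radii["facility_type"] == ftype]
                      .set_index("iris_id")["radius"])
    area_ids = list(areas["area_id"])
    iris_of = areas.set_index("area_id")["iris_id"]
    missing = set(iris_of[area_ids]) - set(radius_by_iris.index)
    if missing:
        raise ScaleAccessError(f"no radius computed for iris {sorted(missing)[:5]}")
    fac_ids, cols = _type_columns(od, facilities)
    costs = _masked_costs(od, fac_ids, cols, area_ids, candidates, impedance)
    fac_arr = np.array(fac_ids, dtype=object)
    rows = []
    for i, aid in enumerate(area_ids):
        r = float(radius_by_iris[iris_of[aid]])
        members = tuple(fac_arr[costs[i] <= r])
        assert members, "ZAP must contain the nearest facility"
        rows.append((aid, ftype, r, members))
    return pd.DataFrame(rows, columns=["area_id", "facility_type", "radius", "member_ids"])


def zap_table_for_dump(zaps: pd.DataFrame) -> pd.DataFrame:
    """Inspection form of the ZAP table: member ids semicolon-joined."""
    out = zaps.copy()
    out["member_ids"] = out["member_ids"].map(";".join)
    return out.rename(columns={"radius": "radius_min"})
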