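"""Facility pressure (Voronoi demand load) and potential accessibility distances.

Pressure is the theoretical demand each facility absorbs: every residential
area's full population is assigned to its nearest facility of the type (a
travel-cost Voronoi tessellation), then divided by the facility's professional
head count. The potential accessibility distance (PAD) of an area is the
pressure-weighted mean travel cost to the facilities in its ZAP, so a nearby
but overloaded facility does not dominate the picture of effective access.

The weighting direction is configurable: ``pressure`` (default) emphasizes
the costs of reaching the facilities carrying demand; ``inverse_pressure``
weights by availability (1/pressure) instead. Both satisfy the same bounds
and scaling invariants.
"""

from __future__ import annotations

from typing import Collection, Mapping

import numpy as np
import pandas as pd

from .catchment import nearest_per_area
from .errors import ScaleAccessError
from .travel_cost import ODMatrix

WEIGHT_MODES = ("pressure", "inverse_pressure")


def compute_pressure(
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    od: ODMatrix,
    candidates: Mapping[str, Collection[str]] | None = None,
    impedance: str = "travel_time",
) -> pd.DataFrame:
    """Voronoi population assignment and per-professional pressure for one type.

    Each area's population goes entirely to its nearest facility (same travel
    metric as the OD matrix, not geometric polygons); facilities that are
    nearest to nobody get zero. Population is conserved:
    sum(assigned_population) == sum(area populations).

    Returns ``facility_id, facility_type, assigned_population, pressure``.
    """
    nearest = nearest_per_area(od, facilities, areas, candidates, impedance)
    pop = areas.set_index("area_id")["population"]
    assigned = (nearest.assign(population=nearest["area_id"].map(pop))
                .groupby("nearest_facility_id")["population"].sum())
    out = facilities[["facility_id", "facility_type", "n_professionals"]].copy()
    out["assigned_population"] = out["facility_id"].map(assigned).fillna(0.0)
    out["pressure"] = out["assigned_population"] / out["n_professionals"]
    return out.drop(columns="n_professionals")


def compute_pad(
    member_ids,
    costs: np.ndarray,
    pressures: np.ndarray,
    weight_mode: str = "pressure",
) -> float:
    """Weighted mean cost over one ZAP's member facilities.

    pad = sum(w_j * cost_j) / sum(w_j). Under ``pressure`` w_j = pressure_j;
    under ``inverse_pressure`` w_j = 1/pressure_j with zero pressures replaced
    by the smallest positive member pressure. A zero total weight falls back
    to the unweighted mean, which keeps pad inside [min cost, max cost].
    """
    if weight_mode not in WEIGHT_MODES:
        raise ScaleAccessError(f"weight_mode must be one of {WEIGHT_MODES}, got {weight_mode!r}")
    costs = np.asarray(costs, dtype=float)
    pressures = np.asarray(pressures, dtype=float)
    if len(costs) != len(member_ids) or len(pressures) != len(member_ids):
        raise ScaleAccessError("compute_pad: costs/pressures misaligned with member set")
    if np.isnan(pressures).any():
        raise ScaleAccessError(f"missing pressure for a ZAP member of {list(member_ids)}")
    if weight_mode == "pressure":
        w = pressures
    else:
        positive = pressures[pressures > 0]
        if len(positive) == 0:
            w = np.zeros_like(pressures)
        else:
            w = 1.0 / np.where(pressures > 0, pressures, positive.min())
    total = w.sum()
    if total == 0:
        return float(costs.mean())
    return float((w * costs).sum() / total)


def pad_all(
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    zaps: pd.DataFrame,
    od: ODMatrix,
    pressures: pd.DataFrame,
    weight_mode: str = "pressure",
    impedance: str = "travel_time",
) -> pd.DataFrame:
    """Potential accessibility distance for every (area, facility type) pair.

    ``zaps`` and ``pressures`` are the concatenated per-type tables. Returns
    one row per (area_id, facility_type) with the pad bounded by the ZAP's
    min and max member costs.
    """
    pressure_of = pressures.set_index(["facility_type", "facility_id"])["pressure"]
    rows = []
    for _, z in zaps.iterrows():
        members = list(z["member_ids"])
        costs = np.array([od.cost(z["area_id"], m, impedance) for m in members])
        try:
            p = pressure_of.loc[[(z["facility_type"], m) for m in members]].to_numpy()
        except KeyError as exc:
            raise ScaleAccessError(
                f"missing pressure for ZAP member of area {z['area_id']!r}: {exc}"
            ) from None
        rows.append((z["area_id"], z["facility_type"],
                     compute_pad(members, costs, p, weight_mode)))
    return pd.DataFrame(rows, columns=["area_id", "facility_type", "pad"])
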