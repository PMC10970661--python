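"""Origin-destination travel costs between residential areas and facilities.

Two metrics are supported: straight-line (Euclidean) distance converted to
minutes at a constant speed, and shortest-path costs on a road graph with
travel time (or length) as the impedance. Demand and supply points are snapped
to their nearest network node; snap legs contribute zero cost by default.

Large study regions are processed in chunks: each region's residential areas
are matched against candidate facilities drawn from the region itself plus
neighboring departments (proximity-range facility types) or neighboring
regions (tertiary-range types).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ScaleAccessError, SchemaError, UnreachableError


@dataclass
class ODMatrix:
    """Dense travel-cost matrix between origin areas and destination facilities.

    ``travel_time`` is in minutes, ``road_distance`` in meters; unreachable
    pairs hold ``inf``. ``metric_tag`` records how the costs were produced.
    """

    origins: list[str]
    destinations: list[str]
    travel_time: np.ndarray
    road_distance: np.ndarray
    metric_tag: str = "euclidean"
    _oi: dict = field(default_factory=dict, repr=False, compare=False)
    _di: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.travel_time = np.asarray(self.travel_time, dtype=float)
        self.road_distance = np.asarray(self.road_distance, dtype=float)
        if self.travel_time.shape != (len(self.origins), len(self.destinations)):
            raise SchemaError("ODMatrix: travel_time shape does not match origins x destinations")
        if self.road_distance.shape != self.travel_time.shape:
            raise SchemaError("ODMatrix: road_distance shape mismatch")
        finite = self.travel_time[np.isfinite(self.travel_time)]
        if len(finite) and finite.min() < 0:
            raise SchemaError("ODMatrix: negative travel time")
        self._oi = {o: i for i, o in enumerate(self.origins)}
        self._di = {d: j for j, d in enumerate(self.destinations)}

    def time(self, origin: str, destination: str) -> float:
        return float(self.travel_time[self._oi[origin], self._di[destination]])

    def distance(self, origin: str, destination: str) -> float:
        return float(self.road_distance[self._oi[origin], self._di[destination]])

    def cost(self, origin: str, destination: str, impedance: str = "travel_time") -> float:
        return self.time(origin, destination) if impedance == "travel_time" \
            else self.distance(origin, destination)

    def column_indices(self, destinations) -> np.ndarray:
        return np.array([self._di[d] for d in destinations], dtype=int)

    def row_index(self, origin: str) -> int:
        return self._oi[origin]

    def to_frame(self) -> pd.DataFrame:
        oo, dd = np.meshgrid(np.arange(len(self.origins)), np.arange(len(self.destinations)),
                             indexing="ij")
        return pd.DataFrame({
            "origin_id": np.asarray(self.origins, dtype=object)[oo.ravel()],
            "destination_id": np.asarray(self.destinations, dtype=object)[dd.ravel()],
            "travel_time_min": self.travel_time.ravel(),
            "distance_m": self.road_distance.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric_tag: str = "network") -> "ODMatrix":
        origins = list(pd.unique(df["origin_id"]))
        destinations = list(pd.unique(df["destination_id"]))
        oi = {o: i for i, o in enumerate(origins)}
        di = {d: j for j, d in enumerate(destinations)}
        tt = np.full((len(origins), len(destinations)), np.inf)
        dist = np.full_like(tt, np.inf)
        tt[df["origin_id"].map(oi), df["destination_id"].map(di)] = df["travel_time_min"]
        dist[df["origin_id"].map(oi), df["destination_id"].map(di)] = df["distance_m"]
        return cls(origins, destinations, tt, dist, metric_tag)


def euclidean_costs(areas: pd.DataFrame, facilities: pd.DataFrame,
                    speed_kmh: float = 50.0) -> ODMatrix:
    """Straight-line OD costs: distance in meters, time = distance / speed.

    The legacy metric of the index (greatest Euclidean distance to the nearest
    facility), kept as a network-free fallback.
    """
    if speed_kmh <= 0:
        raise ScaleAccessError(f"speed_kmh must be > 0, got {speed_kmh}")
    dist = cdist(areas[["x", "y"]].to_numpy(float), facilities[["x", "y"]].to_numpy(float))
    tt = dist / 1000.0 / speed_kmh * 60.0
    return ODMatrix(list(areas["area_id"]), list(facilities["facility_id"]),
                    tt, dist, metric_tag="euclidean")


def build_graph(nodes: pd.DataFrame, edges: pd.DataFrame,
                impedance: str = "travel_time") -> nx.DiGraph:
    """Directed road graph; edges doubled unless a oneway column marks them.

    Parallel edges between the same node pair keep the one with the smallest
    impedance (shortest-path routing never uses the slower duplicate).
    """
    g = nx.DiGraph()
    for _, n in nodes.iterrows():
        g.add_node(str(n["node_id"]), x=float(n["x"]), y=float(n["y"]))
    key = "travel_time" if impedance == "travel_time" else "length"
    oneway = edges["oneway"].astype(int) if "oneway" in edges.columns \
        else pd.Series(0, index=edges.index)
    for (_, e), ow in zip(edges.iterrows(), oneway):
        u, v = str(e["from_node"]), str(e["to_node"])
        attrs = {"length": float(e["length_m"]), "travel_time": float(e["travel_time_min"])}
        for a, b in ((u, v),) if ow else ((u, v), (v, u)):
            if not g.has_edge(a, b) or attrs[key] < g[a][b][key]:
                g.add_edge(a, b, **attrs)
    return g


def snap_points(points: pd.DataFrame, nodes: pd.DataFrame,
                max_snap_m: float = 5000.0) -> pd.DataFrame:
    """Snap each point to its nearest network node (cKDTree nearest query).

    Returns a frame with ``node_id`` and ``snap_dist_m`` per point; a snap
    distance beyond ``max_snap_m`` raises.
    """
    tree = cKDTree(nodes[["x", "y"]].to_numpy(float))
    d, idx = tree.query(points[["x", "y"]].to_numpy(float))
    if np.any(d > max_snap_m):
        worst = points.iloc[int(np.argmax(d))]
        raise ScaleAccessError(
            f"point {worst.iloc[0]!r} snaps {d.max():.0f} m to the nearest network node, "
            f"beyond max_snap_m={max_snap_m:.0f}"
        )
    return pd.DataFrame({
        "node_id": nodes["node_id"].astype(str).to_numpy()[idx],
        "snap_dist_m": d,
    }, index=points.index)


def network_costs(
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
    impedance: str = "travel_time",
    allow_unreachable: bool = False,
    max_snap_m: float = 5000.0,
) -> ODMatrix:
    """Shortest-path OD costs on the road graph.

    ``travel_time`` and ``road_distance`` are both accumulated along the
    impedance-optimal path (Dijkstra from every distinct snapped origin node),
    so the two fields describe the same route. Snap legs cost zero.
    """
    if impedance not in ("travel_time", "length"):
        raise ScaleAccessError(f"impedance must be travel_time or length, got {impedance!r}")
    g = build_graph(nodes, edges, impedance)
    o_snap = snap_points(areas.rename(columns={"area_id": "id"}), nodes, max_snap_m)
    d_snap = snap_points(facilities.rename(columns={"facility_id": "id"}), nodes, max_snap_m)
    o_nodes = o_snap["node_id"].to_numpy()
    d_nodes = d_snap["node_id"].to_numpy()
    dest_set = list(dict.fromkeys(d_nodes))

    n_o, n_d = len(areas), len(facilities)
    tt = np.full((n_o, n_d), np.inf)
    dist = np.full_like(tt, np.inf)
    other_attr = "length" if impedance == "travel_time" else "travel_time"
    cache: dict[str, tuple[dict, dict]] = {}
    for src in dict.fromkeys(o_nodes):
        costs, paths = nx.single_source_dijkstra(g, src, weight=impedance)
        secondary = {}
        for dn in dest_set:
            if dn in paths:
                p = paths[dn]
                secondary[dn] = sum(g[u][v][other_attr] for u, v in zip(p[:-1], p[1:]))
        cache[src] = (costs, secondary)

    for i, src in enumerate(o_nodes):
        costs, secondary = cache[src]
        for j, dn in enumerate(d_nodes):
            if dn in costs:
                primary = costs[dn]
                if impedance == "travel_time":
                    tt[i, j] = primary
                    dist[i, j] = secondary[dn]
                else:
                    dist[i, j] = primary
                    tt[i, j] = secondary[dn]

    if not allow_unreachable and not np.all(np.isfinite(tt)):
        bad = np.argwhere(~np.isfinite(tt))
        pairs = [(areas["area_id"].iloc[i], facilities["facility_id"].iloc[j])
                 for i, j in bad[:5]]
        raise UnreachableError(f"unreachable origin-destination pairs: {pairs}"
                               + (" ..." if len(bad) > 5 else ""))
    return ODMatrix(list(areas["area_id"]), list(facilities["facility_id"]),
                    tt, dist, metric_tag="network")


@dataclass
class RegionChunkPlan:
    """Per-region processing chunk: member areas and candidate facilities per range class."""

    region_id: str
    area_ids: list[str]
    candidates: dict[str, list[str]]  # range_class -> facility_ids


def infer_facility_units(facilities: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Attach region_id (and department_id when areas carry one) to facilities
    from the nearest residential area."""
    tree = cKDTree(areas[["x", "y"]].to_numpy(float))
    _, idx = tree.query(facilities[["x", "y"]].to_numpy(float))
    out = facilities.copy()
    out["region_id"] = areas["region_id"].to_numpy()[idx]
    if "department_id" in areas.columns:
        out["department_id"] = areas["department_id"].to_numpy()[idx]
    return out


def plan_chunks(
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    adjacency: pd.DataFrame,
) -> list[RegionChunkPlan]:
    """Build one processing chunk per region.

    Candidate facilities per chunk: those in the region, plus facilities in
    neighboring departments for proximity-range types, or in neighboring
    regions for tertiary-range types. Every region present in ``areas`` must
    appear in the adjacency table's ``unit_id`` column (a self-row suffices
    for a region without neighbors).

    If facilities carry no ``department_id`` column, proximity-range expansion
    falls back to region-level neighbors.
    """
    if "region_id" not in facilities.columns:
        facilities = infer_facility_units(facilities, areas)
    known_units = set(adjacency["unit_id"])
    regions = sorted(set(areas["region_id"]))
    missing = [r for r in regions if r not in known_units]
    if missing:
        raise SchemaError(f"plan_chunks: regions absent from adjacency table: {missing}")
    has_dept = "department_id" in facilities.columns
    region_nbrs = adjacency[adjacency["level"] == "region"]
    dept_nbrs = adjacency[adjacency["level"] == "department"]

    plans = []
    for region in regions:
        in_region = facilities["region_id"] == region
        nbr_regions = set(region_nbrs.loc[region_nbrs["unit_id"] == region, "neighbor_id"])
        nbr_regions.discard(region)
        tert_mask = in_region | facilities["region_id"].isin(nbr_regions)
        if has_dept:
            nbr_depts = set(dept_nbrs.loc[dept_nbrs["unit_id"] == region, "neighbor_id"])
            prox_mask = in_region | facilities["department_id"].isin(nbr_depts)
        else:
            prox_mask = tert_mask
        plans.append(RegionChunkPlan(
            region_id=region,
            area_ids=sorted(areas.loc[areas["region_id"] == region, "area_id"]),
            candidates={
                "proximity": sorted(facilities.loc[prox_mask, "facility_id"]),
                "tertiary": sorted(facilities.loc[tert_mask, "facility_id"]),
            },
        ))
    return plans


def candidate_map(plans: list[RegionChunkPlan], areas: pd.DataFrame,
                  facilities: pd.DataFrame) -> dict[str, dict[str, set]]:
    """Flatten chunk plans into {area_id: {range_class: candidate facility ids}}."""
    out: dict[str, dict[str, set]] = {}
    for plan in plans:
        cand = {rc: set(ids) for rc, ids in plan.candidates.items()}
        for aid in plan.area_ids:
            out[aid] = cand
    return out
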