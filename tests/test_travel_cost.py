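"""Travel-cost correctness: Euclidean arithmetic, shortest paths vs brute force,
chunk planning, and the metric invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scale_access import travel_cost
from scale_access.errors import ScaleAccessError, SchemaError, UnreachableError

from _brute import all_simple_path_costs, bellman_ford
from conftest import make_areas, make_facilities


# ---------------------------------------------------------------- euclidean

def test_euclidean_three_four_five_triangle():
    areas = make_areas([("A1", 0.0, 0.0, 10, "I1")])
    facs = make_facilities([("F1", 3000.0, 4000.0)])
    od = travel_cost.euclidean_costs(areas, facs, speed_kmh=60.0)
    assert od.distance("A1", "F1") == pytest.approx(5000.0)
    assert od.time("A1", "F1") == pytest.approx(5.0)  # 5 km at 60 km/h


def test_euclidean_zero_for_colocated_and_speed_validation():
    areas = make_areas([("A1", 100.0, 200.0, 10, "I1")])
    facs = make_facilities([("F1", 100.0, 200.0)])
    od = travel_cost.euclidean_costs(areas, facs)
    assert od.distance("A1", "F1") == 0.0 and od.time("A1", "F1") == 0.0
    with pytest.raises(ScaleAccessError):
        travel_cost.euclidean_costs(areas, facs, speed_kmh=0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(dx=st.floats(-1e5, 1e5), dy=st.floats(-1e5, 1e5),
       theta=st.floats(0, 2 * math.pi))
def test_euclidean_rigid_motion_invariance(dx, dy, theta):
    """Straight-line costs are unchanged by translation and rotation."""
    rng = np.random.default_rng(7)
    pts_a = rng.uniform(0, 10000, (4, 2))
    pts_f = rng.uniform(0, 10000, (3, 2))
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])

    def build(pa, pf):
        areas = make_areas([(f"A{i}", p[0], p[1], 1, "I1") for i, p in enumerate(pa)])
        facs = make_facilities([(f"F{j}", p[0], p[1]) for j, p in enumerate(pf)])
        return travel_cost.euclidean_costs(areas, facs)

    base = build(pts_a, pts_f)
    moved = build(pts_a @ rot.T + [dx, dy], pts_f @ rot.T + [dx, dy])
    np.testing.assert_allclose(moved.road_distance, base.road_distance,
                               rtol=1e-9, atol=1e-6)


# ------------------------------------------------------------------ network

def _net(nodes, edges):
    nodes_df = pd.DataFrame(nodes, columns=["node_id", "x", "y"])
    edges_df = pd.DataFrame(edges, columns=["from_node", "to_node", "length_m",
                                            "travel_time_min"])
    return nodes_df, edges_df


TRIANGLE = _net(
    [("A", 0, 0), ("B", 1000, 0), ("C", 2000, 0)],
    [("A", "B", 1000, 2.0), ("B", "C", 1000, 2.0), ("A", "C", 2500, 5.0)],
)


def test_triangle_shortcut_beats_direct_edge():
    """A-B-C (2+2 min) must beat the direct A-C edge (5 min)."""
    nodes, edges = TRIANGLE
    areas = make_areas([("O", 0, 0, 1, "I1")])
    facs = make_facilities([("D", 2000, 0)])
    od = travel_cost.network_costs(areas, facs, nodes, edges)
    assert od.time("O", "D") == pytest.approx(4.0)
    # oracle: exhaustive enumeration over the 3-node graph
    ew = {}
    for _, e in edges.iterrows():
        ew[(e.from_node, e.to_node)] = e.travel_time_min
        ew[(e.to_node, e.from_node)] = e.travel_time_min
    assert all_simple_path_costs(ew, "A", "C") == pytest.approx(4.0)


def test_single_edge_cost_is_edge_time():
    nodes, edges = _net([("A", 0, 0), ("B", 5000, 0)], [("A", "B", 5000, 7.5)])
    od = travel_cost.network_costs(
        make_areas([("O", 0, 0, 1, "I1")]), make_facilities([("D", 5000, 0)]),
        nodes, edges)
    assert od.time("O", "D") == pytest.approx(7.5)
    assert od.distance("O", "D") == pytest.approx(5000.0)


def _random_graph(rng, n):
    nodes = [(f"N{i}", float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
             for i in range(n)]
    edges = []
    for i in range(1, n):  # spanning chain keeps it connected
        j = int(rng.integers(0, i))
        edges.append((f"N{j}", f"N{i}", float(rng.uniform(10, 100)),
                      float(rng.uniform(0.5, 10))))
    for _ in range(n):
        i, j = rng.integers(0, n, 2)
        if i != j:
            edges.append((f"N{i}", f"N{j}", float(rng.uniform(10, 100)),
                          float(rng.uniform(0.5, 10))))
    return _net(nodes, edges)


@pytest.mark.parametrize("seed", range(5))
def test_five_node_graphs_match_bellman_ford(seed):
    rng = np.random.default_rng(seed)
    nodes, edges = _random_graph(rng, 5)
    areas = make_areas([(f"O{i}", r.x, r.y, 1, "I1") for i, r in nodes.iterrows()])
    facs = make_facilities([(f"D{i}", r.x, r.y) for i, r in nodes.iterrows()])
    od = travel_cost.network_costs(areas, facs, nodes, edges)
    ew = {}
    for _, e in edges.iterrows():
        for key in ((e.from_node, e.to_node), (e.to_node, e.from_node)):
            ew[key] = min(ew.get(key, math.inf), e.travel_time_min)
    for i, src in enumerate(nodes["node_id"]):
        dist = bellman_ford(ew, list(nodes["node_id"]), src)
        for j, dst in enumerate(nodes["node_id"]):
            assert od.time(f"O{i}", f"D{j}") == pytest.approx(dist[dst])


def test_oneway_edges_are_directional():
    nodes = pd.DataFrame([("A", 0, 0), ("B", 1000, 0)], columns=["node_id", "x", "y"])
    edges = pd.DataFrame([("A", "B", 1000, 2.0, 1), ("B", "A", 3000, 6.0, 1)],
                         columns=["from_node", "to_node", "length_m",
                                  "travel_time_min", "oneway"])
    areas = make_areas([("O1", 0, 0, 1, "I1"), ("O2", 1000, 0, 1, "I1")])
    facs = make_facilities([("D1", 0, 0), ("D2", 1000, 0)])
    od = travel_cost.network_costs(areas, facs, nodes, edges)
    assert od.time("O1", "D2") == pytest.approx(2.0)
    assert od.time("O2", "D1") == pytest.approx(6.0)


def test_unreachable_pair_raises_unless_allowed():
    nodes, edges = _net([("A", 0, 0), ("B", 100, 0), ("C", 5000, 0), ("D", 5100, 0)],
                        [("A", "B", 100, 1.0), ("C", "D", 100, 1.0)])
    areas = make_areas([("O", 0, 0, 1, "I1")])
    facs = make_facilities([("F", 5100, 0)])
    with pytest.raises(UnreachableError, match="O"):
        travel_cost.network_costs(areas, facs, nodes, edges)
    od = travel_cost.network_costs(areas, facs, nodes, edges, allow_unreachable=True)
    assert math.isinf(od.time("O", "F"))


def test_edge_time_scaling_scales_od_linearly():
    rng = np.random.default_rng(11)
    nodes, edges = _random_graph(rng, 8)
    areas = make_areas([(f"O{i}", r.x, r.y, 1, "I1") for i, r in nodes.iterrows()])
    facs = make_facilities([(f"D{i}", r.x, r.y) for i, r in nodes.iterrows()])
    base = travel_cost.network_costs(areas, facs, nodes, edges)
    for k in (0.5, 2.0, 10.0):
        scaled = travel_cost.network_costs(
            areas, facs, nodes, edges.assign(travel_time_min=edges.travel_time_min * k))
        np.testing.assert_allclose(scaled.travel_time, base.travel_time * k, rtol=1e-9)


def test_triangle_inequality_on_network_costs():
    rng = np.random.default_rng(23)
    nodes, edges = _random_graph(rng, 8)
    areas = make_areas([(f"O{i}", r.x, r.y, 1, "I1") for i, r in nodes.iterrows()])
    facs = make_facilities([(f"D{i}", r.x, r.y) for i, r in nodes.iterrows()])
    od = travel_cost.network_costs(areas, facs, nodes, edges)
    n = len(nodes)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert od.time(f"O{i}", f"D{j}") <= \
                    od.time(f"O{i}", f"D{k}") + od.time(f"O{k}", f"D{j}") + 1e-9


def test_snap_distance_limit():
    nodes, edges = _net([("A", 0, 0), ("B", 100, 0)], [("A", "B", 100, 1.0)])
    areas = make_areas([("O", 90000.0, 0, 1, "I1")])
    facs = make_facilities([("F", 0, 0)])
    with pytest.raises(ScaleAccessError, match="snap"):
        travel_cost.network_costs(areas, facs, nodes, edges)


# ------------------------------------------------------------------- chunks

ADJ = pd.DataFrame([
    ("R1", "R1", "region"), ("R1", "R2", "region"),
    ("R2", "R2", "region"), ("R2", "R1", "region"),
    ("R1", "R2-D1", "department"), ("R2", "R1-D1", "department"),
], columns=["unit_id", "neighbor_id", "level"])


def _two_region_world():
    areas = make_areas([
        ("A1", 1000, 1000, 50, "I1", "C1", "R1"),
        ("A2", 2000, 1000, 60, "I1", "C1", "R1"),
        ("A3", 9000, 1000, 70, "I2", "C2", "R2"),
    ])
    areas["department_id"] = ["R1-D1", "R1-D1", "R2-D1"]
    facs = make_facilities([("F1", 1500, 1000), ("F2", 8500, 1000)])
    facs["region_id"] = ["R1", "R2"]
    facs["department_id"] = ["R1-D1", "R2-D1"]
    return areas, facs


def test_single_region_plan_holds_everything():
    areas, facs = _two_region_world()
    areas = areas.assign(region_id="R1", department_id="R1-D1")
    facs = facs.assign(region_id="R1", department_id="R1-D1")
    adj = pd.DataFrame([("R1", "R1", "region")],
                       columns=["unit_id", "neighbor_id", "level"])
    plans = travel_cost.plan_chunks(areas, facs, adj)
    assert len(plans) == 1
    assert plans[0].area_ids == ["A1", "A2", "A3"]
    assert plans[0].candidates["proximity"] == ["F1", "F2"]
    assert plans[0].candidates["tertiary"] == ["F1", "F2"]


def test_adjacent_regions_include_neighbor_departments():
    areas, facs = _two_region_world()
    plans = {p.region_id: p for p in travel_cost.plan_chunks(areas, facs, ADJ)}
    assert plans["R1"].candidates["proximity"] == ["F1", "F2"]  # own + neighbor dept
    assert plans["R2"].candidates["proximity"] == ["F1", "F2"]
    assert plans["R1"].candidates["tertiary"] == ["F1", "F2"]   # own + neighbor region


def test_region_missing_from_adjacency_raises():
    areas, facs = _two_region_world()
    adj = pd.DataFrame([("R1", "R1", "region")],
                       columns=["unit_id", "neighbor_id", "level"])
    with pytest.raises(SchemaError, match="R2"):
        travel_cost.plan_chunks(areas, facs, adj)


def test_chunked_nearest_equals_unchunked_on_two_region_layout():
    """Chunking must not change nearest-facility answers when the true nearest
    is inside the candidate set (here: candidates cover everything)."""
    from scale_access import catchment
    areas, facs = _two_region_world()
    od = travel_cost.euclidean_costs(areas, facs)
    plans = travel_cost.plan_chunks(areas, facs, ADJ)
    cand = {aid: c["proximity"]
            for aid, c in travel_cost.candidate_map(plans, areas, facs).items()}
    chunked = catchment.nearest_per_area(od, facs, areas, cand)
    unchunked = catchment.nearest_per_area(od, facs, areas)
    pd.testing.assert_frame_equal(chunked, unchunked)


def test_facility_units_inferred_from_nearest_area():
    areas, facs = _two_region_world()
    bare = facs.drop(columns=["region_id", "department_id"])
    inferred = travel_cost.infer_facility_units(bare, areas)
    assert list(inferred["region_id"]) == ["R1", "R2"]
    assert list(inferred["department_id"]) == ["R1-D1", "R2-D1"]
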