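"""Pressure assignment and potential accessibility distances."""

import numpy as np
import pandas as pd
import pytest

from scale_access import catchment, pressure_pad, travel_cost
from scale_access.errors import ScaleAccessError

from _brute import brute_pressure, brute_weighted_mean
from conftest import make_areas, make_facilities, random_fixture


def test_voronoi_assignment_hand_example():
    """F1 at (0,0), F2 at (10,0): areas at 1, 9 and 4 km split 130 / 50."""
    areas = make_areas([("A1", 1000, 0, 100, "I1"), ("A2", 9000, 0, 50, "I1"),
                        ("A3", 4000, 0, 30, "I1")])
    facs = make_facilities([("F1", 0, 0), ("F2", 10000, 0)])
    od = travel_cost.euclidean_costs(areas, facs)
    got = pressure_pad.compute_pressure(areas, facs, od).set_index("facility_id")
    assert got.loc["F1", "assigned_population"] == pytest.approx(130.0)
    assert got.loc["F2", "assigned_population"] == pytest.approx(50.0)


def test_single_facility_absorbs_everything_and_division_by_professionals():
    areas = make_areas([("A1", 0, 0, 70, "I1"), ("A2", 500, 0, 30, "I1")])
    facs = make_facilities([("F1", 100, 0, 2)])
    od = travel_cost.euclidean_costs(areas, facs)
    got = pressure_pad.compute_pressure(areas, facs, od)
    assert got.loc[0, "assigned_population"] == pytest.approx(100.0)
    assert got.loc[0, "pressure"] == pytest.approx(50.0)  # 100 persons / 2 professionals


def test_population_conservation_on_random_fixtures(rng):
    for _ in range(20):
        areas, facs, od = random_fixture(rng)
        got = pressure_pad.compute_pressure(areas, facs, od)
        assert got["assigned_population"].sum() == pytest.approx(areas["population"].sum())
        expected = brute_pressure(
            dict(zip(areas["area_id"], areas["population"])),
            {aid: {fid: od.time(aid, fid) for fid in facs["facility_id"]}
             for aid in areas["area_id"]})
        by_id = got.set_index("facility_id")["assigned_population"]
        for fid in facs["facility_id"]:
            assert by_id[fid] == pytest.approx(expected.get(fid, 0.0))


def test_pad_weighted_mean_hand_example():
    # (2*100 + 6*50) / 150 = 10/3
    pad = pressure_pad.compute_pad(["F1", "F2"], [2.0, 6.0], [100.0, 50.0])
    assert pad == pytest.approx(10.0 / 3.0)


def test_pad_singleton_and_zero_weight_fallback():
    assert pressure_pad.compute_pad(["F1"], [7.0], [123.0]) == 7.0
    # all pressures zero -> unweighted mean
    assert pressure_pad.compute_pad(["F1", "F2"], [2.0, 6.0], [0.0, 0.0]) == 4.0


def test_pad_missing_pressure_raises():
    with pytest.raises(ScaleAccessError):
        pressure_pad.compute_pad(["F1", "F2"], [2.0, 6.0], [100.0, np.nan])


def test_inverse_pressure_mode_prefers_available_facilities():
    near_busy = pressure_pad.compute_pad(["F1", "F2"], [2.0, 6.0], [100.0, 10.0],
                                         weight_mode="pressure")
    near_free = pressure_pad.compute_pad(["F1", "F2"], [2.0, 6.0], [100.0, 10.0],
                                         weight_mode="inverse_pressure")
    # inverse mode pulls the mean toward the low-pressure (available) facility
    assert near_free > near_busy
    lo, hi = 2.0, 6.0
    assert lo <= near_free <= hi and lo <= near_busy <= hi


def _full_tables(areas, facs, od, weight_mode="pressure"):
    nearest = catchment.nearest_per_area(od, facs, areas)
    radii = catchment.iris_radius(nearest, areas)
    zaps = catchment.zap_members(od, radii, areas, facs)
    pressure = pressure_pad.compute_pressure(areas, facs, od)
    pads = pressure_pad.pad_all(areas, facs, zaps, od, pressure, weight_mode)
    return zaps, pressure, pads


def test_pad_all_matches_brute_force_weighted_mean(rng):
    for _ in range(10):
        areas, facs, od = random_fixture(rng, n_areas=10, n_fac=6)
        zaps, pressure, pads = _full_tables(areas, facs, od)
        p_of = pressure.set_index("facility_id")["pressure"]
        pads = pads.set_index("area_id")["pad"]
        for _, z in zaps.iterrows():
            costs = [od.time(z["area_id"], m) for m in z["member_ids"]]
            weights = [p_of[m] for m in z["member_ids"]]
            assert pads[z["area_id"]] == pytest.approx(
                brute_weighted_mean(costs, weights))
            assert min(costs) - 1e-12 <= pads[z["area_id"]] <= max(costs) + 1e-12


def test_pad_cardinality_and_uniform_pressure_reduces_to_plain_mean():
    areas = make_areas([("A1", 0, 0, 10, "I1"), ("A2", 3000, 0, 10, "I1"),
                        ("A3", 6000, 0, 10, "I2")])
    facs = pd.concat([
        make_facilities([("F1", 1000, 0), ("F2", 5000, 0)], ftype="gp"),
        make_facilities([("G1", 2000, 0), ("G2", 4000, 0)], ftype="pharmacist"),
    ], ignore_index=True)
    od = travel_cost.euclidean_costs(areas, facs)
    frames = []
    pressures = []
    for ftype in ("gp", "pharmacist"):
        ft = facs[facs["facility_type"] == ftype]
        nearest = catchment.nearest_per_area(od, ft, areas)
        radii = catchment.iris_radius(nearest, areas)
        frames.append(catchment.zap_members(od, radii, areas, ft))
        p = pressure_pad.compute_pressure(areas, ft, od)
        p["pressure"] = 5.0  # force uniform pressure: weights must cancel
        pressures.append(p)
    zaps = pd.concat(frames, ignore_index=True)
    pressure = pd.concat(pressures, ignore_index=True)
    pads = pressure_pad.pad_all(areas, facs, zaps, od, pressure)
    assert len(pads) == 6  # 3 areas x 2 types
    for _, z in zaps.iterrows():
        costs = [od.time(z["area_id"], m) for m in z["member_ids"]]
        got = pads.set_index(["area_id", "facility_type"]).loc[
            (z["area_id"], z["facility_type"]), "pad"]
        assert got == pytest.approx(np.mean(costs))


def test_pad_invariances(rng):
    """Scaling costs by k scales pads by k; rescaling all pressures is a no-op;
    adding a member at exactly the current pad leaves the pad unchanged."""
    areas, facs, od = random_fixture(rng, n_areas=8, n_fac=5)
    zaps, pressure, pads = _full_tables(areas, facs, od)
    k = 3.5
    od_scaled = travel_cost.ODMatrix(od.origins, od.destinations,
                                     od.travel_time * k, od.road_distance * k,
                                     od.metric_tag)
    pads_scaled = pressure_pad.pad_all(areas, facs, zaps, od_scaled, pressure)
    np.testing.assert_allclose(pads_scaled["pad"], pads["pad"] * k, rtol=1e-12)

    pressure2 = pressure.assign(pressure=pressure["pressure"] * 17.0)
    pads2 = pressure_pad.pad_all(areas, facs, zaps, od, pressure2)
    np.testing.assert_allclose(pads2["pad"], pads["pad"], rtol=1e-12)

    pad0 = pressure_pad.compute_pad(["F1", "F2"], [2.0, 6.0], [100.0, 50.0])
    pad1 = pressure_pad.compute_pad(["F1", "F2", "F3"], [2.0, 6.0, pad0],
                                    [100.0, 50.0, 30.0])
    assert pad1 == pytest.approx(pad0)
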