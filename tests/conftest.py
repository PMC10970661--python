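import numpy as np
import pandas as pd
import pytest

from scale_access import travel_cost


def make_areas(rows):
    """rows: (area_id, x, y, population, iris_id[, commune_id, region_id])"""
    out = []
    for r in rows:
        aid, x, y, pop, iris = r[:5]
        commune = r[5] if len(r) > 5 else "C1"
        region = r[6] if len(r) > 6 else "R1"
        out.append(dict(area_id=aid, x=x, y=y, population=pop,
                        iris_id=iris, commune_id=commune, region_id=region))
    return pd.DataFrame(out)


def make_facilities(rows, ftype="gp", range_class="proximity"):
    """rows: (facility_id, x, y[, n_professionals])"""
    return pd.DataFrame([
        dict(facility_id=r[0], x=r[1], y=r[2], facility_type=ftype,
             range_class=range_class, n_professionals=r[3] if len(r) > 3 else 1)
        for r in rows
    ])


def random_fixture(rng, n_areas=None, n_fac=None, n_iris=None):
    """Random small geography + euclidean OD, for oracle comparisons."""
    n_areas = n_areas or int(rng.integers(5, 51))
    n_fac = n_fac or int(rng.integers(2, 11))
    n_iris = n_iris or max(1, n_areas // 4)
    areas = make_areas([
        (f"A{i:03d}", float(rng.uniform(0, 10000)), float(rng.uniform(0, 10000)),
         float(np.round(rng.uniform(0, 500), 1)), f"I{int(rng.integers(n_iris)):03d}")
        for i in range(n_areas)
    ])
    facs = make_facilities([
        (f"F{j:03d}", float(rng.uniform(0, 10000)), float(rng.uniform(0, 10000)),
         int(rng.integers(1, 4)))
        for j in range(n_fac)
    ])
    od = travel_cost.euclidean_costs(areas, facs, speed_kmh=50.0)
    return areas, facs, od


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)
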