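"""Reproducible synthetic geographies for exercising the full pipeline.

Emulates the structure of the reference inputs — residential-area centroids
with heterogeneous populations, typed care facilities of very different
densities, a connected planar road network, and a nested administrative
partition (region ⊃ department ⊃ commune ⊃ IRIS) — without any real data.
Everything derives from a single integer seed through one ``numpy`` Generator,
so identical configs give bit-identical outputs.

Populations are lognormal by default: residential blocks are many and small
with a heavy right tail, like real settlement structure. The geography is a
rectangle partitioned by nested grids; this is deliberately schematic (see the
methods note for what it does and does not emulate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ScaleAccessError
from .geodata_io import DEFAULT_CATALOGUE


@dataclass
class FacilitySpec:
    """How many facilities of one type to place and how."""

    count: int
    placement: str = "uniform"  # uniform | population_biased
    n_professionals: int = 1


#: Default facility mix: dense proximity-range professions, sparse tertiary
#: services, mirroring the relative densities of a primary-care supply base.
DEFAULT_FACILITIES: dict[str, FacilitySpec] = {
    "gp": FacilitySpec(40, "population_biased"),
    "pharmacist": FacilitySpec(25, "population_biased"),
    "nurse": FacilitySpec(35, "population_biased"),
    "physiotherapist": FacilitySpec(30, "population_biased"),
    "dentist": FacilitySpec(25, "population_biased"),
    "ophthalmologist": FacilitySpec(8, "population_biased"),
    "pediatrician": FacilitySpec(6, "population_biased"),
    "obgyn": FacilitySpec(6, "population_biased"),
    "maternity": FacilitySpec(3, "uniform"),
    "short_stay": FacilitySpec(3, "uniform"),
    "emergency": FacilitySpec(3, "uniform"),
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 40000.0, 40000.0)
    n_areas: int = 500
    layout: str = "clustered"  # uniform | clustered
    n_clusters: int = 4
    cluster_spread: float = 2500.0
    population_mu: float = 4.0     # lognormal log-median: ~55 persons per block
    population_sigma: float = 1.0
    facility_types: dict[str, FacilitySpec] = field(
        default_factory=lambda: dict(DEFAULT_FACILITIES))
    network: str = "grid"          # grid | none
    network_rows: int = 15
    network_cols: int = 15
    speed_kmh: float = 50.0
    #: per-edge relative speed spread: edge speed ~ U(1-j, 1+j) * speed_kmh.
    #: Real road links are heterogeneous; a perfectly uniform grid would also
    #: create massive exact travel-time ties that no real network exhibits.
    speed_jitter: float = 0.25
    region_grid: tuple[int, int] = (2, 1)
    dept_grid: tuple[int, int] = (2, 1)      # departments per region
    commune_grid: tuple[int, int] = (2, 2)   # communes per department
    iris_grid: tuple[int, int] = (2, 2)      # iris per commune

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "facility_types" in d:
            d["facility_types"] = {
                t: FacilitySpec(**spec) if isinstance(spec, dict) else spec
                for t, spec in d["facility_types"].items()
            }
        for key in ("extent", "region_grid", "dept_grid", "commune_grid", "iris_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    areas: pd.DataFrame
    facilities: pd.DataFrame
    nodes: pd.DataFrame | None
    edges: pd.DataFrame | None
    adjacency: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("areas", self.areas), ("facilities", self.facilities),
                         ("nodes", self.nodes), ("edges", self.edges),
                         ("adjacency", self.adjacency)):
            if df is None:
                continue
            paths[name] = out / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        return paths


def _grid_cell(coord: np.ndarray, lo: float, size: float, n: int) -> np.ndarray:
    """Index of the grid cell containing each coordinate, clipped to [0, n)."""
    return np.clip(((coord - lo) / size * n).astype(int), 0, n - 1)


def assign_units(x: np.ndarray, y: np.ndarray, cfg: SyntheticConfig) -> pd.DataFrame:
    """Nested unit ids (region, department, commune, iris) from grid position."""
    x0, y0, x1, y1 = cfg.extent
    rx, ry = cfg.region_grid
    dx, dy = cfg.dept_grid
    cx, cy = cfg.commune_grid
    ix, iy = cfg.iris_grid
    gx = _grid_cell(x, x0, x1 - x0, rx * dx * cx * ix)
    gy = _grid_cell(y, y0, y1 - y0, ry * dy * cy * iy)

    reg_i, reg_j = gx // (dx * cx * ix), gy // (dy * cy * iy)
    dep_i, dep_j = (gx // (cx * ix)) % dx, (gy // (cy * iy)) % dy
    com_i, com_j = (gx // ix) % cx, (gy // iy) % cy
    irs_i, irs_j = gx % ix, gy % iy
    region = [f"R{i:02d}{j:02d}" for i, j in zip(reg_i, reg_j)]
    dept = [f"{r}-D{i:02d}{j:02d}" for r, i, j in zip(region, dep_i, dep_j)]
    commune = [f"{d}-C{i:02d}{j:02d}" for d, i, j in zip(dept, com_i, com_j)]
    iris = [f"{c}-I{i:02d}{j:02d}" for c, i, j in zip(commune, irs_i, irs_j)]
    return pd.DataFrame({"iris_id": iris, "commune_id": commune,
                         "department_id": dept, "region_id": region})


def region_adjacency(cfg: SyntheticConfig) -> pd.DataFrame:
    """Neighborhood table of the rectangular partition.

    Region-level rows list 4-adjacent regions (plus a self-row so every region
    is registered even without neighbors); department-level rows list, per
    region, the departments of *other* regions whose cell touches the region.
    """
    rx, ry = cfg.region_grid
    dx, dy = cfg.dept_grid
    rows = []
    regions = {(i, j): f"R{i:02d}{j:02d}" for i in range(rx) for j in range(ry)}
    gdx, gdy = rx * dx, ry * dy
    dept_id = {}
    for gi in range(gdx):
        for gj in range(gdy):
            r = regions[(gi // dx, gj // dy)]
            dept_id[(gi, gj)] = f"{r}-D{gi % dx:02d}{gj % dy:02d}"
    for (i, j), rid in regions.items():
        rows.append((rid, rid, "region"))
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (i + di, j + dj)
            if nb in regions:
                rows.append((rid, regions[nb], "region"))
        # departments of other regions touching this region's rectangle
        touching = set()
        for gi in range(i * dx, (i + 1) * dx):
            for gj in range(j * dy, (j + 1) * dy):
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (gi + di, gj + dj)
                    if 0 <= nb[0] < gdx and 0 <= nb[1] < gdy \
                            and (nb[0] // dx, nb[1] // dy) != (i, j):
                        touching.add(dept_id[nb])
        rows.extend((rid, d, "department") for d in sorted(touching))
    return pd.DataFrame(rows, columns=["unit_id", "neighbor_id", "level"])


def _place_areas(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    x0, y0, x1, y1 = cfg.extent
    if cfg.layout == "uniform":
        x = rng.uniform(x0, x1, cfg.n_areas)
        y = rng.uniform(y0, y1, cfg.n_areas)
    elif cfg.layout == "clustered":
        margin = 0.1 * min(x1 - x0, y1 - y0)
        cx = rng.uniform(x0 + margin, x1 - margin, cfg.n_clusters)
        cy = rng.uniform(y0 + margin, y1 - margin, cfg.n_clusters)
        which = rng.integers(0, cfg.n_clusters, cfg.n_areas)
        x = cx[which] + rng.normal(0, cfg.cluster_spread, cfg.n_areas)
        y = cy[which] + rng.normal(0, cfg.cluster_spread, cfg.n_areas)
        x = np.clip(x, x0, x1)
        y = np.clip(y, y0, y1)
    else:
        raise ScaleAccessError(f"unknown layout {cfg.layout!r}")
    return x, y


def _place_facilities(cfg: SyntheticConfig, areas: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    x0, y0, x1, y1 = cfg.extent
    pop = areas["population"].to_numpy(float)
    prob = pop / pop.sum() if pop.sum() > 0 else None
    rows = []
    for ftype in sorted(cfg.facility_types):
        fspec = cfg.facility_types[ftype]
        if fspec.count < 1:
            raise ScaleAccessError(f"facility type {ftype!r} declared with count 0")
        if ftype not in DEFAULT_CATALOGUE:
            raise ScaleAccessError(f"facility type {ftype!r} not in the catalogue")
        if fspec.placement == "uniform":
            fx = rng.uniform(x0, x1, fspec.count)
            fy = rng.uniform(y0, y1, fspec.count)
        elif fspec.placement == "population_biased":
            pick = rng.choice(len(areas), size=fspec.count, p=prob)
            jitter = 0.01 * min(x1 - x0, y1 - y0)
            fx = np.clip(areas["x"].to_numpy()[pick] + rng.normal(0, jitter, fspec.count), x0, x1)
            fy = np.clip(areas["y"].to_numpy()[pick] + rng.normal(0, jitter, fspec.count), y0, y1)
        else:
            raise ScaleAccessError(f"unknown placement {fspec.placement!r}")
        for k in range(fspec.count):
            rows.append((f"F-{ftype}-{k:04d}", fx[k], fy[k], ftype,
                         DEFAULT_CATALOGUE[ftype], fspec.n_professionals))
    fac = pd.DataFrame(rows, columns=["facility_id", "x", "y", "facility_type",
                                      "range_class", "n_professionals"])
    units = assign_units(fac["x"].to_numpy(), fac["y"].to_numpy(), cfg)
    return pd.concat([fac, units[["department_id", "region_id"]]], axis=1)


def _grid_network(cfg: SyntheticConfig,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    x0, y0, x1, y1 = cfg.extent
    r, c = cfg.network_rows, cfg.network_cols
    xs = np.linspace(x0, x1, c)
    ys = np.linspace(y0, y1, r)
    nodes = [(f"N{i:03d}_{j:03d}", xs[j], ys[i]) for i in range(r) for j in range(c)]
    edges = []
    for i in range(r):
        for j in range(c):
            if j + 1 < c:
                edges.append((f"N{i:03d}_{j:03d}", f"N{i:03d}_{j + 1:03d}",
                              xs[j + 1] - xs[j]))
            if i + 1 < r:
                edges.append((f"N{i:03d}_{j:03d}", f"N{i + 1:03d}_{j:03d}",
                              ys[i + 1] - ys[i]))
    edges_df = pd.DataFrame(edges, columns=["from_node", "to_node", "length_m"])
    speeds = cfg.speed_kmh * rng.uniform(1 - cfg.speed_jitter, 1 + cfg.speed_jitter,
                                         len(edges_df))
    edges_df["travel_time_min"] = np.round(
        edges_df["length_m"] / 1000.0 / speeds * 60.0, 6)
    return pd.DataFrame(nodes, columns=["node_id", "x", "y"]), edges_df


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic geography from one seed.

    Returns areas, facilities (with unit ids), an optional grid road network,
    and the region/department adjacency table. Deterministic under seed.
    """
    if not cfg.facility_types:
        raise ScaleAccessError("config declares no facility types")
    rng = np.random.default_rng(cfg.seed)
    x, y = _place_areas(cfg, rng)
    population = np.round(rng.lognormal(cfg.population_mu, cfg.population_sigma,
                                        cfg.n_areas), 1)
    units = assign_units(x, y, cfg)
    areas = pd.DataFrame({
        "area_id": [f"A{k:05d}" for k in range(cfg.n_areas)],
        "x": np.round(x, 3), "y": np.round(y, 3),
        "population": population,
    })
    areas = pd.concat([areas, units], axis=1)
    facilities = _place_facilities(cfg, areas, rng)
    facilities["x"] = facilities["x"].round(3)
    facilities["y"] = facilities["y"].round(3)
    if cfg.network == "grid":
        nodes, edges = _grid_network(cfg, rng)
    elif cfg.network == "none":
        nodes = edges = None
    else:
        raise ScaleAccessError(f"unknown network kind {cfg.network!r}")
    return SyntheticDataset(areas, facilities, nodes, edges, region_adjacency(cfg))


def accessibility_gradient_fixture(
    seed: int = 0,
    n_city: int = 150,
    n_rural: int = 120,
    extent: tuple[float, float, float, float] = (0.0, 0.0, 30000.0, 30000.0),
    facility_types: dict[str, int] | None = None,
    city_share: float = 0.85,
) -> SyntheticDataset:
    """Geography with a planted accessibility gradient and ground-truth labels.

    A dense city cluster (many areas, most facilities) sits in one corner; a
    sparse rural margin (few, distant facilities) fills the far half. Every
    area carries a ``ground_truth`` column (city|rural); with the default
    sign convention the city group's median index must exceed the rural one.
    """
    if facility_types is None:
        facility_types = {"gp": 20, "pharmacist": 12, "emergency": 3}
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = extent
    cxc, cyc = x0 + 0.25 * (x1 - x0), y0 + 0.25 * (y1 - y0)
    city_x = np.clip(rng.normal(cxc, 1500.0, n_city), x0, x1)
    city_y = np.clip(rng.normal(cyc, 1500.0, n_city), y0, y1)
    # rural margin: the far band of the extent, well away from the city core
    rural_x = rng.uniform(x0 + 0.55 * (x1 - x0), x1, n_rural)
    rural_y = rng.uniform(y0 + 0.35 * (y1 - y0), y1, n_rural)
    x = np.concatenate([city_x, rural_x])
    y = np.concatenate([city_y, rural_y])
    population = np.round(np.concatenate([
        rng.lognormal(4.5, 0.8, n_city),   # denser city blocks
        rng.lognormal(3.5, 0.8, n_rural),
    ]), 1)
    cfg = SyntheticConfig(seed=seed, extent=extent, region_grid=(2, 1), dept_grid=(1, 1),
                          commune_grid=(2, 2), iris_grid=(2, 2))
    units = assign_units(x, y, cfg)
    areas = pd.DataFrame({
        "area_id": [f"A{k:05d}" for k in range(n_city + n_rural)],
        "x": np.round(x, 3), "y": np.round(y, 3),
        "population": population,
        "ground_truth": ["city"] * n_city + ["rural"] * n_rural,
    })
    areas = pd.concat([areas, units], axis=1)

    rows = []
    for ftype in sorted(facility_types):
        count = facility_types[ftype]
        n_in_city = max(1, int(round(city_share * count)))
        for k in range(count):
            if k < n_in_city:
                fx = float(np.clip(rng.normal(cxc, 1800.0), x0, x1))
                fy = float(np.clip(rng.normal(cyc, 1800.0), y0, y1))
            else:
                fx = float(rng.uniform(x0 + 0.55 * (x1 - x0), x1))
                fy = float(rng.uniform(y0 + 0.35 * (y1 - y0), y1))
            rows.append((f"F-{ftype}-{k:04d}", round(fx, 3), round(fy, 3), ftype,
                         DEFAULT_CATALOGUE[ftype], 1))
    facilities = pd.DataFrame(rows, columns=["facility_id", "x", "y", "facility_type",
                                             "range_class", "n_professionals"])
    funits = assign_units(facilities["x"].to_numpy(), facilities["y"].to_numpy(), cfg)
    facilities = pd.concat([facilities, funits[["department_id", "region_id"]]], axis=1)
    return SyntheticDataset(areas, facilities, None, None, region_adjacency(cfg))
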