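"""End-to-end orchestration of the five-stage computation.

Stages, in order: (1) travel costs between areas and candidate facilities;
(2) nearest facility and per-IRIS catchment radius per type; (3) ZAP
membership; (4) facility pressure and pressure-weighted potential
accessibility distances; (5) normalization, linear combination, deciles, and
multiscalar aggregation. Reruns on identical inputs are byte-identical: no
timestamps enter any output, and every stage is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import aggregation, catchment, geodata_io, index, pressure_pad, travel_cost
from .errors import ScaleAccessError

log = logging.getLogger("scale_access")


@dataclass
class RunConfig:
    areas: str
    facilities: str
    out_dir: str
    network_nodes: str | None = None
    network_edges: str | None = None
    adjacency: str | None = None
    od: str | None = None
    metric: str = "euclidean"           # euclidean | network
    impedance: str = "travel_time"      # travel_time | length
    speed_kmh: float = 50.0
    max_snap_m: float = 5000.0
    weight_mode: str = "pressure"
    normalization: str = "rank_normal"
    sign_convention: int = -1
    weights: dict | None = None
    aggregate_levels: list = field(default_factory=lambda: ["iris", "commune"])
    criteria: list = field(default_factory=lambda: list(aggregation.CRITERIA))
    dump_zap: bool = False
    dump_pressure: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def validate(self) -> None:
        for name in ("areas", "facilities"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ScaleAccessError(f"config: {name} path {p!r} does not exist")
        if self.metric not in ("euclidean", "network"):
            raise ScaleAccessError(f"config: unknown metric {self.metric!r}")
        if self.metric == "network" and self.od is None:
            if not (self.network_nodes and self.network_edges):
                raise ScaleAccessError(
                    "config: metric=network requires network_nodes and network_edges paths")
        for name in ("network_nodes", "network_edges", "adjacency", "od"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ScaleAccessError(f"config: {name} path {p!r} does not exist")
        if self.impedance not in ("travel_time", "length"):
            raise ScaleAccessError(f"config: unknown impedance {self.impedance!r}")
        if self.weight_mode not in pressure_pad.WEIGHT_MODES:
            raise ScaleAccessError(f"config: unknown weight_mode {self.weight_mode!r}")
        if self.normalization not in index.NORMALIZATIONS:
            raise ScaleAccessError(f"config: unknown normalization {self.normalization!r}")
        if self.sign_convention not in (-1, 1):
            raise ScaleAccessError("config: sign_convention must be -1 or 1")
        bad = set(self.aggregate_levels) - set(aggregation.LEVELS)
        if bad:
            raise ScaleAccessError(f"config: unknown aggregate levels {sorted(bad)}")
        bad = set(self.criteria) - set(aggregation.CRITERIA)
        if bad:
            raise ScaleAccessError(f"config: unknown criteria {sorted(bad)}")


def compute_scale(
    areas: pd.DataFrame,
    facilities: pd.DataFrame,
    od: travel_cost.ODMatrix,
    adjacency: pd.DataFrame | None = None,
    impedance: str = "travel_time",
    weight_mode: str = "pressure",
    normalization: str = "rank_normal",
    sign_convention: int = -1,
    weights: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """In-memory computation of the per-area index from prepared inputs.

    Returns a dict with the intermediate tables (``nearest``, ``radii``,
    ``zaps``, ``pressure``, ``pads``) and the final ``results`` table.
    """
    cand_by_area = None
    if adjacency is not None and len(adjacency):
        plans = travel_cost.plan_chunks(areas, facilities, adjacency)
        cand_by_area = travel_cost.candidate_map(plans, areas, facilities)

    nearest_frames, radii_frames, zap_frames, pressure_frames = [], [], [], []
    for ftype in sorted(facilities["facility_type"].unique()):
        fac_t = facilities[facilities["facility_type"] == ftype]
        rc = fac_t["range_class"].iloc[0]
        cand_t = ({aid: c[rc] for aid, c in cand_by_area.items()}
                  if cand_by_area is not None else None)
        t0 = time.perf_counter()
        nearest = catchment.nearest_per_area(od, fac_t, areas, cand_t, impedance)
        radii = catchment.iris_radius(nearest, areas)
        zaps = catchment.zap_members(od, radii, areas, fac_t, cand_t, impedance)
        pressure = pressure_pad.compute_pressure(areas, fac_t, od, cand_t, impedance)
        log.info("type %-16s %4d facilities, median radius %.2f  (%.2fs)",
                 ftype, len(fac_t), radii["radius"].median(), time.perf_counter() - t0)
        nearest_frames.append(nearest)
        radii_frames.append(radii)
        zap_frames.append(zaps)
        pressure_frames.append(pressure)

    zaps = pd.concat(zap_frames, ignore_index=True)
    pressure = pd.concat(pressure_frames, ignore_index=True)
    pads = pressure_pad.pad_all(areas, facilities, zaps, od, pressure,
                                weight_mode, impedance)
    results = index.build_results(areas, pads, normalization, weights, sign_convention)
    return {
        "nearest": pd.concat(nearest_frames, ignore_index=True),
        "radii": pd.concat(radii_frames, ignore_index=True),
        "zaps": zaps,
        "pressure": pressure,
        "pads": pads,
        "results": results,
    }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline from files to files; returns the output paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    areas = geodata_io.read_areas(config.areas)
    facilities = geodata_io.read_facilities(config.facilities)
    log.info("inputs: %d areas, %d facilities, %d types",
             len(areas), len(facilities), facilities["facility_type"].nunique())
    adjacency = geodata_io.read_adjacency(config.adjacency) if config.adjacency else None

    if config.od:
        od = geodata_io.read_od(config.od)
    elif config.metric == "euclidean":
        od = travel_cost.euclidean_costs(areas, facilities, config.speed_kmh)
    else:
        nodes, edges, report = geodata_io.read_network(config.network_nodes,
                                                       config.network_edges)
        log.info("network: %d nodes, %d edges, %d component(s)",
                 len(nodes), len(edges), report["n_components"])
        od = travel_cost.network_costs(areas, facilities, nodes, edges,
                                       config.impedance, max_snap_m=config.max_snap_m)

    tables = compute_scale(areas, facilities, od, adjacency, config.impedance,
                           config.weight_mode, config.normalization,
                           config.sign_convention, config.weights)

    agg, agr = aggregation.aggregate_all(tables["results"], config.aggregate_levels,
                                         config.criteria)
    outputs: dict[str, Path] = {}
    outputs["results"] = out_dir / "results.csv"
    geodata_io.write_results(tables["results"], outputs["results"])
    outputs["aggregated"] = out_dir / "aggregated.csv"
    agg.to_csv(outputs["aggregated"], index=False)
    outputs["agreement"] = out_dir / "agreement.csv"
    agr.to_csv(outputs["agreement"], index=False)
    if config.dump_zap:
        outputs["zap"] = out_dir / "zap.csv"
        catchment.zap_table_for_dump(tables["zaps"]).to_csv(outputs["zap"], index=False)
    if config.dump_pressure:
        outputs["pressure"] = out_dir / "pressure.csv"
        tables["pressure"].to_csv(outputs["pressure"], index=False)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {name: _sha256(p) for name, p in
                   (("areas", config.areas), ("facilities", config.facilities),
                    ("network_nodes", config.network_nodes),
                    ("network_edges", config.network_edges),
                    ("adjacency", config.adjacency), ("od", config.od)) if p},
        "rows": {"areas": len(areas), "facilities": len(facilities),
                 "results": len(tables["results"]), "aggregated": len(agg)},
    }
    outputs["manifest"] = out_dir / "manifest.json"
    with open(outputs["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("wrote %d output files to %s", len(outputs), out_dir)
    return outputs
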