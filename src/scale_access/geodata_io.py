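"""Read, validate and write the point layers, networks, OD matrices and result tables.

All geometry lives in one projected planar CRS chosen by the caller (the
reference deployment uses RGF93 / Lambert-93); this module never reprojects.
Coordinates that look like lon/lat degrees are refused outright, because every
downstream distance computation assumes meters.

Supported formats are deliberately plain text: CSV (comma, UTF-8, header row,
"." decimal mark) and GeoJSON Point feature collections.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CoordinateSystemError, NetworkError, SchemaError

AREA_COLUMNS = ["area_id", "x", "y", "population", "iris_id", "commune_id", "region_id"]
FACILITY_COLUMNS = ["facility_id", "x", "y", "facility_type", "range_class", "n_professionals"]
RANGE_CLASSES = {"proximity", "tertiary"}

#: Facility-type catalogue of the reference deployment: five proximity-range
#: professions and six tertiary-range services.
DEFAULT_CATALOGUE = {
    "gp": "proximity",
    "physiotherapist": "proximity",
    "nurse": "proximity",
    "dentist": "proximity",
    "pharmacist": "proximity",
    "obgyn": "tertiary",
    "maternity": "tertiary",
    "pediatrician": "tertiary",
    "ophthalmologist": "tertiary",
    "short_stay": "tertiary",
    "emergency": "tertiary",
}


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".geojson", ".json"}:
        return "geojson"
    if suffix == ".csv":
        return "csv"
    raise SchemaError(f"cannot infer format from suffix {suffix!r}; pass format explicitly")


def _read_point_table(path: str | Path, fmt: str | None) -> pd.DataFrame:
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return pd.read_csv(path, dtype={"iris_id": str, "commune_id": str, "region_id": str,
                                        "area_id": str, "facility_id": str})
    if fmt == "geojson":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rows = []
        for feat in doc.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise SchemaError(f"non-Point geometry {geom.get('type')!r} in {path}")
            x, y = geom["coordinates"][:2]
            row = dict(feat.get("properties") or {})
            row["x"], row["y"] = x, y
            rows.append(row)
        return pd.DataFrame(rows)
    raise SchemaError(f"unsupported format {fmt!r}")


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required field {col!r}")


def _check_planar(df: pd.DataFrame, what: str) -> None:
    # Genuine planar data in meters essentially never fits in a 360x180 box.
    if len(df) and (df["x"].abs() <= 180).all() and (df["y"].abs() <= 90).all():
        raise CoordinateSystemError(
            f"{what}: coordinates look like lon/lat degrees; supply projected planar "
            "coordinates in meters (e.g. RGF93 / Lambert-93)"
        )


def read_areas(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read and validate residential areas (population points with nested unit ids).

    Returns a DataFrame with columns ``area_id, x, y, population, iris_id,
    commune_id, region_id`` (plus any extra columns such as ``department_id``).

    Raises
    ------
    SchemaError
        on a missing field, duplicated ``area_id``, negative population,
        empty ``iris_id``, or inconsistent iris→commune→region nesting.
    CoordinateSystemError
        if coordinates look like lon/lat degrees.
    """
    df = _read_point_table(path, fmt)
    _require_columns(df, AREA_COLUMNS, "areas")
    df = df.copy()
    for col in ("area_id", "iris_id", "commune_id", "region_id"):
        df[col] = df[col].astype(str)
    if df["area_id"].duplicated().any():
        dupes = df.loc[df["area_id"].duplicated(), "area_id"].unique()[:5]
        raise SchemaError(f"areas: duplicated area_id {list(dupes)}")
    df["population"] = pd.to_numeric(df["population"], errors="raise").astype(float)
    if (df["population"] < 0).any():
        raise SchemaError("areas: population must be >= 0")
    if (df["iris_id"].str.len() == 0).any() or df["iris_id"].isin(["nan", "None"]).any():
        raise SchemaError("areas: every area needs a non-empty iris_id")
    _check_planar(df, "areas")
    validate_nesting(df)
    return df.reset_index(drop=True)


def validate_nesting(areas: pd.DataFrame) -> None:
    """Check that each iris maps to one commune and each commune to one region."""
    for child, parent in (("iris_id", "commune_id"), ("commune_id", "region_id")):
        n_parents = areas.groupby(child)[parent].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            raise SchemaError(
                f"areas: {child} {bad.index[0]!r} maps to {bad.iloc[0]} distinct {parent} values"
            )


def read_facilities(
    path: str | Path,
    fmt: str | None = None,
    catalogue: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate supply points (typed facilities with professional head counts).

    ``catalogue`` maps facility_type → range_class and defaults to the
    eleven-type primary-care catalogue; an unknown facility_type raises.
    ``n_professionals`` defaults to 1 when the column is absent.
    """
    if catalogue is None:
        catalogue = DEFAULT_CATALOGUE
    df = _read_point_table(path, fmt)
    if "n_professionals" not in df.columns:
        df["n_professionals"] = 1
    _require_columns(df, FACILITY_COLUMNS, "facilities")
    df = df.copy()
    df["facility_id"] = df["facility_id"].astype(str)
    if df["facility_id"].duplicated().any():
        dupes = df.loc[df["facility_id"].duplicated(), "facility_id"].unique()[:5]
        raise SchemaError(f"facilities: duplicated facility_id {list(dupes)}")
    unknown = set(df["facility_type"]) - set(catalogue)
    if unknown:
        raise SchemaError(
            f"facilities: unknown facility_type {sorted(unknown)}; catalogue = {sorted(catalogue)}"
        )
    bad_range = set(df["range_class"]) - RANGE_CLASSES
    if bad_range:
        raise SchemaError(f"facilities: unknown range_class {sorted(bad_range)}")
    mismatched = df[df["range_class"] != df["facility_type"].map(catalogue)]
    if len(mismatched):
        row = mismatched.iloc[0]
        raise SchemaError(
            f"facilities: {row.facility_id} declares range_class {row.range_class!r} but the "
            f"catalogue assigns {catalogue[row.facility_type]!r} to {row.facility_type!r}"
        )
    df["n_professionals"] = pd.to_numeric(df["n_professionals"], errors="raise")
    if (df["n_professionals"] < 1).any() or (df["n_professionals"] % 1 != 0).any():
        raise SchemaError("facilities: n_professionals must be an integer >= 1")
    df["n_professionals"] = df["n_professionals"].astype(int)
    _check_planar(df, "facilities")
    return df.reset_index(drop=True)


def read_network(
    nodes_path: str | Path, edges_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read a road network as nodes.csv + edges.csv.

    Returns ``(nodes, edges, report)`` where ``report`` describes the connected
    components of the undirected graph (``n_components`` and component sizes).

    Edges are bidirectional unless a 0/1 ``oneway`` column is present.
    """
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    _require_columns(nodes, ["node_id", "x", "y"], "network nodes")
    _require_columns(edges, ["from_node", "to_node", "length_m", "travel_time_min"], "network edges")
    if len(edges) == 0:
        raise NetworkError("empty network: edge file has no rows")
    nodes = nodes.copy()
    nodes["node_id"] = nodes["node_id"].astype(str)
    if nodes["node_id"].duplicated().any():
        raise NetworkError("network: duplicated node_id")
    edges = edges.copy()
    edges["from_node"] = edges["from_node"].astype(str)
    edges["to_node"] = edges["to_node"].astype(str)
    known = set(nodes["node_id"])
    referenced = set(edges["from_node"]) | set(edges["to_node"])
    missing = referenced - known
    if missing:
        raise NetworkError(f"network: edges reference unknown nodes {sorted(missing)[:5]}")
    if (edges["length_m"] <= 0).any() or (edges["travel_time_min"] <= 0).any():
        raise NetworkError("network: length_m and travel_time_min must be > 0")
    g = nx.Graph()
    g.add_nodes_from(nodes["node_id"])
    g.add_edges_from(zip(edges["from_node"], edges["to_node"]))
    components = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)
    report = {"n_components": len(components), "component_sizes": [len(c) for c in components],
              "components": components}
    return nodes, edges, report


def read_adjacency(path: str | Path) -> pd.DataFrame:
    """Read the unit-neighborhood table: unit_id, neighbor_id, level(region|department)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["unit_id", "neighbor_id", "level"], "adjacency")
    bad = set(df["level"]) - {"region", "department"}
    if bad:
        raise SchemaError(f"adjacency: unknown level {sorted(bad)}")
    return df


def read_od(path: str | Path):
    """Read a long-format OD matrix CSV (origin_id,destination_id,travel_time_min,distance_m)."""
    from .travel_cost import ODMatrix

    df = pd.read_csv(path, dtype={"origin_id": str, "destination_id": str})
    _require_columns(df, ["origin_id", "destination_id", "travel_time_min", "distance_m"], "od")
    return ODMatrix.from_frame(df)


def write_od(od, path: str | Path) -> None:
    od.to_frame().to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a result table as CSV or GeoJSON; raises on an empty table."""
    if len(results) == 0:
        raise SchemaError("write_results: refusing to write an empty result table")
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        results.to_csv(path, index=False)
    elif fmt == "geojson":
        if not {"x", "y"} <= set(results.columns):
            raise SchemaError("write_results: geojson output needs x and y columns")
        features = []
        for _, row in results.iterrows():
            props = {k: (row[k] if not (isinstance(row[k], float) and math.isnan(row[k])) else None)
                     for k in results.columns if k not in ("x", "y")}
            features.append({"type": "Feature",
                             "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                             "properties": props})
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise SchemaError(f"unsupported format {fmt!r}")


def read_results(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return pd.read_csv(path, dtype={"area_id": str})
    df = _read_point_table(path, fmt)
    df["area_id"] = df["area_id"].astype(str)
    return df


def write_points(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a point layer (areas or facilities) as CSV or GeoJSON."""
    write_results(df, path, fmt)
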