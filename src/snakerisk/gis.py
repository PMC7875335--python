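"""Readers/writers for the pipeline's standard formats, plus zonal statistics.

Tables travel as UTF-8 comma-separated CSV with a header row (a declared
decimal-separator option accommodates sources that print decimal commas);
geometry travels as GeoJSON FeatureCollections whose features carry a
``muni_id`` property (Polygon and MultiPolygon both accepted; coordinates are
treated as planar — real-world inputs must already be in a projected CRS for
contiguity to make sense).  Invalid surveillance rows (negative counts,
deaths exceeding cases, non-positive population) are collected into a
rejection report rather than silently dropped.

``zonal_stats`` aggregates a gridded raster field over polygons using the
cell-centre rule: a cell contributes to the polygon containing its centre.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "read_surveillance",
    "read_drivers",
    "write_table",
    "read_geometry",
    "write_geojson",
    "read_adjacency",
    "write_adjacency",
    "zonal_stats",
]

SURVEILLANCE_COLUMNS = ("muni_id", "state_id", "region_id", "population", "cases", "deaths")


def _read_csv(path, decimal: str = ".") -> pd.DataFrame:
    return pd.read_csv(path, decimal=decimal)


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing required column(s): {', '.join(missing)}")


def read_surveillance(path, decimal: str = ".") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the surveillance table.

    Returns ``(records, rejections)``: valid rows, and a report of excluded
    rows with the reason each violated an invariant.
    """
    df = _read_csv(path, decimal=decimal)
    _require(df, SURVEILLANCE_COLUMNS, "surveillance")
    reasons = []
    for idx, row in df.iterrows():
        problems = []
        if row["population"] <= 0:
            problems.append("population must be positive")
        if row["cases"] < 0 or row["deaths"] < 0:
            problems.append("counts must be non-negative")
        if row["deaths"] > row["cases"]:
            problems.append("deaths exceed cases")
        if problems:
            reasons.append({"row": idx, "muni_id": row["muni_id"], "reason": "; ".join(problems)})
    rejections = pd.DataFrame(reasons, columns=["row", "muni_id", "reason"])
    bad = set(rejections["row"]) if not rejections.empty else set()
    records = df.loc[[i for i in df.index if i not in bad]].reset_index(drop=True)
    dup = records["muni_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate muni_id in surveillance table: {records['muni_id'][dup].tolist()}")
    return records, rejections


def read_drivers(path, decimal: str = ".") -> pd.DataFrame:
    df = _read_csv(path, decimal=decimal)
    _require(df, ("muni_id",), "drivers")
    if df["muni_id"].duplicated().any():
        raise ValueError("duplicate muni_id in drivers table")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV writer (fixed column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------- #
# geometry
# ---------------------------------------------------------------------- #
def read_geometry(path) -> tuple[dict, pd.DataFrame]:
    """Read a GeoJSON FeatureCollection keyed by ``muni_id``.

    Returns ``(geometries, properties)``: a dict muni_id -> shapely geometry
    and a DataFrame of all feature properties.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("geometry file must be a GeoJSON FeatureCollection")
    geoms: dict = {}
    props = []
    for feat in gj.get("features", []):
        p = feat.get("properties") or {}
        if "muni_id" not in p:
            raise ValueError("GeoJSON feature lacks required 'muni_id' property")
        mid = p["muni_id"]
        if mid in geoms:
            raise ValueError(f"duplicate muni_id {mid!r} in geometry file")
        g = geom_shape(feat["geometry"])
        if g.is_empty:
            raise ValueError(f"empty geometry for muni_id {mid!r}")
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unsupported geometry type {g.geom_type} for {mid!r}")
        geoms[mid] = g
        props.append(p)
    return geoms, pd.DataFrame(props)


def write_geojson(geometries: Mapping, properties: pd.DataFrame | None, path) -> None:
    """Write geometries (id -> shapely) with per-id properties as GeoJSON.

    ``properties`` must contain a ``muni_id`` column; extra columns become
    feature properties (e.g. cluster quadrant, risk grade).  Output is
    deterministic: features sorted by id, keys sorted.
    """
    prop_map: dict = {}
    if properties is not None:
        prop_map = {
            row["muni_id"]: {k: _jsonable(v) for k, v in row.items()}
            for row in properties.to_dict("records")
        }
    features = []
    for mid in sorted(geometries, key=str):
        p = prop_map.get(mid, {"muni_id": mid})
        features.append(
            {"type": "Feature", "properties": p, "geometry": geom_mapping(geometries[mid])}
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return None if np.isnan(v) else float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def read_adjacency(path) -> list[tuple]:
    """Adjacency CSV (muni_id, neighbor_id) -> symmetric edge list."""
    df = _read_csv(path)
    _require(df, ("muni_id", "neighbor_id"), "adjacency")
    return list(zip(df["muni_id"], df["neighbor_id"]))


def write_adjacency(weights, path) -> None:
    rows = [
        {"muni_id": i, "neighbor_id": j}
        for i in weights.ids
        for j in weights.neighbors[i]
    ]
    write_table(pd.DataFrame(rows, columns=["muni_id", "neighbor_id"]), path)


# ---------------------------------------------------------------------- #
# zonal statistics
# ---------------------------------------------------------------------- #
def zonal_stats(
    raster: np.ndarray,
    polygons: Mapping,
    origin: tuple[float, float] = (0.0, 0.0),
    cellsize: float = 1.0,
) -> pd.DataFrame:
    """Per-polygon min, mean, max, standard deviation and range of a raster.

    ``raster`` is a 2-D array whose row 0 is the *top* row; cell (i, j) has
    centre ``(x0 + (j+0.5)*cellsize, y0 - (i+0.5)*cellsize)`` with the origin
    at the top-left corner.  A cell belongs to the polygon covering its
    centre.  Standard deviation is the population SD (ddof=0), the zonal
    convention.  Polygons containing no cell centre get missing statistics
    and a warning.
    """
    r = np.asarray(raster, dtype=float)
    if r.ndim != 2:
        raise ValueError("raster must be 2-dimensional")
    x0, y0 = origin
    nrow, ncol = r.shape
    xs = x0 + (np.arange(ncol) + 0.5) * cellsize
    ys = y0 - (np.arange(nrow) + 0.5) * cellsize
    gx, gy = np.meshgrid(xs, ys)
    gx, gy, vals = gx.ravel(), gy.ravel(), r.ravel()

    rows = []
    for mid in polygons:
        inside = shapely.contains_xy(polygons[mid], gx, gy)
        v = vals[inside]
        if v.size == 0:
            warnings.warn(f"polygon {mid!r} contains no raster cell centres", stacklevel=2)
            rows.append({"muni_id": mid, "min": np.nan, "mean": np.nan, "max": np.nan,
                         "std": np.nan, "range": np.nan, "n_cells": 0})
            continue
        rows.append(
            {
                "muni_id": mid,
                "min": float(v.min()),
                "mean": float(v.mean()),
                "max": float(v.max()),
                "std": float(v.std(ddof=0)),
                "range": float(v.max() - v.min()),
                "n_cells": int(v.size),
            }
        )
    return pd.DataFrame(rows)
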