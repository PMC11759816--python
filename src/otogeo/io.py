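"""Readers and writers for the pipeline's on-disk formats.

Tables are delimited text with a header row (CSV); gridded fields and maps are
NetCDF with CF-style coordinate names (written through xarray's scipy engine);
polygons are GeoJSON.  All readers are order-invariant and round-trip
losslessly with the corresponding writers.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math

import numpy as np
import pandas as pd
import xarray as xr

from .types import (
    AblationPoint,
    AreaPolygon,
    DepthStratum,
    EnvField,
    FishRecord,
    OtolithTransect,
    RegionSignature,
    wrap_lon,
)

log = logging.getLogger("otogeo")

_META_COLS = {"fish_id", "index", "distance"}


# --------------------------------------------------------------------------
# transect tables
# --------------------------------------------------------------------------

def read_transects(path) -> list[OtolithTransect]:
    """Read a long-format ablation table into one transect per fish.

    The table must have columns ``fish_id``, ``index``, ``distance`` plus one
    column per element (element:Ca ratio); an optional ``Al`` column is used
    as the contamination sentinel.  Rows may appear in any order; unparseable
    ratio cells become missing (nan).  Duplicate (fish_id, index) pairs and
    non-monotone distances are hard errors naming the fish.
    """
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = _META_COLS - set(df.columns)
    if missing:
        raise ValueError(f"transect table missing columns: {sorted(missing)}")
    elements = [c for c in df.columns if c not in _META_COLS]
    for el in elements:
        df[el] = pd.to_numeric(df[el], errors="coerce")

    dup = df.duplicated(subset=["fish_id", "index"])
    if dup.any():
        bad = sorted(df.loc[dup, "fish_id"].unique())
        raise ValueError(f"duplicate (fish_id, index) rows for fish: {bad}")

    transects = []
    for fish_id, grp in df.sort_values(["fish_id", "index"]).groupby("fish_id", sort=True):
        points = []
        for _, row in grp.iterrows():
            ratios = {el: float(row[el]) for el in elements if el != "Al"}
            al = float(row["Al"]) if "Al" in elements and not pd.isna(row["Al"]) else None
            points.append(
                AblationPoint(
                    index=int(row["index"]),
                    distance_from_core=float(row["distance"]),
                    ratios=ratios,
                    al_ratio=al,
                )
            )
        try:
            transects.append(OtolithTransect(fish_id=str(fish_id), points=points))
        except ValueError as err:
            raise ValueError(str(err)) from None
    log.info("read %d transects from %s", len(transects), path)
    return transects


def write_transects(transects: list[OtolithTransect], path) -> None:
    rows = []
    for tr in transects:
        for p in tr.points:
            row = {"fish_id": tr.fish_id, "index": p.index, "distance": p.distance_from_core}
            row.update(p.ratios)
            if p.al_ratio is not None:
                row["Al"] = p.al_ratio
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# fish metadata
# --------------------------------------------------------------------------

def read_fish(path) -> list[FishRecord]:
    df = pd.read_csv(path, dtype={"fish_id": str, "capture_event_id": str})
    fish = []
    for _, row in df.iterrows():
        fish.append(
            FishRecord(
                fish_id=str(row["fish_id"]),
                total_length=float(row["total_length"]),
                capture_date=_dt.date.fromisoformat(str(row["capture_date"])),
                capture_lon=float(wrap_lon(row["capture_lon"])),
                capture_lat=float(row["capture_lat"]),
                capture_event_id=str(row["capture_event_id"]),
                total_weight=float(row["total_weight"]) if "total_weight" in df and not pd.isna(row.get("total_weight")) else None,
                sex=str(row.get("sex", "unknown")) if not pd.isna(row.get("sex", "unknown")) else "unknown",
                age_at_capture=float(row["age_at_capture"]) if "age_at_capture" in df and not pd.isna(row.get("age_at_capture")) else None,
                birth_year=int(row["birth_year"]) if "birth_year" in df and not pd.isna(row.get("birth_year")) else None,
            )
        )
    return fish


def write_fish(fish: list[FishRecord], path) -> None:
    rows = []
    for f in fish:
        rows.append(
            {
                "fish_id": f.fish_id,
                "total_length": f.total_length,
                "total_weight": f.total_weight,
                "sex": f.sex,
                "capture_date": f.capture_date.isoformat(),
                "capture_lon": f.capture_lon,
                "capture_lat": f.capture_lat,
                "capture_event_id": f.capture_event_id,
                "age_at_capture": f.age_at_capture,
                "birth_year": f.birth_year,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# region signatures
# --------------------------------------------------------------------------

def read_signatures(path) -> list[RegionSignature]:
    df = pd.read_csv(path, dtype={"fish_id": str})
    elements = [c for c in df.columns if c not in {"fish_id", "region", "d18O", "d13C"}]
    sigs = []
    for _, row in df.iterrows():
        sigs.append(
            RegionSignature(
                fish_id=str(row["fish_id"]),
                region=str(row["region"]),
                elemental={e: float(row[e]) for e in elements if not pd.isna(row[e])},
                d18O=float(row["d18O"]) if "d18O" in df and not pd.isna(row.get("d18O")) else None,
                d13C=float(row["d13C"]) if "d13C" in df and not pd.isna(row.get("d13C")) else None,
            )
        )
    return sigs


def write_signatures(sigs: list[RegionSignature], path) -> None:
    rows = []
    for s in sigs:
        row = {"fish_id": s.fish_id, "region": s.region}
        row.update(s.elemental)
        row["d18O"] = s.d18O
        row["d13C"] = s.d13C
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def signatures_frame(sigs: list[RegionSignature], region: str, elements: list[str],
                     isotopes: bool = False) -> pd.DataFrame:
    """Assemble a per-fish signature matrix for one region."""
    rows = {}
    for s in sigs:
        if s.region != region:
            continue
        row = {e: s.elemental.get(e, math.nan) for e in elements}
        if isotopes:
            row["d18O"] = math.nan if s.d18O is None else s.d18O
            row["d13C"] = math.nan if s.d13C is None else s.d13C
        rows[s.fish_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "fish_id"
    return df.sort_index()


# --------------------------------------------------------------------------
# gridded fields
# --------------------------------------------------------------------------

def _strata_to_arrays(strata: list[DepthStratum]):
    return (
        np.array([s.lower for s in strata], dtype=float),
        np.array([s.upper for s in strata], dtype=float),
    )


def env_to_dataset(field: EnvField) -> xr.Dataset:
    lo, hi = _strata_to_arrays(field.strata)
    data = {
        field.variable: (("stratum", "lat", "lon"), field.values),
        "stratum_lower": (("stratum",), lo),
        "stratum_upper": (("stratum",), hi),
    }
    if field.variance is not None:
        data[field.variable + "_variance"] = (("stratum", "lat", "lon"), field.variance)
    return xr.Dataset(
        data,
        coords={
            "stratum": np.arange(len(field.strata)),
            "lat": field.lat,
            "lon": field.lon,
        },
        attrs={"variable": field.variable},
    )


def dataset_to_env(ds: xr.Dataset, variable: str | None = None) -> EnvField:
    if "stratum_lower" not in ds or "stratum_upper" not in ds:
        raise ValueError("gridded file lacks stratum metadata (stratum_lower/upper)")
    if variable is None:
        variable = str(ds.attrs.get("variable", ""))
        if not variable:
            candidates = [v for v in ds.data_vars
                          if v not in {"stratum_lower", "stratum_upper"} and not v.endswith("_variance")]
            if len(candidates) != 1:
                raise ValueError("cannot infer field variable name; pass variable=")
            variable = str(candidates[0])
    strata = [
        DepthStratum(float(a), float(b))
        for a, b in zip(ds["stratum_lower"].values, ds["stratum_upper"].values)
    ]
    var_name = variable + "_variance"
    return EnvField(
        variable=variable,
        lon=ds["lon"].values.copy(),
        lat=ds["lat"].values.copy(),
        strata=strata,
        values=ds[variable].values.copy(),
        variance=ds[var_name].values.copy() if var_name in ds else None,
    )


def write_env_field(field: EnvField, path) -> None:
    env_to_dataset(field).to_netcdf(path, engine="scipy")


def read_env_field(path, variable: str | None = None) -> EnvField:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_env(ds.load(), variable)


# write_map / read_map: occurrence and isoscape grids share the EnvField layout
write_map = write_env_field
read_map = read_env_field


# --------------------------------------------------------------------------
# polygons
# --------------------------------------------------------------------------

def read_polygons(path) -> list[AreaPolygon]:
    with open(path) as fh:
        gj = json.load(fh)
    polys = []
    for feat in gj["features"]:
        ring = [tuple(map(float, xy)) for xy in feat["geometry"]["coordinates"][0]]
        polys.append(AreaPolygon(name=str(feat["properties"]["name"]), boundary=ring))
    return polys


def write_polygons(polys: list[AreaPolygon], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": p.name},
            "geometry": {"type": "Polygon", "coordinates": [[list(xy) for xy in p.boundary]]},
        }
        for p in polys
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
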