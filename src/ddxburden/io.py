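"""Readers and writers for station tables, study polygons, and rasters.

File dialects:

* ``stations.csv``: id, x_m, y_m, water_depth_m, sampling_year,
  cross_section_ratio (optional).
* ``slices.csv``: station_id, z_top_cm, z_bottom_cm, the six congener
  columns ``<congener>_ug_kg``, total_solids_frac.
* ``minicores.csv``: station_id, replicate, interval ("0-12"|"12-24"),
  six congener columns.
* ``study_area.geojson``: one polygon feature, planar meters.
* Rasters: ESRI ASCII grid dialect (ncols/nrows/xllcorner/yllcorner/
  cellsize/nodata_value header).

A DDX column is never read: DDX is recomputed as the congener sum. If a
supplied DDX column disagrees with that sum by more than 0.1% relative, a
warning is logged.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping, Polygon

from .model import (
    CONGENERS,
    DepthProfile,
    MiniCore,
    SchemaError,
    Slice,
    Station,
    StudyArea,
    Surface,
    ValidationError,
)

logger = logging.getLogger("ddxburden")

_CONC_COLS = {c: f"{c}_ug_kg" for c in CONGENERS}

_STATION_COLS = ["id", "x_m", "y_m", "water_depth_m", "sampling_year"]
_SLICE_COLS = ["station_id", "z_top_cm", "z_bottom_cm"] + list(_CONC_COLS.values())
_MINICORE_COLS = ["station_id", "replicate", "interval"] + list(_CONC_COLS.values())


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_supplied_ddx(df: pd.DataFrame, path) -> None:
    """DDX is always derived; a supplied column is only cross-checked."""
    if "ddx_ug_kg" not in df.columns:
        return
    derived = sum(df[c] for c in _CONC_COLS.values())
    supplied = df["ddx_ug_kg"]
    scale = np.maximum(np.abs(derived), 1e-30)
    bad = np.abs(supplied - derived) / scale > 1e-3
    if bad.any():
        logger.warning(
            "%s: supplied ddx_ug_kg differs from the congener sum by >0.1%% "
            "on %d row(s); the derived sum is used", path, int(bad.sum())
        )


def read_stations(stations_path, slices_path, minicores_path=None) -> list[Station]:
    """Read and validate the station/slice(/mini-core) tables.

    Returns Stations with depth-sorted profiles. Congener columns are mapped
    onto analyte keys; DDX is computed, never read.
    """
    st = pd.read_csv(stations_path, float_precision="round_trip")
    sl = pd.read_csv(slices_path, float_precision="round_trip")
    _require(st, _STATION_COLS, stations_path)
    _require(sl, _SLICE_COLS, slices_path)
    _check_supplied_ddx(sl, slices_path)

    minicores: dict[str, list[MiniCore]] = {}
    if minicores_path is not None:
        mc = pd.read_csv(minicores_path, float_precision="round_trip")
        _require(mc, _MINICORE_COLS, minicores_path)
        _check_supplied_ddx(mc, minicores_path)
        for row in mc.itertuples(index=False):
            content = {c: float(getattr(row, col)) for c, col in _CONC_COLS.items()}
            w = float(getattr(row, "cross_section_weight", 1.0))
            core = MiniCore(station_id=str(row.station_id),
                            replicate=int(row.replicate),
                            interval=str(row.interval).strip(),
                            content=content,
                            cross_section_weight=w)
            minicores.setdefault(core.station_id, []).append(core)

    stations: list[Station] = []
    has_ts = "total_solids_frac" in sl.columns
    for row in st.itertuples(index=False):
        sid = str(row.id)
        rows = sl[sl["station_id"].astype(str) == sid]
        slices = []
        for r in rows.itertuples(index=False):
            conc = {c: float(getattr(r, col)) for c, col in _CONC_COLS.items()}
            ts = float(r.total_solids_frac) if has_ts else math.nan
            try:
                slices.append(Slice(z_top=float(r.z_top_cm),
                                    z_bottom=float(r.z_bottom_cm),
                                    conc=conc,
                                    total_solids=None if math.isnan(ts) else ts))
            except ValidationError as e:
                raise ValidationError(f"station {sid}: {e}") from None
        try:
            profile = DepthProfile(slices)
        except ValidationError as e:
            raise ValidationError(f"station {sid}: {e}") from None
        ratio = float(getattr(row, "cross_section_ratio", 12.0))
        if math.isnan(ratio):
            ratio = 12.0
        stations.append(Station(id=sid, x=float(row.x_m), y=float(row.y_m),
                                water_depth=float(row.water_depth_m),
                                sampling_year=float(row.sampling_year),
                                profile=profile,
                                minicores=minicores.get(sid, []),
                                core_cross_section_ratio=ratio))
    return stations


def write_stations(stations: list[Station], stations_path, slices_path,
                   minicores_path=None) -> None:
    """Write station/slice(/mini-core) tables in the dialect read back by
    :func:`read_stations`. Full float precision is preserved."""
    st_rows, sl_rows, mc_rows = [], [], []
    for s in stations:
        st_rows.append({"id": s.id, "x_m": s.x, "y_m": s.y,
                        "water_depth_m": s.water_depth,
                        "sampling_year": s.sampling_year,
                        "cross_section_ratio": s.core_cross_section_ratio})
        for sl in s.profile:
            row = {"station_id": s.id, "z_top_cm": sl.z_top,
                   "z_bottom_cm": sl.z_bottom}
            row.update({col: sl.conc.get(c, 0.0) for c, col in _CONC_COLS.items()})
            row["total_solids_frac"] = (math.nan if sl.total_solids is None
                                        else sl.total_solids)
            sl_rows.append(row)
        for mc in s.minicores:
            row = {"station_id": s.id, "replicate": mc.replicate,
                   "interval": mc.interval,
                   "cross_section_weight": mc.cross_section_weight}
            row.update({col: mc.content.get(c, 0.0)
                        for c, col in _CONC_COLS.items()})
            mc_rows.append(row)
    pd.DataFrame(st_rows).to_csv(stations_path, index=False,
                                 float_format="%.17g")
    pd.DataFrame(sl_rows).to_csv(slices_path, index=False,
                                 float_format="%.17g")
    if minicores_path is not None:
        pd.DataFrame(mc_rows).to_csv(minicores_path, index=False,
                                     float_format="%.17g")


# --------------------------------------------------------------------------
# Polygons
# --------------------------------------------------------------------------

def read_polygon(path) -> StudyArea:
    """Read the study-area polygon from GeoJSON (planar meters).

    The area is computed from the ring geometry (holes subtracted); a
    self-intersecting ring raises a validation error.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        feats = gj["features"]
        if len(feats) != 1:
            raise ValidationError(
                f"{path}: expected exactly one polygon feature, got {len(feats)}"
            )
        geom = shape(feats[0]["geometry"])
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValidationError(f"{path}: geometry is {geom.geom_type}, "
                              "expected Polygon")
    return StudyArea(polygon=geom)


def write_polygon(area: StudyArea, path) -> None:
    gj = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": {},
                        "geometry": mapping(area.polygon)}]}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def local_projection(lon, lat, lon0: float, lat0: float):
    """Approximate equirectangular projection of lon/lat (degrees) to local
    planar meters around (lon0, lat0).

    Adequate only for basin-scale extents (tens of km); for anything larger
    use a proper projected CRS upstream.
    """
    R = 6371000.0
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - lon0) * R * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * R
    return x, y


# --------------------------------------------------------------------------
# Rasters (ESRI ASCII grid)
# --------------------------------------------------------------------------

_NODATA = -9999.0


def write_surface(surface: Surface, path) -> None:
    """Write a Surface as an ESRI ASCII grid. Values are written with
    17 significant digits so a read-back reproduces them bit-identically."""
    vals = surface.values
    with open(path, "w") as fh:
        fh.write(f"ncols {surface.ncols}\n")
        fh.write(f"nrows {surface.nrows}\n")
        fh.write(f"xllcorner {surface.x_ll:.17g}\n")
        fh.write(f"yllcorner {surface.y_ll:.17g}\n")
        fh.write(f"cellsize {surface.cellsize:.17g}\n")
        fh.write(f"nodata_value {_NODATA:g}\n")
        for row in vals:
            fh.write(" ".join(f"{_NODATA:g}" if np.isnan(v) else f"{v:.17g}"
                              for v in row))
            fh.write("\n")


def read_surface(path) -> Surface:
    """Read an ESRI ASCII grid written by :func:`write_surface`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in header:
            raise SchemaError(f"{path}: missing raster header field {k!r}")
    vals = np.array(rows, dtype=float)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"{path}: data block shape {vals.shape} does not match header"
        )
    nodata = header.get("nodata_value", _NODATA)
    vals[vals == nodata] = np.nan
    return Surface(x_ll=header["xllcorner"], y_ll=header["yllcorner"],
                   cellsize=header["cellsize"], values=vals)
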