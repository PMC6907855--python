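"""Readers and writers for the pipeline's on-disk formats.

Rasters travel as ESRI ASCII grids (plain text, one header block and a
whitespace-separated matrix); tables as headed CSV. Grids written and
read back round-trip exactly for integer layers and to the printed
precision for floats. Inputs must already be aligned — a mismatch in
shape, origin or cell size is an error, never a silent resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class GridMeta:
    """Geometry of an ASCII grid: shape, lower-left corner, cell size."""

    nrows: int
    ncols: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    @property
    def origin_upper_left(self) -> tuple[float, float]:
        return (self.xllcorner, self.yllcorner + self.nrows * self.cellsize)

    def matches(self, other: "GridMeta", tol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )


def write_ascii_grid(path, grid: np.ndarray, meta: GridMeta | None = None, *,
                     cellsize: float = 1.0, xllcorner: float = 0.0,
                     yllcorner: float = 0.0, nodata_value: float = -9999.0,
                     fmt: str = "%.17g") -> GridMeta:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes the nodata value."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if meta is None:
        meta = GridMeta(grid.shape[0], grid.shape[1], xllcorner, yllcorner,
                        cellsize, nodata_value)
    if (meta.nrows, meta.ncols) != grid.shape:
        raise ValueError("meta shape does not match grid")
    out = grid.astype(float).copy()
    out[~np.isfinite(out)] = meta.nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {meta.ncols}\n")
        fh.write(f"nrows {meta.nrows}\n")
        fh.write(f"xllcorner {meta.xllcorner:.10g}\n")
        fh.write(f"yllcorner {meta.yllcorner:.10g}\n")
        fh.write(f"cellsize {meta.cellsize:.10g}\n")
        fh.write(f"NODATA_value {meta.nodata_value:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)
    return meta


def read_ascii_grid(path) -> tuple[np.ndarray, GridMeta]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unexpected end of header")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    meta = GridMeta(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=header.get("nodata_value", -9999.0),
    )
    if data.shape != (meta.nrows, meta.ncols):
        raise ValueError(
            f"{path}: data shape {data.shape} disagrees with header "
            f"({meta.nrows}, {meta.ncols})"
        )
    data = data.astype(float)
    data[data == meta.nodata_value] = np.nan
    return data, meta


def require_aligned(metas: dict[str, GridMeta]) -> GridMeta:
    """Check all grid geometries agree; return the common one.

    The error message prints every geotransform so mismatches are
    diagnosable from the log alone.
    """
    items = list(metas.items())
    ref_name, ref = items[0]
    for name, meta in items[1:]:
        if not ref.matches(meta):
            detail = "; ".join(
                f"{n}: nrows={m.nrows} ncols={m.ncols} xll={m.xllcorner} "
                f"yll={m.yllcorner} cell={m.cellsize}"
                for n, m in items
            )
            raise ValueError(f"rasters are not aligned ({detail})")
    return ref


def read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read a headed CSV, erroring with the names of any missing columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_occurrences(path) -> np.ndarray:
    """Occurrence CSV with header columns ``x,y`` -> (n, 2) array."""
    df = read_table(path, required=("x", "y"))
    return df[["x", "y"]].to_numpy(dtype=float)


def write_json_report(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def rasterize_district_polygons(geojson_path, meta: GridMeta) -> np.ndarray:
    """Rasterize GeoJSON district polygons onto the grid defined by ``meta``.

    Each cell is labelled by the polygon containing its center; the
    feature property ``district_id`` (or the feature index) supplies the
    label. Cells covered by no polygon become -1.
    """
    from shapely.geometry import Point, shape as shp_shape
    from shapely.prepared import prep

    with open(geojson_path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for k, feat in enumerate(feats):
        geom = shp_shape(feat["geometry"])
        label = int(feat.get("properties", {}).get("district_id", k))
        polys.append((label, prep(geom)))
    labels = np.full((meta.nrows, meta.ncols), -1, dtype=int)
    x0, y0 = meta.origin_upper_left
    for r in range(meta.nrows):
        y = y0 - (r + 0.5) * meta.cellsize
        for c in range(meta.ncols):
            pt = Point(x0 + (c + 0.5) * meta.cellsize, y)
            for label, pgeom in polys:
                if pgeom.contains(pt):
                    labels[r, c] = label
                    break
    return labels
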