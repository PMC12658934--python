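"""Plain-text raster and vector I/O.

Rasters are read and written as single-band ESRI ASCII grids
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header followed
by row-major values, northernmost row first), which round-trips the
integer land-cover codes and the float proportion grids exactly enough
for this pipeline and needs no GDAL stack.  Line sets are exported as
GeoJSON ``LineString`` features (via shapely) or as a WKT
``MULTILINESTRING``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, mapping

from beecorridors.landcover import BinaryFeatureGrid, LandCoverGrid, LineSet, ProportionGrid


def write_ascii_grid(path, values: np.ndarray, cell_size: float,
                     origin: tuple[float, float], nodata: int | float = -9999) -> None:
    values = np.asarray(values)
    n_rows, n_cols = values.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\n"
        f"cellsize {cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(values.dtype, np.integer) else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Returns (values, cell_size, origin, nodata); dtype is int if all
    values are integral."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.asarray(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {values.shape} does not match header")
    if np.allclose(values, np.round(values)):
        values = values.astype(np.int64)
    origin = (header["xllcorner"], header["yllcorner"])
    return values, header["cellsize"], origin, header.get("nodata_value", -9999)


def read_landcover(path, nodata: int | None = None) -> LandCoverGrid:
    values, cs, origin, nd = read_ascii_grid(path)
    return LandCoverGrid(values.astype(np.int64), cs, origin,
                         nodata=int(nodata if nodata is not None else nd))


def write_landcover(path, grid: LandCoverGrid) -> None:
    write_ascii_grid(path, grid.values, grid.cell_size, grid.origin, grid.nodata)


def write_proportion_grid(path, grid: ProportionGrid) -> None:
    write_ascii_grid(path, grid.values, grid.cell_size, grid.origin, -9999)


def read_proportion_grid(path, factor: int) -> ProportionGrid:
    values, cs, origin, _ = read_ascii_grid(path)
    return ProportionGrid(values.astype(float), cs, origin, factor=factor)


def write_binary_grid(path, grid: BinaryFeatureGrid) -> None:
    write_ascii_grid(path, grid.values.astype(np.int64), grid.cell_size, grid.origin, -9999)


def lines_to_geojson(lines: LineSet) -> dict:
    feats = [
        {
            "type": "Feature",
            "properties": {"class_tag": lines.class_tag},
            "geometry": mapping(LineString(seg)),
        }
        for seg in lines.segments
    ]
    return {"type": "FeatureCollection", "features": feats}


def write_lines_geojson(path, lines: LineSet) -> None:
    Path(path).write_text(json.dumps(lines_to_geojson(lines)))


def lines_to_wkt(lines: LineSet) -> str:
    if not lines.segments:
        return "MULTILINESTRING EMPTY"
    parts = [
        "(" + ", ".join(f"{x:.6f} {y:.6f}" for x, y in seg) + ")"
        for seg in lines.segments
    ]
    return "MULTILINESTRING (" + ", ".join(parts) + ")"
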