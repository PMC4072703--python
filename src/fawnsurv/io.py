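"""Plain-text geospatial I/O: ESRI ASCII grids and GeoJSON line layers.

All geometry lives in a planar metric coordinate system. Rasters follow the
ESRI ASCII convention: row 0 is the *top* row, ``xllcorner``/``yllcorner``
give the lower-left corner, cells are square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, mapping, shape

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid", "read_roads", "write_roads"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band square-cell raster on a planar grid.

    ``data[0, 0]`` is the north-west cell. ``xll``/``yll`` locate the
    lower-left corner of the lower-left cell.
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 30.0
    nodata: float = field(default=_NODATA)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster extent."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def value_at(self, x, y):
        """Nearest-cell lookup for arrays of planar coordinates.

        Coordinates outside the extent are clamped to the edge cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        y_top = self.yll + self.nrows * self.cellsize
        col = np.clip(np.floor((x - self.xll) / self.cellsize).astype(int), 0, self.ncols - 1)
        row = np.clip(np.floor((y_top - y) / self.cellsize).astype(int), 0, self.nrows - 1)
        return self.data[row, col]

    def same_georeference(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
            and self.data.shape == other.data.shape
        )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    data = np.where(np.isfinite(raster.data), raster.data, raster.nodata)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xll:.6f}\n"
        f"yllcorner {raster.yll:.6f}\n"
        f"cellsize {raster.cellsize:.6f}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data=data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_roads(lines: list[LineString], path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(line), "properties": {"road_id": i}}
        for i, line in enumerate(lines)
    ]
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection))


def read_roads(path: str | Path) -> list[LineString]:
    collection = json.loads(Path(path).read_text())
    return [shape(feat["geometry"]) for feat in collection["features"]]
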