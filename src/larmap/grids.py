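"""Core spatial containers: point sets and regular raster grids.

Coordinates are planar metres in a projected CRS; no geodesy is attempted.
Rasters follow the ESRI ASCII grid convention: row 0 of ``values`` is the
*northernmost* row, ``x_origin``/``y_origin`` are the coordinates of the
lower-left corner of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PointSet", "RasterGrid", "read_esri_ascii", "write_esri_ascii"]


@dataclass
class PointSet:
    """Point-referenced (geostatistical) observations.

    Parameters
    ----------
    ids : array-like of identifiers, one per point.
    easting, northing : coordinates in metres.
    values : DataFrame with one column per observed variable (n_points rows).
    """

    ids: np.ndarray
    easting: np.ndarray
    northing: np.ndarray
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.easting = np.asarray(self.easting, dtype=float)
        self.northing = np.asarray(self.northing, dtype=float)
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        n = len(self.ids)
        if not (len(self.easting) == len(self.northing) == len(self.values) == n):
            raise ValueError("ids, coordinates and values must have equal length")
        if not (np.isfinite(self.easting).all() and np.isfinite(self.northing).all()):
            raise ValueError("coordinates must be finite")
        coords = np.column_stack([self.easting, self.northing])
        if len(np.unique(coords, axis=0)) != n:
            raise ValueError("duplicated (easting, northing) pairs in point set")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (easting, northing)."""
        return np.column_stack([self.easting, self.northing])

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        """Write as an id,easting,northing,<value columns> CSV table."""
        df = pd.DataFrame({"id": self.ids, "easting": self.easting, "northing": self.northing})
        for c in self.values.columns:
            df[c] = self.values[c].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet":
        df = pd.read_csv(path)
        lower = {c.lower(): c for c in df.columns}
        for required in ("id", "easting", "northing"):
            if required not in lower:
                raise ValueError(f"{path}: missing column '{required}'")
        value_cols = [c for c in df.columns
                      if c not in (lower["id"], lower["easting"], lower["northing"])]
        return cls(
            ids=df[lower["id"]].to_numpy(),
            easting=df[lower["easting"]].to_numpy(dtype=float),
            northing=df[lower["northing"]].to_numpy(dtype=float),
            values=df[value_cols].copy(),
        )


@dataclass
class RasterGrid:
    """Regular rectangular grid of pixel values.

    ``values[0, :]`` is the northernmost row (ESRI ASCII order);
    ``(x_origin, y_origin)`` is the lower-left (south-west) corner.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 25.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_origin + self.ncols * self.pixel_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.nrows * self.pixel_size

    def same_georeference(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.pixel_size, other.pixel_size)
        )

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (easting, northing) arrays of shape (nrows, ncols)."""
        xs = self.x_origin + (np.arange(self.ncols) + 0.5) * self.pixel_size
        ys = self.y_max - (np.arange(self.nrows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def index_of(self, easting, northing) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-pixel (row, col) indices for the given coordinates.

        Raises if any coordinate falls outside the raster extent.
        """
        easting = np.asarray(easting, dtype=float)
        northing = np.asarray(northing, dtype=float)
        inside = (
            (easting >= self.x_origin) & (easting <= self.x_max)
            & (northing >= self.y_origin) & (northing <= self.y_max)
        )
        if not inside.all():
            bad = np.argwhere(~inside).ravel()[:5]
            pts = [(float(np.atleast_1d(easting)[i]), float(np.atleast_1d(northing)[i]))
                   for i in np.atleast_1d(bad)]
            raise ValueError(f"coordinates outside raster extent: {pts}")
        col = np.clip(((easting - self.x_origin) / self.pixel_size).astype(int), 0, self.ncols - 1)
        row = np.clip(((self.y_max - northing) / self.pixel_size).astype(int), 0, self.nrows - 1)
        return row, col

    def sample(self, easting, northing) -> np.ndarray:
        """Nearest-pixel value lookup at the given coordinates."""
        row, col = self.index_of(easting, northing)
        return self.values[row, col]

    def is_nodata(self, v: np.ndarray) -> np.ndarray:
        return np.isclose(v, self.nodata) | ~np.isfinite(v)


def write_esri_ascii(raster: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc) with full-precision values."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x_origin!r}\n")
        fh.write(f"yllcorner {raster.y_origin!r}\n")
        fh.write(f"cellsize {raster.pixel_size!r}\n")
        fh.write(f"nodata_value {raster.nodata!r}\n")
        vals = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_esri_ascii(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; supports xllcorner/yllcorner and xllcenter/yllcenter."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise ValueError(f"{path}: malformed ESRI ASCII header (missing {required})")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header.get("yllcorner", 0.0)
    else:
        x0 = header.get("xllcenter", 0.0) - cell / 2
        y0 = header.get("yllcenter", 0.0) - cell / 2
    values = np.loadtxt(data_lines).reshape(nrows, ncols)
    return RasterGrid(
        values=values, x_origin=x0, y_origin=y0, pixel_size=cell,
        nodata=header.get("nodata_value", -9999.0),
    )
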