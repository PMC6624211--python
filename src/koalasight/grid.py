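"""Planar study windows and gridded rasters.

All coordinates are planar kilometres.  A :class:`StudyWindow` is a
rectangle anchored at the origin, discretised into square cells whose
edges lie on integer multiples of the cell size.  A :class:`Raster`
holds one value per cell (distance covariates, elevation, density
surfaces) together with minimal georeferencing: the origin of the
lower-left cell corner and the cell size.

Rasters serialise to the plain-text ESRI ASCII grid format and vector
features to GeoJSON, so every artifact the pipeline writes is
human-readable text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "StudyWindow",
    "Raster",
    "PointPattern",
    "FeatureSet",
    "read_geojson",
    "write_geojson",
]


@dataclass(frozen=True)
class StudyWindow:
    """Rectangular observation window ``[0, width] x [0, height]`` in km.

    The window owns the reference grid used by every raster in a run:
    square cells of ``cellsize`` km, edges anchored at (0, 0).  When the
    width or height is not an integer multiple of the cell size the grid
    ceil-covers the rectangle and boundary cells carry their clipped
    area, so area-weighted summaries remain exact.
    """

    width_km: float
    height_km: float
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        if not (self.width_km > 0 and self.height_km > 0):
            raise ValueError(
                f"window dimensions must be strictly positive, got "
                f"{self.width_km} x {self.height_km} km"
            )
        if not self.cellsize > 0:
            raise ValueError("cellsize must be strictly positive")

    # -- basic geometry -------------------------------------------------
    @property
    def area(self) -> float:
        return self.width_km * self.height_km

    @property
    def polygon(self) -> BaseGeometry:
        return shapely.box(0.0, 0.0, self.width_km, self.height_km)

    @property
    def nx(self) -> int:
        return int(np.ceil(self.width_km / self.cellsize - 1e-12))

    @property
    def ny(self) -> int:
        return int(np.ceil(self.height_km / self.cellsize - 1e-12))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.cellsize

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre coordinates, shape (ny, nx) each."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_areas(self) -> np.ndarray:
        """Clipped area of each grid cell inside the rectangle, km²."""
        wx = np.minimum(self.cellsize, self.width_km - np.arange(self.nx) * self.cellsize)
        wy = np.minimum(self.cellsize, self.height_km - np.arange(self.ny) * self.cellsize)
        return np.clip(wy, 0.0, None)[:, None] * np.clip(wx, 0.0, None)[None, :]

    def mask(self) -> np.ndarray:
        """Boolean (ny, nx): cells with positive clipped area."""
        return self.cell_areas() > 0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width_km) & (y >= 0) & (y <= self.height_km)

    def empty_raster(self, fill: float = 0.0) -> "Raster":
        return Raster(
            values=np.full((self.ny, self.nx), fill, dtype=float),
            cellsize=self.cellsize,
        )


@dataclass
class Raster:
    """A gridded surface Z(u): one value per cell, row 0 at the bottom.

    ``values[j, i]`` is the value at the centre of the cell spanning
    ``[origin_x + i*cs, origin_x + (i+1)*cs] x [origin_y + j*cs, ...]``.
    """

    values: np.ndarray
    cellsize: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    feature_class: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.cellsize

    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.cellsize, y0, y0 + self.ny * self.cellsize)

    # -- sampling -------------------------------------------------------
    def sample(
        self,
        x: np.ndarray,
        y: np.ndarray,
        mode: str = "bilinear",
    ) -> np.ndarray:
        """Sample the surface at points.

        ``mode="bilinear"`` interpolates between the four surrounding
        cell centres (values clamped to the centre lattice at the
        margin); ``mode="nearest"`` returns the containing cell's value.
        Points outside the raster extent raise, listing the offenders.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        xmin, xmax, ymin, ymax = self.extent()
        bad = ~((x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax))
        if bad.any():
            idx = np.flatnonzero(bad)
            raise ValueError(
                f"{idx.size} point(s) outside raster extent, indices {idx[:10].tolist()}"
            )
        gx = (x - self.origin[0]) / self.cellsize - 0.5
        gy = (y - self.origin[1]) / self.cellsize - 0.5
        if mode == "nearest":
            i = np.clip(np.round(gx), 0, self.nx - 1).astype(int)
            j = np.clip(np.round(gy), 0, self.ny - 1).astype(int)
            return self.values[j, i]
        if mode != "bilinear":
            raise ValueError(f"unknown sampling mode {mode!r}")
        gx = np.clip(gx, 0.0, self.nx - 1.0)
        gy = np.clip(gy, 0.0, self.ny - 1.0)
        i0 = np.clip(np.floor(gx).astype(int), 0, self.nx - 2) if self.nx > 1 else np.zeros_like(gx, int)
        j0 = np.clip(np.floor(gy).astype(int), 0, self.ny - 2) if self.ny > 1 else np.zeros_like(gy, int)
        i1 = np.minimum(i0 + 1, self.nx - 1)
        j1 = np.minimum(j0 + 1, self.ny - 1)
        fx = gx - i0
        fy = gy - j0
        v = (
            self.values[j0, i0] * (1 - fx) * (1 - fy)
            + self.values[j0, i1] * fx * (1 - fy)
            + self.values[j1, i0] * (1 - fx) * fy
            + self.values[j1, i1] * fx * fy
        )
        return v

    # -- text serialisation --------------------------------------------
    def to_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write as an ESRI ASCII grid (top row first)."""
        path = Path(path)
        header = (
            f"ncols {self.nx}\n"
            f"nrows {self.ny}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cellsize:.6f}\n"
            f"NODATA_value {nodata}\n"
        )
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals[::-1], fmt="%.6g")

    @classmethod
    def from_ascii(cls, path: str | Path, feature_class: str = "") -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        values = np.loadtxt(lines[n_header:], ndmin=2)[::-1]
        nodata = meta.get("nodata_value")
        if nodata is not None:
            values = np.where(values == nodata, np.nan, values)
        return cls(
            values=values,
            cellsize=meta.get("cellsize", 1.0),
            origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
            feature_class=feature_class,
        )


@dataclass
class PointPattern:
    """Planar event locations confined to a study window.

    The realization analysed as a spatial point process: x/y in km,
    every point inside the window.
    """

    x: np.ndarray
    y: np.ndarray
    window: StudyWindow

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.n and not self.window.contains(self.x, self.y).all():
            raise ValueError("point pattern contains points outside its window")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def intensity(self) -> float:
        """Average intensity n / |W|, events per km²."""
        return self.n / self.window.area

    def subset(self, mask: np.ndarray) -> "PointPattern":
        return PointPattern(self.x[mask], self.y[mask], self.window)


@dataclass
class FeatureSet:
    """A bag of shapely geometries sharing one feature class."""

    geometries: list[BaseGeometry] = field(default_factory=list)
    feature_class: str = ""

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(self.geometries)

    def union(self) -> BaseGeometry:
        return shapely.union_all(self.geometries) if self.geometries else shapely.GeometryCollection()


def write_geojson(
    path: str | Path,
    geometries: Iterable[BaseGeometry],
    properties: Sequence[dict] | None = None,
) -> None:
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props
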