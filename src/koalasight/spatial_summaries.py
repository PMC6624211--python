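"""Tabulations of sightings by coast distance, elevation and polygons.

Each summary is a partition: band / class / level counts plus an
explicit unassigned bucket always sum to the number of points.
Interval convention throughout: half-open on the right, ``[a, b)``,
with the first interval closed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grid import FeatureSet, PointPattern, Raster

__all__ = [
    "BandTabulation",
    "coast_distance_bands",
    "elevation_classes",
    "polygon_tabulate",
]

DEFAULT_COAST_BREAKS_KM = (0.0, 5.0, 10.0, 15.0, 20.0)
DEFAULT_ELEVATION_BREAKS_M = (100.0, 200.0)


@dataclass
class BandTabulation:
    """Counts of points per interval of a continuous variable."""

    breaks: tuple[float, ...]
    labels: list[str]
    counts: np.ndarray
    n_unassigned: int = 0
    unit: str = "km"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def n(self) -> int:
        return int(self.counts.sum()) + self.n_unassigned

    @property
    def proportions(self) -> np.ndarray:
        total = self.n
        return self.counts / total if total else np.full_like(self.counts, np.nan, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"band": self.labels, "count": self.counts, "proportion": self.proportions}
        )


def _band_labels(breaks: tuple[float, ...], unit: str) -> list[str]:
    labels = [
        f"[{breaks[i]:g}, {breaks[i + 1]:g}) {unit}" for i in range(len(breaks) - 1)
    ]
    labels.append(f">= {breaks[-1]:g} {unit}")
    return labels


def _tabulate(values: np.ndarray, breaks: tuple[float, ...], unit: str) -> BandTabulation:
    edges = np.asarray(breaks, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("breaks must be strictly ascending")
    # np.digitize(right=False): value == break goes to the upper band
    idx = np.digitize(values, edges[1:], right=False)
    counts = np.bincount(idx, minlength=edges.size)
    return BandTabulation(
        breaks=tuple(edges),
        labels=_band_labels(tuple(edges), unit),
        counts=counts,
        unit=unit,
    )


def coast_distance_bands(
    pattern: PointPattern,
    coastline: FeatureSet,
    breaks: tuple[float, ...] = DEFAULT_COAST_BREAKS_KM,
) -> BandTabulation:
    """Count sightings per Euclidean-distance-to-coast band (km)."""
    if len(coastline) == 0:
        raise ValueError("coastline is empty; coast distance undefined")
    pts = shapely.points(pattern.x, pattern.y)
    coast = coastline.union()
    shapely.prepare(coast)
    dist = shapely.distance(pts, coast)
    return _tabulate(dist, breaks, "km")


def elevation_classes(
    pattern: PointPattern,
    dem: Raster,
    breaks: tuple[float, ...] = DEFAULT_ELEVATION_BREAKS_M,
) -> BandTabulation:
    """Classify sightings by elevation sampled nearest-cell from a DEM.

    Points outside the DEM extent are counted as unassigned rather
    than raising: a partial DEM is a data problem worth surfacing, not
    a programming error.
    """
    xmin, xmax, ymin, ymax = dem.extent()
    inside = (
        (pattern.x >= xmin) & (pattern.x <= xmax)
        & (pattern.y >= ymin) & (pattern.y <= ymax)
    )
    elev = dem.sample(pattern.x[inside], pattern.y[inside], mode="nearest")
    full_breaks = (-np.inf,) + tuple(breaks)
    edges = np.asarray(full_breaks[1:], dtype=float)
    idx = np.digitize(elev, edges, right=False)
    counts = np.bincount(idx, minlength=edges.size + 1)
    labels = [f"< {breaks[0]:g} m"] + [
        f"[{breaks[i]:g}, {breaks[i + 1]:g}) m" for i in range(len(breaks) - 1)
    ] + [f">= {breaks[-1]:g} m"]
    return BandTabulation(
        breaks=tuple(full_breaks),
        labels=labels,
        counts=counts,
        n_unassigned=int((~inside).sum()),
        unit="m",
    )


def polygon_tabulate(
    pattern: PointPattern,
    polygons: FeatureSet | list,
    levels: list[str],
    periods: pd.Series | None = None,
) -> pd.DataFrame:
    """Point-in-polygon counts per attribute level (land type, LGA, ...).

    ``levels[i]`` labels ``polygons[i]``; a point on a polygon boundary
    counts as inside (covers semantics).  Points covered by several
    polygons are assigned to the first matching level; points in none
    go to ``unassigned``.  With ``periods`` given (one label per
    point), counts are additionally split by period.
    """
    geoms = list(polygons.geometries if isinstance(polygons, FeatureSet) else polygons)
    if len(geoms) != len(levels):
        raise ValueError("one level label per polygon required")
    pts = shapely.points(pattern.x, pattern.y)
    assigned = np.full(pattern.n, "unassigned", dtype=object)
    unclaimed = np.ones(pattern.n, dtype=bool)
    for geom, level in zip(geoms, levels):
        shapely.prepare(geom)
        hit = unclaimed & shapely.covers(geom, pts)
        assigned[hit] = level
        unclaimed &= ~hit
    level_order = list(dict.fromkeys(levels)) + ["unassigned"]
    if periods is None:
        vc = pd.Series(assigned).value_counts()
        out = pd.DataFrame(
            {
                "level": level_order,
                "count": [int(vc.get(lv, 0)) for lv in level_order],
            }
        )
        total = out["count"].sum()
        out["share"] = out["count"] / total if total else np.nan
        return out
    df = pd.DataFrame({"level": assigned, "period": np.asarray(periods)})
    out = (
        df.groupby(["period", "level"], sort=True).size().rename("count").reset_index()
    )
    return out
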