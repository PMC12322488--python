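"""Territory delineation by minimum convex polygon (MCP).

A male's territory is the convex hull of his observation points, optionally
after discarding the farthest points from the centroid (percentile MCP, as
in the home-range literature).  Coordinates are planar meters; geographic
lon/lat input must be projected first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon


@dataclass
class TerritoryObservations:
    male_id: str
    species: str
    points: np.ndarray  # (n, 2) meters
    n_surveys: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"male {self.male_id!r}: points must be (n, 2)")
        if not np.isfinite(self.points).all():
            raise ValueError(f"male {self.male_id!r}: non-finite coordinates")


@dataclass
class Territory:
    male_id: str
    species: str
    vertices: np.ndarray  # convex, counter-clockwise
    area: float

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (absolute value)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def mcp(obs: TerritoryObservations, percentile: float = 100.0) -> Territory:
    """Minimum convex polygon of the retained observation points.

    At ``percentile`` < 100 the farthest (100 - percentile)% of points from
    the centroid of all points are removed before taking the hull.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    pts = obs.points
    if percentile < 100:
        center = pts.mean(axis=0)
        d = np.linalg.norm(pts - center, axis=1)
        keep = max(3, int(np.ceil(len(pts) * percentile / 100.0)))
        pts = pts[np.argsort(d)[:keep]]
    if len(pts) < 3:
        raise ValueError(
            f"male {obs.male_id!r}: need >= 3 points for a polygon, have {len(pts)}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError(
            f"male {obs.male_id!r}: degenerate (collinear?) observation points"
        ) from err
    vertices = pts[hull.vertices]  # counter-clockwise in 2-D
    area = shoelace_area(vertices)
    if area <= 0:
        raise ValueError(f"male {obs.male_id!r}: zero-area hull")
    return Territory(obs.male_id, obs.species, vertices, area)


def overlap_fraction(t1: Territory, t2: Territory) -> float:
    """Intersection area divided by the smaller territory's area."""
    inter = t1.polygon.intersection(t2.polygon).area
    return float(inter / min(t1.area, t2.area))


def read_points(path) -> list[TerritoryObservations]:
    """Read points.csv (male_id, species, x, y) into per-male observations.

    Tables with lon/lat-named coordinate columns are rejected: MCP areas
    are planar, so geographic coordinates must be projected to meters first.
    """
    df = pd.read_csv(path)
    lonlat = {"lon", "lat", "longitude", "latitude"} & {c.lower() for c in df.columns}
    if lonlat:
        raise ValueError(
            f"found geographic coordinate columns {sorted(lonlat)}; project to "
            "planar meter coordinates (x, y) before territory mapping"
        )
    required = {"male_id", "species", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"points table missing columns {sorted(missing)}")
    out = []
    for (male, sp), grp in df.groupby(["male_id", "species"], sort=True):
        out.append(
            TerritoryObservations(
                male_id=str(male),
                species=str(sp),
                points=grp[["x", "y"]].to_numpy(dtype=float),
            )
        )
    return out


def map_territories(
    observations: list[TerritoryObservations], percentile: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MCP every male; returns (vertices table, areas table)."""
    vert_rows, area_rows = [], []
    for obs in observations:
        t = mcp(obs, percentile=percentile)
        for i, (x, y) in enumerate(t.vertices):
            vert_rows.append(
                {"male_id": t.male_id, "species": t.species, "vertex": i,
                 "x": float(x), "y": float(y)}
            )
        area_rows.append(
            {"male_id": t.male_id, "species": t.species, "area_m2": t.area,
             "n_points": len(obs.points)}
        )
    return pd.DataFrame(vert_rows), pd.DataFrame(area_rows)
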