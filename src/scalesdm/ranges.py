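"""Range-shift diagnostics: minimum convex polygons and elevation shifts.

A 95% minimum convex polygon (MCP) — the classic home-range estimator —
trims the 5% of points farthest from the centroid of all points and takes
the convex hull of the remainder. Overlap between two periods' MCPs and the
shift in the elevation distribution of occurrences between periods are
crude but robust indicators of range contraction and upslope movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .grids import Grid2D
from .occurrences import OccurrenceSet

__all__ = ["ConvexRegion", "mcp", "mcp_overlap", "elevation_shift"]


@dataclass
class ConvexRegion:
    """A convex polygon given as an ordered vertex ring."""

    vertices: np.ndarray  # (k, 2), closed ring not repeated
    area: float

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def to_geojson_dict(self) -> dict:
        ring = self.vertices.tolist() + [self.vertices[0].tolist()]
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"area": self.area},
        }


def mcp(points, coverage: float = 0.95) -> ConvexRegion:
    """Minimum convex polygon covering the given fraction of points.

    The ceil((1 - coverage) * n) points farthest (Euclidean) from the
    centroid of all points are dropped; ties at the trimming rank drop the
    later record in input order. The convex hull of the remainder must have
    at least 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must lie in (0, 1]")
    # epsilon guards the ceil against float artifacts like 0.05*20 -> 1.0000…9
    n_drop = math.ceil((1.0 - coverage) * n - 1e-9)
    if n_drop > 0:
        centroid = pts.mean(axis=0)
        dist = np.hypot(*(pts - centroid).T)
        # sort by (distance, input order); farthest last, later index dropped
        # first among ties
        order = sorted(range(n), key=lambda i: (dist[i], i))
        keep = sorted(order[: n - n_drop])
        pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("fewer than 3 points remain after trimming")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError("points are collinear; no polygon exists")
    ring = np.asarray(hull.exterior.coords)[:-1]
    return ConvexRegion(vertices=ring, area=float(hull.area))


def mcp_overlap(region_a: ConvexRegion, region_b: ConvexRegion) -> dict[str, float]:
    """Fractions of each region's area covered by the intersection."""
    if region_a.area <= 0 or region_b.area <= 0:
        raise ValueError("zero-area region; overlap undefined")
    inter = region_a.polygon.intersection(region_b.polygon).area
    return {"frac_a": float(inter / region_a.area), "frac_b": float(inter / region_b.area)}


def elevation_shift(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    elevation: Grid2D,
    n_bins: int = 30,
) -> dict:
    """Elevation-distribution comparison between two occurrence periods.

    Elevations come from each record (falling back to the elevation layer at
    the record's cell); unresolvable records are counted, not dropped
    silently. Returns per-period means, their difference (b - a), the count
    of unresolved records, and a shared-bin density table for plotting.
    """
    def resolve(occ: OccurrenceSet) -> tuple[np.ndarray, int]:
        vals, missing = [], 0
        for rec in occ.records:
            e = rec.elevation
            if e is None:
                e = elevation.value_at(rec.x, rec.y)
            if e is None or not np.isfinite(e):
                missing += 1
            else:
                vals.append(float(e))
        return np.array(vals), missing

    elev_a, miss_a = resolve(occ_a)
    elev_b, miss_b = resolve(occ_b)
    if elev_a.size == 0 or elev_b.size == 0:
        raise ValueError("a period has no resolvable elevations")
    lo = min(elev_a.min(), elev_b.min())
    hi = max(elev_a.max(), elev_b.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    dens_a, _ = np.histogram(elev_a, bins=edges, density=True)
    dens_b, _ = np.histogram(elev_b, bins=edges, density=True)
    density = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "density_a": dens_a,
            "density_b": dens_b,
        }
    )
    return {
        "mean_a": float(elev_a.mean()),
        "mean_b": float(elev_b.mean()),
        "delta": float(elev_b.mean() - elev_a.mean()),
        "unresolved": miss_a + miss_b,
        "density_summary": density,
    }
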