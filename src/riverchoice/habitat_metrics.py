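"""Transect-based channel-width metrics, nearest-forest distance and flow
covariates for in-channel points.

Measurement conventions
-----------------------
* The transect at a point is the line through the point perpendicular to
  the centerline tangent at the point's arc-length projection.
* **TCW** is the bank-to-bank length of the transect segment containing the
  point.  **UOCW** is the length of that segment after removing
  dense-vegetation intersections, keeping the portion containing the point
  (segmented channels are delineated by the portion the point lies within).
  **UFCW** is the segment length after removing riparian-forest
  intersections instead.
* **NF** is the planar Euclidean distance from the point to the nearest
  forest patch in any direction, truncated at 400 m.
* **UD** = discharge / wetted width; **DIS** = discharge / total width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import shapely
from shapely.geometry import LineString, Point

from riverchoice.errors import DomainError, EdgeError
from riverchoice.synthetic_river import NF_CAP_M

if TYPE_CHECKING:  # pragma: no cover
    from riverchoice.synthetic_river import RiverLandscape


@dataclass(frozen=True)
class HabitatMetrics:
    """The six covariates attached to an in-channel point."""

    uocw: float  # unobstructed channel width (m)
    tcw: float  # total bank-to-bank channel width (m)
    ufcw: float  # unforested channel width (m)
    nf: float  # distance to nearest forest, truncated (m)
    ud: float  # discharge per metre of wetted width (cms/m)
    dis: float  # discharge per metre of total width (cms/m)

    FIELDS = ("uocw", "tcw", "ufcw", "nf", "ud", "dis")


def _component_containing(geom, point: Point, tol: float = 1e-6):
    """Pick the line component of ``geom`` that contains ``point``."""
    if geom.is_empty:
        return None
    parts = list(geom.geoms) if hasattr(geom, "geoms") else [geom]
    parts = [p for p in parts if isinstance(p, LineString) and p.length > 0]
    if not parts:
        return None
    dists = [p.distance(point) for p in parts]
    i = int(np.argmin(dists))
    return parts[i] if dists[i] <= tol else None


def transect_line(
    landscape: "RiverLandscape", point: Point, s: float | None = None
) -> LineString:
    """Perpendicular transect through ``point``, long enough to span the
    channel anywhere in the landscape."""
    if s is None:
        s = landscape.arc_coord(point)
    t = landscape.tangent_at(s)
    n = np.array([-t[1], t[0]])
    r = landscape.transect_reach()
    p = np.array([point.x, point.y])
    return LineString([p - n * r, p + n * r])


def measure_widths(landscape: "RiverLandscape", point: Point) -> tuple[float, float, float]:
    """Return ``(uocw, tcw, ufcw)`` in metres at an in-channel point."""
    if not landscape.contains(point):
        raise DomainError(f"point ({point.x:.1f}, {point.y:.1f}) is not inside the channel")
    s = landscape.arc_coord(point)
    line = transect_line(landscape, point, s)

    # clip the channel to the transect's bounding box first: identical
    # intersection, much cheaper on long landscapes
    minx, miny, maxx, maxy = line.bounds
    local = shapely.clip_by_rect(
        landscape.channel_polygon, minx - 5, miny - 5, maxx + 5, maxy + 5
    )
    chan_seg = _component_containing(line.intersection(local), point)
    if chan_seg is None:  # pragma: no cover - contains() guards this
        raise DomainError("transect does not intersect the channel at the point")
    # transect exiting through the upstream/downstream cap means the
    # "bank-to-bank" reading is meaningless there
    end_tol = 1.0
    if s < landscape.transect_reach() or s > landscape.length_m - landscape.transect_reach():
        for ex, ey in (chan_seg.coords[0], chan_seg.coords[-1]):
            se = landscape.arc_coord(Point(ex, ey))
            if se < end_tol or se > landscape.length_m - end_tol:
                raise EdgeError(
                    "transect runs off the end of the landscape "
                    f"(arc coordinate {se:.0f} m)"
                )
    tcw = float(chan_seg.length)

    uocw = _width_after_removing(chan_seg, landscape._veg_tree, line, point)
    if uocw is None:
        raise DomainError("point lies within a dense-vegetation patch")
    ufcw = _width_after_removing(chan_seg, landscape._forest_tree, line, point)
    if ufcw is None:  # forest touching exactly at the point: treat as zero-width
        ufcw = 0.0
    return uocw, tcw, ufcw


def _width_after_removing(chan_seg, tree, line, point: Point) -> float | None:
    """Length of the component of ``chan_seg`` containing ``point`` after
    removing intersections with the patches in ``tree``."""
    if tree is None:
        return float(chan_seg.length)
    idx = tree.query(line, predicate="intersects")
    if len(idx) == 0:
        return float(chan_seg.length)
    blockers = shapely.union_all([tree.geometries[i] for i in idx])
    remaining = chan_seg.difference(blockers)
    seg = _component_containing(remaining, point)
    return float(seg.length) if seg is not None else None


def measure_nf(landscape: "RiverLandscape", point: Point) -> float:
    """Distance (m) from an in-channel point to the nearest forest patch,
    in any direction, truncated at 400 m."""
    if not landscape.contains(point):
        raise DomainError(f"point ({point.x:.1f}, {point.y:.1f}) is not inside the channel")
    tree = landscape._forest_tree
    if tree is None:
        return NF_CAP_M
    nearest = tree.geometries[tree.nearest(point)]
    return float(min(nearest.distance(point), NF_CAP_M))


def flow_metrics(discharge: float, wetted_width: float, tcw: float) -> tuple[float, float]:
    """``(ud, dis)`` = discharge over wetted width, discharge over total width."""
    if wetted_width <= 0 or tcw <= 0:
        raise DomainError("widths must be positive for flow metrics")
    if discharge < 0:
        raise DomainError("discharge must be non-negative")
    return discharge / wetted_width, discharge / tcw


def measure_point(
    landscape: "RiverLandscape", point: Point, discharge: float, wetted_fraction: float
) -> HabitatMetrics:
    """All six covariates at one point (wetted width = fraction of TCW)."""
    uocw, tcw, ufcw = measure_widths(landscape, point)
    nf = measure_nf(landscape, point)
    ud, dis = flow_metrics(discharge, wetted_fraction * tcw, tcw)
    return HabitatMetrics(uocw=uocw, tcw=tcw, ufcw=ufcw, nf=nf, ud=ud, dis=dis)


def attach_metrics(landscape: "RiverLandscape", points, dates=None):
    """Batch mode: metrics for a sequence of ``(x, y)`` pairs.

    ``dates`` selects per-point discharge / wetted fraction from the
    landscape tables; when omitted the first available date is used for all
    points.  Returns a :class:`pandas.DataFrame` with one row per point.
    """
    import pandas as pd

    default_date = sorted(landscape.discharge)[0] if landscape.discharge else None
    rows = []
    for i, xy in enumerate(points):
        p = Point(xy[0], xy[1])
        date = dates[i] if dates is not None else default_date
        if date is None:
            raise DomainError("landscape has no discharge table and no dates given")
        m = measure_point(
            landscape, p, landscape.discharge[date], landscape.wetted_fraction[date]
        )
        rows.append(
            {
                "x": p.x,
                "y": p.y,
                "x_m": landscape.arc_coord(p),
                "date": date,
                **{f: getattr(m, f) for f in HabitatMetrics.FIELDS},
            }
        )
    return pd.DataFrame(rows)
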