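"""Contour geometry: azimuthal ordering, shoelace area, acircularity.

The measurement model: a manually drawn FAZ perimeter is an unordered cloud
of pixels.  Points are ordered by azimuth about their centroid (the drawn
boundary is assumed star-shaped with respect to that centre), the enclosed
polygon area is computed with the shoelace (Gauss) formula and converted to
mm² with the device pixel size, and shape irregularity is summarised by the
acircularity statistic

    acircularity = sigma(R) / mean(R)

over the radial distances ``R_i`` of the contour points from their geometric
centre: zero for a perfect circle, larger for irregular boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateContour, ZeroRadius
from .types import ContourMeta, PixelScale, PointSet

__all__ = [
    "Contour",
    "ContourMetrics",
    "sort_by_azimuth",
    "shoelace_area",
    "to_mm2",
    "contour_centre",
    "radial_coordinates",
    "acircularity",
    "compute_metrics",
    "metrics_table",
]


@dataclass
class Contour:
    """Closed boundary: points ordered by azimuth about their centroid.

    The polygon is implicitly closed (last vertex connects to the first).
    Real-valued coordinates are allowed; integer pixel inputs are promoted.
    """

    points: np.ndarray  # (N, 2) float, azimuth-ordered
    meta: Optional[ContourMeta] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise DegenerateContour(
                f"a contour needs at least 3 (x, y) points, got shape {pts.shape}"
            )
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def _as_xy(points) -> np.ndarray:
    if isinstance(points, (PointSet, Contour)):
        return np.asarray(points.points, dtype=float)
    return np.asarray(points, dtype=float)


def sort_by_azimuth(points) -> Contour:
    """Order a point cloud azimuthally about its centroid.

    Cartesian locations are transformed to polar coordinates about the
    centroid of the input and sorted by ascending azimuth in (−π, π]; the
    starting vertex is the one with the smallest azimuth.  Azimuth ties
    (common for thick drawn lines) are broken by ascending radius so that
    near-duplicate ring pixels stay adjacent instead of creating long
    chords.

    Raises
    ------
    DegenerateContour
        If fewer than 3 distinct points remain or all points are collinear.
    """
    xy = _as_xy(points)
    meta = points.meta if isinstance(points, (PointSet, Contour)) else None
    if xy.ndim != 2 or (len(xy) and xy.shape[1] != 2) or len(xy) < 3:
        raise DegenerateContour(f"need at least 3 points, got {len(xy)}")
    distinct = np.unique(xy, axis=0)
    if len(distinct) < 3:
        raise DegenerateContour(f"only {len(distinct)} distinct points")
    # collinearity: all cross products relative to the first edge vanish
    v = distinct - distinct[0]
    cross = v[1:, 0] * v[-1, 1] - v[1:, 1] * v[-1, 0]
    span = float(np.abs(v).max())
    if np.all(np.abs(cross) <= 1e-12 * max(span, 1.0) ** 2):
        raise DegenerateContour("all points are collinear")

    centre = xy.mean(axis=0)
    d = xy - centre
    azimuth = np.arctan2(d[:, 1], d[:, 0])
    radius = np.hypot(d[:, 0], d[:, 1])
    order = np.lexsort((radius, azimuth))
    return Contour(xy[order], meta)


def shoelace_area(contour) -> float:
    """Polygon area by the shoelace (Gauss) method, in squared input units.

    Returns the absolute value of the signed cross-product sum over the
    closed vertex sequence; orientation-independent.
    """
    xy = _as_xy(contour)
    if len(xy) < 3:
        raise DegenerateContour(f"need at least 3 points, got {len(xy)}")
    x, y = xy[:, 0], xy[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed))


def to_mm2(area_px2: float, scale: PixelScale) -> float:
    """Convert a pixel² area to mm² using the per-axis pixel size."""
    if area_px2 < 0:
        raise ValueError("area_px2 must be non-negative")
    return area_px2 * scale.px_area_mm2


def contour_centre(contour) -> Tuple[float, float]:
    """Geometric centre: the mean of the coordinates of all contour points."""
    xy = _as_xy(contour)
    cx, cy = xy.mean(axis=0)
    return float(cx), float(cy)


def radial_coordinates(contour, centre) -> np.ndarray:
    """Euclidean distance of each contour point from ``centre``, in order."""
    xy = _as_xy(contour)
    cx, cy = centre
    return np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)


def _radial_stats(radii: np.ndarray, ddof: int) -> Tuple[float, float]:
    mean_r = float(radii.mean())
    sd_r = float(radii.std(ddof=ddof))
    return mean_r, sd_r


def acircularity(contour, ddof: int = 0) -> float:
    """sigma(R) / mean(R) over radial distances from the geometric centre.

    ``ddof=0`` (population SD, divisor N) is the default; ``ddof=1`` gives
    the sample-SD variant.  The statistic is invariant to translation,
    rotation and uniform scaling of the contour and is 0 for a perfect
    circle.
    """
    if not isinstance(contour, Contour):
        contour = sort_by_azimuth(contour)
    centre = contour_centre(contour)
    radii = radial_coordinates(contour, centre)
    mean_r, sd_r = _radial_stats(radii, ddof)
    if mean_r <= 0:
        raise ZeroRadius("all contour points coincide with the centre")
    return sd_r / mean_r


def _is_simple_polygon(xy: np.ndarray) -> bool:
    """True if the closed polygon through ``xy`` is simple (no crossings).

    Consecutive duplicate vertices are dropped first; shapely's planar
    predicate does the segment-crossing work.
    """
    from shapely.geometry import LinearRing

    keep = np.any(np.diff(xy, axis=0, append=xy[:1]) != 0, axis=1)
    pts = xy[keep]
    if len(pts) < 3:
        return False
    try:
        return bool(LinearRing(pts).is_simple)
    except Exception:
        return False


@dataclass
class ContourMetrics:
    """Per-segmentation morphometry results."""

    centre: Tuple[float, float]
    mean_radius_px: float
    radial_sd_px: float
    acircularity: float
    area_px2: float
    area_mm2: float
    n_points: int
    star_shaped: bool
    meta: Optional[ContourMeta] = None


def compute_metrics(
    points,
    scale: PixelScale,
    ddof: int = 0,
    check_star_shaped: bool = True,
) -> ContourMetrics:
    """Full per-contour pipeline: azimuth sort → centre → radii → area.

    The azimuth sort assumes the drawn boundary is star-shaped about its
    centroid; a non-star-shaped input yields a self-intersecting polygon,
    which is diagnosed and reported through ``star_shaped=False`` rather
    than raised (the area of a self-intersecting polygon is still returned
    but should be treated with suspicion).
    """
    contour = points if isinstance(points, Contour) else sort_by_azimuth(points)
    centre = contour_centre(contour)
    radii = radial_coordinates(contour, centre)
    mean_r, sd_r = _radial_stats(radii, ddof)
    if mean_r <= 0:
        raise ZeroRadius("all contour points coincide with the centre")
    area_px2 = shoelace_area(contour)
    star = _is_simple_polygon(contour.points) if check_star_shaped else True
    return ContourMetrics(
        centre=centre,
        mean_radius_px=mean_r,
        radial_sd_px=sd_r,
        acircularity=sd_r / mean_r,
        area_px2=area_px2,
        area_mm2=to_mm2(area_px2, scale),
        n_points=len(contour),
        star_shaped=star,
        meta=contour.meta if contour.meta is not None else getattr(points, "meta", None),
    )


_TABLE_COLUMNS = [
    "record_id", "eye_id", "plexus", "cohort", "observer", "series",
    "criterion", "n_points", "centre_x", "centre_y", "mean_radius_px",
    "radial_sd_px", "acircularity", "area_px2", "area_mm2", "star_shaped",
]


def metrics_table(
    pointsets: Iterable[PointSet],
    scale: Optional[PixelScale] = None,
    ddof: int = 0,
    check_star_shaped: bool = True,
) -> pd.DataFrame:
    """Tidy table: one row of ContourMetrics fields per segmentation.

    When ``scale`` is None, each record's scale is derived from its own
    metadata (width_mm / image dimension).
    """
    rows = []
    for ps in pointsets:
        rec_scale = scale if scale is not None else PixelScale.from_meta(ps.meta)
        m = compute_metrics(ps, rec_scale, ddof=ddof, check_star_shaped=check_star_shaped)
        meta = ps.meta
        rows.append({
            "record_id": meta.record_id if meta else "",
            "eye_id": meta.eye_id if meta else "",
            "plexus": meta.plexus.value if meta else "",
            "cohort": meta.cohort.value if meta else "",
            "observer": meta.observer if meta else "",
            "series": meta.series if meta else 0,
            "criterion": meta.criterion.value if meta else "",
            "n_points": m.n_points,
            "centre_x": m.centre[0],
            "centre_y": m.centre[1],
            "mean_radius_px": m.mean_radius_px,
            "radial_sd_px": m.radial_sd_px,
            "acircularity": m.acircularity,
            "area_px2": m.area_px2,
            "area_mm2": m.area_mm2,
            "star_shaped": m.star_shaped,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
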