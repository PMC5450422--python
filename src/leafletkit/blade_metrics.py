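"""Blade-level size and shape measurements for a separated leaflet.

Lengths follow the junction-midpoint convention: the blade length L is the
largest distance from the midpoint of the blade--stalk junction to any
margin point (optionally measured along a manually supplied curved midvein),
and the width W is the longest chord orthogonal to the length axis, probed
at stations every 5 px along it.  Areas of pixel-traced contours use the
lattice-point (Pick) correction so they agree with foreground pixel counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import LineString, MultiLineString, Polygon
from shapely.ops import split as shapely_split

from .segmentation import Contour, LeafletRecord

STATION_SPACING = 5.0  # px between orthogonal width probes


@dataclass
class BladeMetrics:
    length: float
    width: float
    area: float
    perimeter: float
    length_width_ratio: float
    symmetry: float
    compactness: float
    tip_index: int
    inner_blade_area: float | None = None
    blade_inner_perimeter: float | None = None


def pixel_area(contour: Contour) -> float:
    """Foreground pixel count of a traced boundary chain (Pick's theorem)."""
    return contour.area() + 0.5 * len(contour) + 1.0


def smoothed_perimeter(contour: Contour, sigma: float = 2.0) -> float:
    """Perimeter after a light circular Gaussian smoothing of the contour.

    Removes the stair-step bias of pixel chains (a digital disk's raw chain
    length overshoots 2*pi*r by ~5%) without altering shape-scale features.
    """
    pts = contour.points
    sm = np.column_stack(
        [gaussian_filter1d(pts[:, k], sigma, mode="wrap") for k in (0, 1)]
    )
    return Contour(sm).perimeter()


def _blade_polygon(record: LeafletRecord) -> Polygon:
    poly = Polygon(record.contour.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def blade_length(record: LeafletRecord) -> tuple[float, int]:
    """Blade length L = max_i d(junction midpoint, margin point i).

    Returns (L, tip_index); the junction-midpoint -> tip segment is the
    length axis used by the width search.
    """
    if len(record.contour) < 3:
        raise ValueError("degenerate contour")
    x0, y0 = record.junction_midpoint
    margin = record.contour.points[record.margin_indices]
    d = np.hypot(margin[:, 0] - x0, margin[:, 1] - y0)
    tip = int(np.argmax(d))
    return float(d[tip]), tip


def blade_length_curved(
    record: LeafletRecord, midvein_points: np.ndarray
) -> tuple[float, CubicSpline]:
    """Blade length along a curved midvein through manual control points.

    Fits a natural cubic curve through {junction midpoint, control points,
    blade tip} parameterized by cumulative chord length and integrates its
    arc length.  Control points must advance monotonically from base to tip.
    """
    midvein_points = np.asarray(midvein_points, dtype=np.float64)
    if midvein_points.ndim != 2 or len(midvein_points) < 3:
        raise ValueError("at least 3 ordered midvein control points required")
    _, tip = blade_length(record)
    base = np.asarray(record.junction_midpoint)
    tip_pt = record.contour.points[tip]
    pts = np.vstack([base, midvein_points, tip_pt])
    axis = tip_pt - base
    proj = (pts - base) @ axis
    if np.any(np.diff(proj) <= 0):
        raise ValueError("midvein control points must be ordered base -> tip")
    chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    spline = CubicSpline(chord, pts, bc_type="natural")
    t = np.linspace(0.0, chord[-1], 2000)
    xy = spline(t)
    length = float(np.hypot(*np.diff(xy, axis=0).T).sum())
    return length, spline


def _longest_crossing(poly: Polygon, p: np.ndarray, direction: np.ndarray,
                      reach: float) -> float:
    """Length of the longest in-blade piece of the probe line through p."""
    d = direction / np.hypot(*direction)
    line = LineString([p - reach * d, p + reach * d])
    inter = poly.intersection(line)
    if inter.is_empty:
        return 0.0
    if isinstance(inter, LineString):
        return inter.length
    if isinstance(inter, MultiLineString):
        return max(g.length for g in inter.geoms)
    try:  # GeometryCollection from grazing contacts
        return max(
            (g.length for g in inter.geoms if isinstance(g, LineString)),
            default=0.0,
        )
    except AttributeError:
        return 0.0


def blade_width(
    record: LeafletRecord,
    axis_curve: CubicSpline | None = None,
    station_spacing: float = STATION_SPACING,
) -> float:
    """Blade width W: the longest chord orthogonal to the length axis.

    Probe chords are erected every *station_spacing* px along the axis
    (straight junction-midpoint -> tip by default, or the curved midvein);
    each probe contributes its longest single in-blade crossing, so sinuses
    in a concave margin cannot inflate the width.
    """
    L, tip = blade_length(record)
    poly = _blade_polygon(record)
    base = np.asarray(record.junction_midpoint)
    reach = 4.0 * L

    if axis_curve is None:
        tip_pt = record.contour.points[tip]
        axis = tip_pt - base
        n_stations = int(np.floor(L / station_spacing)) + 1
        best = 0.0
        unit = axis / np.hypot(*axis)
        normal = np.array([-unit[1], unit[0]])
        for s in range(n_stations):
            p = base + unit * (s * station_spacing)
            best = max(best, _longest_crossing(poly, p, normal, reach))
    else:
        total = float(axis_curve.x[-1])
        n_stations = int(np.floor(total / station_spacing)) + 1
        best = 0.0
        for s in range(n_stations):
            t = min(s * station_spacing, total)
            p = np.asarray(axis_curve(t), dtype=float)
            tang = np.asarray(axis_curve(t, 1), dtype=float)
            normal = np.array([-tang[1], tang[0]])
            best = max(best, _longest_crossing(poly, p, normal, reach))
    if best <= 0:
        raise ValueError("no orthogonal chord intersects the contour")
    return float(best)


def blade_shape_params(
    record: LeafletRecord,
    length: float | None = None,
    width: float | None = None,
) -> BladeMetrics:
    """Area, perimeter, L/W ratio, left/right symmetry and compactness.

    Symmetry is the ratio of blade area left vs right of the length axis
    (as seen on the scan, y pointing down); compactness is 4*pi*A/P^2,
    equal to 1 for a circle.
    """
    if length is None:
        length, tip = blade_length(record)
    else:
        _, tip = blade_length(record)
    if width is None:
        width = blade_width(record)

    traced = bool(record.meta.get("traced"))
    area = pixel_area(record.contour) if traced else record.contour.area()
    perim = (
        smoothed_perimeter(record.contour)
        if traced
        else record.contour.perimeter()
    )

    base = np.asarray(record.junction_midpoint)
    tip_pt = record.contour.points[tip]
    axis = tip_pt - base
    unit = axis / np.hypot(*axis)
    poly = _blade_polygon(record)
    ext = 4.0 * length
    cutter = LineString([base - ext * unit, base + ext * unit])
    left_area = right_area = 0.0
    try:
        pieces = shapely_split(poly, cutter).geoms
    except Exception:
        pieces = [poly]
    for g in pieces:
        w = np.asarray(g.representative_point().coords[0]) - base
        cross = unit[0] * w[1] - unit[1] * w[0]
        if cross < 0:
            left_area += g.area
        else:
            right_area += g.area
    if right_area <= 0 or left_area <= 0:
        warnings.warn("length axis does not split the blade; symmetry set to 1")
        symmetry = 1.0
    else:
        symmetry = left_area / right_area

    return BladeMetrics(
        length=float(length),
        width=float(width),
        area=float(area),
        perimeter=float(perim),
        length_width_ratio=float(length / width),
        symmetry=float(symmetry),
        compactness=float(4.0 * np.pi * area / perim**2),
        tip_index=tip,
    )
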