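"""Detection and measurement of margin serrations (teeth) and sinuses.

Teeth and valleys are extrema of the centroid radial-distance profile.  The
raw profile mixes two scales: the slowly varying blade outline (the broad
distal maximum of any elongated blade) and the fast serration signal.  The
detector therefore removes a sharply low-passed outline baseline from the
lightly smoothed profile and finds strict local extrema of the residual, filtered
by prominence, so a smooth ellipse or a low-pass-reconstructed outline
yields zero teeth while genuine serrations of a few pixels survive.
Geometry (heights, areas, angles) is always measured on the raw contour so
measurements are not blurred by the detection smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .blade_metrics import BladeMetrics
from .segmentation import Contour, LeafletRecord, RadialProfile, radial_profile

SMOOTH_WINDOW = 5


@dataclass
class Tooth:
    tip_index: int
    left_valley_index: int
    right_valley_index: int
    height: float
    area: float
    perimeter: float
    base_length: float
    tip_angle: float
    left_angle: float
    right_angle: float


@dataclass
class Valley:
    bottom_index: int
    left_tip_index: int
    right_tip_index: int
    depth: float
    area: float
    base_length: float


@dataclass
class SerrationSummary:
    tooth_number: int
    total_tooth_area: float
    mean_tooth_area: float
    total_tooth_height: float
    mean_tooth_height: float
    total_tooth_perimeter: float
    mean_tooth_perimeter: float
    mean_tip_angle: float
    mean_left_angle: float
    mean_right_angle: float
    tooth_base_length: float
    outer_toothed_area: float
    inner_toothed_area: float
    length_of_outer_edge: float
    inner_blade_area: float
    blade_inner_perimeter: float
    valley_number: int
    total_valley_area: float
    mean_valley_area: float
    mean_valley_depth: float
    tooth_valley_area_ratio: float
    inner_toothed_area_ratio: float
    tooth_number_blade_ratio: float
    relative_tooth_area: float


def default_min_prominence(distances: np.ndarray) -> float:
    """1.5 px plus 2% of the median radial distance.

    The strict 5-point extremum rule alone fires on single-pixel stair
    steps of a traced margin; this floor suppresses that noise while
    staying far below any real tooth of a few px height.
    """
    return 1.5 + 0.02 * float(np.median(distances))


def _circular_mean(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    k = np.ones(window) / window
    pad = np.concatenate([x[-window:], x, x[:window]])
    return np.convolve(pad, k, mode="same")[window:-window]


def _outline_baseline(y: np.ndarray, cutoff_fraction: float = 1 / 6) -> np.ndarray:
    """Sharp circular low-pass baseline separating outline from serration.

    Fourth-order Whittaker smoother: ``z = argmin |y - z|^2 + lam |D4 z|^2``
    with circular fourth differences.  The 8th-power transfer rolls off
    steeply around the half-power wavelength ``cutoff_fraction * n``, which
    sits between the blade-outline scale (about half the contour) and the
    widest credible tooth, so the broad distal lobe of an elongated blade
    stays in the baseline while even sparse, wide serrations pass to the
    residual essentially unattenuated.
    """
    n = len(y)
    lam = (cutoff_fraction * n / (2.0 * np.pi)) ** 8
    # the circulant penalty diagonalizes in Fourier space: exact solve
    omega = 2.0 * np.pi * np.fft.rfftfreq(n)
    gain = 1.0 / (1.0 + lam * (2.0 - 2.0 * np.cos(omega)) ** 4)
    return np.fft.irfft(np.fft.rfft(y) * gain, n=n)


def _residual_peaks(resid: np.ndarray, prominence: float,
                    circular: bool) -> np.ndarray:
    """Strict local maxima of the residual, filtered by local prominence.

    This is the operative form of the strict five-point extremum rule on
    the plateau-collapsed, smoothed profile: `find_peaks` requires a
    strict rise on both sides (runs of equal values are collapsed to
    their midpoint), and the prominence filter discards extrema whose
    excursion stays below the noise floor.  Prominence is evaluated in a
    local window (wlen) so a remote deep feature such as the basal
    junction notch cannot inflate the prominence of a sub-threshold
    ripple half a contour away.
    """
    n = len(resid)
    wlen = max(50, n // 4)
    if circular:
        ext = np.concatenate([resid, resid, resid])
        pk, _ = find_peaks(ext, prominence=prominence, wlen=wlen)
        pk = np.unique(pk[(pk >= n) & (pk < 2 * n)] - n)
    else:
        pk, _ = find_peaks(resid, prominence=prominence, wlen=wlen)
    return np.asarray(pk, dtype=int)


def detect_extrema(
    profile: RadialProfile,
    min_prominence: float | None = None,
    exclude: np.ndarray | None = None,
    smooth_window: int = SMOOTH_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Find tooth tips and valley bottoms on a radial profile.

    *exclude* marks contour indices (the junction cut and its surround)
    barred from the search; when given, the profile is treated as an open
    margin, otherwise as circular.  Returns ``(tip_indices,
    valley_indices)`` refined to raw-profile extrema and strictly
    interleaved: every pair of consecutive tips brackets exactly one
    valley, and the outermost teeth receive flank valleys where the
    detrended profile returns to the outline baseline.
    """
    d = profile.distances
    n = len(d)
    if min_prominence is None:
        min_prominence = default_min_prominence(d)
    circular = exclude is None or len(exclude) == 0

    ds = _circular_mean(d, smooth_window)
    if not circular:
        # bridge the excluded (junction/notch) region with a linear ramp so
        # the deep basal dip cannot ring through the low-pass baseline
        ds = _bridge(ds, np.asarray(exclude, dtype=int) % n)
    # two-pass baseline: strip serration-scale excursions found by the
    # first fit, then refit, so wide teeth cannot drag the baseline into
    # themselves and attenuate their own residual
    base = _outline_baseline(ds)
    strip = np.abs(ds - base) > 0.5 * min_prominence
    if strip.any() and not strip.all():
        base = _outline_baseline(_bridge(ds, np.nonzero(strip)[0]))
    resid = ds - base

    tips = _residual_peaks(resid, min_prominence, circular)
    valleys = _residual_peaks(-resid, min_prominence, circular)

    if not circular:
        # the sharp low-pass rings near the bridged junction kink; pad the
        # exclusion by about half the filter cutoff wavelength
        buffer = max(10, n // 12)
        excl = np.zeros(n, dtype=bool)
        excl[np.asarray(exclude, dtype=int) % n] = True
        excl = np.convolve(excl.astype(int), np.ones(2 * buffer + 1),
                           mode="same") > 0
        tips = tips[~excl[tips]]
        valleys = valleys[~excl[valleys]]

    if len(tips) == 0:
        return tips, valleys[:0]

    tips = np.sort(tips)
    valleys = np.sort(valleys)

    if circular:
        # between consecutive tips (cyclically) keep exactly one valley
        out_valleys = []
        for a, b in zip(tips, np.roll(tips, -1)):
            span = np.arange(a + 1, b if b > a else b + n) % n
            vs = [v for v in valleys if v in set(span.tolist())]
            if vs:
                out_valleys.append(min(vs, key=lambda v: d[v]))
            else:
                out_valleys.append(int(span[np.argmin(d[span])]))
        valleys = np.sort(np.asarray(out_valleys, dtype=int))
    else:
        out_valleys = []
        # interior valleys: deepest raw-profile point between tip pairs
        for a, b in zip(tips[:-1], tips[1:]):
            span = np.arange(a + 1, b)
            inner = [v for v in valleys if a < v < b]
            if inner:
                out_valleys.append(min(inner, key=lambda v: d[v]))
            elif len(span):
                out_valleys.append(int(span[np.argmin(d[span])]))
        # outer flanks: first return of the residual to the baseline
        tol = 0.25 * min_prominence
        lo = _flank(resid, tips[0], -1, valleys, n, tol)
        hi = _flank(resid, tips[-1], +1, valleys, n, tol)
        if lo is not None:
            out_valleys.insert(0, lo)
        if hi is not None:
            out_valleys.append(hi)
        valleys = np.asarray(sorted(out_valleys), dtype=int)

    # refine to raw-profile extrema (detection ran on the smoothed residual)
    half = smooth_window
    tips = np.asarray(
        [_refine(d, i, half, n, circular, np.argmax) for i in tips], dtype=int
    )
    tips = np.unique(tips)
    return tips, valleys


def _bridge(values: np.ndarray, exclude: np.ndarray) -> np.ndarray:
    """Replace excluded samples by circular linear interpolation."""
    n = len(values)
    mask = np.zeros(n, dtype=bool)
    mask[exclude] = True
    if not mask.any() or mask.all():
        return values
    out = values.astype(float).copy()
    keep = np.nonzero(~mask)[0]
    miss = np.nonzero(mask)[0]
    # circular interpolation via index unwrapping around the kept points
    out[miss] = np.interp(
        miss,
        np.concatenate([keep - n, keep, keep + n]),
        np.tile(values[keep], 3),
    )
    return out


def _flank(resid: np.ndarray, tip: int, step: int, valleys: np.ndarray,
           n: int, tol: float) -> int | None:
    """Walk outward from an outermost tip to its base-level flank."""
    vset = set(valleys.tolist())
    j = tip
    for _ in range(n):
        j2 = j + step
        if not (0 <= j2 < n):
            return None
        if j2 in vset:
            return j2
        if resid[j2] <= tol:
            return j2
        j = j2
    return None


def _refine(d, i, half, n, circular, fn):
    if circular:
        win = (np.arange(i - half, i + half + 1)) % n
    else:
        win = np.arange(max(0, i - half), min(n, i + half + 1))
    return int(win[fn(d[win])])


def detect_serrations(
    record: LeafletRecord,
    min_prominence: float | None = None,
    notch_exclude_fraction: float = 0.8,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, RadialProfile]:
    """Tooth/valley detection on a separated leaflet.

    The junction cut is excluded from the extremum search, together with
    the basal notch: margin points contiguous with the cut whose distance
    stays below ``notch_exclude_fraction x median`` belong to the blade
    base, never to a sinus.
    """
    prof = radial_profile(record.contour)
    m = record.junction_endpoints[1]
    n = len(record.contour)
    thr = notch_exclude_fraction * float(np.median(prof.distances))
    lo = 0
    while lo < m and prof.distances[lo] < thr:
        lo += 1
    hi = m
    while hi > lo and prof.distances[hi] < thr:
        hi -= 1
    exclude = np.concatenate([
        np.arange(0, lo + 1), np.arange(hi, n)
    ])
    tips, valleys = detect_extrema(
        prof, min_prominence=min_prominence, exclude=exclude, **kwargs
    )
    return tips, valleys, prof


def _arc(contour: Contour, i: int, j: int) -> np.ndarray:
    n = len(contour)
    if j >= i:
        idx = np.arange(i, j + 1)
    else:
        idx = np.concatenate([np.arange(i, n), np.arange(0, j + 1)])
    return contour.points[idx]


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def _poly_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    norm = np.hypot(*ab)
    if norm < 1e-12:
        return float(np.hypot(*(p - a)))
    return float(abs(ab[0] * (p[1] - a[1]) - ab[1] * (p[0] - a[0])) / norm)


def _triangle_angles(tip, left, right) -> tuple[float, float, float]:
    def ang(a, b, c):  # angle at a
        u, v = b - a, c - a
        cosv = np.dot(u, v) / (np.hypot(*u) * np.hypot(*v))
        return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))

    return ang(tip, left, right), ang(left, tip, right), ang(right, tip, left)


def tooth_geometry(
    contour: Contour, tips: np.ndarray, valleys: np.ndarray
) -> list[Tooth]:
    """Per-tooth geometry from flanking valley connection lines.

    The tooth base is the segment joining the two flanking valley bottoms;
    height is the tip's perpendicular distance to it, area the shoelace
    area between margin arc and base, and the three angles come from the
    tip--valley--valley triangle.
    """
    teeth: list[Tooth] = []
    valleys = np.sort(np.asarray(valleys, dtype=int))
    for t in np.sort(np.asarray(tips, dtype=int)):
        left_c = valleys[valleys < t]
        right_c = valleys[valleys > t]
        if len(left_c) == 0 and len(valleys):
            left_c = valleys[-1:]  # circular wrap
        if len(right_c) == 0 and len(valleys):
            right_c = valleys[:1]
        if len(left_c) == 0 or len(right_c) == 0:
            warnings.warn(f"tooth at index {t} has no flanking valleys; skipped")
            continue
        vl, vr = int(left_c[-1]), int(right_c[0])
        p_tip = contour.points[t]
        p_l, p_r = contour.points[vl], contour.points[vr]
        base = float(np.hypot(*(p_r - p_l)))
        if base < 1e-9:
            warnings.warn(f"tooth at index {t}: flanking valleys coincide; skipped")
            continue
        arc = _arc(contour, vl, vr)
        tip_a, left_a, right_a = _triangle_angles(p_tip, p_l, p_r)
        teeth.append(
            Tooth(
                tip_index=int(t),
                left_valley_index=vl,
                right_valley_index=vr,
                height=_point_line_distance(p_tip, p_l, p_r),
                area=_poly_area(arc),
                perimeter=_polyline_length(arc) + base,
                base_length=base,
                tip_angle=tip_a,
                left_angle=left_a,
                right_angle=right_a,
            )
        )
    return teeth


def valley_geometry(
    contour: Contour, tips: np.ndarray, valleys: np.ndarray
) -> list[Valley]:
    """Per-valley geometry; the base joins the two flanking tooth tips."""
    out: list[Valley] = []
    tips = np.sort(np.asarray(tips, dtype=int))
    for v in np.sort(np.asarray(valleys, dtype=int)):
        left_c = tips[tips < v]
        right_c = tips[tips > v]
        if len(left_c) == 0 or len(right_c) == 0:
            continue  # outer flank valleys have no bracketing tip pair
        tl, tr = int(left_c[-1]), int(right_c[0])
        p_v = contour.points[v]
        p_l, p_r = contour.points[tl], contour.points[tr]
        base = float(np.hypot(*(p_r - p_l)))
        if base < 1e-9:
            continue
        arc = _arc(contour, tl, tr)
        out.append(
            Valley(
                bottom_index=int(v),
                left_tip_index=tl,
                right_tip_index=tr,
                depth=_point_line_distance(p_v, p_l, p_r),
                area=_poly_area(arc),
                base_length=base,
            )
        )
    return out


def serration_summary(
    record: LeafletRecord,
    teeth: list[Tooth],
    valleys: list[Valley],
    blade: BladeMetrics,
) -> SerrationSummary:
    """Aggregate tooth/valley measures and the derived margin parameters.

    The tooth base line is the polyline through all tooth-base endpoints;
    the chord joining its first and last point divides the blade into the
    distal (outer toothed) and proximal parts.  Area bookkeeping uses the
    exact identities outer = teeth + inner-toothed strip and inner blade =
    blade - teeth, which avoids rasterisation error in the split.
    """
    contour = record.contour
    nt = len(teeth)
    if nt == 0:
        return SerrationSummary(
            tooth_number=0, total_tooth_area=0.0, mean_tooth_area=0.0,
            total_tooth_height=0.0, mean_tooth_height=0.0,
            total_tooth_perimeter=0.0, mean_tooth_perimeter=0.0,
            mean_tip_angle=0.0, mean_left_angle=0.0, mean_right_angle=0.0,
            tooth_base_length=0.0, outer_toothed_area=0.0,
            inner_toothed_area=0.0, length_of_outer_edge=0.0,
            inner_blade_area=blade.area,
            blade_inner_perimeter=blade.perimeter,
            valley_number=0, total_valley_area=0.0, mean_valley_area=0.0,
            mean_valley_depth=0.0, tooth_valley_area_ratio=float("nan"),
            inner_toothed_area_ratio=0.0, tooth_number_blade_ratio=0.0,
            relative_tooth_area=0.0,
        )

    total_area = sum(t.area for t in teeth)
    total_height = sum(t.height for t in teeth)
    total_perim = sum(t.perimeter for t in teeth)
    base_len = sum(t.base_length for t in teeth)

    # base-endpoint polyline in margin order (consecutive teeth share valleys)
    base_idx: list[int] = []
    for t in sorted(teeth, key=lambda t: t.tip_index):
        for v in (t.left_valley_index, t.right_valley_index):
            if not base_idx or base_idx[-1] != v:
                base_idx.append(v)
    base_pts = contour.points[np.asarray(base_idx)]

    inner_toothed = _poly_area(base_pts) if len(base_pts) >= 3 else 0.0
    outer_toothed = total_area + inner_toothed

    first, last = base_idx[0], base_idx[-1]
    outer_edge = _polyline_length(_arc(contour, first, last))
    blade_perim = blade.perimeter
    inner_perimeter = max(blade_perim - outer_edge, 0.0) + base_len
    inner_blade = blade.area - total_area

    nv = len(valleys)
    tv_area = sum(v.area for v in valleys)
    tv_depth = sum(v.depth for v in valleys)

    return SerrationSummary(
        tooth_number=nt,
        total_tooth_area=total_area,
        mean_tooth_area=total_area / nt,
        total_tooth_height=total_height,
        mean_tooth_height=total_height / nt,
        total_tooth_perimeter=total_perim,
        mean_tooth_perimeter=total_perim / nt,
        mean_tip_angle=sum(t.tip_angle for t in teeth) / nt,
        mean_left_angle=sum(t.left_angle for t in teeth) / nt,
        mean_right_angle=sum(t.right_angle for t in teeth) / nt,
        tooth_base_length=base_len,
        outer_toothed_area=outer_toothed,
        inner_toothed_area=inner_toothed,
        length_of_outer_edge=outer_edge,
        inner_blade_area=inner_blade,
        blade_inner_perimeter=inner_perimeter,
        valley_number=nv,
        total_valley_area=tv_area,
        mean_valley_area=tv_area / nv if nv else 0.0,
        mean_valley_depth=tv_depth / nv if nv else 0.0,
        tooth_valley_area_ratio=(total_area / tv_area) if tv_area > 0 else float("nan"),
        inner_toothed_area_ratio=inner_toothed / blade.area if blade.area else 0.0,
        tooth_number_blade_ratio=nt / blade.area if blade.area else 0.0,
        relative_tooth_area=total_area / blade.area if blade.area else 0.0,
    )
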