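"""Tooth/valley detection and geometry on margins."""

import numpy as np
import pytest

from leafletkit.blade_metrics import blade_shape_params
from leafletkit.segmentation import Contour, radial_profile
from leafletkit.serration_metrics import (
    detect_extrema,
    detect_serrations,
    serration_summary,
    tooth_geometry,
    valley_geometry,
)
from leafletkit.synthetic import LeafletSpec, make_leaflet_record


def lobed_circle(k=12, r=100.0, amp=8.0, n=3600):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = r + amp * np.sin(k * phi)
    return Contour(np.column_stack([rr * np.cos(phi), rr * np.sin(phi)]))


class TestDetectExtrema:
    def test_sinusoidal_lobes_recovered(self):
        contour = lobed_circle()
        tips, valleys = detect_extrema(radial_profile(contour))
        # oracle: analytic extrema of r(phi) = 100 + 8 sin(12 phi)
        assert len(tips) == 12
        assert len(valleys) == 12

    def test_smooth_ellipse_zero_teeth(self):
        phi = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        ellipse = Contour(np.column_stack([100 * np.cos(phi), 60 * np.sin(phi)]))
        tips, _ = detect_extrema(radial_profile(ellipse))
        assert len(tips) == 0

    def test_interleaving(self):
        contour = lobed_circle()
        tips, valleys = detect_extrema(radial_profile(contour))
        events = sorted([(t, "t") for t in tips] + [(v, "v") for v in valleys])
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    @pytest.mark.parametrize("tooth_count", [0, 5, 12, 25, 40])
    def test_generator_recovery(self, tooth_count):
        rec, gt = make_leaflet_record(
            LeafletSpec(tooth_count=tooth_count, seed=500 + tooth_count)
        )
        tips, valleys, _ = detect_serrations(rec)
        assert len(tips) == gt.tooth_count


class TestToothGeometry:
    def _triangular_tooth_contour(self, base=20.0, height=10.0):
        """A flat margin with one triangular tooth, closed below."""
        left = np.column_stack([np.linspace(-60, -base / 2, 80),
                                np.zeros(80)])
        up = np.column_stack([np.linspace(-base / 2, 0, 40),
                              np.linspace(0, -height, 40)])
        down = np.column_stack([np.linspace(0, base / 2, 40),
                                np.linspace(-height, 0, 40)])
        right = np.column_stack([np.linspace(base / 2, 60, 80),
                                 np.zeros(80)])
        bottom = np.column_stack([np.linspace(60, -60, 100),
                                  np.full(100, 40.0)])
        pts = np.vstack([left, up[1:], down[1:], right[1:], bottom])
        return Contour(pts).oriented(), base, height

    def test_triangular_tooth_height_and_area(self):
        contour, base, height = self._triangular_tooth_contour()
        d = radial_profile(contour)
        # indices of tip and flanking valleys known by construction
        pts = contour.points
        tip = int(np.argmin(pts[:, 1] * np.sign(contour.signed_area()))) \
            if False else int(np.argmin(pts[:, 1]))
        vl = int(np.argmin(np.hypot(pts[:, 0] + base / 2, pts[:, 1])))
        vr = int(np.argmin(np.hypot(pts[:, 0] - base / 2, pts[:, 1])))
        lo, hi = sorted((vl, vr))
        teeth = tooth_geometry(contour, np.array([tip]), np.array([lo, hi]))
        assert len(teeth) == 1
        t = teeth[0]
        assert abs(t.height - height) <= 0.5
        # oracle: shoelace of the generator triangle = base*height/2
        assert abs(t.area - base * height / 2) <= 5.0

    def test_equilateral_tip_angle(self):
        side = 30.0
        contour, base, height = self._triangular_tooth_contour(
            base=side, height=side * np.sqrt(3) / 2
        )
        pts = contour.points
        tip = int(np.argmin(pts[:, 1]))
        vl = int(np.argmin(np.hypot(pts[:, 0] + side / 2, pts[:, 1])))
        vr = int(np.argmin(np.hypot(pts[:, 0] - side / 2, pts[:, 1])))
        lo, hi = sorted((vl, vr))
        teeth = tooth_geometry(contour, np.array([tip]), np.array([lo, hi]))
        assert abs(teeth[0].tip_angle - 60.0) <= 2.0

    def test_angle_sum_identity(self, default_record):
        rec, _ = default_record
        tips, valleys, _ = detect_serrations(rec)
        for t in tooth_geometry(rec.contour, tips, valleys):
            assert t.tip_angle + t.left_angle + t.right_angle == pytest.approx(
                180.0, abs=0.1
            )


class TestValleyGeometry:
    def test_sinusoid_symmetry(self):
        # high lobe count so the chord sag from circle curvature is
        # second-order relative to the lobe amplitude
        contour = lobed_circle(k=36, r=150.0, amp=16.0, n=7200)
        tips, valleys = detect_extrema(radial_profile(contour))
        teeth = tooth_geometry(contour, tips, valleys)
        vals = valley_geometry(contour, tips, valleys)
        mean_h = np.mean([t.height for t in teeth])
        mean_d = np.mean([v.depth for v in vals])
        assert abs(mean_h - mean_d) / mean_h < 0.10

    def test_toothless_margin_empty(self, smooth_record):
        rec, _ = smooth_record
        tips, valleys, _ = detect_serrations(rec)
        assert valley_geometry(rec.contour, tips, valleys) == []

    def test_tooth_valley_area_ratio_near_one(self):
        contour = lobed_circle(k=36, r=150.0, amp=16.0, n=7200)
        tips, valleys = detect_extrema(radial_profile(contour))
        teeth = tooth_geometry(contour, tips, valleys)
        vals = valley_geometry(contour, tips, valleys)
        ratio = sum(t.area for t in teeth) / sum(v.area for v in vals)
        assert abs(ratio - 1.0) <= 0.1


class TestSerrationSummary:
    def test_smooth_margin_zeros(self, smooth_record):
        rec, _ = smooth_record
        blade = blade_shape_params(rec)
        summ = serration_summary(rec, [], [], blade)
        assert summ.tooth_number == 0
        assert summ.tooth_number_blade_ratio == 0.0
        assert summ.relative_tooth_area == 0.0
        assert np.isnan(summ.tooth_valley_area_ratio)
        assert summ.inner_blade_area == blade.area

    def test_identical_teeth_total(self):
        # 8 identical sawtooth teeth tiling a circle; the single-tooth
        # oracle polygon is built directly from the generator formula
        k, r, h, n = 8, 120.0, 10.0, 4800
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        frac = (phi * k / (2 * np.pi)) % 1.0
        rr = r + h * (1.0 - np.abs(2 * frac - 1.0))
        contour = Contour(np.column_stack([rr * np.cos(phi),
                                           rr * np.sin(phi)]))
        tips, valleys = detect_extrema(radial_profile(contour))
        teeth = tooth_geometry(contour, tips, valleys)
        assert len(teeth) == 8
        # oracle: shoelace of one analytic tooth polygon (arc + chord)
        cell = phi <= 2 * np.pi / k
        arc = np.column_stack([rr[cell] * np.cos(phi[cell]),
                               rr[cell] * np.sin(phi[cell])])
        x, y = arc[:, 0], arc[:, 1]
        single = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        total = sum(t.area for t in teeth)
        assert abs(total - 8 * single) / (8 * single) < 0.02

    def test_area_bookkeeping(self, default_record):
        rec, _ = default_record
        blade = blade_shape_params(rec)
        tips, valleys, _ = detect_serrations(rec)
        teeth = tooth_geometry(rec.contour, tips, valleys)
        vals = valley_geometry(rec.contour, tips, valleys)
        summ = serration_summary(rec, teeth, vals, blade)
        # identity: outer = teeth + inner-toothed strip
        assert summ.outer_toothed_area == pytest.approx(
            summ.total_tooth_area + summ.inner_toothed_area
        )
        # independent oracle: split the blade polygon with the dividing chord
        from shapely.geometry import LineString, Polygon
        from shapely.ops import split as shapely_split

        poly = Polygon(rec.contour.points)
        if not poly.is_valid:
            poly = poly.buffer(0)
        first = rec.contour.points[teeth[0].left_valley_index]
        last = rec.contour.points[teeth[-1].right_valley_index]
        d = last - first
        d = d / np.hypot(*d)
        cutter = LineString([first - 500 * d, last + 500 * d])
        pieces = shapely_split(poly, cutter).geoms
        tip_pt = rec.contour.points[teeth[0].tip_index]
        outer = sum(g.area for g in pieces
                    if g.distance(__import__("shapely").geometry.Point(tip_pt))
                    < 1.0)
        assert abs(outer - summ.outer_toothed_area) / outer < 0.02

    def test_scaling(self):
        spec = LeafletSpec(tooth_count=15, seed=4, margin_noise_sd=0.0)
        rec1, _ = make_leaflet_record(spec)
        big = LeafletSpec(
            tooth_count=15, seed=4, margin_noise_sd=0.0,
            semi_major=spec.semi_major * 2, semi_minor=spec.semi_minor * 2,
            tooth_height=spec.tooth_height * 2,
            stalk_length=spec.stalk_length * 2,
            stalk_width=spec.stalk_width * 2,
        )
        rec2, _ = make_leaflet_record(big)
        out = []
        for rec in (rec1, rec2):
            tips, valleys, _ = detect_serrations(rec)
            teeth = tooth_geometry(rec.contour, tips, valleys)
            out.append((np.mean([t.height for t in teeth]),
                        np.mean([t.area for t in teeth])))
        (h1, a1), (h2, a2) = out
        assert h2 / h1 == pytest.approx(2.0, rel=0.02)
        assert a2 / a1 == pytest.approx(4.0, rel=0.02)
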