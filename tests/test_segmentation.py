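"""Contour tracing, radial profiles, junction detection, leaflet separation."""

import numpy as np
import pytest

from leafletkit.image_io import BinaryMask, segment_foreground
from leafletkit.segmentation import (
    Contour,
    find_junction,
    radial_profile,
    separate_leaflets,
    trace_contour,
)
from leafletkit.synthetic import render_leaf_image


def _disk_mask(radius, pad=10):
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[:n, :n]
    return BinaryMask((yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2)


class TestTraceContour:
    def test_square_boundary_pixel_count(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        contour = trace_contour(BinaryMask(m))
        # oracle: pixels of a 10x10 square with a background 4-neighbor
        assert len(contour) == 36

    def test_disk_perimeter_within_five_percent(self):
        contour = trace_contour(_disk_mask(50))
        assert abs(contour.perimeter() - 2 * np.pi * 50) / (2 * np.pi * 50) < 0.05

    def test_ccw_orientation(self):
        contour = trace_contour(_disk_mask(20))
        assert contour.signed_area() > 0

    def test_multi_component_rejected(self):
        m = np.zeros((40, 40), bool)
        m[5:15, 5:15] = True
        m[25:35, 25:35] = True
        with pytest.raises(ValueError, match="exactly one"):
            trace_contour(BinaryMask(m))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trace_contour(BinaryMask(np.zeros((10, 10), bool)))


class TestRadialProfile:
    def test_digital_circle_constant_distance(self):
        prof = radial_profile(trace_contour(_disk_mask(60)))
        assert prof.distances.min() >= 59.0
        assert prof.distances.max() <= 61.0

    def test_square_corner_distance(self):
        s = 101
        m = np.zeros((s + 20, s + 20), bool)
        m[10:10 + s, 10:10 + s] = True
        prof = radial_profile(trace_contour(BinaryMask(m)))
        # oracle: exact corner distance s*sqrt(2)/2 (boundary pixel centers
        # span s-1 px)
        assert abs(prof.distances.max() - (s - 1) * np.sqrt(2) / 2) <= 1.0

    @pytest.mark.parametrize("shift", [(17, -5), (-3, 40)])
    def test_translation_equivariance(self, shift):
        contour = trace_contour(_disk_mask(40))
        moved = Contour(contour.points + np.asarray(shift, float))
        p0, p1 = radial_profile(contour), radial_profile(moved)
        assert np.allclose(p0.distances, p1.distances)
        assert np.allclose(
            np.asarray(p1.centroid) - np.asarray(p0.centroid), shift
        )


class TestFindJunction:
    def test_generator_leaflet_junction_location(self, stalked_leaflet):
        contour, gt = stalked_leaflet
        i, j = find_junction(radial_profile(contour))
        found = contour.points[[i, j]]
        for f in found:
            err = min(np.hypot(*(f - e)) for e in gt.junction_endpoints)
            assert err <= 3.0

    def test_stalkless_ellipse_raises(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ellipse = Contour(np.column_stack([100 * np.cos(t), 40 * np.sin(t)]))
        with pytest.raises(ValueError, match="no junction"):
            find_junction(radial_profile(ellipse))

    def test_sinus_bottoms_never_selected(self, stalked_leaflet):
        # the selected pair must lie at the stalk, not in any tooth sinus
        contour, gt = stalked_leaflet
        i, j = find_junction(radial_profile(contour))
        mid = contour.points[[i, j]].mean(axis=0)
        assert np.hypot(*(mid - gt.junction_midpoint)) <= 3.0


class TestSeparateLeaflets:
    def test_three_records_with_correct_roles_and_areas(self, leaf_image):
        img, truth = leaf_image
        mask = segment_foreground(img)
        records = separate_leaflets(mask)
        assert sorted(r.role for r in records) == [
            "left_lateral", "right_lateral", "terminal"
        ]
        for rec in records:
            measured = rec.contour.area() + len(rec.contour) / 2 + 1
            gt = truth.leaflet_masks[rec.role].sum()
            assert abs(measured - gt) / gt < 0.02

    def test_area_conservation_bound(self, leaf_image):
        img, truth = leaf_image
        mask = segment_foreground(img)
        records = separate_leaflets(mask)
        total = sum(r.contour.area() + len(r.contour) / 2 + 1 for r in records)
        assert total <= mask.area  # stalk pixels excluded

    def test_rotation_invariance(self, leaf_image):
        img, truth = leaf_image
        mask = segment_foreground(img)
        base = {r.role: np.asarray(r.junction_midpoint)
                for r in separate_leaflets(mask)}
        rot_pixels = np.rot90(mask.pixels)  # 90 deg counterclockwise
        rots = separate_leaflets(BinaryMask(rot_pixels))
        W = mask.pixels.shape[1]
        for rec in rots:
            x, y = rec.junction_midpoint
            # map back: rot90 sends pixel (x, y) -> (y, W - 1 - x)
            back = np.array([W - 1 - y, x])
            # roles flip left/right under rotation-induced relabeling only
            errs = [np.hypot(*(back - base[r])) for r in base]
            assert min(errs) <= 2.0

    def test_manual_junction_override(self, leaf_image):
        img, truth = leaf_image
        mask = segment_foreground(img)
        manual = [g.junction_endpoints.tolist()
                  for g in truth.leaflets.values()]
        records = separate_leaflets(mask, manual_junctions=manual)
        assert len(records) == 3
        for rec in records:
            gt = truth.leaflet_masks[rec.role].sum()
            measured = rec.contour.area() + len(rec.contour) / 2 + 1
            assert abs(measured - gt) / gt < 0.03

    def test_non_trifoliate_mask_raises(self):
        with pytest.raises(ValueError, match="expected 3"):
            separate_leaflets(_disk_mask(60))


class TestProfileProperties:
    """Property-based invariants of the radial profile."""

    def test_translation_equivariance_property(self):
        from hypothesis import given, settings, strategies as st

        contour = trace_contour(_disk_mask(35))

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(
            dx=st.floats(-500, 500, allow_nan=False),
            dy=st.floats(-500, 500, allow_nan=False),
        )
        def check(dx, dy):
            moved = Contour(contour.points + np.array([dx, dy]))
            p0 = radial_profile(contour)
            p1 = radial_profile(moved)
            assert np.allclose(p0.distances, p1.distances, atol=1e-8)
            assert np.allclose(
                np.asarray(p1.centroid) - np.asarray(p0.centroid),
                [dx, dy], atol=1e-8,
            )

        check()

    def test_scaling_property(self):
        from hypothesis import given, settings, strategies as st

        contour = trace_contour(_disk_mask(35))

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(c=st.floats(0.1, 20.0, allow_nan=False))
        def check(c):
            scaled = Contour(contour.points * c)
            p0 = radial_profile(contour)
            p1 = radial_profile(scaled)
            assert np.allclose(p1.distances, c * p0.distances, rtol=1e-9)

        check()
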