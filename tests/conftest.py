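"""Shared fixtures: synthetic leaflets, rendered leaves, feature tables."""

from __future__ import annotations

import numpy as np
import pytest

from leafletkit.segmentation import LeafletRecord, build_record
from leafletkit.synthetic import (
    LeafletSpec,
    make_leaflet_contour,
    make_leaflet_record,
    render_leaf_image,
)


@pytest.fixture(scope="session")
def default_record():
    """A 20-tooth leaflet blade record with its ground truth."""
    return make_leaflet_record(LeafletSpec(tooth_count=20, seed=3))


@pytest.fixture(scope="session")
def smooth_record():
    """A toothless, noise-free blade (mirror-symmetric)."""
    return make_leaflet_record(
        LeafletSpec(tooth_count=0, margin_noise_sd=0.0, asymmetry=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def stalked_leaflet():
    """Full stalked leaflet contour (blade + petiolule) for junction tests."""
    return make_leaflet_contour(LeafletSpec(tooth_count=20, seed=3))


@pytest.fixture(scope="session")
def leaf_image():
    """One rendered trifoliate leaf scan with ground truth."""
    return render_leaf_image(seed=5)


def ellipse_record(a=100.0, b=40.0, n=3000, gap=0.02) -> LeafletRecord:
    """Blade record for an axis-aligned ellipse with the junction midpoint
    at one end of the major axis (a tiny margin gap around that end)."""
    t = np.linspace(np.pi + gap, 3 * np.pi - gap, n)
    margin = np.column_stack([a * np.cos(t), b * np.sin(t)])
    return build_record(margin)


def margin_fraction_record(recon, frac) -> LeafletRecord:
    """Rebuild a blade record from a reconstructed contour.

    The reconstruction preserves the arc-length parameterization and the
    starting point, so the margin occupies the first *frac* of the points.
    """
    m = int(len(recon.points) * frac)
    return build_record(recon.points[: m + 1])


def margin_arc_fraction(record) -> float:
    """Arc-length fraction of the contour that is true margin."""
    pts = record.contour.points
    m = record.junction_endpoints[1]
    seg = np.hypot(*np.diff(pts, axis=0).T)
    total = seg.sum() + np.hypot(*(pts[0] - pts[-1]))
    return float(seg[:m].sum() / total)
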