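"""Seeded generator of synthetic trifoliate leaves with full ground truth.

Each leaflet blade is a polar outline r(phi) = base(phi) + teeth(phi) +
noise around the blade center: the base is an (super)ellipse with the
major axis along the proximodistal blade axis, the serrations are
asymmetric triangular (sawtooth) bumps confined to the distal fraction of
the margin, and the stalk (petiolule) is a thin rectangular strip appended
at the proximal pole.  Whole leaves are assembled from three such blades
(terminal on the rachis, two laterals on the petiole) and rasterized as
green tissue on a dark or gray scanner background, with optional thin
grayish trichome strokes along the margins.

All geometry of every output is known by construction and returned as
ground truth, so pipeline measurements can be checked against it exactly.
Sizes drawn for populations are log-normal (margin and blade measures of
real leaves are right-skewed and strictly positive); counts are rounded
log-normal draws so group scatter follows the stated coefficient of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .image_io import RasterImage
from .segmentation import Contour, LeafletRecord, build_record

LEAF_GREEN = np.array([45, 140, 45], dtype=np.uint8)
TRICHOME_GRAY = np.array([205, 205, 208], dtype=np.uint8)
DARK_BG = np.array([8, 8, 8], dtype=np.uint8)
GRAY_BG = np.array([120, 120, 120], dtype=np.uint8)


@dataclass
class LeafletSpec:
    """Parameters of one synthetic leaflet blade (pixel units, 800 dpi)."""

    semi_major: float = 110.0      # proximodistal semi-axis (px)
    semi_minor: float = 65.0       # mediolateral semi-axis (px)
    superellipse_n: float = 2.0    # 2 = ellipse
    tooth_count: int = 20
    tooth_height: float = 9.0      # px
    toothed_arc: float = 0.6       # fraction of margin carrying teeth (distal)
    asymmetry: float = 0.25        # tooth tip skew within its cell, [0, 0.5)
    margin_noise_sd: float = 0.4   # px, smoothed Gaussian margin jitter
    stalk_length: float = 45.0     # px
    stalk_width: float = 8.0       # px
    notch_fraction: float = 0.45   # proximal notch bottom radius / semi_minor
    notch_width: float = 0.5       # angular half-width of the notch (rad)
    n_margin_points: int = 1800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tooth_count < 0:
            raise ValueError("tooth_count must be >= 0")
        if not (0.0 < self.toothed_arc <= 1.0):
            raise ValueError("toothed_arc must be in (0, 1]")
        for name in ("semi_major", "semi_minor", "stalk_length", "stalk_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tooth_height >= self.semi_minor:
            raise ValueError("tooth height must be smaller than the base radius")


@dataclass
class GroundTruth:
    """Construction-time geometry of a generated leaflet."""

    tooth_count: int
    tooth_tips: np.ndarray               # (k, 2) tip coordinates
    junction_endpoints: np.ndarray       # (2, 2): margin start / end points
    junction_midpoint: np.ndarray
    blade_length: float                  # junction midpoint -> farthest margin pt
    blade_area: float                    # shoelace area of the blade polygon
    blade_polygon: np.ndarray            # margin points (open, base -> base)
    spec: LeafletSpec | None = None

    def transformed(self, rot: np.ndarray, shift: np.ndarray) -> "GroundTruth":
        f = lambda p: p @ rot.T + shift
        return GroundTruth(
            tooth_count=self.tooth_count,
            tooth_tips=f(self.tooth_tips) if len(self.tooth_tips) else self.tooth_tips,
            junction_endpoints=f(self.junction_endpoints),
            junction_midpoint=f(self.junction_midpoint[None, :])[0],
            blade_length=self.blade_length,
            blade_area=self.blade_area,
            blade_polygon=f(self.blade_polygon),
            spec=self.spec,
        )


def _base_radius(spec: LeafletSpec, alpha: np.ndarray) -> np.ndarray:
    """(Super)ellipse radius with a recessed proximal notch.

    Real leaflet blades are rounded at the base with the petiolule seated
    in a concavity; the notch makes the junction a deep radial-profile
    minimum, the feature turning-point detection relies on.
    """
    a, b, n = spec.semi_major, spec.semi_minor, spec.superellipse_n
    alpha = np.asarray(alpha, dtype=float)
    r = (a * b) / (np.abs(b * np.cos(alpha)) ** n
                   + np.abs(a * np.sin(alpha)) ** n) ** (1.0 / n)
    r_pole = (a * b) / (np.abs(b * np.cos(np.pi)) ** n) ** (1.0 / n)
    depth = 1.0 - spec.notch_fraction * b / r_pole
    if depth > 0:
        delta = np.pi - np.abs(alpha)  # angular distance from the proximal pole
        r = r * (1.0 - depth * np.exp(-((delta / spec.notch_width) ** 2)))
    return r


def _tooth_profile(spec: LeafletSpec, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sawtooth bump profile over the distal arc; returns (dr, tip_alphas)."""
    dr = np.zeros_like(alpha)
    if spec.tooth_count == 0:
        return dr, np.empty(0)
    span = spec.toothed_arc * np.pi
    edges = np.linspace(-span, span, spec.tooth_count + 1)
    tip_alphas = []
    for k in range(spec.tooth_count):
        lo, hi = edges[k], edges[k + 1]
        tip = lo + (0.5 + spec.asymmetry) * (hi - lo)
        tip_alphas.append(tip)
        sel = (alpha >= lo) & (alpha <= hi)
        a = alpha[sel]
        up = a <= tip
        frac = np.where(up, (a - lo) / (tip - lo), (hi - a) / (hi - tip))
        dr[sel] = spec.tooth_height * frac
    return dr, np.asarray(tip_alphas)


def make_leaflet_contour(spec: LeafletSpec) -> tuple[Contour, GroundTruth]:
    """Generate one stalked leaflet contour with ground truth.

    The contour is closed and ordered: margin from one junction turning
    point around the distal pole to the other, then down and around the
    stalk.  In the local frame the blade axis points up (-y) and the stalk
    extends down (+y) from the proximal pole; deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    half_w = spec.stalk_width / 2.0
    if spec.margin_noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        raw = gaussian_filter1d(rng.normal(0.0, 1.0, spec.n_margin_points), 3.0)
        noise = raw * (spec.margin_noise_sd / raw.std()) if raw.std() > 0 else raw
    else:
        noise = np.zeros(spec.n_margin_points)

    def build(r_bottom: float):
        s = replace(spec, notch_fraction=r_bottom / spec.semi_minor)
        # smallest gap half-angle at which the margin endpoints sit
        # stalk_width apart (dense scan; the notch makes this non-monotone
        # enough that naive fixed-point iteration can cycle)
        gg = np.linspace(1e-3, 1.2, 2000)
        xg = _base_radius(s, np.pi - gg) * np.sin(gg)
        above = np.nonzero(xg >= half_w)[0]
        gap = float(gg[above[0]]) if len(above) else float(gg[-1])
        alpha = np.linspace(-(np.pi - gap), np.pi - gap, spec.n_margin_points)
        r = _base_radius(s, alpha)
        dr, tip_alphas = _tooth_profile(spec, alpha)
        r = r + dr + noise
        theta = -np.pi / 2.0 + alpha
        margin = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return margin, tip_alphas, alpha

    r_b = max(spec.notch_fraction * spec.semi_minor, half_w + 3.0)
    margin, tip_alphas, alpha = build(r_b)

    a_end, b_end = margin[0], margin[-1]
    y_bot = max(a_end[1], b_end[1]) + spec.stalk_length

    def seg(p, q, step=1.5):
        npts = max(int(np.hypot(*(q - p)) / step), 1)
        t = np.linspace(0.0, 1.0, npts + 1)[1:]
        return p[None, :] + t[:, None] * (q - p)[None, :]

    bb = np.array([b_end[0], y_bot])
    ab = np.array([a_end[0], y_bot])
    stalk = np.vstack([seg(b_end, bb), seg(bb, ab), seg(ab, a_end)[:-1]])
    pts = np.vstack([margin, stalk])
    contour = Contour(pts).oriented()

    if len(tip_alphas):
        tip_idx = np.argmin(np.abs(alpha[:, None] - tip_alphas[None, :]), axis=0)
        tips_xy = margin[tip_idx]
    else:
        tips_xy = np.empty((0, 2))
    midpoint = (a_end + b_end) / 2.0
    dmax = float(np.hypot(*(margin - midpoint).T).max())
    # blade polygon = margin closed by the junction chord
    x, y = margin[:, 0], margin[:, 1]
    area = abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    gt = GroundTruth(
        tooth_count=spec.tooth_count,
        tooth_tips=tips_xy,
        junction_endpoints=np.vstack([a_end, b_end]),
        junction_midpoint=midpoint,
        blade_length=dmax,
        blade_area=area,
        blade_polygon=margin,
        spec=spec,
    )
    return contour, gt


def make_leaflet_record(
    spec: LeafletSpec, role: str = "terminal", meta: dict | None = None
) -> tuple[LeafletRecord, GroundTruth]:
    """Blade-only record (stalk cut at the junction chord) plus ground truth."""
    _, gt = make_leaflet_contour(spec)
    record = build_record(gt.blade_polygon, role=role, meta=meta)
    return record, gt


def _rot(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s], [s, c]])


@dataclass
class LeafGroundTruth:
    """Ground truth for a rendered trifoliate leaf image."""

    leaflets: dict[str, GroundTruth]
    hairless_mask: np.ndarray
    leaflet_masks: dict[str, np.ndarray]
    node: np.ndarray


def render_leaf_image(
    specs: tuple[LeafletSpec, LeafletSpec, LeafletSpec] | None = None,
    trichome_density: float = 0.0,
    seed: int = 0,
    background: str = "dark",
    rachis_length: float = 70.0,
    petiole_length: float = 90.0,
    margin_px: int = 25,
) -> tuple[RasterImage, LeafGroundTruth]:
    """Rasterize a trifoliate leaf: terminal on the rachis, laterals beside.

    *specs* gives (terminal, left, right) leaflet specs; trichome_density
    is the expected number of hair strokes per 100 px of margin.  The
    canvas is sized to fit with *margin_px* padding; dpi is stamped 800.
    Raises if the laid-out blades overlap.
    """
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = (
            LeafletSpec(seed=seed * 3 + 1),
            replace(LeafletSpec(seed=seed * 3 + 2), semi_major=95.0, semi_minor=58.0),
            replace(LeafletSpec(seed=seed * 3 + 3), semi_major=95.0, semi_minor=58.0),
        )
    term_spec, left_spec, right_spec = specs

    placed: dict[str, tuple[np.ndarray, GroundTruth]] = {}
    node = np.zeros(2)

    def place(spec: LeafletSpec, angle_deg: float, extra: float) -> tuple[np.ndarray, GroundTruth]:
        contour, gt = make_leaflet_contour(spec)
        base = np.array([0.0, gt.junction_endpoints[:, 1].max() + spec.stalk_length])
        rot = _rot(angle_deg)
        # stalk bottom lands `extra` px from the node along the stalk axis
        shift = node - (base + np.array([0.0, extra])) @ rot.T
        return contour.points @ rot.T + shift, gt.transformed(rot, shift)

    # terminal points up; rachis continues below its stalk to the node
    pts_t, gt_t = place(term_spec, 0.0, rachis_length)
    # laterals point sideways: rotate the up-pointing blade by -/+ 90 deg;
    # their petiolules meet the petiole a little clear of the node
    pts_l, gt_l = place(left_spec, 90.0, 8.0)    # distal -> left on screen
    pts_r, gt_r = place(right_spec, -90.0, 8.0)  # distal -> right on screen
    placed = {"terminal": (pts_t, gt_t), "left_lateral": (pts_l, gt_l),
              "right_lateral": (pts_r, gt_r)}

    from shapely.geometry import Polygon

    polys = {k: Polygon(v[0]) for k, (v) in zip(placed, placed.values())}
    keys = list(polys)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            inter = polys[keys[i]].intersection(polys[keys[j]])
            if inter.area > 1.0:
                raise ValueError(
                    f"leaflets overlap in layout: {keys[i]} / {keys[j]}"
                )

    allpts = np.vstack([p for p, _ in placed.values()]
                       + [node[None, :] + [0.0, petiole_length]])
    lo = allpts.min(axis=0) - margin_px
    hi = allpts.max(axis=0) + margin_px
    shift = -lo
    W = int(np.ceil(hi[0] - lo[0]))
    H = int(np.ceil(hi[1] - lo[1]))

    bg = DARK_BG if background == "dark" else GRAY_BG
    img = np.tile(bg, (H, W, 1))
    hairless = np.zeros((H, W), dtype=bool)
    leaflet_masks: dict[str, np.ndarray] = {}

    def fill_poly(pts_xy: np.ndarray) -> np.ndarray:
        rr, cc = draw_polygon(pts_xy[:, 1] + shift[1], pts_xy[:, 0] + shift[0],
                              shape=(H, W))
        m = np.zeros((H, W), dtype=bool)
        m[rr, cc] = True
        return m

    for key, (pts, gt) in placed.items():
        m = fill_poly(pts)
        hairless |= m
        leaflet_masks[key] = fill_poly(gt.blade_polygon)

    def stroke(p: np.ndarray, q: np.ndarray, width: float) -> None:
        d = q - p
        nrm = np.hypot(*d)
        if nrm < 1e-9:
            return
        nvec = np.array([-d[1], d[0]]) / nrm * (width / 2.0)
        quad = np.array([p + nvec, q + nvec, q - nvec, p - nvec])
        hairless[fill_poly(quad)] = True

    stalk_w = term_spec.stalk_width
    rachis_top = node - np.array([0.0, rachis_length])
    stroke(node, rachis_top, stalk_w)
    stroke(node, node + np.array([0.0, petiole_length]), stalk_w)
    # short connectors bridging the lateral petiolules to the node
    stroke(node, node + np.array([-10.0, 0.0]), stalk_w)
    stroke(node, node + np.array([10.0, 0.0]), stalk_w)

    img[hairless] = LEAF_GREEN

    if trichome_density > 0:
        for key, (pts, gt) in placed.items():
            poly = gt.blade_polygon
            per = float(np.hypot(*np.diff(poly, axis=0).T).sum())
            n_hairs = rng.poisson(trichome_density * per / 100.0)
            center = poly.mean(axis=0)
            for _ in range(n_hairs):
                i = rng.integers(1, len(poly))
                p = poly[i]
                out = p - center
                out = out / np.hypot(*out)
                ang = rng.normal(0.0, 0.3)
                c, s = np.cos(ang), np.sin(ang)
                out = np.array([c * out[0] - s * out[1], s * out[0] + c * out[1]])
                length = rng.uniform(5.0, 14.0)
                p0 = p - out * 1.5  # root the hair just inside the blade
                p1 = p + out * length
                rr, cc = draw_line(int(p0[1] + shift[1]), int(p0[0] + shift[0]),
                                   int(p1[1] + shift[1]), int(p1[0] + shift[0]))
                ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
                rr, cc = rr[ok], cc[ok]
                keep = ~hairless[rr, cc]
                img[rr[keep], cc[keep]] = TRICHOME_GRAY
                if rng.random() < 0.5:  # some hairs 2 px wide
                    rr2 = np.clip(rr + 1, 0, H - 1)
                    keep2 = ~hairless[rr2, cc]
                    img[rr2[keep2], cc[keep2]] = TRICHOME_GRAY

    gts = {k: gt.transformed(np.eye(2), shift) for k, (_, gt) in placed.items()}
    masks = {k: leaflet_masks[k] for k in leaflet_masks}
    truth = LeafGroundTruth(
        leaflets=gts, hairless_mask=hairless, leaflet_masks=masks,
        node=node + shift,
    )
    return RasterImage(img, dpi=800.0), truth


# ---------------------------------------------------------------------------
# populations

@dataclass
class GroupSpec:
    label: str
    means: dict[str, float]
    cv: float = 0.05


@dataclass
class PopulationSpec:
    groups: list[GroupSpec]
    n_per_group: int = 32
    seed: int = 0


def _group(label, tooth, a, aspect, h, cv=0.05):
    # turning-point junction detection needs roundish blades (the species'
    # leaflets are obovate); aspect = semi_major / semi_minor <= 2
    return GroupSpec(
        label=label,
        means={
            "tooth_count": tooth,
            "semi_major": a,
            "semi_minor": a / aspect,
            "tooth_height": h,
        },
        cv=cv,
    )


def _preset_heteroblasty6(n: int = 32) -> PopulationSpec:
    """Developmental series L1..L6: tooth number falls 40 -> 10 nearly
    linearly, blade size peaks at L2-L3, length/width ratio declines
    (dropping below 1 by L6)."""
    rows = [
        ("L1", 40, 70, 2.00, 9.0),
        ("L2", 34, 95, 1.90, 8.2),
        ("L3", 28, 93, 1.80, 7.4),
        ("L4", 22, 82, 1.70, 6.6),
        ("L5", 16, 72, 1.55, 5.8),
        ("L6", 10, 62, 1.40, 5.0),
    ]
    return PopulationSpec(groups=[_group(*r) for r in rows], n_per_group=n)


def _preset_mutants5(n: int = 16) -> PopulationSpec:
    """Wild type plus five leaf-shape mutants with well separated blade and
    serration phenotypes (one mutant has an entirely smooth margin)."""
    rows = [
        ("wt", 24, 90, 1.80, 8.0),
        ("m1_smooth", 0, 75, 1.50, 0.1),
        ("m2_small_round", 12, 50, 1.25, 6.0),
        ("m3_narrow", 8, 85, 2.00, 7.0),
        ("m4_mid", 18, 70, 1.50, 8.0),
        ("m5_long", 34, 110, 2.00, 9.0),
    ]
    return PopulationSpec(groups=[_group(*r) for r in rows], n_per_group=n)


def _preset_ecotypes4(n: int = 22) -> PopulationSpec:
    rows = [
        ("A17", 22, 80, 1.90, 9.0),
        ("PI516927", 30, 96, 1.70, 8.0),
        ("PI516939", 20, 84, 2.00, 6.0),
        ("PI577609", 26, 92, 1.45, 7.5),
    ]
    return PopulationSpec(
        groups=[_group(*r, cv=0.06) for r in rows], n_per_group=n
    )


PRESETS = {
    "heteroblasty6": _preset_heteroblasty6,
    "mutants5": _preset_mutants5,
    "ecotypes4": _preset_ecotypes4,
}


def preset_population(name: str, n_per_group: int | None = None) -> PopulationSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    ps = PRESETS[name]() if n_per_group is None else PRESETS[name](n_per_group)
    return ps


@dataclass
class PopulationSample:
    labels: list[str]
    records: list[LeafletRecord]
    truth: pd.DataFrame


def make_population(pspec: PopulationSpec) -> PopulationSample:
    """Draw a labeled population of leaflet records around the group means.

    Size-like parameters are log-normal with the group's coefficient of
    variation; tooth counts are rounded draws from the same scheme.
    Deterministic for a given (pspec, seed).
    """
    ss = np.random.SeedSequence(pspec.seed)
    labels: list[str] = []
    records: list[LeafletRecord] = []
    rows = []
    children = ss.spawn(len(pspec.groups))
    for group, child in zip(pspec.groups, children):
        rng = np.random.default_rng(child)
        for i in range(pspec.n_per_group):
            draw = {}
            for key, mu in group.means.items():
                if mu <= 0:
                    draw[key] = 0.0
                    continue
                sigma = np.sqrt(np.log(1.0 + group.cv**2))
                val = float(np.exp(rng.normal(np.log(mu), sigma)))
                draw[key] = val
            tooth_count = int(round(draw.get("tooth_count", 0.0)))
            spec = LeafletSpec(
                semi_major=draw["semi_major"],
                semi_minor=draw["semi_minor"],
                tooth_count=tooth_count,
                tooth_height=max(draw.get("tooth_height", 0.0), 0.0) or 0.1,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if spec.tooth_count == 0:
                spec = replace(spec, tooth_height=0.1)
            rec, gt = make_leaflet_record(
                spec, meta={"group": group.label, "sample_index": i}
            )
            labels.append(group.label)
            records.append(rec)
            rows.append({
                "group": group.label,
                "sample_index": i,
                "true_tooth_count": gt.tooth_count,
                "true_blade_length": gt.blade_length,
                "true_blade_area": gt.blade_area,
                "true_semi_major": spec.semi_major,
                "true_semi_minor": spec.semi_minor,
            })
    return PopulationSample(labels=labels, records=records,
                            truth=pd.DataFrame(rows))
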