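"""Boundary tracing and leaflet separation.

The central idea: trace the closed pixel boundary of a leaf mask, express it
as a *centroid radial profile* (distance and angle from the shape centroid to
every boundary point, ordered along the contour), and read the geometry off
that profile.  Blade--petiole/rachis junctions appear as paired deep local
minima of the distance profile ("turning points") where the boundary doubles
back across a thin stalk; serration sinuses are far shallower and are
excluded by a depth threshold.  A trifoliate leaf is separated into its
terminal and two lateral leaflet blades by cutting straight across each
junction pair.

Contour points are (x, y) = (column, row) pixel coordinates.  Contours are
closed and oriented so the signed shoelace area is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, _remove_small

# Moore neighborhood in clockwise order, (row, col) offsets starting north
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class Contour:
    """Ordered closed boundary polygon, CCW (signed area > 0)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an N x 2 array")

    def __len__(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def perimeter(self) -> float:
        diff = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(diff[:, 0], diff[:, 1]).sum())

    def centroid(self) -> tuple[float, float]:
        """Area (interior) centroid via the polygon first moments."""
        p = self.points
        q = np.roll(p, -1, axis=0)
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return tuple(p.mean(axis=0))
        cx = float(np.sum((p[:, 0] + q[:, 0]) * cross) / (6.0 * a))
        cy = float(np.sum((p[:, 1] + q[:, 1]) * cross) / (6.0 * a))
        return cx, cy

    def oriented(self) -> "Contour":
        """Return a copy with positive signed area."""
        if self.signed_area() >= 0:
            return Contour(self.points.copy())
        return Contour(self.points[::-1].copy())

    def resample(self, n: int) -> "Contour":
        """Resample to *n* points equally spaced in arc length."""
        closed = np.vstack([self.points, self.points[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        total = t[-1]
        if total <= 0:
            raise ValueError("degenerate contour")
        ti = np.linspace(0.0, total, n, endpoint=False)
        x = np.interp(ti, t, closed[:, 0])
        y = np.interp(ti, t, closed[:, 1])
        return Contour(np.column_stack([x, y]))


@dataclass
class RadialProfile:
    """Distances and angles from the area centroid to each contour point."""

    centroid: tuple[float, float]
    distances: np.ndarray
    angles: np.ndarray
    contour: Contour

    def __len__(self) -> int:
        return len(self.distances)


@dataclass
class LeafletRecord:
    """One separated leaflet blade.

    The contour is arranged margin-first: index 0 and ``junction_endpoints[1]``
    are the two junction turning points, the margin runs between them, and the
    straight junction cut closes the polygon after that.
    """

    contour: Contour
    junction_endpoints: tuple[int, int]
    junction_midpoint: tuple[float, float]
    role: str = "terminal"
    meta: dict = field(default_factory=dict)

    @property
    def margin_indices(self) -> np.ndarray:
        """Contour indices belonging to the true leaf margin (not the cut)."""
        return np.arange(0, self.junction_endpoints[1] + 1)

    def blade_area(self) -> float:
        return self.contour.area()


def trace_contour(mask: BinaryMask, min_area: int = 9) -> Contour:
    """Moore-neighbor boundary following of a single-component mask.

    Returns the ordered closed CCW boundary-pixel chain.  Raises on empty
    or multi-component masks.
    """
    arr = np.asarray(mask.pixels, dtype=bool)
    if not arr.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(arr, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    big = [i + 1 for i, s in enumerate(sizes) if s >= min_area]
    if len(big) != 1:
        raise ValueError(f"mask must contain exactly one component, found {len(big)}")
    arr = labels == big[0]

    pad = np.pad(arr, 1)
    rows, cols = np.nonzero(pad)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    # Moore tracing with the "previously examined neighbor" backtrack rule;
    # termination when the (pixel, backtrack) tracer state repeats, which
    # closes the boundary cycle exactly once.
    cur = start
    backtrack = (start[0], start[1] - 1)  # west of the raster-first pixel
    boundary: list[tuple[int, int]] = [start]
    start_state = (cur, backtrack)
    max_steps = 8 * pad.size
    for _ in range(max_steps):
        bd = next(
            k
            for k, (dr, dc) in enumerate(_MOORE)
            if (cur[0] + dr, cur[1] + dc) == backtrack
        )
        nxt = None
        for k in range(1, 9):
            di = (bd + k) % 8
            nb = (cur[0] + _MOORE[di][0], cur[1] + _MOORE[di][1])
            if pad[nb]:
                prev = (cur[0] + _MOORE[(bd + k - 1) % 8][0],
                        cur[1] + _MOORE[(bd + k - 1) % 8][1])
                nxt = (nb, prev)
                break
        if nxt is None:  # isolated single pixel
            break
        cur, backtrack = nxt
        if (cur, backtrack) == start_state:
            break
        boundary.append(cur)
    else:
        raise ValueError("boundary tracing failed to terminate")
    pts = np.array([(c - 1, r - 1) for r, c in boundary], dtype=np.float64)
    return Contour(pts).oriented()


def radial_profile(contour: Contour) -> RadialProfile:
    """Centroid distances d_i and angles theta_i for every contour point."""
    cx, cy = contour.centroid()
    dx = contour.points[:, 0] - cx
    dy = contour.points[:, 1] - cy
    return RadialProfile(
        centroid=(cx, cy),
        distances=np.hypot(dx, dy),
        angles=np.arctan2(dy, dx),
        contour=contour,
    )


def _circular_smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    if window <= 1:
        return x.astype(np.float64)
    kernel = np.ones(window) / window
    padded = np.concatenate([x[-window:], x, x[:window]])
    return np.convolve(padded, kernel, mode="same")[window:-window]


def _low_runs(below: np.ndarray) -> list[np.ndarray]:
    """Circular runs of True indices."""
    n = len(below)
    if below.all():
        return [np.arange(n)]
    if not below.any():
        return []
    # rotate so position 0 is False, making runs non-wrapping
    offset = int(np.argmin(below))
    rolled = np.roll(below, -offset)
    runs = []
    idx = np.nonzero(rolled)[0]
    if len(idx):
        splits = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
        for s in splits:
            runs.append((s + offset) % n)
    return runs


def _junction_candidates(profile: RadialProfile, depth_fraction: float) -> list[int]:
    """Representative indices of deep distance-profile minima.

    Contiguous below-threshold runs are reduced to their interior local
    minima (at least the deepest point): a short stalk whose whole outline
    stays below the threshold holds both turning points in a single run,
    separated by the small rise at the stalk end, and must contribute both.
    """
    from scipy.signal import find_peaks

    ds = _circular_smooth(profile.distances, 5)
    thr = depth_fraction * float(np.median(ds))
    reps: list[int] = []
    for run in _low_runs(ds < thr):
        seg = ds[run]
        minima, _ = find_peaks(-seg, prominence=1.0)
        if len(minima) == 0:
            minima = [int(np.argmin(seg))]
        reps.extend(int(run[k]) for k in minima)
    return sorted(set(reps))


def find_junction(
    profile: RadialProfile,
    depth_fraction: float = 0.8,
    max_gap: float = 30.0,
    min_separation: int = 20,
    restrict: np.ndarray | None = None,
) -> tuple[int, int]:
    """Locate the two turning points bounding a blade--stalk junction.

    Candidates are local minima of the radial distance profile deeper than
    ``depth_fraction x median distance``.  A junction is a candidate pair
    whose two points nearly coincide in space -- and hence in both the
    distance and the angle profile, the paired "turning points" -- while
    lying far apart along the contour (the boundary doubles back across the
    stalk neck).  The spatially closest such pair is returned, ordered by
    contour index.  Raises ``ValueError`` when no junction exists: on a
    stalk-less ellipse the minor-axis minima are far apart in space and
    form no pair.

    *restrict*, when given, limits candidates to those contour indices
    (used by leaflet separation, which knows the stalk neighborhood).
    """
    reps = _junction_candidates(profile, depth_fraction)
    if restrict is not None:
        allowed = set(np.asarray(restrict, dtype=int).tolist())
        reps = [r for r in reps if r in allowed]
    if len(reps) < 2:
        raise ValueError("no junction found")
    pts = profile.contour.points
    n = len(profile)
    best = None
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            sep = abs(reps[j] - reps[i])
            sep = min(sep, n - sep)
            if sep < min_separation:
                continue
            gap = float(np.hypot(*(pts[reps[i]] - pts[reps[j]])))
            if gap > max_gap:
                continue
            if best is None or gap < best[0]:
                best = (gap, reps[i], reps[j])
    if best is None:
        raise ValueError("no junction found")
    return best[1], best[2]


def _arc_indices(n: int, i: int, j: int) -> np.ndarray:
    """Circular index range i..j inclusive (forward direction)."""
    if j >= i:
        return np.arange(i, j + 1)
    return np.concatenate([np.arange(i, n), np.arange(0, j + 1)])


def _cut_segment(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Interior points of a ~1 px discretized straight cut from p to q."""
    length = float(np.hypot(*(q - p)))
    n = max(int(round(length)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[1:-1]
    return p[None, :] + t[:, None] * (q - p)[None, :]


def build_record(
    margin: np.ndarray,
    role: str = "terminal",
    meta: dict | None = None,
) -> LeafletRecord:
    """Assemble a LeafletRecord from an open margin polyline.

    The margin runs from one junction turning point to the other; the
    junction cut closing the blade polygon is synthesized here.
    """
    margin = np.asarray(margin, dtype=np.float64)
    closing = _cut_segment(margin[-1], margin[0])
    pts = np.vstack([margin, closing]) if len(closing) else margin
    contour = Contour(pts)
    m = len(margin) - 1
    if contour.signed_area() < 0:
        # reverse the margin (junction endpoints swap but stay at 0 and m)
        margin = margin[::-1]
        closing = _cut_segment(margin[-1], margin[0])
        pts = np.vstack([margin, closing]) if len(closing) else margin
        contour = Contour(pts)
    midpoint = tuple((margin[0] + margin[-1]) / 2.0)
    return LeafletRecord(
        contour=contour,
        junction_endpoints=(0, m),
        junction_midpoint=midpoint,
        role=role,
        meta=meta or {},
    )


def separate_leaflets(
    leaf_mask: BinaryMask,
    depth_fraction: float = 0.8,
    stalk_width: float = 8.0,
    min_blade_area: int = 500,
    manual_junctions: Sequence[Sequence[Sequence[float]]] | None = None,
    meta: dict | None = None,
) -> list[LeafletRecord]:
    """Separate a trifoliate leaf mask into three leaflet blade records.

    Blade bodies are located by a morphological opening that erases the
    thin petiole/rachis network; every leaf pixel is then assigned to its
    nearest blade and junction turning points are detected on each blade's
    own radial profile (where the centroid sits inside the blade, the
    regime the turning-point rule is valid in).  Each blade is cut straight
    across its junction pair; the cut is applied twice in sequence by
    construction -- laterals part from the petiole, the terminal from the
    rachis.  Roles: the blade farthest from the petiole base is terminal;
    the other two are left/right lateral relative to the petiole->terminal
    axis as seen on the scan.

    ``manual_junctions`` (sidecar corrections) is an optional list of
    ``[[x1, y1], [x2, y2]]`` endpoint pairs overriding detection.
    """
    from skimage import morphology as _morph

    contour = trace_contour(leaf_mask)  # validates single connected leaf
    pts = contour.points
    n = len(contour)

    mask = leaf_mask.pixels
    radius = max(2, int(round(stalk_width / 2.0)) + 2)
    opened = _morph.opening(mask, _morph.disk(radius))
    opened = _remove_small(opened, min_blade_area)
    blob_labels, n_blobs = ndimage.label(opened, structure=np.ones((3, 3), int))

    margins: list[np.ndarray] = []
    if manual_junctions is not None:
        if len(manual_junctions) != 3:
            raise ValueError("manual corrections must supply 3 junction pairs")
        idx_pairs = []
        for (p1, p2) in manual_junctions:
            i = int(np.argmin(np.hypot(*(pts - np.asarray(p1, float)).T)))
            j = int(np.argmin(np.hypot(*(pts - np.asarray(p2, float)).T)))
            idx_pairs.append((i, j))
        all_idx = {k for pair in idx_pairs for k in pair}
        for i, j in idx_pairs:
            # the blade arc is the one free of the other junction points
            for a, b in ((i, j), (j, i)):
                arc = _arc_indices(n, a, b)
                if not (all_idx - {a, b}) & set(arc[1:-1].tolist()):
                    margins.append(pts[arc])
                    break
    else:
        if n_blobs != 3:
            raise ValueError(
                f"expected 3 separable leaflet blades, found {n_blobs}"
            )
        # assign every leaf pixel to the nearest blade body
        ind = ndimage.distance_transform_edt(
            blob_labels == 0, return_distances=False, return_indices=True
        )
        nearest = blob_labels[tuple(ind)]
        for lab in range(1, 4):
            sub = mask & (nearest == lab)
            sub_labels, k = ndimage.label(sub, structure=np.ones((3, 3), int))
            if k > 1:  # keep the blade, drop crumbs of the shared node
                sizes = ndimage.sum_labels(np.ones_like(sub_labels), sub_labels,
                                           index=range(1, k + 1))
                sub = sub_labels == (int(np.argmax(sizes)) + 1)
            sub_contour = trace_contour(BinaryMask(sub, dpi=leaf_mask.dpi))
            sub_profile = radial_profile(sub_contour)
            # the junction turning points lie where the contour meets the
            # stalk stub; the opening erased all thin structure (teeth as
            # well as the stalk), so keep only eroded components reaching
            # far from the blade body -- that is the stalk, not margin fringe
            blob_i = blob_labels == lab
            stub_all = sub & ~blob_i
            reach = ndimage.distance_transform_edt(~blob_i)
            stub_lab, ks = ndimage.label(stub_all, structure=np.ones((3, 3), int))
            stub = np.zeros_like(sub)
            for sl in range(1, ks + 1):
                comp = stub_lab == sl
                if reach[comp].max() > 2.0 * radius:
                    stub |= comp
            if not stub.any():
                stub = stub_all
            near_stub = ndimage.binary_dilation(stub, np.ones((9, 9), bool))
            sp = sub_contour.points.astype(int)
            on_stub = near_stub[sp[:, 1], sp[:, 0]]
            # pad along the contour: profile smoothing can shift a minimum
            # a few indices past the spatial stub neighborhood
            padded = np.convolve(on_stub.astype(int), np.ones(31), "same") > 0
            restrict = np.nonzero(padded)[0]
            try:
                i, j = find_junction(sub_profile, depth_fraction,
                                     restrict=restrict)
            except ValueError:
                # marginal junction depth on elongated blades: within the
                # stub neighborhood any paired minima are the junction
                i, j = find_junction(sub_profile, 1.0, restrict=restrict)
            m = len(sub_contour)
            # the blade margin is the arc that does not run along the stub
            arc_a = _arc_indices(m, i, j)
            arc_b = _arc_indices(m, j, i)
            arc = min((arc_a, arc_b), key=lambda a: on_stub[a].mean())
            margins.append(sub_contour.points[arc])

    if len(margins) != 3:
        raise ValueError(
            f"expected 3 separable leaflet blades, found {len(margins)}"
        )

    records = [
        build_record(marg, meta=dict(meta or {}, traced=True))
        for marg in margins
    ]

    # role assignment: the petiole tip is the far-reaching thin pixel
    # (stalk network, not margin fringe) farthest from the blades
    centroids = np.array([r.contour.centroid() for r in records])
    thin = mask & ~opened
    reach_all = ndimage.distance_transform_edt(~opened)
    thin_lab, kt = ndimage.label(thin, structure=np.ones((3, 3), int))
    stalk = np.zeros_like(thin)
    for sl in range(1, kt + 1):
        comp = thin_lab == sl
        if reach_all[comp].max() > 2.0 * radius:
            stalk |= comp
    if not stalk.any():
        stalk = thin
    ref = centroids.mean(axis=0)
    sr, sc = np.nonzero(stalk)
    if len(sr):
        far = np.argmax(np.hypot(sc - ref[0], sr - ref[1]))
        base = np.array([sc[far], sr[far]], dtype=float)
    else:
        base = pts[np.argmin(radial_profile(contour).distances)]
    dist_to_base = np.hypot(*(centroids - base).T)
    term = int(np.argmax(dist_to_base))
    axis = centroids[term] - base
    roles = {}
    roles[term] = "terminal"
    others = [k for k in range(3) if k != term]
    crosses = {}
    for k in others:
        w = centroids[k] - base
        crosses[k] = axis[0] * w[1] - axis[1] * w[0]
    # image coordinates have y pointing down: negative cross product means
    # the blade lies to the viewer's left of the base->terminal axis
    left = min(others, key=lambda k: crosses[k])
    right = max(others, key=lambda k: crosses[k])
    roles[left] = "left_lateral"
    roles[right] = "right_lateral"
    for k, r in roles.items():
        records[k].role = r
    order = {"terminal": 0, "left_lateral": 1, "right_lateral": 2}
    records.sort(key=lambda r: order[r.role])
    return records
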