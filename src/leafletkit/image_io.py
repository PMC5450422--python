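"""Loading and segmentation of scanned leaf images.

Leaves are scanned flat against a dark or gray background (nominally 800 dpi).
This module turns such scans into clean binary leaf masks: foreground
segmentation, trichome (leaf hair) removal in YCbCr chroma space, and
splitting of multi-leaf scans into per-leaf masks ordered the way the
operator arranged the leaves on the scanner bed (row-major).

Coordinate convention: (row, col) pixel indices, origin top-left, 0-based.
All geometry downstream is in pixel units; the physical conversion
``mm = px * 25.4 / dpi`` is applied only at export time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure, morphology

DEFAULT_DPI = 800.0
#: minimum connected-component area (px^2) kept by segmentation / splitting
MIN_COMPONENT_AREA = 500


@dataclass
class RasterImage:
    """An RGB scan with its physical resolution.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    dpi : float
        Dots per inch, used only for pixel -> mm conversion at export.
    """

    pixels: np.ndarray
    dpi: float = DEFAULT_DPI

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = np.stack([self.pixels] * 3, axis=-1)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Boolean leaf-tissue mask aligned with its source image."""

    pixels: np.ndarray
    dpi: float = DEFAULT_DPI

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def load_scan(path: str | Path, dpi_override: float | None = None) -> RasterImage:
    """Load a TIFF or PNG scan.

    The dpi is taken from the file's resolution metadata when present,
    else from *dpi_override*, else the 800 dpi acquisition default.
    Grayscale input is replicated to three channels.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            dpi = None
            info_dpi = im.info.get("dpi")
            if info_dpi:
                # Pillow reports (x_dpi, y_dpi); a zero means "unset"
                if float(info_dpi[0]) > 0:
                    dpi = float(info_dpi[0])
            arr = np.asarray(im.convert("RGB"))
    except IOError:
        raise
    except Exception as exc:  # corrupt / unsupported content
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if dpi is None:
        dpi = float(dpi_override) if dpi_override else DEFAULT_DPI
    return RasterImage(arr, dpi=dpi)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop connected components below *min_area* px (8-connectivity)."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.asarray(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=range(1, n + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s >= min_area]
    return np.isin(labels, keep)


def _luma(pixels: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma in [0, 255]."""
    rgb = pixels.astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _ycbcr(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BT.601 full-range YCbCr channels of an RGB array."""
    rgb = pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return y, cb, cr


def is_trichome_color(
    rgb: np.ndarray,
    cb_tol: float = 12.0,
    cr_tol: float = 12.0,
    min_luma: float = 120.0,
) -> np.ndarray:
    """Chroma rule for trichome pixels: near-neutral Cb/Cr with high luma.

    Trichomes are transparent, grayish-white hairs; blade tissue is a
    green/red mix whose Cb sits well below neutral.  Accepts a single RGB
    triple or an (..., 3) array; returns booleans of the leading shape.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    y, cb, cr = _ycbcr(arr)
    out = (np.abs(cb - 128.0) < cb_tol) & (np.abs(cr - 128.0) < cr_tol) & (y > min_luma)
    return bool(out[0]) if single else out


def segment_foreground(
    img: RasterImage,
    background: str = "dark",
    min_area: int = MIN_COMPONENT_AREA,
    green_threshold: float = 15.0,
) -> BinaryMask:
    """Separate leaf tissue from a dark or gray scanner background.

    ``background="dark"`` applies a parameter-free Otsu threshold on luma
    (leaves are bright on black); ``background="gray"`` uses green dominance
    ``G - max(R, B) > green_threshold`` since leaves and a neutral gray
    background can overlap in luma.  Holes are filled and specks below
    *min_area* removed.  Raises ``ValueError`` when no leaf is found.
    """
    if background == "dark":
        luma = _luma(img.pixels)
        # guard against a degenerate all-background scan before Otsu
        if luma.max() - luma.min() < 1.0:
            raise ValueError("no leaf found: image has no contrast")
        from skimage.filters import threshold_otsu

        fg = luma > threshold_otsu(luma)
    elif background == "gray":
        rgb = img.pixels.astype(np.float64)
        fg = rgb[..., 1] - np.maximum(rgb[..., 0], rgb[..., 2]) > green_threshold
    else:
        raise ValueError(f"unknown background model: {background!r}")

    fg = ndimage.binary_fill_holes(fg)
    fg = _remove_small(fg, min_area)
    if not fg.any():
        raise ValueError("no leaf found after segmentation")
    return BinaryMask(fg, dpi=img.dpi)


def remove_trichomes(
    img: RasterImage,
    mask: BinaryMask,
    max_trichome_width: int = 4,
    cb_tol: float = 12.0,
    cr_tol: float = 12.0,
    min_luma: float = 120.0,
) -> BinaryMask:
    """Strip trichome pixels (grayish hairs) from a leaf mask.

    Candidate pixels match the YCbCr chroma rule; of those, only structures
    thinner than *max_trichome_width* px are removed (a morphological opening
    by a disk of half that width protects pale but thick blade regions).
    A no-op when nothing matches.
    """
    if mask.shape != img.shape:
        raise ValueError("mask and image dimensions differ")
    candidate = is_trichome_color(img.pixels, cb_tol, cr_tol, min_luma) & mask.pixels
    if not candidate.any():
        return BinaryMask(mask.pixels.copy(), dpi=mask.dpi)
    radius = max(1, int(np.ceil(max_trichome_width / 2)))
    thick = morphology.opening(candidate, morphology.disk(radius))
    removed = candidate & ~thick
    cleaned = mask.pixels & ~removed
    cleaned = ndimage.binary_fill_holes(cleaned)
    cleaned = _remove_small(cleaned, MIN_COMPONENT_AREA)
    return BinaryMask(cleaned, dpi=mask.dpi)


def split_leaves(
    mask: BinaryMask,
    min_area: int = MIN_COMPONENT_AREA,
    row_band_factor: float = 0.6,
) -> list[BinaryMask]:
    """Split a multi-leaf scan into per-leaf masks in scan order.

    One mask per connected component above *min_area*, ordered row-major
    (top-to-bottom bands, then left-to-right within a band) so the physical
    L1..Ln arrangement on the scanner maps to list order.  Components whose
    vertical centroids differ by less than *row_band_factor* x the median
    component height share a band.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    if not props:
        return []
    heights = [p.bbox[2] - p.bbox[0] for p in props]
    band = row_band_factor * float(np.median(heights))
    props.sort(key=lambda p: p.centroid[0])
    rows: list[list] = [[props[0]]]
    for p in props[1:]:
        if p.centroid[0] - rows[-1][-1].centroid[0] <= band:
            rows[-1].append(p)
        else:
            rows.append([p])
    ordered: list[BinaryMask] = []
    for row in rows:
        row.sort(key=lambda p: p.centroid[1])
        for p in row:
            ordered.append(BinaryMask(labels == p.label, dpi=mask.dpi))
    return ordered
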