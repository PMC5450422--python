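"""Batch orchestration: scan images -> per-leaflet feature table -> reports.

``run_batch`` walks a directory of scans, runs segmentation, optional
trichome removal, leaf splitting and leaflet separation, measures every
leaflet (blade, serration and spectral parameters) and collects one row
per leaflet.  Failures are logged per image/leaf and skipped; a batch
never aborts on a single bad scan.  Manual corrections are read from
sidecar JSON files (``<image stem>.sidecar.json``) holding junction
endpoint and midvein control points per leaflet.

All geometry is measured in pixels; ``export_features`` converts length
and area columns to millimetres (25.4 / dpi per axis) when asked.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blade_metrics import blade_length, blade_length_curved, blade_shape_params, blade_width
from .efd import band_summary, efd_transform
from .image_io import load_scan, remove_trichomes, segment_foreground, split_leaves
from .segmentation import LeafletRecord, separate_leaflets
from .serration_metrics import (
    detect_serrations,
    serration_summary,
    tooth_geometry,
    valley_geometry,
)

log = logging.getLogger("leafletkit")

METADATA_COLUMNS = ["sample_id", "leaf_index", "leaflet_role", "group"]

#: stable export order of measured parameters
FEATURE_COLUMNS = [
    "blade_length", "blade_width", "blade_area", "blade_perimeter",
    "length_width_ratio", "leaflet_symmetry", "compactness",
    "inner_blade_area", "blade_inner_perimeter",
    "tooth_number", "total_tooth_area", "mean_tooth_area",
    "total_tooth_height", "mean_tooth_height",
    "total_tooth_perimeter", "mean_tooth_perimeter",
    "mean_tip_angle", "mean_left_angle", "mean_right_angle",
    "tooth_base_length", "outer_toothed_area", "inner_toothed_area",
    "length_of_outer_edge", "valley_number", "total_valley_area",
    "mean_valley_area", "mean_valley_depth", "tooth_valley_area_ratio",
    "inner_toothed_area_ratio", "tooth_number_blade_ratio",
    "relative_tooth_area",
    "delta_power", "alpha_power", "beta_power", "half_power_frequency",
]

LENGTH_COLUMNS = {
    "blade_length", "blade_width", "blade_perimeter", "blade_inner_perimeter",
    "total_tooth_height", "mean_tooth_height", "total_tooth_perimeter",
    "mean_tooth_perimeter", "tooth_base_length", "length_of_outer_edge",
    "mean_valley_depth",
}
AREA_COLUMNS = {
    "blade_area", "inner_blade_area", "total_tooth_area", "mean_tooth_area",
    "outer_toothed_area", "inner_toothed_area", "total_valley_area",
    "mean_valley_area",
}


@dataclass
class RunConfig:
    """Batch run settings (mirrors the ``leafletkit run`` YAML config)."""

    input_dir: str = "."
    output_dir: str = "out"
    background: str = "dark"
    dpi_default: float = 800.0
    remove_trichomes: bool = True
    exclude_leaf_indices: tuple = ()   # e.g. (0,) drops the juvenile leaf
    n_harmonics: int = 120
    min_prominence: float | None = None
    include_harmonics: bool = True
    units: str = "px"
    seed: int = 0
    image: dict = field(default_factory=dict)       # image_io overrides
    serration: dict = field(default_factory=dict)   # detection overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if not Path(cfg.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {cfg.input_dir}")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def measure_record(
    record: LeafletRecord,
    n_harmonics: int = 120,
    min_prominence: float | None = None,
    midvein_points: np.ndarray | None = None,
) -> dict:
    """All blade, serration and spectral parameters of one leaflet (px)."""
    L, _tip = blade_length(record)
    axis_curve = None
    if midvein_points is not None:
        L, axis_curve = blade_length_curved(record, midvein_points)
    W = blade_width(record, axis_curve=axis_curve)
    blade = blade_shape_params(record, L, W)
    tips, valleys, profile = detect_serrations(
        record, min_prominence=min_prominence
    )
    teeth = tooth_geometry(record.contour, tips, valleys)
    vall = valley_geometry(record.contour, tips, valleys)
    serr = serration_summary(record, teeth, vall, blade)

    row = {
        "blade_length": blade.length,
        "blade_width": blade.width,
        "blade_area": blade.area,
        "blade_perimeter": blade.perimeter,
        "length_width_ratio": blade.length_width_ratio,
        "leaflet_symmetry": blade.symmetry,
        "compactness": blade.compactness,
        "inner_blade_area": serr.inner_blade_area,
        "blade_inner_perimeter": serr.blade_inner_perimeter,
        "tooth_number": serr.tooth_number,
        "total_tooth_area": serr.total_tooth_area,
        "mean_tooth_area": serr.mean_tooth_area,
        "total_tooth_height": serr.total_tooth_height,
        "mean_tooth_height": serr.mean_tooth_height,
        "total_tooth_perimeter": serr.total_tooth_perimeter,
        "mean_tooth_perimeter": serr.mean_tooth_perimeter,
        "mean_tip_angle": serr.mean_tip_angle,
        "mean_left_angle": serr.mean_left_angle,
        "mean_right_angle": serr.mean_right_angle,
        "tooth_base_length": serr.tooth_base_length,
        "outer_toothed_area": serr.outer_toothed_area,
        "inner_toothed_area": serr.inner_toothed_area,
        "length_of_outer_edge": serr.length_of_outer_edge,
        "valley_number": serr.valley_number,
        "total_valley_area": serr.total_valley_area,
        "mean_valley_area": serr.mean_valley_area,
        "mean_valley_depth": serr.mean_valley_depth,
        "tooth_valley_area_ratio": serr.tooth_valley_area_ratio,
        "inner_toothed_area_ratio": serr.inner_toothed_area_ratio,
        "tooth_number_blade_ratio": serr.tooth_number_blade_ratio,
        "relative_tooth_area": serr.relative_tooth_area,
    }
    spectrum = efd_transform(record.contour, n_harmonics=n_harmonics)
    bands = band_summary(spectrum)
    row.update({
        "delta_power": bands.delta_power,
        "alpha_power": bands.alpha_power,
        "beta_power": bands.beta_power,
        "half_power_frequency": bands.half_power_frequency,
    })
    amp = spectrum.amplitude
    for f in range(len(amp)):
        row[f"A_{f + 1:03d}"] = float(amp[f])
    return row


def measure_population(records, labels=None, **kwargs) -> pd.DataFrame:
    """Measure a list of LeafletRecords into a feature table.

    *labels* (optional) provides the ``group`` column; record meta fields
    are carried into the metadata columns.
    """
    rows = []
    for i, rec in enumerate(records):
        row = {
            "sample_id": rec.meta.get("sample_id", i),
            "leaf_index": rec.meta.get("leaf_index", 0),
            "leaflet_role": rec.role,
            "group": labels[i] if labels is not None else rec.meta.get("group"),
        }
        row.update(measure_record(rec, **kwargs))
        rows.append(row)
    return pd.DataFrame(rows)


def _load_sidecar(image_path: Path) -> dict | None:
    sc = image_path.with_suffix(".sidecar.json")
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return None


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Process every scan in ``config.input_dir`` into a feature table.

    Per image: segment -> optional trichome removal -> split into leaves
    (scan order; configured indices such as the juvenile leaf excluded) ->
    separate leaflets -> measure.  Any failure is logged with its image
    and leaf index and skipped.
    """
    in_dir = Path(config.input_dir)
    paths = sorted(
        p for p in in_dir.iterdir()
        if p.suffix.lower() in {".tif", ".tiff", ".png"}
    )
    rows = []
    for path in paths:
        try:
            img = load_scan(path, dpi_override=config.dpi_default)
            mask = segment_foreground(img, config.background, **config.image)
            if config.remove_trichomes:
                mask = remove_trichomes(img, mask)
            leaves = split_leaves(mask)
        except Exception as exc:
            log.error("image %s failed: %s", path.name, exc)
            continue
        sidecar = _load_sidecar(path)
        for leaf_idx, leaf in enumerate(leaves):
            if leaf_idx in tuple(config.exclude_leaf_indices):
                continue
            try:
                manual, midveins = _sidecar_for(sidecar, leaf_idx)
                records = separate_leaflets(
                    leaf, manual_junctions=manual,
                    meta={"sample_id": path.stem, "leaf_index": leaf_idx},
                )
                for rec in records:
                    mv = midveins.get(rec.role) if midveins else None
                    row = {
                        "sample_id": path.stem,
                        "leaf_index": leaf_idx,
                        "leaflet_role": rec.role,
                        "group": f"L{leaf_idx + 1}",
                    }
                    row.update(measure_record(
                        rec, n_harmonics=config.n_harmonics,
                        min_prominence=config.min_prominence,
                        midvein_points=mv,
                        **config.serration,
                    ))
                    rows.append(row)
            except Exception as exc:
                log.error("leaf %d of %s failed: %s", leaf_idx, path.name, exc)
                continue
    table = pd.DataFrame(rows)
    return table


def _sidecar_for(sidecar: dict | None, leaf_idx: int):
    """Junction and midvein corrections for one leaf, if present."""
    if not sidecar:
        return None, {}
    corrections = [
        c for c in sidecar.get("corrections", [])
        if c.get("leaf_index", sidecar.get("leaf_index")) == leaf_idx
    ]
    if not corrections:
        return None, {}
    manual = []
    midveins = {}
    for c in corrections:
        if "junction_px" in c:
            manual.append(c["junction_px"])
        if "midvein_px" in c:
            midveins[c.get("leaflet_role", "terminal")] = np.asarray(
                c["midvein_px"], dtype=float
            )
    return (manual if len(manual) == 3 else None), midveins


def export_features(
    table: pd.DataFrame,
    path: str | Path,
    units: str = "px",
    dpi: float = 800.0,
    include_harmonics: bool = True,
    config_digest: str = "",
) -> Path:
    """Write the feature table as CSV (or .xlsx) with a stable column order.

    ``units="mm"`` converts length columns by 25.4/dpi and area columns by
    its square.  CSV output starts with a provenance comment line carrying
    the software version and the config digest.
    """
    if table.empty:
        raise ValueError("refusing to export an empty feature table")
    if units not in {"px", "mm"}:
        raise ValueError("units must be 'px' or 'mm'")
    out = table.copy()
    if units == "mm":
        scale = 25.4 / dpi
        for col in LENGTH_COLUMNS & set(out.columns):
            out[col] = out[col] * scale
        for col in AREA_COLUMNS & set(out.columns):
            out[col] = out[col] * scale**2
        out["tooth_number_blade_ratio"] = out.get("tooth_number_blade_ratio")
        if "tooth_number_blade_ratio" in out.columns:
            out["tooth_number_blade_ratio"] /= scale**2

    meta = [c for c in METADATA_COLUMNS if c in out.columns]
    harm = sorted(c for c in out.columns if c.startswith("A_"))
    feats = [c for c in FEATURE_COLUMNS if c in out.columns]
    rest = [c for c in out.columns if c not in set(meta + feats + harm)]
    cols = meta + feats + rest + (harm if include_harmonics else [])
    out = out[cols]

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".xlsx":
        out.to_excel(path, index=False)
    else:
        header = (
            f"# leafletkit {__version__} units={units} dpi={dpi:g} "
            f"config={config_digest or 'n/a'}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, index=False, float_format="%.10g",
                       lineterminator="\n")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`export_features`."""
    return pd.read_csv(path, comment="#")
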