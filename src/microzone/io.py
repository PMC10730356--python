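"""Readers, writers and the on-disk layout of a pipeline run.

Artifacts are plain, versioned formats: masks as TIFF (16-bit labels,
8-bit binary tumor masks), tables as CSV with typed headers, reports and
manifests as JSON, configuration as YAML.  Every run directory carries a
manifest recording the config hash, seeds and package version so results
can be tied back to their inputs.  Coordinates are pixel-grid, 0-based,
row-major ``(row, col)``; physical units are micrometers with the pixel
size recorded in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .features import FeatureMatrix, NeighborConfig
from .simulate import EffectSpec, PopulationSpec, SyntheticCohortConfig
from .zoning import ZoneConfig


class LoadError(ValueError):
    pass


REQUIRED_CELL_COLUMNS = (
    "cell_id",
    "roi_id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "area",
    "eccentricity",
)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary masks as 8-bit {0,255}; label masks as 16-bit."""
    path = Path(path)
    if mask.dtype == bool:
        tifffile.imwrite(path, mask.astype(np.uint8) * 255)
    else:
        tifffile.imwrite(path, mask.astype(np.uint16))


def read_tumor_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise LoadError(f"{path}: tumor mask is not binary (values {vals[:5]})")
    return arr > 0


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def read_roi_bundle(
    label_path: str | Path,
    tumor_path: str | Path,
    cells_path: str | Path,
    roi_id: str | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load and validate one ROI's label mask, tumor mask and cell table.

    Checks: mask shapes match; the tumor mask is binary; required table
    columns exist; every table cell id is present in the label mask.
    """
    tag = roi_id or Path(cells_path).stem
    label = read_label_mask(label_path)
    tumor = read_tumor_mask(tumor_path)
    if label.shape != tumor.shape:
        raise LoadError(
            f"ROI {tag}: label mask {label.shape} and tumor mask "
            f"{tumor.shape} shapes differ"
        )
    cells = pd.read_csv(cells_path)
    missing_cols = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing_cols:
        raise LoadError(f"ROI {tag}: missing cell-table columns {missing_cols}")
    present = np.unique(label)
    orphans = np.setdiff1d(cells["cell_id"].to_numpy(), present)
    if orphans.size:
        raise LoadError(
            f"ROI {tag}: cell ids absent from label mask: "
            f"{orphans[:10].tolist()}"
        )
    return label, tumor, cells


def write_feature_matrix(fm: FeatureMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fm.data.to_csv(directory / "features.csv")
    fm.col_info.to_csv(directory / "feature_columns.csv")
    fm.row_info.to_csv(directory / "feature_rows.csv")


def read_feature_matrix(directory: str | Path) -> FeatureMatrix:
    directory = Path(directory)
    data = pd.read_csv(directory / "features.csv", index_col=0)
    data.columns.name = "feature"
    col_info = pd.read_csv(directory / "feature_columns.csv", index_col=0)
    row_info = pd.read_csv(directory / "feature_rows.csv", index_col=0)
    return FeatureMatrix(data=data, col_info=col_info, row_info=row_info)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    blob = json.dumps(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config, seed: int, extra: dict | None = None):
    payload = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "version": __version__,
    }
    if extra:
        payload.update(_as_plain(extra))
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (see the CLI)."""

    output_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    zone: ZoneConfig = dataclasses.field(default_factory=ZoneConfig)
    neighbors: NeighborConfig = dataclasses.field(default_factory=NeighborConfig)
    cohort: SyntheticCohortConfig = dataclasses.field(
        default_factory=SyntheticCohortConfig
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("output_dir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "zone" in raw:
            kwargs["zone"] = ZoneConfig(**raw["zone"])
        if "neighbors" in raw:
            kwargs["neighbors"] = NeighborConfig(**raw["neighbors"])
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "populations" in c:
                c["populations"] = tuple(
                    PopulationSpec(**{**p, "zone_density": tuple(p["zone_density"])})
                    for p in c["populations"]
                )
            if "grade_effects" in c:
                c["grade_effects"] = tuple(
                    EffectSpec(**e) for e in c["grade_effects"]
                )
            if "zone_modulation" in c:
                c["zone_modulation"] = {
                    (m["population"], m["marker"]): dict(m["shifts"])
                    for m in c["zone_modulation"]
                }
            for tup in ("roi_shape", "tumor_fraction_range", "markers"):
                if tup in c:
                    c[tup] = tuple(c[tup])
            kwargs["cohort"] = SyntheticCohortConfig(**c)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        plain = _as_plain(self)
        # tuple-keyed zone modulation becomes a list of records so the
        # YAML round trip is lossless
        plain["cohort"]["zone_modulation"] = [
            {"population": pop, "marker": marker, "shifts": dict(shifts)}
            for (pop, marker), shifts in self.cohort.zone_modulation.items()
        ]
        Path(path).write_text(yaml.safe_dump(plain, sort_keys=False))


def write_cohort(bundles, metadata: pd.DataFrame, directory: str | Path) -> None:
    """Write a generated cohort: per-ROI TIFF masks + CSV cell tables,
    cohort metadata CSV, and a manifest tying ROIs to patients."""
    directory = Path(directory)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    (directory / "cells").mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_mask(directory / "masks" / f"{b.roi_id}_labels.tiff", b.label_mask)
        write_mask(directory / "masks" / f"{b.roi_id}_tumor.tiff", b.tumor_mask)
        b.cells.to_csv(directory / "cells" / f"{b.roi_id}.csv", index=False)
    metadata.to_csv(directory / "metadata.csv")
    manifest = {
        "rois": {
            b.roi_id: {"patient_id": b.patient_id, "cohort_id": b.cohort_id}
            for b in bundles
        }
    }
    (directory / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
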