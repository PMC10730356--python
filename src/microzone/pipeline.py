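"""End-to-end orchestration: simulate -> phenotype -> features ->
variability -> model, with on-disk intermediates and resume.

Each stage reads only the previous stage's artifacts, writes its own
under the run directory, and is skipped on rerun when its outputs
already exist (delete a stage directory to recompute it and everything
after it is still reusable).  Logs carry per-stage timings and seeds.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import features as feat
from . import io as mio
from . import model as mmod
from . import phenotype as phen
from . import simulate as sim
from . import variability as varb
from . import zoning

log = logging.getLogger("microzone")

STAGES = ("simulate", "phenotype", "features", "variability", "model")


def _stage_done(path: Path, *files: str) -> bool:
    return all((path / f).exists() for f in files)


def cohort_to_features(
    bundles,
    metadata: pd.DataFrame,
    neighbor_config: feat.NeighborConfig | None = None,
    pixel_size: float = 1.0,
) -> feat.FeatureMatrix:
    """In-memory shortcut: transform + QC + gate + extract all feature
    classes for a generated cohort, without touching disk."""
    cells = pd.concat([b.cells for b in bundles], ignore_index=True)
    raw_cols = [c for c in cells.columns if c.startswith("raw_")]
    for c in raw_cols:
        cells["asinh_" + c[4:]] = phen.arcsinh_transform(cells[c])
    cells, _ = phen.qc_filter(cells)
    cells = phen.gate_cell_types(cells)
    dens_frames = []
    for b in bundles:
        sub = cells[cells["roi_id"] == b.roi_id]
        dens = feat.zonal_density(sub, b.zone_map)
        dens["roi_id"] = b.roi_id
        dens_frames.append(dens)
    combos = feat.retained_combos(pd.concat(dens_frames, ignore_index=True))
    roi_features = {
        b.roi_id: feat.extract_roi_features(
            cells[cells["roi_id"] == b.roi_id],
            b.zone_map,
            combos,
            neighbor_config=neighbor_config,
            label_mask=b.label_mask,
            pixel_size=pixel_size,
        )
        for b in bundles
    }
    return feat.assemble_feature_matrix(roi_features, metadata, combos)


def run_pipeline(config: mio.RunConfig, stages=STAGES) -> dict:
    """Run the requested stages; returns a dict of stage output paths."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {s: out / s for s in STAGES}
    results: dict[str, Path] = {}

    for stage in stages:
        t0 = time.perf_counter()
        stage_dir = paths[stage]
        fn = globals()[f"_stage_{stage}"]
        skipped = fn(config, paths)
        dt = time.perf_counter() - t0
        log.info(
            "stage %-12s %s in %.1fs (seed %d)",
            stage,
            "skipped (resume)" if skipped else "completed",
            dt,
            config.seed,
        )
        results[stage] = stage_dir
    return results


def _stage_simulate(config: mio.RunConfig, paths) -> bool:
    d = paths["simulate"]
    if _stage_done(d, "metadata.csv"):
        return True
    cohort_cfg = sim.SyntheticCohortConfig(
        **{
            **{
                f.name: getattr(config.cohort, f.name)
                for f in config.cohort.__dataclass_fields__.values()
            },
            "seed": config.seed,
        }
    )
    bundles, meta = sim.generate_cohort(cohort_cfg)
    mio.write_cohort(bundles, meta, d)
    mio.write_manifest(d / "manifest.json", cohort_cfg, config.seed)
    return False


def _load_bundles(config: mio.RunConfig, paths):
    d = paths["simulate"]
    meta = pd.read_csv(d / "metadata.csv", index_col=0)
    bundles = []
    for roi_id in meta.index:
        label, tumor, cells = mio.read_roi_bundle(
            d / "masks" / f"{roi_id}_labels.tiff",
            d / "masks" / f"{roi_id}_tumor.tiff",
            d / "cells" / f"{roi_id}.csv",
            roi_id=roi_id,
        )
        zm = zoning.zone_areas(tumor, config.zone)
        bundles.append(
            sim.ROIBundle(
                roi_id=roi_id,
                patient_id=meta.loc[roi_id, "patient_id"],
                cohort_id=meta.loc[roi_id, "cohort_id"],
                grade=int(meta.loc[roi_id, "grade"]),
                tumor_mask=tumor,
                label_mask=label,
                zone_map=zm,
                cells=cells,
            )
        )
    return bundles, meta


def _stage_phenotype(config: mio.RunConfig, paths) -> bool:
    d = paths["phenotype"]
    if _stage_done(d, "cells.csv"):
        return True
    bundles, meta = _load_bundles(config, paths)
    cells = pd.concat([b.cells for b in bundles], ignore_index=True)
    raw_cols = [c for c in cells.columns if c.startswith("raw_")]
    for c in raw_cols:
        cells["asinh_" + c[4:]] = phen.arcsinh_transform(cells[c])
    cells, removed = phen.qc_filter(cells)
    cells = phen.gate_cell_types(cells)
    d.mkdir(parents=True, exist_ok=True)
    cells.to_csv(d / "cells.csv", index=False)
    (d / "qc_report.json").write_text(json.dumps(removed))
    mio.write_manifest(d / "manifest.json", config.zone, config.seed)
    return False


def _stage_features(config: mio.RunConfig, paths) -> bool:
    d = paths["features"]
    if _stage_done(d, "features.csv"):
        return True
    bundles, meta = _load_bundles(config, paths)
    cells = pd.read_csv(paths["phenotype"] / "cells.csv")
    dens_frames = []
    for b in bundles:
        sub = cells[cells["roi_id"] == b.roi_id]
        dens = feat.zonal_density(sub, b.zone_map)
        dens["roi_id"] = b.roi_id
        dens_frames.append(dens)
    combos = feat.retained_combos(pd.concat(dens_frames, ignore_index=True))
    roi_features = {}
    for b in bundles:
        sub = cells[cells["roi_id"] == b.roi_id]
        roi_features[b.roi_id] = feat.extract_roi_features(
            sub,
            b.zone_map,
            combos,
            neighbor_config=config.neighbors,
            label_mask=b.label_mask,
            pixel_size=config.zone.pixel_size,
        )
    fm = feat.assemble_feature_matrix(roi_features, meta, combos)
    mio.write_feature_matrix(fm, d)
    mio.write_manifest(
        d / "manifest.json", config.neighbors, config.seed,
        extra={"n_combos": len(combos)},
    )
    return False


def _stage_variability(config: mio.RunConfig, paths) -> bool:
    d = paths["variability"]
    if _stage_done(d, "cv_report.csv"):
        return True
    fm = mio.read_feature_matrix(paths["features"])
    dens_cols = fm.columns_of_class("density")
    patients = fm.row_info["patient_id"]
    intra = varb.intrapatient_cv(fm.data[dens_cols], patients)
    inter = varb.interpatient_cv(fm.data[dens_cols], patients, seed=config.seed)
    d.mkdir(parents=True, exist_ok=True)
    intra.to_csv(d / "cv_report.csv")
    inter.to_frame("interpatient_cv").to_csv(d / "interpatient_cv.csv")
    mio.write_manifest(d / "manifest.json", config, config.seed)
    return False


def _stage_model(config: mio.RunConfig, paths) -> bool:
    d = paths["model"]
    if _stage_done(d, "auc_report.json"):
        return True
    fm = mio.read_feature_matrix(paths["features"])
    result = mmod.monte_carlo_cv(
        fm, config=mmod.StabilityConfig(seed=config.seed)
    )
    d.mkdir(parents=True, exist_ok=True)
    result.frequencies.to_frame("frequency").to_csv(d / "selection_frequencies.csv")
    result.oof_scores.to_csv(d / "oof_scores.csv", index=False)
    result.fused_coef.to_frame("coef").to_csv(d / "fused_coefficients.csv")
    (d / "auc_report.json").write_text(json.dumps(result.auc_report, indent=2))
    (d / "fold_manifest.json").write_text(
        json.dumps(result.fold_diagnostics, indent=2)
    )
    mio.write_manifest(d / "manifest.json", result.config, config.seed)
    return False
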