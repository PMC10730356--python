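"""Shared fixtures: seeded synthetic cohorts at the study's geometry.

The two 72-ROI cohorts are expensive (a minute or two each), so they are
built once per session and reduced to the light objects the tests need
(cell summaries, feature matrices); pixel data is dropped.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from microzone.features import zonal_density
from microzone.phenotype import arcsinh_transform, gate_cell_types, qc_filter
from microzone.pipeline import cohort_to_features
from microzone.simulate import (
    SyntheticCohortConfig,
    default_grade_effects,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """4 patients x 2 ROIs: fast, for plumbing-level tests."""
    cfg = SyntheticCohortConfig(n_patients=4, rois_per_patient=2, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundles, meta = generate_cohort(cfg)
    return cfg, bundles, meta


def _typed_cells(bundles):
    cells = pd.concat([b.cells for b in bundles], ignore_index=True)
    for c in [c for c in cells.columns if c.startswith("raw_")]:
        cells["asinh_" + c[4:]] = arcsinh_transform(cells[c])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells, _ = qc_filter(cells)
    return gate_cell_types(cells)


@pytest.fixture(scope="session")
def decorr_cohort():
    """The decorrelation cohort: 72 ROIs, tumor fraction uniform in
    [0.1, 0.8] drawn per ROI, zone-piecewise-constant intensities, no
    planted effects.  Reduced to per-ROI population counts, zonal
    densities and tumor fractions."""
    cfg = SyntheticCohortConfig(
        n_patients=24,
        rois_per_patient=3,
        tumor_fraction_range=(0.1, 0.8),
        fraction_per_patient=False,
        seed=101,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundles, meta = generate_cohort(cfg)
    cells = _typed_cells(bundles)
    counts = (
        cells.groupby(["roi_id", "type_label"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(meta.index, fill_value=0)
    )
    dens_frames = []
    for b in bundles:
        d = zonal_density(cells[cells["roi_id"] == b.roi_id], b.zone_map)
        d["roi_id"] = b.roi_id
        dens_frames.append(d)
    densities = pd.concat(dens_frames, ignore_index=True)
    return {
        "meta": meta,
        "counts": counts,
        "densities": densities,
        "patients": meta["patient_id"],
    }


@pytest.fixture(scope="session")
def acceptance_features():
    """The default acceptance cohort: 24 patients x 3 ROIs with the
    ten-feature planted panel at d = 1.2, reduced to its feature
    matrix."""
    cfg = SyntheticCohortConfig(
        n_patients=24,
        rois_per_patient=3,
        grade_effects=default_grade_effects(1.2),
        seed=202,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundles, meta = generate_cohort(cfg)
        fm = cohort_to_features(bundles, meta)
    return fm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
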