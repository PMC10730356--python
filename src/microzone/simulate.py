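"""Seeded synthetic multiplexed-imaging cohorts.

Emulates the data structure that the zonal analysis assumes: rectangular
ROIs (default 500 x 1000 px at 1 um/px, i.e. 500,000 pixels), a smooth
binary tumor mask covering a variable fraction of each ROI, and a cell
label mask populated by 15 cell populations placed by an inhomogeneous
Poisson process whose intensity is piecewise-constant over the three
tissue zones (stroma / tumor front / tumor core).  Cells are ellipses
with population-specific area and eccentricity; marker intensities are
drawn log-normal on the raw scale so the arcsinh transform downstream is
meaningful.  Patients contribute ``rois_per_patient`` ROIs each and share
a multiplicative density factor plus (by default) a tumor-fraction
target, which induces intrapatient correlation; a Gaussian copula
additionally couples the Poisson draws of sibling ROIs.

Grade is assigned to patients in a balanced, alternating fashion, and
``EffectSpec`` entries plant standardized differences between the two
grade classes in any of the density, function, or metavariable (size /
eccentricity) per-ROI features, so recovery of known effects can be
tested end to end.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import draw as skdraw

from . import zoning
from .phenotype import (
    FUNCTIONAL_MARKERS,
    LINEAGE_MARKERS,
    POPULATIONS,
    arcsinh_transform,
)
from .zoning import ZONE_NAMES, ZoneConfig

FEATURE_CLASSES = ("density", "function", "metavariable", "neighborhood")


class GenerationError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """One cell population: expected density per zone (cells/mm^2 in
    stroma, front, core), mean cell area (um^2), mean eccentricity, and
    the log-scale location of each marker's raw intensity."""

    name: str
    zone_density: tuple[float, float, float]
    size_mean: float = 40.0
    eccentricity_mean: float = 0.6
    marker_means: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.zone_density):
            raise ConfigurationError("zone_density must be >= 0")
        if self.size_mean <= 0:
            raise ConfigurationError("size_mean must be > 0")
        if not 0 <= self.eccentricity_mean < 1:
            raise ConfigurationError("eccentricity_mean must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """A planted two-class difference: ``effect_size`` is the
    standardized mean shift (Cohen's d on the per-ROI feature) applied to
    the higher-grade class.  ``marker`` names the functional marker for
    function effects, or the metric (``size``/``eccentricity``) for
    metavariable effects."""

    feature_class: str
    zone: str
    population: str
    marker: str | None = None
    effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ConfigurationError(
                f"feature_class must be one of {FEATURE_CLASSES}"
            )
        if self.zone not in ZONE_NAMES:
            raise ConfigurationError(f"zone must be one of {ZONE_NAMES}")


# log-scale levels for lineage markers: clearly separated positive and
# negative modes so threshold gating has a noise-free limit
_HI, _LO = 2.0, -2.0


def _marker_means(
    positive_lineage: Sequence[str], functional: dict[str, float] | None = None
) -> dict[str, float]:
    means = {m: (_HI if m in positive_lineage else _LO) for m in LINEAGE_MARKERS}
    means.update({m: 0.2 for m in FUNCTIONAL_MARKERS})
    means["Ki67"] = -0.5
    means["GranzymeB"] = -0.5
    if functional:
        means.update(functional)
    return means


def default_populations() -> list[PopulationSpec]:
    """The study-default 15 populations.

    Densities (stroma, front, core) are calibrated qualitatively: tumor
    populations dominate front/core, immune and structural populations
    the stroma, CD8 T cells infiltrate consistently, and proliferating
    tumor cells concentrate at the front.  Totals give on the order of
    3,000 cells per 0.5 mm^2 ROI at a 40% tumor fraction.
    """
    P = PopulationSpec
    return [
        P("tumor_proliferating", (15, 1000, 700), 55, 0.55,
          _marker_means(["panCK"], {"Ki67": 2.0, "ECadherin": 1.5})),
        P("tumor_nonproliferating", (40, 2000, 3200), 60, 0.55,
          _marker_means(["panCK"], {"Ki67": -1.5, "ECadherin": 1.5})),
        P("cd4_regulatory", (80, 65, 8), 35, 0.6,
          _marker_means(["CD45", "CD3", "CD4", "FoxP3"])),
        P("cd4_naive", (200, 130, 15), 35, 0.6,
          _marker_means(["CD45", "CD3", "CD4", "CD45RA"])),
        P("cd4_memory", (580, 450, 40), 35, 0.6,
          _marker_means(["CD45", "CD3", "CD4"])),
        P("cd8_t", (650, 800, 400), 35, 0.6,
          _marker_means(["CD45", "CD3", "CD8"], {"GranzymeB": 1.0})),
        P("b_cell", (260, 150, 15), 32, 0.55,
          _marker_means(["CD45", "CD20"])),
        P("vessel", (520, 200, 25), 55, 0.75,
          _marker_means(["CD31"], {"VEGF": 1.0})),
        P("fibroblast", (900, 320, 20), 60, 0.85,
          _marker_means(["aSMA"])),
        P("m1_macrophage", (320, 290, 50), 45, 0.6,
          _marker_means(["CD45", "CD68"])),
        P("m2_macrophage", (160, 100, 20), 45, 0.6,
          _marker_means(["CD45", "CD68", "CD206", "CD163"])),
        P("monocyte", (230, 160, 20), 40, 0.6,
          _marker_means(["CD45", "CD14"])),
        P("granulocyte", (160, 120, 15), 35, 0.6,
          _marker_means(["CD45", "CD11b"], {"GranzymeB": 2.0})),
        P("dendritic", (130, 90, 12), 40, 0.6,
          _marker_means(["CD45", "CD11c"])),
        P("mdsc", (65, 35, 6), 40, 0.6,
          _marker_means(["CD45", "CD14", "CD11b"])),
    ]


#: mild zone-dependent functional modulation (additive log-scale shift),
#: emulating higher inflammatory signaling near the tumor border
DEFAULT_ZONE_MODULATION: dict[tuple[str, str], dict[str, float]] = {
    ("m1_macrophage", "pSTAT1"): {"front": 0.8},
    ("monocyte", "pSTAT1"): {"front": 0.6},
    ("cd8_t", "pNFkB"): {"front": 0.6, "core": 0.6},
    ("granulocyte", "GranzymeB"): {"stroma": 0.4},
    ("granulocyte", "Ki67"): {"stroma": 0.4},
}


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    """All generator knobs; identical config + seed gives bit-identical
    cohorts.

    ``intrapatient_corr`` in [0, 1] splits a fixed log-scale noise budget
    (``sigma_total``) between a patient-shared density factor and
    ROI-level jitter, and sets the Gaussian-copula coupling of sibling
    ROIs' Poisson draws; at 1, a patient's ROIs have identical expected
    and sampled counts (up to mask-realization area differences).
    """

    n_patients: int = 24
    rois_per_patient: int = 3
    roi_shape: tuple[int, int] = (500, 1000)
    tumor_fraction_range: tuple[float, float] = (0.1, 0.7)
    populations: tuple[PopulationSpec, ...] = dataclasses.field(
        default_factory=lambda: tuple(default_populations())
    )
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS
    grade_effects: tuple[EffectSpec, ...] = ()
    intrapatient_corr: float = 0.5
    seed: int = 0
    cohort_id: str = "synthetic"
    sigma_total: float = 0.35
    max_zone_occupancy: float = 0.45
    marker_sdlog: float = 0.4
    size_sdlog: float = 0.22
    fraction_per_patient: bool = True
    zone_modulation: dict[tuple[str, str], dict[str, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ZONE_MODULATION)
    )
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.tumor_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("tumor_fraction_range must be within [0, 1]")
        if self.rois_per_patient < 1:
            raise ConfigurationError("rois_per_patient must be >= 1")
        if not 0 <= self.intrapatient_corr <= 1:
            raise ConfigurationError("intrapatient_corr must be in [0, 1]")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]


@dataclasses.dataclass
class ROIBundle:
    """One generated ROI: masks, zonal partition and the cell table."""

    roi_id: str
    patient_id: str
    cohort_id: str
    grade: int
    tumor_mask: np.ndarray
    label_mask: np.ndarray
    zone_map: zoning.ZoneMap
    cells: pd.DataFrame


def generate_tumor_mask(
    roi_shape: tuple[int, int], target_fraction: float, seed: int
) -> np.ndarray:
    """Smooth random tumor blobs covering ``target_fraction`` of the ROI.

    A white-noise field is Gaussian-smoothed and thresholded at the
    quantile matching the target, which produces organic borders with
    convex and concave stretches and hits the requested covered fraction
    to within one pixel's worth of ties.  Fractions 0 and 1 are exact.
    """
    if not 0 <= target_fraction <= 1:
        raise ValueError("target_fraction must be in [0, 1]")
    if target_fraction == 0:
        return np.zeros(roi_shape, dtype=bool)
    if target_fraction == 1:
        return np.ones(roi_shape, dtype=bool)
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(
        rng.standard_normal(roi_shape), sigma=50.0, mode="reflect"
    )
    thresh = np.quantile(field, 1 - target_fraction)
    return field > thresh


def _ellipse_axes(area: float, ecc: float) -> tuple[float, float]:
    """Half-axes (major, minor) of an ellipse with given area and
    eccentricity."""
    q = np.sqrt(max(1 - ecc**2, 1e-6))  # minor/major ratio
    a = np.sqrt(area / (np.pi * q))
    return a, a * q


def _render_roi(
    shape: tuple[int, int],
    zone_image: np.ndarray,
    placements: list[tuple[str, int, float, float]],
    rng: np.random.Generator,
    roi_id: str,
    max_retries: int = 100,
    max_shrinks: int = 4,
) -> tuple[np.ndarray, list[dict]]:
    """Rasterize non-overlapping ellipses into a label mask.

    ``placements``: (population, zone_code, area_um2, eccentricity) per
    cell.  Centers are drawn uniformly from the pixels of the requested
    zone; overlaps are resolved by re-drawing the center (up to
    ``max_retries`` times), then shrinking the ellipse by 20% and
    retrying, up to ``max_shrinks`` shrink rounds.
    """
    label_mask = np.zeros(shape, dtype=np.uint16)
    zone_pixels = {
        code: np.flatnonzero(zone_image.ravel() == code)
        for code in range(len(ZONE_NAMES))
    }
    records: list[dict] = []
    # big cells first: packs better, keeps retries rare
    order = sorted(range(len(placements)), key=lambda i: -placements[i][2])
    cell_id = 0
    for idx in order:
        pop, zcode, area, ecc = placements[idx]
        pool = zone_pixels[zcode]
        if pool.size == 0:
            raise GenerationError(
                f"ROI {roi_id}: zone {ZONE_NAMES[zcode]} has no pixels"
            )
        placed = False
        cur_area = max(area, 12.0)
        theta = rng.uniform(0, np.pi)
        for shrink_round in range(max_shrinks + 1):
            a, b = _ellipse_axes(cur_area, ecc)
            for _ in range(max_retries):
                flat = int(pool[rng.integers(pool.size)])
                r0, c0 = divmod(flat, shape[1])
                rr, cc = skdraw.ellipse(
                    r0, c0, a, b, shape=shape, rotation=theta
                )
                if rr.size == 0:
                    continue
                if (label_mask[rr, cc] == 0).all():
                    cell_id += 1
                    label_mask[rr, cc] = cell_id
                    records.append(
                        {
                            "cell_id": cell_id,
                            "true_type": pop,
                            "gen_zone": ZONE_NAMES[zcode],
                        }
                    )
                    placed = True
                    break
            if placed:
                break
            cur_area *= 0.8**2
        if not placed:
            raise GenerationError(
                f"ROI {roi_id}: could not place a {pop} cell after "
                f"{max_shrinks} shrink rounds"
            )
    return label_mask, records


def _fast_geometry(label_mask: np.ndarray) -> pd.DataFrame:
    """Vectorized per-cell centroid/area/eccentricity.

    Same definitions as ``phenotype.region_geometry`` (second-moment
    ellipse eccentricity) but computed with bincount arithmetic instead
    of per-region props; the equality is covered by a test.
    """
    rr, cc = np.nonzero(label_mask)
    labels = label_mask[rr, cc].astype(np.int64)
    nmax = int(labels.max()) + 1
    area = np.bincount(labels, minlength=nmax)
    sr = np.bincount(labels, weights=rr, minlength=nmax)
    sc = np.bincount(labels, weights=cc, minlength=nmax)
    ids = np.flatnonzero(area)
    a = area[ids].astype(float)
    cr, cm = sr[ids] / a, sc[ids] / a
    dr = rr - cr[np.searchsorted(ids, labels)]
    dc = cc - cm[np.searchsorted(ids, labels)]
    mu20 = np.bincount(labels, weights=dr * dr, minlength=nmax)[ids] / a
    mu02 = np.bincount(labels, weights=dc * dc, minlength=nmax)[ids] / a
    mu11 = np.bincount(labels, weights=dr * dc, minlength=nmax)[ids] / a
    # eigenvalues of the second-central-moment matrix, closed form
    half = (mu20 + mu02) / 2
    root = np.sqrt(((mu20 - mu02) / 2) ** 2 + mu11**2)
    l1, l2 = half + root, np.maximum(half - root, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ecc = np.sqrt(np.clip(1 - l2 / np.where(l1 > 0, l1, 1), 0, 1))
    ecc[l1 <= 0] = 0.0
    return pd.DataFrame(
        {
            "cell_id": ids,
            "centroid_row": cr,
            "centroid_col": cm,
            "area_px": area[ids].astype(int),
            "area": a,
            "eccentricity": ecc,
        }
    )


def _per_roi_means(
    cells: pd.DataFrame, column: str, pop: str, zone: str, zone_col: str = "zone"
) -> pd.Series:
    sub = cells[(cells["true_type"] == pop) & (cells[zone_col] == zone)]
    return sub.groupby("roi_id")[column].mean()


def plant_effects(
    cells: pd.DataFrame,
    effects: Sequence[EffectSpec],
    grade: pd.Series | None = None,
    seed: int | None = None,
    zone_col: str = "zone",
) -> pd.DataFrame:
    """Apply planted grade effects to a generated cohort cell table.

    Function effects shift the arcsinh-scale marker value of
    higher-grade cells of the named population/zone by
    ``effect_size x SD``, where SD is the standard deviation across ROIs
    of the per-ROI mean (computed on the table before the shift); raw
    values are kept consistent through the inverse transform.
    Metavariable effects shift cell size (``area``) or eccentricity the
    same way.  Density effects thin the *lower*-grade class binomially to
    open a ``effect_size x SD`` gap (note: thinning removes table rows
    without re-rendering label masks; inside ``generate_cohort`` density
    effects are instead applied to the point-process intensity before
    placement).  Effects with size 0 and empty effect lists return the
    input unchanged.
    """
    out = cells.copy()
    if not effects:
        return out
    if grade is None:
        grade = out["grade"]
    grade = np.asarray(grade)
    rng = np.random.default_rng(seed)
    known_pops = set(out["true_type"].unique())
    for eff in effects:
        if eff.effect_size == 0:
            continue
        if eff.population not in known_pops:
            raise ConfigurationError(f"unknown population {eff.population!r}")
        in_combo = (
            (out["true_type"] == eff.population) & (out[zone_col] == eff.zone)
        ).to_numpy()
        hi = in_combo & (grade == 1)
        if eff.feature_class == "function":
            col = "raw_" + (eff.marker or "")
            if col not in out.columns:
                raise ConfigurationError(f"unknown marker {eff.marker!r}")
            roi_means = _per_roi_means(
                out.assign(**{"t": arcsinh_transform(out[col])}),
                "t", eff.population, eff.zone, zone_col,
            )
            sd = roi_means.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"no spread to scale effect {eff}; skipped")
                continue
            shifted = arcsinh_transform(out.loc[hi, col]) + eff.effect_size * sd
            out.loc[hi, col] = np.sinh(shifted)
        elif eff.feature_class == "metavariable":
            col = {"size": "area", "eccentricity": "eccentricity"}.get(
                eff.marker or ""
            )
            if col is None:
                raise ConfigurationError(
                    "metavariable effects support 'size' and 'eccentricity'"
                )
            roi_means = _per_roi_means(out, col, eff.population, eff.zone, zone_col)
            sd = roi_means.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"no spread to scale effect {eff}; skipped")
                continue
            out.loc[hi, col] = out.loc[hi, col] + eff.effect_size * sd
            if col == "eccentricity":
                out.loc[hi, col] = out.loc[hi, col].clip(0, 0.99)
        elif eff.feature_class == "density":
            # thin the lower-grade class so the higher class sits
            # effect_size SDs above it (counts stand in for densities;
            # zone areas are not carried on the cell table)
            dens = out[in_combo].groupby("roi_id").size()
            sd, mu = dens.std(ddof=1), dens.mean()
            if not np.isfinite(sd) or sd == 0 or mu == 0:
                warnings.warn(f"no spread to scale effect {eff}; skipped")
                continue
            keep_p = float(np.clip(1 - eff.effect_size * sd / mu, 0, 1))
            lo = in_combo & (grade == 0)
            drop = lo & (rng.random(len(out)) > keep_p)
            out = out.loc[~drop]
        else:
            raise ConfigurationError(
                "neighborhood effects cannot be planted at the cell-table "
                "level; encode them through zone densities instead"
            )
    return out.reset_index(drop=True)


def _density_effect_factors(
    effects: Sequence[EffectSpec],
    lam: np.ndarray,
    areas: np.ndarray,
    grades: np.ndarray,
    pop_index: dict[str, int],
) -> np.ndarray:
    """Multiplicative intensity factors implementing density effects.

    ``lam``/``areas``: (n_roi, n_pop, n_zone) expected counts and zone
    areas.  For each density effect the factor f on the higher-grade
    class solves shift = d * pooled-SD(f) of the per-ROI density, using
    the exact decomposition Var(D) = Var(lam/A) + E[lam/A^2] of a Poisson
    mixture, iterated to a fixed point.
    """
    factors = np.ones_like(lam)
    for eff in effects:
        if eff.feature_class != "density" or eff.effect_size == 0:
            continue
        if eff.population not in pop_index:
            raise ConfigurationError(f"unknown population {eff.population!r}")
        p = pop_index[eff.population]
        z = ZONE_NAMES.index(eff.zone)
        lam_pz, a_pz = lam[:, p, z], areas[:, p, z]
        ok = a_pz > 0
        rate = lam_pz[ok] / a_pz[ok]
        mu = rate.mean()
        var_mult = rate.var(ddof=1)
        var_pois = (lam_pz[ok] / a_pz[ok] ** 2).mean()
        if mu == 0:
            warnings.warn(f"zero mean density for {eff}; skipped")
            continue
        s1 = np.sqrt(var_mult + var_pois)
        f = 1.0
        for _ in range(25):
            s2 = np.sqrt(f**2 * var_mult + f * var_pois)
            s_pool = np.sqrt((s1**2 + s2**2) / 2)
            f_new = max(1 + eff.effect_size * s_pool / mu, 0.0)
            if abs(f_new - f) < 1e-10:
                f = f_new
                break
            f = f_new
        factors[grades == 1, p, z] *= f
    return factors


def default_grade_effects(effect_size: float = 1.2) -> tuple[EffectSpec, ...]:
    """The standard planted-effect panel: ten grade-associated features
    spread over density, function and metavariable classes and all three
    zones, mirroring the mix of immune, tumor and structural differences
    such studies report."""
    E = EffectSpec
    return (
        E("density", "stroma", "cd8_t", None, effect_size),
        E("density", "front", "m1_macrophage", None, effect_size),
        E("density", "core", "tumor_nonproliferating", None, effect_size),
        E("density", "stroma", "cd4_memory", None, -effect_size),
        E("function", "front", "m1_macrophage", "pSTAT1", effect_size),
        E("function", "front", "granulocyte", "pMAPKAPK2", -effect_size),
        E("function", "core", "tumor_nonproliferating", "pS6", effect_size),
        E("function", "front", "cd8_t", "pNFkB", effect_size),
        E("metavariable", "stroma", "cd4_memory", "size", -effect_size),
        E("metavariable", "front", "vessel", "eccentricity", effect_size),
    )


def effect_feature_name(effect: EffectSpec) -> str:
    """Feature-matrix column targeted by a planted effect."""
    if effect.feature_class == "density":
        return f"density:{effect.zone}:{effect.population}"
    return (
        f"{effect.feature_class}:{effect.zone}:{effect.population}:{effect.marker}"
    )


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[ROIBundle], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns the list of per-ROI bundles and a cohort metadata table (one
    row per ROI: roi_id, patient_id, cohort_id, grade, outcomes, target
    and realized tumor fraction, seeds).  Deterministic given the config
    (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    zone_cfg = ZoneConfig()
    n_pat, n_roi = config.n_patients, config.rois_per_patient
    pops = config.populations
    pop_index = {p.name: i for i, p in enumerate(pops)}
    c = config.intrapatient_corr
    sigma_p = config.sigma_total * np.sqrt(c)
    sigma_j = config.sigma_total * np.sqrt(1 - c)

    patients = [f"{config.cohort_id}_P{i:03d}" for i in range(n_pat)]
    grades = np.array([i % 2 for i in range(n_pat)])
    pat_factor = np.exp(sigma_p * rng.standard_normal(n_pat) - sigma_p**2 / 2)
    recurrence = (rng.random(n_pat) < 0.35).astype(int)
    mortality = (rng.random(n_pat) < 0.30).astype(int)

    lo, hi = config.tumor_fraction_range
    if config.fraction_per_patient:
        frac_target = np.repeat(rng.uniform(lo, hi, n_pat), n_roi)
    else:
        frac_target = rng.uniform(lo, hi, n_pat * n_roi)

    # --- masks, zones, intensities -------------------------------------
    mask_seeds = rng.integers(2**31, size=n_pat * n_roi)
    tumor_masks, zone_maps = [], []
    for r in range(n_pat * n_roi):
        tm = generate_tumor_mask(
            config.roi_shape, float(frac_target[r]), int(mask_seeds[r])
        )
        tumor_masks.append(tm)
        zone_maps.append(zoning.zone_areas(tm, zone_cfg))

    n_total = n_pat * n_roi
    n_pop, n_zone = len(pops), len(ZONE_NAMES)
    areas = np.zeros((n_total, n_pop, n_zone))
    for r, zm in enumerate(zone_maps):
        for z, zn in enumerate(ZONE_NAMES):
            areas[r, :, z] = zm.zone_areas[zn]
    base_density = np.array([p.zone_density for p in pops])  # (pop, zone)
    jitter = np.exp(
        sigma_j * rng.standard_normal((n_total, n_pop, n_zone)) - sigma_j**2 / 2
    )
    roi_pat = np.repeat(np.arange(n_pat), n_roi)
    lam = (
        base_density[None, :, :]
        * pat_factor[roi_pat][:, None, None]
        * jitter
        * areas
    )
    roi_grade = grades[roi_pat]
    lam = lam * _density_effect_factors(
        config.grade_effects, lam, areas, roi_grade, pop_index
    )

    # packing guard: non-overlapping ellipse placement jams well below
    # full coverage, so rescale the rare intensity draws whose expected
    # pixel occupancy would exceed the cap (affects ~1% of zone draws at
    # default densities; realized counts stay unbiased otherwise)
    size_mu = np.array([p.size_mean for p in pops])
    zone_px = areas[:, 0, :] * 1e6  # (roi, zone), same for every pop
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = (lam * size_mu[None, :, None]).sum(axis=1) / zone_px
    over = occ > config.max_zone_occupancy
    if over.any():
        warnings.warn(
            f"occupancy cap rescaled {int(over.sum())} zone draws"
        )
        scale = np.where(over, config.max_zone_occupancy / occ, 1.0)
        lam = lam * scale[:, None, :]

    # --- correlated Poisson counts (Gaussian copula within patients) ----
    z_pat = rng.standard_normal((n_pat, n_pop, n_zone))
    z_roi = rng.standard_normal((n_total, n_pop, n_zone))
    u = stats.norm.cdf(
        np.sqrt(c) * z_pat[roi_pat] + np.sqrt(1 - c) * z_roi
    )
    counts = stats.poisson.ppf(np.clip(u, 1e-12, 1 - 1e-12), lam).astype(int)

    # --- per-cell sizes/eccentricities, with metavariable effects -------
    ecc_mu = np.array([p.eccentricity_mean for p in pops])
    cell_attrs: list[list[tuple[str, int, float, float]]] = []
    attr_frames = []
    for r in range(n_total):
        rows = []
        for p in range(n_pop):
            for z in range(n_zone):
                n = counts[r, p, z]
                if n == 0:
                    continue
                sizes = size_mu[p] * np.exp(
                    config.size_sdlog * rng.standard_normal(n)
                    - config.size_sdlog**2 / 2
                )
                eccs = np.clip(
                    ecc_mu[p] + 0.12 * rng.standard_normal(n), 0.0, 0.95
                )
                for s, e in zip(sizes, eccs):
                    rows.append((pops[p].name, z, float(s), float(e)))
        cell_attrs.append(rows)
        attr_frames.append(
            pd.DataFrame(rows, columns=["pop", "zcode", "size", "ecc"]).assign(
                roi=r
            )
        )
    meta_effects = [
        e for e in config.grade_effects if e.feature_class == "metavariable"
    ]
    if meta_effects:
        allattr = pd.concat(attr_frames, ignore_index=True)
        allattr["grade"] = roi_grade[allattr["roi"]]
        for eff in meta_effects:
            if eff.population not in pop_index:
                raise ConfigurationError(f"unknown population {eff.population!r}")
            col = {"size": "size", "eccentricity": "ecc"}.get(eff.marker or "")
            if col is None:
                raise ConfigurationError(
                    "metavariable effects support 'size' and 'eccentricity'"
                )
            zc = ZONE_NAMES.index(eff.zone)
            sel = (allattr["pop"] == eff.population) & (allattr["zcode"] == zc)
            roi_means = allattr[sel].groupby("roi")[col].mean()
            sd = roi_means.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"no spread to scale effect {eff}; skipped")
                continue
            shift = eff.effect_size * sd
            hi_rows = sel & (allattr["grade"] == 1)
            allattr.loc[hi_rows, col] += shift
            if col == "ecc":
                allattr.loc[hi_rows, col] = allattr.loc[hi_rows, col].clip(0, 0.95)
            if col == "size":
                allattr.loc[hi_rows, col] = allattr.loc[hi_rows, col].clip(lower=12)
        cell_attrs = [
            [
                (row.pop, int(row.zcode), float(row.size), float(row.ecc))
                for row in allattr[allattr["roi"] == r].itertuples()
            ]
            for r in range(n_total)
        ]

    # --- render label masks, measure geometry, assign zones -------------
    bundles: list[ROIBundle] = []
    meta_rows = []
    all_cells = []
    for r in range(n_total):
        pat = roi_pat[r]
        roi_id = f"{config.cohort_id}_P{pat:03d}_R{r % n_roi}"
        label_mask, records = _render_roi(
            config.roi_shape, zone_maps[r].zone_image, cell_attrs[r], rng, roi_id
        )
        geo = _fast_geometry(label_mask)
        tab = pd.DataFrame(records).merge(geo, on="cell_id")
        sdm = zoning.signed_border_distance(tumor_masks[r], zone_cfg)
        tab["border_distance"] = zoning.cell_border_distance(
            label_mask, sdm, tab["cell_id"].to_numpy()
        )
        tab["zone"] = zoning.assign_zones(tab["border_distance"], zone_cfg)
        tab.insert(0, "roi_id", roi_id)
        tab.insert(1, "patient_id", patients[pat])
        tab.insert(2, "cohort_id", config.cohort_id)
        tab.insert(3, "grade", int(grades[pat]))
        all_cells.append(tab)
        bundles.append(
            ROIBundle(
                roi_id=roi_id,
                patient_id=patients[pat],
                cohort_id=config.cohort_id,
                grade=int(grades[pat]),
                tumor_mask=tumor_masks[r],
                label_mask=label_mask,
                zone_map=zone_maps[r],
                cells=tab,  # markers attached below
            )
        )
        meta_rows.append(
            {
                "roi_id": roi_id,
                "patient_id": patients[pat],
                "cohort_id": config.cohort_id,
                "grade": int(grades[pat]),
                "recurrence": int(recurrence[pat]),
                "mortality": int(mortality[pat]),
                "target_tumor_fraction": float(frac_target[r]),
                "tumor_fraction": zone_maps[r].area_tumor / zone_maps[r].area_roi,
                "mask_seed": int(mask_seeds[r]),
            }
        )

    cells = pd.concat(all_cells, ignore_index=True)

    # --- markers ---------------------------------------------------------
    sdlog = config.marker_sdlog
    all_markers = list(LINEAGE_MARKERS) + [
        m for m in config.markers if m not in LINEAGE_MARKERS
    ]
    mu_table = np.zeros((n_pop, len(all_markers)))
    for p, spec in enumerate(pops):
        for m, marker in enumerate(all_markers):
            mu_table[p, m] = spec.marker_means.get(marker, _LO)
    pop_of_cell = cells["true_type"].map(pop_index).to_numpy()
    mu = mu_table[pop_of_cell]  # (n_cells, n_markers)
    # modulation keyed to the computed (distance-derived) zone: signaling
    # depends on where the cell actually sits relative to the border
    for (pop, marker), shifts in config.zone_modulation.items():
        if pop not in pop_index or marker not in all_markers:
            continue
        mcol = all_markers.index(marker)
        for zone, delta in shifts.items():
            sel = (cells["true_type"] == pop) & (cells["zone"] == zone)
            mu[sel.to_numpy(), mcol] += delta
    raw = np.exp(mu + sdlog * rng.standard_normal(mu.shape))
    if config.label_noise > 0:
        scramble = rng.random(len(cells)) < config.label_noise
        n_lin = len(LINEAGE_MARKERS)
        raw[scramble, :n_lin] = np.exp(
            _LO + sdlog * rng.standard_normal((scramble.sum(), n_lin))
        )
    for m, marker in enumerate(all_markers):
        cells["raw_" + marker] = raw[:, m]
    cells["dna1"] = np.exp(1.5 + 0.2 * rng.standard_normal(len(cells)))
    cells["dna2"] = np.exp(1.5 + 0.2 * rng.standard_normal(len(cells)))

    # --- planted function effects (density/meta already applied) --------
    func_effects = [
        e for e in config.grade_effects if e.feature_class == "function"
    ]
    if func_effects:
        cells = plant_effects(
            cells,
            func_effects,
            grade=cells["grade"],
            seed=int(rng.integers(2**31)),
        )

    for b in bundles:
        b.cells = cells[cells["roi_id"] == b.roi_id].reset_index(drop=True)
    metadata = pd.DataFrame(meta_rows).set_index("roi_id")
    return bundles, metadata
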