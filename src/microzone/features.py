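"""Zone-resolved feature engineering: the four per-ROI feature classes.

Each ROI (sample) yields features in four classes:

* ``density`` — zonal cell densities, cells/mm^2, for every
  (population, zone) pair;
* ``function`` — mean arcsinh-transformed expression of each functional
  marker per (population, zone);
* ``metavariable`` — mean cell size and eccentricity per
  (population, zone), plus mean signed tumor-border distance per
  population, emitted for the tumor-front zone only (border distance in
  other zones is dominated by the tumor-to-stroma area ratio of the ROI
  rather than by cell behavior);
* ``neighborhood`` — mean neighborhood coefficients: for each center
  cell the proportions of its up-to-k nearest neighbors (within a border
  distance cutoff) belonging to each cell type, averaged over center
  cells of a population within a zone.

Populations whose median zonal density across the cohort is zero are
excluded from the function, metavariable and neighborhood classes for
that zone (their values would reflect cell scarcity, not biology); the
density class itself always spans the full population x zone grid.

Feature names follow ``class:zone:population[:marker|:partner|:metric]``
and are stable across runs, so selection results are joinable.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phenotype import FUNCTIONAL_MARKERS, POPULATIONS, UNCLASSIFIED
from .zoning import ZONE_NAMES, ZoneMap


@dataclasses.dataclass(frozen=True)
class NeighborConfig:
    """Neighborhood definition: up to ``k`` nearest cells within
    ``max_dist`` um; distances border-to-border by default (minimum
    pairwise distance between the two cells' boundary-pixel sets), with a
    faster centroid mode available."""

    k: int = 5
    max_dist: float = 20.0
    distance_mode: str = "border"  # or "centroid"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_dist <= 0:
            raise ValueError("max_dist must be > 0")
        if self.distance_mode not in ("border", "centroid"):
            raise ValueError("distance_mode must be 'border' or 'centroid'")


def tumor_covered_fraction(zone_map: ZoneMap) -> float:
    """Fraction of the ROI covered by tumor, in [0, 1]."""
    if zone_map.area_roi == 0:
        raise ValueError("empty ROI")
    return zone_map.area_tumor / zone_map.area_roi


def zonal_density(
    cells: pd.DataFrame,
    zone_map: ZoneMap,
    populations: Sequence[str] = POPULATIONS,
) -> pd.DataFrame:
    """Cells/mm^2 of each population in each zone of one ROI.

    Zones with zero area yield missing values (NaN), never zeros; zones
    with positive area but no cells yield 0.
    """
    counts = (
        cells.groupby(["type_label", "zone"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    rows = []
    for pop in populations:
        for zone in ZONE_NAMES:
            area = zone_map.zone_areas[zone]
            n = int(counts.loc[pop, zone]) if (
                pop in counts.index and zone in counts.columns
            ) else 0
            rows.append(
                {
                    "population": pop,
                    "zone": zone,
                    "count": n,
                    "density": n / area if area > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def retained_combos(
    densities: pd.DataFrame, populations: Sequence[str] = POPULATIONS
) -> set[tuple[str, str]]:
    """(population, zone) pairs with median zonal density > 0 over ROIs.

    ``densities`` is the long-format concatenation of per-ROI
    ``zonal_density`` outputs (columns roi_id/population/zone/density).
    The exclusion applies only to the function, metavariable and
    neighborhood classes downstream; the density class is untouched.
    """
    med = densities.groupby(["population", "zone"], observed=True)["density"].median()
    out = set()
    for pop, zone in itertools.product(populations, ZONE_NAMES):
        if (pop, zone) in med.index and med.loc[(pop, zone)] > 0:
            out.add((pop, zone))
    return out


def functional_features(
    cells: pd.DataFrame,
    combos: set[tuple[str, str]],
    markers: Sequence[str] = FUNCTIONAL_MARKERS,
    prefix: str = "asinh_",
) -> dict[str, float]:
    """Mean transformed marker expression per retained (marker,
    population, zone) for one ROI; missing (NaN) when the ROI has no such
    cells."""
    grouped = cells.groupby(["type_label", "zone"], observed=True)
    means = grouped[[prefix + m for m in markers]].mean()
    out = {}
    for pop, zone in sorted(combos):
        for m in markers:
            key = f"function:{zone}:{pop}:{m}"
            if (pop, zone) in means.index:
                out[key] = float(means.loc[(pop, zone), prefix + m])
            else:
                out[key] = np.nan
    return out


def spatial_metavariables(
    cells: pd.DataFrame, combos: set[tuple[str, str]]
) -> dict[str, float]:
    """Mean cell size (um^2) and eccentricity per retained (population,
    zone), plus mean signed border distance per population for the front
    zone only."""
    grouped = cells.groupby(["type_label", "zone"], observed=True)
    means = grouped[["area", "eccentricity", "border_distance"]].mean()
    out = {}
    for pop, zone in sorted(combos):
        have = (pop, zone) in means.index
        for metric in ("size", "eccentricity"):
            col = "area" if metric == "size" else metric
            out[f"metavariable:{zone}:{pop}:{metric}"] = (
                float(means.loc[(pop, zone), col]) if have else np.nan
            )
        if zone == "front":
            out[f"metavariable:front:{pop}:distance"] = (
                float(means.loc[(pop, zone), "border_distance"]) if have else np.nan
            )
    return out


def _boundary_pixel_sets(label_mask: np.ndarray) -> dict[int, np.ndarray]:
    """Coordinates (row, col) of each cell's boundary pixels."""
    label_mask = np.asarray(label_mask)
    padded = np.pad(label_mask, 1, mode="constant", constant_values=-1)
    same = (
        (padded[:-2, 1:-1] == label_mask)
        & (padded[2:, 1:-1] == label_mask)
        & (padded[1:-1, :-2] == label_mask)
        & (padded[1:-1, 2:] == label_mask)
    )
    boundary = (label_mask > 0) & ~same
    rr, cc = np.nonzero(boundary)
    labels = label_mask[rr, cc]
    order = np.argsort(labels, kind="stable")
    rr, cc, labels = rr[order], cc[order], labels[order]
    coords = np.column_stack([rr, cc]).astype(float)
    sets: dict[int, np.ndarray] = {}
    uniq, starts = np.unique(labels, return_index=True)
    starts = list(starts) + [len(labels)]
    for i, lab in enumerate(uniq):
        sets[int(lab)] = coords[starts[i] : starts[i + 1]]
    return sets


def neighbor_distances(
    cells: pd.DataFrame,
    config: NeighborConfig,
    label_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> dict[int, list[tuple[float, int]]]:
    """Per cell, the (distance, neighbor cell_id) pairs within
    ``max_dist``, truncated to the ``k`` nearest (ties broken by distance
    then by cell id).

    Border mode measures the minimum Euclidean distance between boundary
    pixel sets (requires ``label_mask``); candidate pairs are pruned with
    a centroid KD-tree before exact evaluation.
    """
    ids = cells["cell_id"].to_numpy()
    cent = cells[["centroid_row", "centroid_col"]].to_numpy()
    n = len(ids)
    result: dict[int, list[tuple[float, int]]] = {int(i): [] for i in ids}
    if n < 2:
        return result
    tree = cKDTree(cent)

    if config.distance_mode == "centroid":
        pairs = tree.query_pairs(config.max_dist, output_type="ndarray")
        dists = np.linalg.norm(cent[pairs[:, 0]] - cent[pairs[:, 1]], axis=1)
        for (i, j), d in zip(pairs, dists):
            result[int(ids[i])].append((float(d), int(ids[j])))
            result[int(ids[j])].append((float(d), int(ids[i])))
    else:
        if label_mask is None:
            raise ValueError("border mode requires the cell label mask")
        bounds = _boundary_pixel_sets(label_mask)
        missing = set(ids.tolist()) - set(bounds)
        if missing:
            raise ValueError(f"cells absent from label mask: {sorted(missing)[:5]}")
        # radius of each cell: max centroid-to-boundary distance
        radius = np.empty(n)
        for idx, cid in enumerate(ids):
            b = bounds[int(cid)] * pixel_size
            radius[idx] = np.max(np.linalg.norm(b - cent[idx], axis=1))
        rmax = radius.max()
        pairs = tree.query_pairs(config.max_dist + 2 * rmax, output_type="ndarray")
        if len(pairs):
            cd = np.linalg.norm(cent[pairs[:, 0]] - cent[pairs[:, 1]], axis=1)
            keep = cd <= config.max_dist + radius[pairs[:, 0]] + radius[pairs[:, 1]]
            pairs = pairs[keep]
        for i, j in pairs:
            bi = bounds[int(ids[i])] * pixel_size
            bj = bounds[int(ids[j])] * pixel_size
            # min pairwise distance between the two boundary pixel sets
            d = np.sqrt(
                np.min(
                    ((bi[:, None, :] - bj[None, :, :]) ** 2).sum(-1)
                )
            )
            if d <= config.max_dist:
                result[int(ids[i])].append((float(d), int(ids[j])))
                result[int(ids[j])].append((float(d), int(ids[i])))

    for cid, lst in result.items():
        lst.sort()
        del lst[config.k :]
    return result


def neighborhood_coefficients(
    cells: pd.DataFrame,
    config: NeighborConfig | None = None,
    label_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
    neighbor_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean neighborhood coefficients per (zone, center population,
    neighbor type) for one ROI.

    Each center cell's coefficient vector holds the proportion of its
    neighbors of each type (a probability vector when the cell has at
    least one neighbor); cells with zero neighbors are excluded from the
    mean.  The zone of a coefficient is the zone of the *center* cell.
    """
    config = config or NeighborConfig()
    if neighbor_types is None:
        neighbor_types = list(POPULATIONS) + [UNCLASSIFIED]
    nb = neighbor_distances(cells, config, label_mask, pixel_size)
    type_of = dict(zip(cells["cell_id"], cells["type_label"]))
    zone_of = dict(zip(cells["cell_id"], cells["zone"]))
    t_index = {t: i for i, t in enumerate(neighbor_types)}

    sums: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    for cid, lst in nb.items():
        if not lst:
            continue
        vec = np.zeros(len(neighbor_types))
        for _, nid in lst:
            t = type_of[nid]
            if t in t_index:
                vec[t_index[t]] += 1
        vec /= len(lst)
        key = (type_of[cid], zone_of[cid])
        if key not in sums:
            sums[key] = np.zeros(len(neighbor_types))
            counts[key] = 0
        sums[key] += vec
        counts[key] += 1

    rows = []
    for (pop, zone), total in sums.items():
        mean = total / counts[(pop, zone)]
        for t, v in zip(neighbor_types, mean):
            rows.append(
                {
                    "population": pop,
                    "zone": zone,
                    "neighbor": t,
                    "coefficient": v,
                    "n_centers": counts[(pop, zone)],
                }
            )
    return pd.DataFrame(
        rows, columns=["population", "zone", "neighbor", "coefficient", "n_centers"]
    )


@dataclasses.dataclass
class FeatureMatrix:
    """ROIs x features with class/zone/population column annotations and
    patient/cohort/grade row annotations."""

    data: pd.DataFrame  # index roi_id, columns feature names
    col_info: pd.DataFrame  # index feature name: feature_class, zone, population
    row_info: pd.DataFrame  # index roi_id: patient_id, cohort_id, grade, ...

    def columns_of_class(self, feature_class: str) -> list[str]:
        return list(
            self.col_info.index[self.col_info["feature_class"] == feature_class]
        )

    @property
    def feature_classes(self) -> np.ndarray:
        return self.col_info["feature_class"].to_numpy()


def feature_schema(
    combos: set[tuple[str, str]],
    populations: Sequence[str] = POPULATIONS,
    markers: Sequence[str] = FUNCTIONAL_MARKERS,
    neighbor_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Deterministic column schema for a retained-combo set.

    Density spans the full population x zone grid regardless of
    retention; the other classes span retained combos only.
    """
    if neighbor_types is None:
        neighbor_types = list(populations) + [UNCLASSIFIED]
    rows = []
    for pop in populations:
        for zone in ZONE_NAMES:
            rows.append((f"density:{zone}:{pop}", "density", zone, pop))
    for pop, zone in sorted(combos):
        for m in markers:
            rows.append((f"function:{zone}:{pop}:{m}", "function", zone, pop))
    for pop, zone in sorted(combos):
        for metric in ("size", "eccentricity"):
            rows.append(
                (f"metavariable:{zone}:{pop}:{metric}", "metavariable", zone, pop)
            )
        if zone == "front":
            rows.append(
                (f"metavariable:front:{pop}:distance", "metavariable", zone, pop)
            )
    for pop, zone in sorted(combos):
        for t in neighbor_types:
            rows.append(
                (f"neighborhood:{zone}:{pop}:{t}", "neighborhood", zone, pop)
            )
    schema = pd.DataFrame(
        rows, columns=["feature", "feature_class", "zone", "population"]
    ).set_index("feature")
    if schema.index.duplicated().any():
        raise ValueError("duplicate feature names in schema")
    return schema


def extract_roi_features(
    cells: pd.DataFrame,
    zone_map: ZoneMap,
    combos: set[tuple[str, str]],
    neighbor_config: NeighborConfig | None = None,
    label_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
    populations: Sequence[str] = POPULATIONS,
    markers: Sequence[str] = FUNCTIONAL_MARKERS,
) -> dict[str, float]:
    """All four feature classes for one ROI, as a flat name->value dict."""
    out: dict[str, float] = {}
    dens = zonal_density(cells, zone_map, populations)
    for _, r in dens.iterrows():
        out[f"density:{r['zone']}:{r['population']}"] = r["density"]
    out.update(functional_features(cells, combos, markers))
    out.update(spatial_metavariables(cells, combos))
    coeffs = neighborhood_coefficients(
        cells, neighbor_config, label_mask, pixel_size
    )
    schema_nb = {
        (pop, zone): True for pop, zone in combos
    }
    nb_lookup = {
        (r["population"], r["zone"], r["neighbor"]): r["coefficient"]
        for _, r in coeffs.iterrows()
    }
    neighbor_types = list(populations) + [UNCLASSIFIED]
    for pop, zone in sorted(schema_nb):
        for t in neighbor_types:
            out[f"neighborhood:{zone}:{pop}:{t}"] = nb_lookup.get(
                (pop, zone, t), np.nan
            )
    return out


def assemble_feature_matrix(
    roi_features: dict[str, dict[str, float]],
    row_info: pd.DataFrame,
    combos: set[tuple[str, str]],
    populations: Sequence[str] = POPULATIONS,
    markers: Sequence[str] = FUNCTIONAL_MARKERS,
) -> FeatureMatrix:
    """Stack per-ROI feature dicts into the model-ready matrix.

    ``roi_features`` maps roi_id to the dict from ``extract_roi_features``;
    ``row_info`` is indexed by roi_id with patient/cohort/grade columns.
    Column order is fixed by the schema; duplicate names raise.
    """
    schema = feature_schema(combos, populations, markers)
    index = list(row_info.index)
    data = pd.DataFrame(
        [
            {c: roi_features.get(rid, {}).get(c, np.nan) for c in schema.index}
            for rid in index
        ],
        index=pd.Index(index, name="roi_id"),
        columns=schema.index,
    )
    return FeatureMatrix(data=data, col_info=schema, row_info=row_info.copy())
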