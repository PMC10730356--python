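"""Intensity transformation, object-level QC and rule-based cell typing.

Raw per-cell mean channel intensities from segmented multiplexed images
are arcsinh-transformed (cofactor 1) to compress the heavy right tail of
mass-cytometry counts.  Objects are then filtered on size and DNA signal,
and assigned to one of 15 cell populations by an ordered set of marker
threshold gates.  Externally computed labels (e.g. from a graph-based
clustering run outside this package) can be ingested instead through
``attach_external_labels``; the built-in gate is the deterministic
default.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from skimage import measure

UNCLASSIFIED = "unclassified"

#: the 15 study populations, in canonical order
POPULATIONS = (
    "tumor_proliferating",
    "tumor_nonproliferating",
    "cd4_regulatory",
    "cd4_naive",
    "cd4_memory",
    "cd8_t",
    "b_cell",
    "vessel",
    "fibroblast",
    "m1_macrophage",
    "m2_macrophage",
    "monocyte",
    "granulocyte",
    "dendritic",
    "mdsc",
)

#: the 14 functional markers whose zonal means form the function class
FUNCTIONAL_MARKERS = (
    "pp38",
    "pSTAT1",
    "pSTAT3",
    "pCREB",
    "pNFkB",
    "pERK12",
    "pMAPKAPK2",
    "pS6",
    "VEGF",
    "GranzymeB",
    "Ki67",
    "ECadherin",
    "CD36",
    "CD44",
)

#: lineage markers used only for gating
LINEAGE_MARKERS = (
    "panCK",
    "CD45",
    "CD3",
    "CD4",
    "CD8",
    "FoxP3",
    "CD45RA",
    "CD20",
    "CD31",
    "aSMA",
    "CD68",
    "CD206",
    "CD163",
    "CD14",
    "CD11b",
    "CD11c",
)


def arcsinh_transform(x, cofactor: float = 1.0):
    """Arcsinh-transform raw intensities: ``asinh(x / cofactor)``.

    Strictly monotone; behaves like x/cofactor near zero and like
    ``ln(2x/cofactor)`` for large x.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def qc_filter(
    cells: pd.DataFrame,
    min_area_px: int = 10,
    dna_sd: float = 2.0,
    area_column: str = "area_px",
    group_column: str = "cohort_id",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove low-quality segmented objects.

    Drops cells with pixel area below ``min_area_px`` or with dna1/dna2
    signal outside mean +/- ``dna_sd`` standard deviations; the DNA
    statistics are computed per cohort on the raw, pre-filter table.  A
    cohort whose DNA SD is zero (constant signal) contributes no DNA
    removals: the band degenerates to the mean and is disabled with a
    warning.

    Returns the filtered table and removal counts per rule.
    """
    if cells.empty:
        warnings.warn("qc_filter: empty cell table")
        return cells.copy(), {"area": 0, "dna": 0}
    small = cells[area_column].to_numpy() < min_area_px
    dna_out = np.zeros(len(cells), dtype=bool)
    groups = (
        cells.groupby(group_column, sort=False).indices
        if group_column in cells.columns
        else {None: np.arange(len(cells))}
    )
    for name, idx in groups.items():
        for col in ("dna1", "dna2"):
            vals = cells[col].to_numpy()[idx]
            mu, sd = vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0
            if sd == 0:
                warnings.warn(
                    f"qc_filter: zero DNA SD for {col} in cohort {name}; "
                    "DNA rule disabled for this group"
                )
                continue
            dna_out[idx] |= np.abs(vals - mu) > dna_sd * sd
    keep = ~(small | dna_out)
    removed = {"area": int(small.sum()), "dna": int((dna_out & ~small).sum())}
    return cells.loc[keep].copy(), removed


@dataclasses.dataclass(frozen=True)
class GatingRule:
    """One gate: the first rule whose predicates all hold wins."""

    label: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()


@dataclasses.dataclass(frozen=True)
class GatingConfig:
    """Ordered threshold gates on arcsinh-transformed intensities.

    ``thresholds`` maps marker name to the transformed-scale cutoff that
    separates negative from positive expression; markers absent from the
    mapping use ``default_threshold``.  Rules are evaluated in order and
    the fallback label is ``unclassified``, so the gate is total and
    deterministic.
    """

    rules: tuple[GatingRule, ...]
    thresholds: dict[str, float] = dataclasses.field(default_factory=dict)
    default_threshold: float = 1.4

    def threshold(self, marker: str) -> float:
        return self.thresholds.get(marker, self.default_threshold)


#: gate hierarchy: epithelium, endothelium, stroma, then CD45+ lineages.
#: Regulatory CD4 T = FoxP3+, naive = CD45RA+, memory = CD45RA-;
#: proliferating tumor = Ki67+; M1 = CD68+CD206-, M2 = CD68+CD163+CD206+,
#: monocyte = CD14+CD68-, granulocyte = CD14-CD11b+GranzymeB+,
#: MDSC = CD14+CD11b+, dendritic = CD11c+.
DEFAULT_RULES = (
    GatingRule("tumor_proliferating", ("panCK", "Ki67")),
    GatingRule("tumor_nonproliferating", ("panCK",), ("Ki67",)),
    GatingRule("vessel", ("CD31",)),
    GatingRule("fibroblast", ("aSMA",)),
    GatingRule("cd4_regulatory", ("CD45", "CD3", "CD4", "FoxP3")),
    GatingRule("cd4_naive", ("CD45", "CD3", "CD4", "CD45RA")),
    GatingRule("cd4_memory", ("CD45", "CD3", "CD4"), ("CD45RA",)),
    GatingRule("cd8_t", ("CD45", "CD3", "CD8")),
    GatingRule("b_cell", ("CD45", "CD20")),
    GatingRule("m2_macrophage", ("CD45", "CD68", "CD206", "CD163")),
    GatingRule("m1_macrophage", ("CD45", "CD68"), ("CD206",)),
    GatingRule("granulocyte", ("CD45", "CD11b", "GranzymeB"), ("CD14",)),
    GatingRule("mdsc", ("CD45", "CD14", "CD11b")),
    GatingRule("monocyte", ("CD45", "CD14"), ("CD68",)),
    GatingRule("dendritic", ("CD45", "CD11c")),
)

DEFAULT_GATING = GatingConfig(rules=DEFAULT_RULES)


def gate_cell_types(
    cells: pd.DataFrame,
    gating: GatingConfig = DEFAULT_GATING,
    prefix: str = "asinh_",
) -> pd.DataFrame:
    """Assign every cell exactly one ``type_label`` by ordered gating.

    Predicates compare transformed intensities (columns ``prefix +
    marker``) against the configured thresholds; cells matching no rule
    are ``unclassified``.
    """
    needed = {m for r in gating.rules for m in (*r.positive, *r.negative)}
    missing = [m for m in sorted(needed) if prefix + m not in cells.columns]
    if missing:
        raise KeyError(f"gating rules reference missing markers: {missing}")

    labels = np.full(len(cells), UNCLASSIFIED, dtype=object)
    unassigned = np.ones(len(cells), dtype=bool)
    for rule in gating.rules:
        match = unassigned.copy()
        for m in rule.positive:
            match &= cells[prefix + m].to_numpy() > gating.threshold(m)
        for m in rule.negative:
            match &= cells[prefix + m].to_numpy() <= gating.threshold(m)
        labels[match] = rule.label
        unassigned &= ~match
    out = cells.copy()
    out["type_label"] = labels
    return out


def attach_external_labels(
    cells: pd.DataFrame,
    labels: pd.Series | dict,
    allowed: Sequence[str] = POPULATIONS,
) -> pd.DataFrame:
    """Ingest cell-type labels computed outside the package.

    ``labels`` maps ``cell_id`` to a population name; ids not covered
    become ``unclassified``; labels outside ``allowed`` raise.
    """
    mapping = pd.Series(labels)
    bad = set(mapping.unique()) - set(allowed) - {UNCLASSIFIED}
    if bad:
        raise ValueError(f"unknown population labels: {sorted(bad)}")
    out = cells.copy()
    out["type_label"] = (
        out["cell_id"].map(mapping).fillna(UNCLASSIFIED).astype(object)
    )
    return out


def eccentricity(region_mask: np.ndarray) -> float:
    """Eccentricity of a region's second-moment ellipse, in [0, 1).

    sqrt(1 - (minor/major)^2) of the ellipse with the same normalized
    second central moments as the region; 0 for a disk, approaching 1 for
    a line.  Degenerate single-pixel regions return 0.
    """
    region_mask = np.asarray(region_mask).astype(np.uint8)
    if region_mask.sum() == 0:
        raise ValueError("empty region")
    if region_mask.sum() == 1:
        return 0.0
    props = measure.regionprops(region_mask)
    return float(props[0].eccentricity)


def region_geometry(label_mask: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-cell geometry from a label image.

    Returns cell_id, centroid (row/col, um), pixel area, area in um^2 and
    second-moment eccentricity, one row per labeled object.
    """
    props = measure.regionprops(np.asarray(label_mask))
    rows = [
        {
            "cell_id": p.label,
            "centroid_row": p.centroid[0] * pixel_size,
            "centroid_col": p.centroid[1] * pixel_size,
            "area_px": int(p.area),
            "area": p.area * pixel_size**2,
            "eccentricity": p.eccentricity,
        }
        for p in props
    ]
    return pd.DataFrame(rows)
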