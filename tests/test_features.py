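"""Feature classes against brute-force group-by and pairwise oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from microzone.features import (
    NeighborConfig,
    assemble_feature_matrix,
    feature_schema,
    functional_features,
    neighbor_distances,
    neighborhood_coefficients,
    retained_combos,
    spatial_metavariables,
    tumor_covered_fraction,
    zonal_density,
)
from microzone.phenotype import FUNCTIONAL_MARKERS, POPULATIONS, UNCLASSIFIED
from microzone.zoning import zone_areas


def test_tumor_covered_fraction_examples():
    empty = zone_areas(np.zeros((100, 200), dtype=bool))
    full = zone_areas(np.ones((100, 200), dtype=bool))
    assert tumor_covered_fraction(empty) == 0
    assert tumor_covered_fraction(full) == 1
    rect = np.zeros((500, 1000), dtype=bool)
    rect[100:200, 100:300] = True
    assert tumor_covered_fraction(zone_areas(rect)) == pytest.approx(0.04)


def _cells(rows):
    return pd.DataFrame(
        rows,
        columns=["cell_id", "type_label", "zone", "area", "eccentricity",
                 "border_distance", "asinh_" + FUNCTIONAL_MARKERS[0]],
    )


def test_zonal_density_arithmetic(small_cohort):
    # hand-checkable case first
    mask = np.zeros((500, 1000), dtype=bool)  # all stroma, 0.5 mm^2
    zm = zone_areas(mask)
    cells = _cells([[i, "cd8_t", "stroma", 30, 0.5, 40.0, 1.0] for i in range(10)])
    dens = zonal_density(cells, zm)
    d = dens.set_index(["population", "zone"])["density"]
    assert d.loc[("cd8_t", "stroma")] == pytest.approx(10 / 0.5)
    assert d.loc[("cd8_t", "front")] != d.loc[("cd8_t", "front")]  # NaN: zero area
    assert d.loc[("vessel", "stroma")] == 0
    # cross-check against a hand count on a generated ROI
    _, bundles, _ = small_cohort
    b = bundles[0]
    cells = b.cells.rename(columns={"true_type": "type_label"})
    dens = zonal_density(cells, b.zone_map).set_index(["population", "zone"])
    for pop, zone in itertools.product(["cd8_t", "fibroblast"], ["stroma", "front"]):
        n = ((cells["type_label"] == pop) & (cells["zone"] == zone)).sum()
        area = b.zone_map.zone_areas[zone]
        assert dens.loc[(pop, zone), "count"] == n
        assert dens.loc[(pop, zone), "density"] == pytest.approx(n / area)


def test_retained_combos_median_rule():
    rows = []
    for roi in range(5):
        for pop in POPULATIONS:
            for zone in ("stroma", "front", "core"):
                dens = 10.0
                if pop == "mdsc" and zone == "core":
                    dens = 5.0 if roi < 2 else 0.0  # median 0 -> excluded
                rows.append(
                    {"roi_id": roi, "population": pop, "zone": zone,
                     "density": dens}
                )
    combos = retained_combos(pd.DataFrame(rows))
    assert ("mdsc", "core") not in combos
    assert len(combos) == 44


def test_functional_and_metavariable_group_mean_oracle(rng):
    rows = []
    for i in range(60):
        rows.append(
            [i, rng.choice(["cd8_t", "vessel"]), rng.choice(["stroma", "front"]),
             rng.uniform(20, 60), rng.uniform(0, 0.9), rng.uniform(-30, 30),
             rng.normal()]
        )
    cells = _cells(rows)
    combos = {("cd8_t", "stroma"), ("cd8_t", "front"), ("vessel", "front")}
    m0 = "asinh_" + FUNCTIONAL_MARKERS[0]
    feats = functional_features(cells, combos, markers=FUNCTIONAL_MARKERS[:1])
    metas = spatial_metavariables(cells, combos)
    for pop, zone in combos:
        sub = cells[(cells["type_label"] == pop) & (cells["zone"] == zone)]
        assert feats[f"function:{zone}:{pop}:{FUNCTIONAL_MARKERS[0]}"] == (
            pytest.approx(sub[m0].mean())
        )
        assert metas[f"metavariable:{zone}:{pop}:size"] == pytest.approx(
            sub["area"].mean()
        )
        assert metas[f"metavariable:{zone}:{pop}:eccentricity"] == (
            pytest.approx(sub["eccentricity"].mean())
        )
    # distance features exist for the front zone only
    assert "metavariable:front:cd8_t:distance" in metas
    assert not any(":distance" in k and ":stroma:" in k for k in metas)
    # single cell -> feature equals its value; two cells -> midpoint
    single = _cells([[1, "cd8_t", "front", 30, 0.5, -5.0, 2.5]])
    f = functional_features(single, {("cd8_t", "front")}, FUNCTIONAL_MARKERS[:1])
    assert f[f"function:front:cd8_t:{FUNCTIONAL_MARKERS[0]}"] == 2.5
    m = spatial_metavariables(single, {("cd8_t", "front")})
    assert m["metavariable:front:cd8_t:distance"] == -5.0
    two = _cells([
        [1, "cd8_t", "front", 30, 0.5, -5.0, 1.0],
        [2, "cd8_t", "front", 30, 0.5, -5.0, 3.0],
    ])
    f2 = functional_features(two, {("cd8_t", "front")}, FUNCTIONAL_MARKERS[:1])
    assert f2[f"function:front:cd8_t:{FUNCTIONAL_MARKERS[0]}"] == 2.0


def _toy_roi(rng, n=30, shape=(64, 64)):
    """Non-overlapping square 'cells' with known centroids and types."""
    label = np.zeros(shape, dtype=int)
    rows = []
    cid = 0
    types = ["cd8_t", "vessel", "fibroblast"]
    while cid < n:
        r, c = rng.integers(2, shape[0] - 3), rng.integers(2, shape[1] - 3)
        if label[r - 2 : r + 3, c - 2 : c + 3].any():
            continue
        cid += 1
        label[r - 1 : r + 2, c - 1 : c + 2] = cid
        rows.append(
            {"cell_id": cid, "type_label": types[cid % 3],
             "zone": "stroma", "centroid_row": float(r), "centroid_col": float(c)}
        )
    return label, pd.DataFrame(rows)


def brute_border_neighbors(label, cells, k=5, max_dist=20.0):
    """Exhaustive O(n^2 * pixels) neighbor oracle (border distances)."""
    coords = {
        cid: np.argwhere(label == cid).astype(float)
        for cid in cells["cell_id"]
    }

    def border(cid):
        pix = coords[cid]
        out = []
        for r, c in pix:
            nbs = [(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)]
            if any(
                not (0 <= rr < label.shape[0] and 0 <= cc < label.shape[1])
                or label[int(rr), int(cc)] != cid
                for rr, cc in nbs
            ):
                out.append((r, c))
        return np.array(out)

    borders = {cid: border(cid) for cid in coords}
    result = {}
    for ci in cells["cell_id"]:
        cand = []
        for cj in cells["cell_id"]:
            if cj == ci:
                continue
            d = np.sqrt(
                ((borders[ci][:, None, :] - borders[cj][None, :, :]) ** 2)
                .sum(-1)
                .min()
            )
            if d <= max_dist:
                cand.append((d, cj))
        cand.sort()
        result[ci] = cand[:k]
    return result


def test_neighborhood_oracle_30_cells(rng):
    label, cells = _toy_roi(rng)
    cfg = NeighborConfig()
    got = neighbor_distances(cells, cfg, label_mask=label)
    want = brute_border_neighbors(label, cells)
    for cid in cells["cell_id"]:
        assert [j for _, j in got[cid]] == [j for _, j in want[cid]]
        assert np.allclose(
            [d for d, _ in got[cid]], [d for d, _ in want[cid]]
        )
    coeffs = neighborhood_coefficients(cells, cfg, label_mask=label)
    # brute-force mean coefficients
    type_of = dict(zip(cells["cell_id"], cells["type_label"]))
    for pop in ("cd8_t", "vessel", "fibroblast"):
        centers = [
            c for c in cells["cell_id"] if type_of[c] == pop and want[c]
        ]
        if not centers:
            continue
        for nb_pop in ("cd8_t", "vessel", "fibroblast"):
            expected = np.mean(
                [
                    np.mean([type_of[j] == nb_pop for _, j in want[c]])
                    for c in centers
                ]
            )
            row = coeffs[
                (coeffs["population"] == pop) & (coeffs["neighbor"] == nb_pop)
            ]
            assert row["coefficient"].iloc[0] == pytest.approx(expected)


def test_neighborhood_trivial_cases():
    # two cells 10 um apart (border distance): A->B and B->A coefficients 1
    label = np.zeros((40, 40), dtype=int)
    label[10, 10] = 1
    label[10, 21] = 2  # border-to-border 11 px
    cells = pd.DataFrame(
        {
            "cell_id": [1, 2],
            "type_label": ["cd8_t", "vessel"],
            "zone": ["stroma", "stroma"],
            "centroid_row": [10.0, 10.0],
            "centroid_col": [10.0, 21.0],
        }
    )
    coeffs = neighborhood_coefficients(cells, label_mask=label)
    c = coeffs.set_index(["population", "neighbor"])["coefficient"]
    assert c.loc[("cd8_t", "vessel")] == 1.0
    assert c.loc[("vessel", "cd8_t")] == 1.0
    # isolated cell contributes nothing
    label[30, 30] = 3
    cells3 = pd.concat(
        [cells, pd.DataFrame({"cell_id": [3], "type_label": ["mdsc"],
                              "zone": ["stroma"], "centroid_row": [30.0],
                              "centroid_col": [30.0]})],
        ignore_index=True,
    )
    coeffs3 = neighborhood_coefficients(cells3, label_mask=label)
    assert "mdsc" not in coeffs3["population"].values


def test_neighborhood_vectors_are_probabilities(small_cohort):
    _, bundles, _ = small_cohort
    b = bundles[0]
    cells = b.cells.rename(columns={"true_type": "type_label"})
    nb = neighbor_distances(cells, NeighborConfig(), b.label_mask)
    type_of = dict(zip(cells["cell_id"], cells["type_label"]))
    types = list(POPULATIONS) + [UNCLASSIFIED]
    rng = np.random.default_rng(4)
    some = rng.choice(cells["cell_id"].to_numpy(), 200, replace=False)
    for cid in some:
        lst = nb[int(cid)]
        if not lst:
            continue
        vec = np.array(
            [np.mean([type_of[j] == t for _, j in lst]) for t in types]
        )
        assert vec.sum() == pytest.approx(1.0)
        assert (vec >= 0).all()
        assert len(lst) <= 5
        assert all(d <= 20.0 for d, _ in lst)


def test_schema_counts_and_assembly():
    all_combos = {(p, z) for p in POPULATIONS for z in ("stroma", "front", "core")}
    schema = feature_schema(all_combos)
    by_class = schema.groupby("feature_class").size()
    assert by_class["density"] == 45
    assert by_class["function"] == 14 * 45
    assert by_class["metavariable"] == 2 * 45 + 15
    assert by_class["neighborhood"] == 45 * 16
    # density class ignores exclusions; others shrink
    fewer = all_combos - {("mdsc", "core")}
    s2 = feature_schema(fewer)
    assert (s2["feature_class"] == "density").sum() == 45
    assert (s2["feature_class"] == "function").sum() == 14 * 44
    # empty cohort: full schema, no rows
    fm = assemble_feature_matrix({}, pd.DataFrame(index=pd.Index([], name="roi_id")), all_combos)
    assert fm.data.shape == (0, len(schema))
    # duplicate names impossible by construction
    assert not schema.index.duplicated().any()


def test_neighbor_config_validation():
    with pytest.raises(ValueError):
        NeighborConfig(k=0)
    with pytest.raises(ValueError):
        NeighborConfig(max_dist=-1)
    with pytest.raises(ValueError):
        NeighborConfig(distance_mode="warp")
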