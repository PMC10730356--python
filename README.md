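# microzone

Zonal spatial subsetting and integrative modeling for multiplexed tissue
imaging of the tumor microenvironment.

Multiplexed imaging (imaging mass cytometry and kin) samples a tumor's
invasive front through small rectangular ROIs. The fraction of each ROI
covered by tumor varies widely with where the window happened to land,
and raw per-ROI cell counts inherit that variation — a sampling artifact,
not biology. `microzone` removes it by partitioning every ROI into three
tissue zones from the tumor border and normalizing all single-cell
features per zone, then models tumor grade from the resulting features.

**Who it is for:** computational biologists analyzing segmented
multiplexed imaging data (cell label masks + binary tumor masks +
per-cell intensity tables) who need tumor-area-unbiased features,
reproducibility statistics across ROIs/patients/cohorts, and a sparse,
interpretable classifier — plus a synthetic cohort generator that makes
the whole chain testable without any imaging data.

## The method

1. **Zonation.** With signed Euclidean border distance d (negative
   inside the tumor): core `d < −20 um`, front `|d| ≤ 20 um`, stroma
   `d > 20 um`. Zone areas come from the same thresholds (expanded area
   A_e: `d ≤ +20`; shrunk area A_s: `d < −20`; stroma = A_ROI − A_e,
   front = A_e − A_s, core = A_s), so areas and labels always agree and
   sum exactly to the ROI area.
2. **Features.** Four zone-resolved classes per ROI: zonal densities
   (cells/mm², all 15 populations x 3 zones), mean transformed
   functional-marker expression, spatial metavariables (mean size,
   eccentricity, and — front zone only — border distance), and
   neighborhood coefficients (type composition of each cell's ≤ 5
   nearest neighbors within 20 um border-to-border, averaged per
   population and zone). Population/zone pairs with median density zero
   across the cohort are dropped from all classes except density.
3. **Classifier.** Per feature class, stability selection: a
   squared-error LASSO, `L(β) = ‖Y − Xβ‖² + λ‖β‖₁` on the 0/1 grade
   label, refit on 500 stratified half-subsamples; features selected in
   > 50% of subsamples are kept. The union of selected features feeds an
   unpenalized logistic regression (late fusion). Performance =
   pooled AUROC over 5 Monte Carlo cross-validation splits grouped by
   patient, with a stratified-bootstrap CI and Mann-Whitney p-value.

## Worked example

```python
import microzone as mz
from microzone.pipeline import cohort_to_features
from microzone.model import StabilityConfig, monte_carlo_cv
from microzone.simulate import default_grade_effects

cfg = mz.SyntheticCohortConfig(
    n_patients=24, rois_per_patient=3,
    grade_effects=default_grade_effects(1.2), seed=202,
)
bundles, meta = mz.generate_cohort(cfg)          # ~1 s per ROI
fm = cohort_to_features(bundles, meta)           # 72 ROIs x 1468 features
res = monte_carlo_cv(fm, config=StabilityConfig(seed=7))

print(res.auc_report)
print(res.frequencies.sort_values(ascending=False).head(6))
```

Output (seeds as above):

```
{'auc': 0.959, 'ci_low': 0.918, 'ci_high': 0.989, 'p': 8.21e-12}
function:core:tumor_nonproliferating:pS6          0.99
density:stroma:cd4_memory                         0.96
density:front:m1_macrophage                       0.93
neighborhood:front:m2_macrophage:m1_macrophage    0.92
density:core:tumor_nonproliferating               0.89
neighborhood:stroma:fibroblast:cd8_t              0.86
```

The cohort carries ten planted grade effects (standardized size 1.2);
the pooled cross-validated AUROC of 0.96 and the top selection
frequencies show the classifier finding them: eight of the ten planted
features exceed the 0.5 frequency threshold while fewer than 0.5% of the
~1,450 unplanted features do. Rerunning with patient-permuted labels
drops the AUROC to 0.52 — the pipeline finds nothing when there is
nothing to find.

The same analysis runs from the shell on on-disk artifacts (TIFF masks,
CSV tables, JSON reports):

```bash
microzone all --output-dir run --seed 7
microzone report --output-dir run
```

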