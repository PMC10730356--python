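# Methods

## The problem

Multiplexed tissue imaging (e.g. imaging mass cytometry at ~1 um/pixel)
yields, per region of interest (ROI), a segmented cell mask and per-cell
marker intensities. Because ROIs are small windows placed along a tumor's
invasive front, the fraction of the window covered by tumor varies widely
from ROI to ROI, and raw per-ROI cell counts largely reflect that
sampling accident rather than biology. The package addresses this by
*spatial subsetting*: every ROI is partitioned into three tissue zones
relative to the tumor border and all single-cell features are normalized
per zone.

## Zonal geometry

The tumor border is the set of tumor-mask pixels 4-adjacent to an
in-image non-tumor pixel; tissue running off the image edge is not
treated as a border. Signed distances are the exact Euclidean distance
transform of that border set, measured center-to-center on the pixel
lattice, negative inside the tumor. A cell's distance is the signed value
of minimal absolute magnitude over its boundary pixels; a cell with
pixels on both sides of the border is at distance 0 by definition.

Zones, with band half-width `h` (default 20 um): **core** `d < -h`,
**front** `|d| <= h` (closed on both ends; exact ties at +-h fall in the
band), **stroma** `d > h`. Zone *areas* are derived from the same
distance thresholds — expanded tumor area A_e = pixels with `d <= +h`,
shrunk area A_s = pixels with `d < -h`, stroma = A_ROI − A_e, front =
A_e − A_s, core = A_s — so per-pixel zone labels and zone areas cannot
disagree and the three areas sum to the ROI area exactly, by pixel
arithmetic. Degenerate masks carry sentinel distances: no tumor → all
`+inf` (every cell stroma), all tumor → all `-inf` (every cell core),
both flagged in the result. Multi-component tumors use the distance to
the nearest border of any component.

## Phenotyping and QC

Raw mean intensities are arcsinh-transformed with cofactor 1. QC removes
objects under 10 px and cells whose DNA channels fall outside the
per-cohort mean ± 2 SD band (statistics on the raw, pre-filter table; a
zero SD disables the rule with a warning). Cell types come from an
ordered threshold gate over 16 lineage markers plus Ki67 and Granzyme B,
producing the 15 populations (two tumor, three CD4 T, CD8 T, B, vessel,
fibroblast, and six myeloid subsets) with `unclassified` as the total
fallback; graph-based clustering is intentionally out of scope, and
externally computed labels can be attached instead. Eccentricity is the
second-central-moment ellipse definition (0 = disk, → 1 = line), the
standard regionprops convention, since no formula is otherwise fixed.

## Feature classes

Per ROI, four classes, all zone-resolved, named
`class:zone:population[:marker|:partner|:metric]`:

1. **density** — cells/mm² per (population, zone); zones of zero area
   give missing values, not zeros. Always the full 15 x 3 = 45 columns.
2. **function** — mean transformed expression of the 14 functional
   markers per (population, zone).
3. **metavariable** — mean cell size and eccentricity per (population,
   zone), plus mean signed border distance per population, emitted for
   the front zone only (elsewhere it mostly encodes the tumor/stroma
   area ratio).
4. **neighborhood** — per center cell, up to 5 nearest cells within
   20 um border-to-border distance count as neighbors; the cell's
   coefficient vector is the type composition of those neighbors (a
   probability vector when at least one neighbor exists); features are
   means over center cells per (population, zone of the center cell);
   zero-neighbor cells are excluded from the mean. Border-to-border is
   the default metric (minimum pairwise distance between boundary-pixel
   sets, KD-tree pruned); a centroid mode exists for speed.

Populations whose median zonal density across the cohort is zero are
excluded from classes 2–4 for that zone (their means would measure
scarcity, not state); the density class is never pruned. ROIs lacking a
retained combination carry missing values; imputation is deferred to the
modeling stage (training-split medians) so absence is not conflated with
low signal.

## Variability analytics

CV = sample SD / mean (missing when the mean is 0). Intrapatient CV is
computed across each patient's ROIs; interpatient CV across patients
after a seeded random draw of one ROI per patient (optionally averaged
over several draws to cut Monte-Carlo noise). Reproducibility
comparisons use Spearman correlation throughout: inter-cohort =
correlation of per-cohort feature means matched by name; intrapatient =
correlation over all pooled within-patient ROI pairs (dataset-wide
pooling, not per-patient averaging).

## Classifier

Per feature class, stability selection with a squared-error LASSO on the
0/1-encoded grade label, `L(beta) = ||Y − X beta||² + lambda ||beta||₁`
(the objective is used as printed, without a 1/2n factor; the
coordinate-descent solver is invoked with `alpha = lambda/(2n)`; an
L1-logistic variant is deliberately not the default). 500 class-stratified
half-subsamples are drawn without replacement; each is standardized and
fit; a feature's selection frequency is the share of subsamples
selecting it, and features with frequency > 0.5 are kept.

How lambda is chosen per subsample is configurable. The default,
`max_path`, fits the whole path on a 25-point log-spaced grid spanning
two decades below each subsample's own lambda_max and takes each
feature's maximum per-lambda frequency — the canonical
stability-selection formulation. Only path points whose support size
stays at or below `max_support = ceil(sqrt(p))` are counted: past that
the fit leaves the sparse regime (with p < n the path ends at plain
least squares, where every coefficient is trivially nonzero and
frequencies saturate), and the per-family error control that motivates
the 0.5 threshold no longer applies. Alternatives: `inner_cv` (5-fold CV
within the subsample over a shared absolute grid — statistically
defensible but ~6x the cost, which is why it is not the default) and
`fixed` (one lambda everywhere).

The union of selected features across the four classes feeds an
unpenalized maximum-likelihood logistic regression (the late-fusion
model) on training-standardized columns; perfect separation or
non-convergence falls back to a ridge-stabilized fit with a warning, and
an empty selection degenerates to an intercept-only model scoring the
training prevalence.

Performance is estimated by Monte Carlo cross-validation: 5 random
80/20 splits, grouped by patient so sibling ROIs never straddle a split
(ungrouped ROI-level splitting is available); imputation,
standardization and selection are computed on the training side only.
Held-out scores are pooled across splits; AUROC uses the tie-corrected
rank (Mann-Whitney) statistic, its 95% CI a stratified bootstrap (2000
resamples, seeded), and its p-value the two-sided Mann-Whitney test of
score separation. The reported feature list comes from a final selection
pass over the entire dataset. The univariate screen applies two-sided
Mann-Whitney tests per feature at the ROI level with **no multiplicity
correction** — flags are descriptive, not confirmatory. Exact
enumeration of the Mann-Whitney null is used when the pooled sample size
is at most 12; otherwise the tie-corrected normal approximation.

## Synthetic cohorts

The generator emulates the study's data structure: 500 x 1000 px ROIs at
1 um/px, 3 ROIs per patient, 24 patients per cohort, grade alternating
over patients so the classes are balanced and never confounded with
patient order. Tumor masks are Gaussian-smoothed white noise thresholded
at the quantile matching a target covered fraction (natural borders with
convex and concave stretches; fraction exact up to ties; 0 and 1 exact).
The fraction target is drawn per patient by default — a patient's tumor
morphology is consistent across their ROIs — or per ROI.

Cells are non-overlapping ellipses with population-specific lognormal
areas and clipped-normal eccentricities, placed by an inhomogeneous
Poisson process whose intensity is piecewise-constant over the zones of
the realized mask. Intensity per (ROI, population, zone) is
`zone_density x patient factor x ROI jitter x zone area`. A fixed
log-scale noise budget `sigma_total` (default 0.35) is split by
`intrapatient_corr` c: patient factor sigma = sigma_total·sqrt(c), ROI
jitter sigma = sigma_total·sqrt(1−c); additionally a Gaussian copula
with weight sqrt(c) couples sibling ROIs' Poisson draws. At c → 1 a
patient's ROIs get identical targets and quantiles, so intrapatient CV
of counts → 0 up to mask-realization differences; at c = 0 ROIs are
independent. Placement draws a center uniformly from the target zone's
pixels and redraws on overlap (100 retries), then shrinks the ellipse by
20% per round (up to 4 rounds) before failing loudly. Because
non-overlapping packing jams well below full coverage, default densities
target ~25% expected pixel occupancy (~2,500–3,000 cells per ROI at a
40% tumor fraction), and an occupancy guard rescales the rare intensity
draws (~1%) that would exceed 45% — keeping realized counts unbiased for
density x area to well within the ±10% Monte-Carlo calibration the tests
enforce.

Marker intensities are lognormal on the raw scale (so the arcsinh
transform is meaningful): lineage markers have well-separated positive
and negative modes per population (log-levels +2 / −2, sdlog 0.4), which
gives threshold gating a clean noise-free limit; gate thresholds default
to the between-mode midpoint on the transformed scale. A small set of
zone-dependent functional shifts (e.g. pSTAT1 in M1 macrophages at the
front) is keyed to the *computed* zone of each cell — signaling should
depend on where the cell actually sits relative to the border, not on
which zone the point process sampled it into (and keying it to the
placement zone couples density effects to function features through
boundary cells).

Planted grade effects (`EffectSpec`) express standardized mean shifts
(Cohen's d on the per-ROI feature) applied to the higher-grade class.
Function effects shift each cell's transformed marker by d x SD of the
pre-effect per-ROI means (raw values updated through the inverse
transform); size/eccentricity effects shift the drawn attributes before
rendering so label masks stay consistent with tables; density effects
multiply the point-process intensity by a factor solving
shift = d x pooled-SD(f) under the exact Poisson-mixture variance
decomposition Var(D) = Var(lambda/A) + E[lambda/A²], iterated to a fixed
point (so the *pooled* post-effect SD is the yardstick, not the
pre-effect one). Neighborhood-class and border-distance effects are not
plantable by editing a finished table — they would require moving cells
— and raise a documented error.

### What the generator does not emulate

No raw multichannel images, spillover, hot pixels or segmentation
errors; marker noise is independent across cells (no spatial
autocorrelation of expression beyond the zone structure); populations
are spatially homogeneous within zones (no niches or gradients); grade
affects only the planted features. Passing tests therefore demonstrate
that the *machinery* is correct and that the modeling chain recovers
known structure under realistic sample sizes and noise — not that any
particular biological conclusion transfers to real tissue.

## Problem sizes and numerical choices

The test suite and the acceptance script exercise cohorts of 24 patients
x 3 ROIs (72 ROIs, ~2,500 cells each), the geometry and arm sizes the
analysis is designed around. Stability selection runs the full 500
subsamples per class; LASSO paths use coordinate descent at tolerance
1e-3 (1e-10 for the closed-form oracle checks, which agree with
soft-thresholded OLS to 1e-6). Ties in neighbor selection break by
distance then cell id; constant columns get unit scale during
standardization (their coefficients are exactly zero anyway); eccentric
eigenvalue computations clip tiny negative roots to zero.

### A small-count caveat on decorrelation

Zonal densities are constructed to be independent of the tumor-covered
fraction, and for abundant population/zone combinations their rank
correlation with the fraction sits at finite-sample noise level (note
the patient-shared factors roughly halve the effective sample size of a
72-ROI cohort). For near-empty combinations — e.g. tumor-population
densities in the stroma at a handful of cells per ROI — Poisson
discreteness leaves a residual artifact: exact zeros become more common
as the zone shrinks, which rank correlations pick up as a weak negative
association. This is a property of counting a rare event in a varying
window, not of the area bias that zonal normalization removes, so the
decorrelation checks are stated on the zones that dominate each
population's abundance.

## Known limitations

Zonal areas and distances assume square pixels and a single pixel size
per run. The gate is a deterministic stand-in for clustering-based
phenotyping and will misassign cells whose marker noise crosses
thresholds (~0.1% at default noise). The interpatient CV depends on the
seeded one-ROI-per-patient draw (average over draws to stabilize). The
uncorrected univariate screen inflates family-wise error by design.
Stability-selection frequencies depend on the penalty grid; the
`max_support` cap trades a small amount of recall for false-selection
control and is the main tuning surface if a different sparsity regime is
expected.
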