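"""Reproducibility and variability analytics.

Quantifies three levels of heterogeneity in a multi-ROI imaging study —
between ROIs of one patient (intrapatient), between patients within a
cohort (interpatient), and between cohorts — and measures how zonal
normalization (densities per tissue zone instead of raw per-ROI counts)
changes feature reproducibility.  All correlations are Spearman.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def coefficient_of_variation(values) -> float:
    """Sample SD divided by mean; NaN (missing) when the mean is 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    mu = v.mean()
    if mu == 0:
        return np.nan
    return float(v.std(ddof=1) / mu)


def intrapatient_cv(
    values: pd.DataFrame | pd.Series, patients: pd.Series
) -> pd.DataFrame:
    """CV across each patient's ROIs, per feature.

    ``values``: per-ROI feature values (rows = ROIs); ``patients`` maps
    each row to its patient.  Patients with fewer than 2 ROIs are skipped
    with a warning.  Returns patients x features.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame()
    rows = {}
    for pat, idx in values.groupby(patients.to_numpy()).groups.items():
        sub = values.loc[idx]
        if len(sub) < 2:
            warnings.warn(f"patient {pat}: fewer than 2 ROIs, skipped")
            continue
        rows[pat] = {
            col: (
                coefficient_of_variation(sub[col].dropna())
                if sub[col].notna().sum() >= 2
                else np.nan
            )
            for col in values.columns
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def interpatient_cv(
    values: pd.DataFrame | pd.Series,
    patients: pd.Series,
    seed: int = 0,
    n_draws: int = 1,
) -> pd.Series:
    """CV across patients after randomly selecting one ROI per patient.

    A single seeded draw by default; ``n_draws > 1`` averages the CV over
    repeated draws to reduce Monte-Carlo noise.  Deterministic given the
    seed.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame()
    pats = patients.to_numpy()
    uniq = pd.unique(pats)
    if len(uniq) < 2:
        raise ValueError("interpatient CV requires >= 2 patients")
    rng = np.random.default_rng(seed)
    pos = np.arange(len(values))
    acc = np.zeros(values.shape[1])
    for _ in range(n_draws):
        chosen = [rng.choice(pos[pats == p]) for p in uniq]
        sub = values.iloc[chosen]
        acc += np.array(
            [
                coefficient_of_variation(sub[col].dropna())
                if sub[col].notna().sum() >= 2
                else np.nan
                for col in values.columns
            ]
        )
    return pd.Series(acc / n_draws, index=values.columns)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    NaN with a warning when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("zero-variance input to Spearman correlation")
        return np.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def intercohort_correlation(
    values_a: pd.DataFrame, values_b: pd.DataFrame
) -> float:
    """Spearman correlation of per-cohort feature means, matched by
    feature name."""
    common = values_a.columns.intersection(values_b.columns)
    if len(common) < 3:
        raise ValueError("need >= 3 shared features")
    return spearman_correlation(
        values_a[common].mean().to_numpy(), values_b[common].mean().to_numpy()
    )


def intrapatient_pairwise_correlation(
    values: pd.DataFrame, patients: pd.Series
) -> float:
    """Spearman correlation over pooled within-patient ROI pairs.

    For every unordered pair of ROIs from the same patient and every
    feature, the pair of values contributes one point (x = first ROI,
    y = second ROI); all points are pooled dataset-wide before the
    correlation is computed.
    """
    xs, ys = [], []
    for _, idx in values.groupby(patients.to_numpy()).groups.items():
        idx = list(idx)
        for i, j in itertools.combinations(range(len(idx)), 2):
            a = values.loc[idx[i]].to_numpy(dtype=float)
            b = values.loc[idx[j]].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            xs.append(a[ok])
            ys.append(b[ok])
    if not xs:
        raise ValueError("no within-patient ROI pairs")
    return spearman_correlation(np.concatenate(xs), np.concatenate(ys))


def reproducibility_report(
    before_a: pd.DataFrame,
    after_a: pd.DataFrame,
    patients_a: pd.Series,
    before_b: pd.DataFrame | None = None,
    after_b: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Reproducibility gains of zonal normalization.

    ``before_*`` hold raw per-ROI population counts, ``after_*`` zonal
    densities (rows = ROIs, matched by feature name across cohorts).
    Reports pooled intrapatient pairwise correlations for cohort A, and
    inter-cohort correlations of per-cohort feature means when a second
    cohort is given.
    """
    out = {
        "intrapatient_before": intrapatient_pairwise_correlation(
            before_a, patients_a
        ),
        "intrapatient_after": intrapatient_pairwise_correlation(
            after_a, patients_a
        ),
    }
    if before_b is not None and after_b is not None:
        out["intercohort_before"] = intercohort_correlation(before_a, before_b)
        out["intercohort_after"] = intercohort_correlation(after_a, after_b)
    return out
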