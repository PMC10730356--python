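"""Stability-selection LASSO and late-fusion logistic classification.

The grade classifier is built in two stages.  First, for each of the
four feature classes separately, a squared-error LASSO
(``L(beta) = ||Y - X beta||^2 + lambda ||beta||_1`` on the 0/1-encoded
class label) is refit on many random half-subsamples of the training
data; a feature's *selection frequency* is the proportion of subsamples
in which its coefficient is nonzero, and features above a frequency
threshold (default 0.5) are kept.  Second, an unpenalized logistic
regression — the late-fusion model — is fit on the union of the
selected features from all classes.  Out-of-sample performance is
estimated with Monte Carlo cross-validation: repeated random
patient-grouped train/test splits, selection and fusion on the training
side only, scoring of held-out ROIs, and a pooled AUROC over all
held-out scores.

Estimators follow scikit-learn conventions (``fit``/``transform``/
``predict_proba``, ``get_params``, trailing-underscore fitted
attributes) and compose with sklearn model selection; the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import Lasso, LogisticRegression, lasso_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix


@dataclasses.dataclass(frozen=True)
class StabilityConfig:
    """Knobs of the selection + fusion + cross-validation procedure."""

    n_bootstrap: int = 500
    subsample_frac: float = 0.5
    freq_threshold: float = 0.5
    lambda_mode: str = "max_path"  # or "inner_cv", "fixed"
    n_grid: int = 25
    grid_ratio: float = 0.01
    fixed_lambda: float | None = None
    inner_cv_folds: int = 5
    max_support: int | None = None
    cv_folds: int = 5
    cv_test_frac: float = 0.2
    grouping: str = "patient"  # or "roi"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_frac < 1:
            raise ValueError("subsample_frac must be in (0, 1)")
        if not 0 <= self.freq_threshold <= 1:
            raise ValueError("freq_threshold must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def lasso_fit(X, y, lam: float, tol: float = 1e-10) -> np.ndarray:
    """Minimize ``||y - X beta||^2 + lam * ||beta||_1`` (no intercept).

    The quoted objective carries no 1/(2n) factor, so the coordinate-
    descent solver is called with ``alpha = lam / (2n)``.  ``lam`` at or
    above ``2 * max|X^T y|`` shrinks every coefficient to exactly zero;
    on orthonormal designs the solution equals soft-thresholded OLS
    coefficients at ``lam / 2``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in LASSO inputs")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = X.shape[0]
    est = Lasso(
        alpha=max(lam, 1e-300) / (2 * n),
        fit_intercept=False,
        tol=tol,
        max_iter=1_000_000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est.coef_.copy()


def lambda_max(X, y) -> float:
    """Smallest lambda with an all-zero solution: ``2 * max|X^T y|``."""
    return float(2 * np.abs(np.asarray(X).T @ np.asarray(y)).max())


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


class StabilitySelection(BaseEstimator, TransformerMixin):
    """Selection frequencies from LASSO refits on random half-subsamples.

    Each bootstrap draws a class-stratified ``subsample_frac`` of the
    samples without replacement, standardizes it, and fits the
    squared-error LASSO.  How the penalty is chosen per bootstrap is set
    by ``lambda_mode``:

    ``"max_path"`` (default)
        The whole regularization path over a log-spaced grid anchored at
        each subsample's own lambda_max is fit and a per-lambda selection
        frequency is accumulated; a feature's frequency is the maximum
        over the grid, the canonical stability-selection formulation.
        Only path points whose support size is at most ``max_support``
        (default ``ceil(sqrt(p))``) are counted: beyond that the fit
        leaves the sparse regime (with p < n the path ends at plain
        least squares, where every coefficient is trivially nonzero) and
        the per-family error bound of stability selection no longer
        holds.
    ``"inner_cv"``
        A shared absolute grid (anchored at the full data's lambda_max)
        is scored by ``inner_cv_folds``-fold CV within the subsample and
        the error-minimizing lambda is used.
    ``"fixed"``
        ``fixed_lambda`` is used everywhere.

    Fitted attributes: ``frequencies_`` in [0, 1] per feature,
    ``support_`` (frequency strictly above ``freq_threshold``),
    ``lambda_grid_``, ``n_features_in_``.
    """

    def __init__(
        self,
        n_bootstrap: int = 500,
        subsample_frac: float = 0.5,
        freq_threshold: float = 0.5,
        lambda_mode: str = "max_path",
        n_grid: int = 25,
        grid_ratio: float = 0.01,
        fixed_lambda: float | None = None,
        inner_cv_folds: int = 5,
        max_support: int | None = None,
        random_state: int | None = None,
    ):
        self.n_bootstrap = n_bootstrap
        self.subsample_frac = subsample_frac
        self.freq_threshold = freq_threshold
        self.lambda_mode = lambda_mode
        self.n_grid = n_grid
        self.grid_ratio = grid_ratio
        self.fixed_lambda = fixed_lambda
        self.inner_cv_folds = inner_cv_folds
        self.max_support = max_support
        self.random_state = random_state

    def _subsample(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Class-stratified half-subsample; both classes guaranteed."""
        idx = []
        for cls in np.unique(y):
            pos = np.flatnonzero(y == cls)
            k = max(1, round(len(pos) * self.subsample_frac))
            idx.append(rng.choice(pos, size=k, replace=False))
        return np.concatenate(idx)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values; impute before selection")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must be binary")
        if min((y == c).sum() for c in classes) < 2:
            raise ValueError("need >= 2 samples per class")
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        ratios = np.logspace(0, np.log10(self.grid_ratio), self.n_grid)
        self.max_support_ = (
            self.max_support
            if self.max_support is not None
            else int(np.ceil(np.sqrt(p)))
        )

        Xs_full, _, _ = _standardize(X)
        yc_full = y - y.mean()
        lam_full = lambda_max(Xs_full, yc_full)
        if self.lambda_mode == "inner_cv":
            self.lambda_grid_ = lam_full * ratios
        elif self.lambda_mode == "fixed":
            if self.fixed_lambda is None:
                raise ValueError("fixed mode requires fixed_lambda")
            self.lambda_grid_ = np.array([self.fixed_lambda])
        else:
            self.lambda_grid_ = ratios  # relative grid

        if self.lambda_mode == "max_path":
            freq = np.zeros((self.n_grid, p))
        else:
            freq = np.zeros(p)

        for _ in range(self.n_bootstrap):
            sub = self._subsample(y, rng)
            Xs, _, _ = _standardize(X[sub])
            ys = y[sub] - y[sub].mean()
            m = len(sub)
            if self.lambda_mode == "max_path":
                lmax = lambda_max(Xs, ys)
                alphas = (lmax * ratios) / (2 * m)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, coefs, _ = lasso_path(Xs, ys, alphas=alphas, tol=1e-3)
                active = (np.abs(coefs.T) > 0)
                sparse_ok = active.sum(axis=1) <= self.max_support_
                freq += active * sparse_ok[:, None]
            elif self.lambda_mode == "inner_cv":
                lam = self._inner_cv_lambda(Xs, ys, rng)
                beta = lasso_fit(Xs, ys, lam, tol=1e-4)
                freq += np.abs(beta) > 0
            else:
                beta = lasso_fit(Xs, ys, float(self.fixed_lambda), tol=1e-4)
                freq += np.abs(beta) > 0

        freq /= self.n_bootstrap
        if self.lambda_mode == "max_path":
            self.frequency_path_ = freq
            self.frequencies_ = freq.max(axis=0)
        else:
            self.frequencies_ = freq
        self.support_ = self.frequencies_ > self.freq_threshold
        self.n_features_in_ = p
        return self

    def _inner_cv_lambda(
        self, Xs: np.ndarray, ys: np.ndarray, rng: np.random.Generator
    ) -> float:
        m = len(ys)
        k = min(self.inner_cv_folds, m)
        perm = rng.permutation(m)
        folds = np.array_split(perm, k)
        errs = np.zeros(len(self.lambda_grid_))
        for f in folds:
            tr = np.setdiff1d(perm, f)
            Xt, mu, sd = _standardize(Xs[tr])
            yt = ys[tr] - ys[tr].mean()
            alphas = self.lambda_grid_ / (2 * len(tr))
            _, coefs, _ = lasso_path(
                Xt, yt, alphas=np.sort(alphas)[::-1], tol=1e-3
            )
            Xv = (Xs[f] - mu) / sd
            pred = Xv @ coefs + ys[tr].mean()
            errs += ((pred - ys[f][:, None]) ** 2).sum(axis=0)
        # lasso_path used descending alphas = ascending lambda order match
        order = np.argsort(self.lambda_grid_)[::-1]
        return float(self.lambda_grid_[order][np.argmin(errs)])

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]


class LateFusionClassifier(BaseEstimator, ClassifierMixin):
    """Stability selection per feature class + fused logistic regression.

    ``feature_classes`` assigns each column of X to a feature class
    (any hashable labels; ``None`` treats all columns as one class).
    ``fit`` imputes missing values with training-column medians, runs
    ``StabilitySelection`` within each class, and fits an unpenalized
    maximum-likelihood logistic regression on the union of selected
    columns (standardized on the training data).  Perfect separation or
    non-convergence falls back to a ridge-stabilized fit with a warning;
    an empty selection yields an intercept-only model scoring the
    training prevalence.
    """

    def __init__(
        self,
        feature_classes=None,
        n_bootstrap: int = 500,
        subsample_frac: float = 0.5,
        freq_threshold: float = 0.5,
        lambda_mode: str = "max_path",
        n_grid: int = 25,
        grid_ratio: float = 0.01,
        fixed_lambda: float | None = None,
        inner_cv_folds: int = 5,
        max_support: int | None = None,
        random_state: int | None = None,
    ):
        self.feature_classes = feature_classes
        self.n_bootstrap = n_bootstrap
        self.subsample_frac = subsample_frac
        self.freq_threshold = freq_threshold
        self.lambda_mode = lambda_mode
        self.n_grid = n_grid
        self.grid_ratio = grid_ratio
        self.fixed_lambda = fixed_lambda
        self.inner_cv_folds = inner_cv_folds
        self.max_support = max_support
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        ybin = (y == self.classes_[1]).astype(float)
        n, p = X.shape
        fclasses = (
            np.asarray(self.feature_classes)
            if self.feature_classes is not None
            else np.zeros(p, dtype=int)
        )
        if len(fclasses) != p:
            raise ValueError("feature_classes length must match n_features")

        self.medians_ = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isfinite(self.medians_), self.medians_, 0.0)
        Xi = np.where(np.isfinite(X), X, self.medians_[None, :])

        rng = np.random.default_rng(self.random_state)
        self.stability_ = {}
        support = np.zeros(p, dtype=bool)
        self.frequencies_ = np.zeros(p)
        for cls in pd.unique(fclasses):
            cols = np.flatnonzero(fclasses == cls)
            sel = StabilitySelection(
                n_bootstrap=self.n_bootstrap,
                subsample_frac=self.subsample_frac,
                freq_threshold=self.freq_threshold,
                lambda_mode=self.lambda_mode,
                n_grid=self.n_grid,
                grid_ratio=self.grid_ratio,
                fixed_lambda=self.fixed_lambda,
                inner_cv_folds=self.inner_cv_folds,
                max_support=self.max_support,
                random_state=int(rng.integers(2**31)),
            ).fit(Xi[:, cols], ybin)
            self.stability_[cls] = sel
            support[cols[sel.support_]] = True
            self.frequencies_[cols] = sel.frequencies_
        self.support_ = support
        self.selected_idx_ = np.flatnonzero(support)

        if support.sum() == 0:
            self.prevalence_ = float(ybin.mean())
            self.coef_ = np.zeros((1, 0))
            self.intercept_ = np.array(
                [np.log(self.prevalence_ / (1 - self.prevalence_))]
                if 0 < self.prevalence_ < 1
                else [0.0]
            )
            self.fusion_mode_ = "intercept_only"
            return self

        Xsel = Xi[:, support]
        Xs, self.means_, self.scales_ = _standardize(Xsel)
        logit = LogisticRegression(
            penalty=None, solver="lbfgs", max_iter=5000
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            logit.fit(Xs, ybin)
        blew_up = np.abs(logit.coef_).max() > 1e3
        not_conv = any("onverge" in str(w.message) for w in caught)
        if blew_up or not_conv:
            warnings.warn(
                "separation or non-convergence in fused logistic fit; "
                "falling back to ridge-stabilized estimates"
            )
            logit = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000)
            logit.fit(Xs, ybin)
            self.fusion_mode_ = "ridge_fallback"
        else:
            self.fusion_mode_ = "ml"
        self.coef_ = logit.coef_
        self.intercept_ = logit.intercept_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isfinite(X), X, self.medians_[None, :])
        if self.support_.sum() == 0:
            return np.full(len(Xi), self.intercept_[0])
        Xs = (Xi[:, self.support_] - self.means_) / self.scales_
        return Xs @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


# --------------------------------------------------------------------------
# statistics


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all label assignments when the pooled sample
    size is at most 12 (ties handled by average ranks under the same
    enumeration); otherwise the tie-corrected normal approximation.
    Returns ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    if nx + ny <= 12:
        center = nx * ny / 2
        dev_obs = abs(u_obs - center)
        count = total = 0
        idx = range(nx + ny)
        for comb in itertools.combinations(idx, nx):
            u = ranks[list(comb)].sum() - nx * (nx + 1) / 2
            if abs(u - center) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return float(u_obs), count / total
    if np.all(pooled == pooled[0]):
        return float(u_obs), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def auroc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict[str, float]:
    """AUROC with a stratified-bootstrap CI and a Mann-Whitney p-value.

    The AUC is the rank (Mann-Whitney) statistic with tie correction;
    the CI is the percentile interval over ``n_boot`` stratified
    resamples; p is the two-sided Mann-Whitney test of score separation
    between the classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    ybin = (labels == classes[1]).astype(int)
    auc = float(roc_auc_score(ybin, scores))
    pos, neg = np.flatnonzero(ybin == 1), np.flatnonzero(ybin == 0)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rp = rng.choice(pos, len(pos))
        rn = rng.choice(neg, len(neg))
        idx = np.concatenate([rp, rn])
        s = scores[idx]
        if np.all(s == s[0]):
            boots[b] = 0.5
            continue
        boots[b] = roc_auc_score(ybin[idx], s)
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    _, p = mann_whitney(scores[pos], scores[neg])
    return {"auc": auc, "ci_low": float(lo), "ci_high": float(hi), "p": p}


def univariate_screen(
    X: pd.DataFrame, labels, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney screen at the ROI level.

    No multiplicity correction is applied (the screen is deliberately
    uncorrected; treat flags as descriptive).  Missing values are
    dropped per feature; constant features get p = 1.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("binary grouping required")
    rows = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        a = v[ok & (labels == classes[0])]
        b = v[ok & (labels == classes[1])]
        if len(a) == 0 or len(b) == 0:
            u, p = np.nan, np.nan
        else:
            u, p = mann_whitney(a, b)
        rows.append({"feature": col, "U": u, "p": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["significant"] = out["p"] < alpha
    return out


# --------------------------------------------------------------------------
# cross-validation


@dataclasses.dataclass
class StabilityResult:
    """Everything the modeling stage produces."""

    frequencies: pd.Series
    selected: dict
    fused_coef: pd.Series
    oof_scores: pd.DataFrame
    auc_report: dict[str, float]
    fold_diagnostics: list[dict]
    config: StabilityConfig
    seed: int


def monte_carlo_cv(
    features: FeatureMatrix,
    y=None,
    config: StabilityConfig | None = None,
    label_column: str = "grade",
) -> StabilityResult:
    """Monte Carlo cross-validated late-fusion classification.

    Repeated random train/test splits (default 5 splits, 20% held out),
    grouped by patient so sibling ROIs never straddle the split (set
    ``config.grouping='roi'`` for ungrouped splitting).  All selection,
    imputation and standardization statistics are computed on the
    training side of each split; held-out ROI scores are pooled across
    splits for the AUROC.  The reported feature list comes from a final
    selection pass over the entire dataset.
    """
    config = config or StabilityConfig()
    X = features.data.to_numpy(dtype=float)
    names = list(features.data.columns)
    if y is None:
        y = features.row_info[label_column].to_numpy()
    else:
        y = np.asarray(y)
    groups = (
        features.row_info["patient_id"].to_numpy()
        if config.grouping == "patient"
        else np.arange(len(y))
    )
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    for cls in classes:
        if len(np.unique(groups[y == cls])) < 2:
            raise ValueError("need >= 2 groups per class for grouped splits")
    fclasses = features.feature_classes

    def make_clf(rs):
        return LateFusionClassifier(
            feature_classes=fclasses,
            n_bootstrap=config.n_bootstrap,
            subsample_frac=config.subsample_frac,
            freq_threshold=config.freq_threshold,
            lambda_mode=config.lambda_mode,
            n_grid=config.n_grid,
            grid_ratio=config.grid_ratio,
            fixed_lambda=config.fixed_lambda,
            inner_cv_folds=config.inner_cv_folds,
            max_support=config.max_support,
            random_state=rs,
        )

    rng = np.random.default_rng(config.seed)
    splitter = GroupShuffleSplit(
        n_splits=config.cv_folds,
        test_size=config.cv_test_frac,
        random_state=int(rng.integers(2**31)),
    )
    oof_rows = []
    diagnostics = []
    ybin = (y == classes[1]).astype(int)
    for fold, (tr, te) in enumerate(splitter.split(X, y, groups)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: single-class training split")
        clf = make_clf(int(rng.integers(2**31)))
        clf.fit(X[tr], y[tr])
        sc = clf.decision_function(X[te])
        for i, s in zip(te, sc):
            oof_rows.append(
                {
                    "roi_id": features.data.index[i],
                    "fold": fold,
                    "score": float(s),
                    "label": int(ybin[i]),
                }
            )
        diagnostics.append(
            {
                "fold": fold,
                "n_train": len(tr),
                "n_test": len(te),
                "n_selected": int(clf.support_.sum()),
                "fusion_mode": clf.fusion_mode_,
            }
        )
    oof = pd.DataFrame(oof_rows)
    auc_report = auroc(
        oof["score"].to_numpy(),
        oof["label"].to_numpy(),
        seed=int(rng.integers(2**31)),
    )

    final = make_clf(int(rng.integers(2**31)))
    final.fit(X, y)
    frequencies = pd.Series(final.frequencies_, index=names)
    selected = {
        cls: [names[i] for i in np.flatnonzero(fclasses == cls)[sel.support_]]
        for cls, sel in final.stability_.items()
    }
    fused_coef = pd.Series(
        final.coef_[0], index=[names[i] for i in final.selected_idx_]
    )
    return StabilityResult(
        frequencies=frequencies,
        selected=selected,
        fused_coef=fused_coef,
        oof_scores=oof,
        auc_report=auc_report,
        fold_diagnostics=diagnostics,
        config=config,
        seed=config.seed,
    )


def stability_selection(X, y, config: StabilityConfig | None = None):
    """Functional wrapper: frequencies and selected mask for one class."""
    config = config or StabilityConfig()
    sel = StabilitySelection(
        n_bootstrap=config.n_bootstrap,
        subsample_frac=config.subsample_frac,
        freq_threshold=config.freq_threshold,
        lambda_mode=config.lambda_mode,
        n_grid=config.n_grid,
        grid_ratio=config.grid_ratio,
        fixed_lambda=config.fixed_lambda,
        inner_cv_folds=config.inner_cv_folds,
        max_support=config.max_support,
        random_state=config.seed,
    ).fit(X, y)
    return sel.frequencies_, sel.support_


def late_fusion_fit(X, y, feature_classes=None, **kwargs) -> LateFusionClassifier:
    """Functional wrapper over :class:`LateFusionClassifier`."""
    return LateFusionClassifier(feature_classes=feature_classes, **kwargs).fit(X, y)
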