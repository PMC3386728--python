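"""PCA exploration, Fisher LDA with leave-one-out CV, Wilks'-lambda screening.

Linear discriminant analysis is the workhorse classifier: discriminant
directions solve the generalized eigenproblem of the between-class versus
pooled within-class scatter, and classification uses Fisher's per-class
linear discriminant functions with equal priors (the study design is
balanced).  Leave-one-out cross-validation refits the model with each row
held out, so no training row ever scores itself.  Wilks' lambda screens
variables one at a time: lambda_j = SSwithin_j / SStotal_j with its exact
one-way ANOVA F equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    loadings: np.ndarray  # (p, p) columns = component loading vectors
    explained_variance_ratio: np.ndarray
    n_retained: int
    mean: np.ndarray

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        n = n_components or self.n_retained
        X = np.asarray(X, dtype=float)
        return (X - self.mean) @ self.loadings[:, :n]


def n_components_for(ratios: np.ndarray, threshold: float = 0.80) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches the threshold."""
    cum = np.cumsum(ratios)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def pca_fit(X: np.ndarray | pd.DataFrame, variance_threshold: float = 0.80) -> PCAModel:
    """Eigendecomposition of the sample covariance; retain PCs per the 80 % rule."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    ratios = eigval / total if total > 0 else np.full_like(eigval, 1.0 / len(eigval))
    return PCAModel(
        loadings=eigvec,
        explained_variance_ratio=ratios,
        n_retained=n_components_for(ratios, variance_threshold),
        mean=mean,
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Fisher LDA: discriminant projections plus linear classification functions."""

    classes: np.ndarray
    means: np.ndarray          # (g, p) class means
    pooled_cov: np.ndarray     # (p, p) Sw / (n - g)
    scalings: np.ndarray       # (p, k) discriminant vectors, unit within-class variance
    eigenvalues: np.ndarray    # (k,) between/within variance ratios, non-increasing
    coef: np.ndarray           # (g, p) Fisher function coefficients
    intercept: np.ndarray      # (g,)
    feature_names: list[str] = field(default_factory=list)

    def scores(self, X: np.ndarray | pd.DataFrame,
               n_components: int | None = None) -> np.ndarray:
        """Discriminant-score projection (centred on the grand mean of class means)."""
        X = np.asarray(X, dtype=float)
        k = n_components or self.scalings.shape[1]
        centre = self.means.mean(axis=0)
        return (X - centre) @ self.scalings[:, :k]

    def decision_function(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        d = self.decision_function(X)
        # argmax returns the first maximum, i.e. the lowest class index on ties
        return self.classes[np.argmax(d, axis=1)]


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    n, p = X.shape
    grand = X.mean(axis=0)
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c, mu in zip(classes, means):
        Xc = X[y == c] - mu
        Sw += Xc.T @ Xc
        d = (mu - grand)[:, None]
        Sb += (y == c).sum() * (d @ d.T)
    return classes, means, Sw, Sb


def lda_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    ridge_tol: float = 1e-10,
) -> LDAModel:
    """Fit Fisher LDA with equal class priors.

    Discriminant vectors solve Sb v = lambda Sw v, sorted by decreasing
    eigenvalue and normalized to unit pooled within-class variance
    (v' Sigma v = 1).  A singular within-class scatter is ridge-regularized
    (eps * trace/p added to the diagonal) with a warning.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
    classes, means, Sw, Sb = _scatter_matrices(X, y)
    n, p = X.shape
    g = len(classes)
    # Guard against numerical singularity (p close to n, or collinear columns)
    try:
        cond_ok = np.linalg.cond(Sw) < 1.0 / ridge_tol
    except np.linalg.LinAlgError:
        cond_ok = False
    if not cond_ok or np.linalg.matrix_rank(Sw) < p:
        eps = 1e-8 * np.trace(Sw) / p
        warnings.warn(
            f"within-class scatter singular or ill-conditioned; adding ridge {eps:.3g}",
            stacklevel=2,
        )
        Sw = Sw + eps * np.eye(p)
    eigval, eigvec = linalg.eigh(Sb, Sw)
    order = np.argsort(eigval)[::-1]
    k = min(g - 1, p)
    eigval = np.clip(eigval[order][:k], 0.0, None)
    V = eigvec[:, order][:, :k]
    pooled = Sw / (n - g)
    # Normalize each discriminant to unit pooled within-class variance.
    wvar = np.einsum("ij,jk,ki->i", V.T, pooled, V)
    V = V / np.sqrt(np.clip(wvar, 1e-300, None))
    # Fisher linear discriminant functions, equal priors.
    icov_mu = np.linalg.solve(pooled, means.T).T  # (g, p)
    coef = icov_mu
    intercept = -0.5 * np.einsum("ij,ij->i", icov_mu, means)
    return LDAModel(
        classes=classes,
        means=means,
        pooled_cov=pooled,
        scalings=V,
        eigenvalues=eigval,
        coef=coef,
        intercept=intercept,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# Classification report (resubstitution + leave-one-out)
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Confusion counts for resubstitution and leave-one-out classification."""

    classes: np.ndarray
    confusion_resub: np.ndarray  # (g, g) rows = true class
    confusion_loo: np.ndarray

    @staticmethod
    def _overall(conf: np.ndarray) -> float:
        total = conf.sum()
        return 100.0 * np.trace(conf) / total if total else float("nan")

    @property
    def resubstitution_accuracy(self) -> float:
        """Percent of rows correctly classified by the fit-on-all model."""
        return self._overall(self.confusion_resub)

    @property
    def loo_accuracy(self) -> float:
        """Percent of rows correctly classified when each is held out of the fit."""
        return self._overall(self.confusion_loo)

    def per_class_percent(self, which: str = "loo") -> np.ndarray:
        conf = self.confusion_loo if which == "loo" else self.confusion_resub
        totals = conf.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * conf / totals

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: section x kind x true class x predicted columns."""
        rows = []
        for section, conf in (("Original", self.confusion_resub),
                              ("Cross-validated", self.confusion_loo)):
            pct = 100.0 * conf / np.maximum(conf.sum(axis=1, keepdims=True), 1)
            for kind, mat in (("Count", conf.astype(float)), ("%", pct)):
                for i, c in enumerate(self.classes):
                    row = {"section": section, "kind": kind, "group": c}
                    for j, cc in enumerate(self.classes):
                        row[f"pred_{cc}"] = mat[i, j]
                    row["total"] = conf[i].sum() if kind == "Count" else 100.0
                    rows.append(row)
        return pd.DataFrame(rows)


def _confusion(classes: np.ndarray, y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    return conf


def loo_crossvalidate(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    screen: "WilksResult | None" = None,
) -> ClassificationReport:
    """Resubstitution and leave-one-out confusion matrices for Fisher LDA.

    When a screening result is supplied, dropped variables are removed
    before any fit.  A fold that would leave a class with fewer than two
    training rows is skipped with a warning.
    """
    if isinstance(X, pd.DataFrame) and screen is not None:
        X = X[screen.kept_columns()]
    elif screen is not None:
        X = np.asarray(X, dtype=float)[:, screen.keep]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    full = lda_fit(X, y)
    classes = full.classes
    conf_resub = _confusion(classes, y, full.predict(X))
    counts = {c: (y == c).sum() for c in classes}
    preds = np.empty(len(y), dtype=y.dtype)
    valid = np.ones(len(y), dtype=bool)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        if counts[y[i]] - 1 < 2:
            warnings.warn(f"LOO fold {i} skipped: class {y[i]!r} too small", stacklevel=2)
            valid[i] = False
            continue
        mask[i] = False
        model = lda_fit(X[mask], y[mask])
        preds[i] = model.predict(X[i:i + 1])[0]
        mask[i] = True
    conf_loo = _confusion(classes, y[valid], preds[valid])
    return ClassificationReport(classes=classes, confusion_resub=conf_resub,
                                confusion_loo=conf_loo)


# ---------------------------------------------------------------------------
# Wilks' lambda screening
# ---------------------------------------------------------------------------

@dataclass
class WilksResult:
    """Per-variable Wilks' lambda, its one-way ANOVA F, p-value and keep flag."""

    columns: list[str]
    wilks_lambda: np.ndarray
    f_statistic: np.ndarray
    p_value: np.ndarray
    keep: np.ndarray
    alpha: float

    def kept_columns(self) -> list[str]:
        return [c for c, k in zip(self.columns, self.keep) if k]

    def dropped_columns(self) -> list[str]:
        return [c for c, k in zip(self.columns, self.keep) if not k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.columns,
                "wilks_lambda": self.wilks_lambda,
                "F": self.f_statistic,
                "p_value": self.p_value,
                "kept": self.keep,
            }
        )


def wilks_screen(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> WilksResult:
    """Univariate Wilks'-lambda screen of every variable.

    lambda_j = SSwithin_j / SStotal_j and
    F_j = ((1 - lambda_j) / lambda_j) * ((n - g) / (g - 1)),
    the exact one-way ANOVA F with (g - 1, n - g) degrees of freedom.
    Variables whose F-test p-value exceeds ``alpha`` are flagged for
    dropping (no class signal).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    classes = np.unique(y)
    n, g = len(y), len(classes)
    if g < 2 or n <= g:
        raise ValueError("need >= 2 classes and n > g")
    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum(axis=0)
    if np.any(ss_total == 0):
        bad = [names[j] for j in np.flatnonzero(ss_total == 0)]
        raise ValueError(f"zero total variance in column(s): {bad}")
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        ss_within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    lam = ss_within / ss_total
    with np.errstate(divide="ignore"):
        F = np.where(lam > 0, (1 - lam) / np.where(lam > 0, lam, 1) * (n - g) / (g - 1),
                     np.inf)
    p = stats.f.sf(F, g - 1, n - g)
    keep = p <= alpha
    return WilksResult(columns=names, wilks_lambda=lam, f_statistic=F,
                       p_value=p, keep=keep, alpha=alpha)
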