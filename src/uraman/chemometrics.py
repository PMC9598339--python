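"""Multivariate models for Raman calibration and classification.

Implements the model suite from scratch on top of numpy: principal
component analysis (PCA) for exploratory analysis, PLS1 regression by
NIPALS with leave-one-out cross-validation and latent-variable selection
by minimum RMSEcv, PLS-DA (PLS against numeric class codes 1 = CT,
2 = DM&HBP, thresholded at the midpoint), and linear discriminant
analysis with a pooled within-class covariance.

Spectra are mean-centered, never variance-scaled: all channels share the
same (arbitrary) intensity units, so scaling would only amplify noise
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import Group

__all__ = [
    "PCAResult",
    "PLSModel",
    "CVResult",
    "LDAModel",
    "CVUnit",
    "fit_pca",
    "variance_captured",
    "pls_fit",
    "pls_predict",
    "loocv_pls",
    "select_latent_variables",
    "plsda_fit",
    "plsda_classify",
    "lda_fit",
    "lda_classify",
    "PLSDA_THRESHOLD",
    "CLASS_CODES",
]

#: Numeric class codes used by PLS-DA regression.
CLASS_CODES = {Group.CT: 1.0, Group.DMHBP: 2.0}
#: Decision threshold at the midpoint of the two codes; ties go to DMHBP.
PLSDA_THRESHOLD = 1.5


class CVUnit(str, Enum):
    """What leave-one-out holds out: single spectra, or whole samples
    (all replicate spectra of one sample leave together)."""

    SPECTRUM = "spectrum"
    SAMPLE = "sample"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """PCA of a spectral matrix.

    ``loadings`` rows are unit-norm component directions over wavenumbers
    (spectrum-shaped); ``scores`` are per-spectrum projections of the
    centered data onto them.
    """

    loadings: np.ndarray  # (k, n_channels), orthonormal rows
    scores: np.ndarray  # (n_spectra, k)
    explained_variance_ratio: np.ndarray  # (k,)
    mean_spectrum: np.ndarray  # (n_channels,)


def fit_pca(X: np.ndarray, n_components: int) -> PCAResult:
    """PCA of ``X`` (spectra as rows) via SVD of the centered matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    k = n_components
    return PCAResult(
        loadings=Vt[:k],
        scores=U[:, :k] * s[:k],
        explained_variance_ratio=(s[:k] ** 2) / total_var,
        mean_spectrum=mean,
    )


def variance_captured(p: PCAResult, k: int) -> float:
    """Cumulative fraction of spectral variance in the first k components."""
    if not 0 <= k <= p.explained_variance_ratio.size:
        raise ValueError(f"k must be in [0, {p.explained_variance_ratio.size}]")
    return float(np.sum(p.explained_variance_ratio[:k]))


# ---------------------------------------------------------------------------
# PLS1 regression (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """PLS1 calibration state.

    Prediction is affine: ``(x - x_mean) @ regression_vector + y_mean``,
    which reproduces the sequential NIPALS score/deflation prediction.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (n_lv, n_channels)
    x_loadings: np.ndarray  # (n_lv, n_channels)
    y_loadings: np.ndarray  # (n_lv,)
    regression_vector: np.ndarray  # (n_channels,)


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by NIPALS deflation on mean-centered X and y.

    Each latent variable maximizes covariance between an X-projection and
    the residual y; X is deflated by the rank-one score/loading product
    before the next component.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X rows and y length differ")
    if n_lv < 1 or n < n_lv + 1:
        raise ValueError(f"need at least n_lv + 1 = {n_lv + 1} rows, got {n}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance; nothing to regress on")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"X residual is uncorrelated with y at component {a + 1};"
                " reduce n_lv"
            )
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise ValueError(f"degenerate score at component {a + 1}; reduce n_lv")
        pvec = (E.T @ t) / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[a], P[a], q[a] = w, pvec, qa

    # b = W (P W^T)^{-1} q  maps centered x to centered prediction
    b = W.T @ np.linalg.solve(P @ W.T, q)
    return PLSModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
    )


def pls_predict(m: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict responses for spectra on the model's wavenumber grid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1]} channels, model expects {m.x_mean.size}"
        )
    return (X - m.x_mean) @ m.regression_vector + m.y_mean


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """RMSEcv / r selection curve and held-out predictions at the chosen LV."""

    rmsecv_by_lv: np.ndarray  # (max_lv,)
    r_by_lv: np.ndarray  # (max_lv,)
    chosen_lv: int
    cv_predictions: np.ndarray  # (n_rows,) held-out predictions at chosen_lv
    cv_unit: CVUnit
    y_true: np.ndarray = field(default=None)  # convenience copy


def _cv_folds(n: int, cv_unit: CVUnit, sample_ids) -> list[np.ndarray]:
    if cv_unit == CVUnit.SPECTRUM:
        return [np.array([i]) for i in range(n)]
    if sample_ids is None:
        raise ValueError("sample-level CV requires sample_ids")
    sample_ids = np.asarray(sample_ids)
    if sample_ids.size != n:
        raise ValueError("sample_ids length must match X rows")
    # preserve first-appearance order for determinism
    _, first = np.unique(sample_ids, return_index=True)
    uniq = sample_ids[np.sort(first)]
    return [np.flatnonzero(sample_ids == u) for u in uniq]


def select_latent_variables(cv) -> int:
    """Number of LVs minimizing RMSEcv; ties broken toward fewer LVs.

    Accepts a :class:`CVResult` or a bare RMSEcv curve.
    """
    curve = cv.rmsecv_by_lv if isinstance(cv, CVResult) else np.asarray(cv, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSEcv curve")
    return int(np.argmin(curve)) + 1  # argmin returns the first minimum


def loocv_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    cv_unit: CVUnit = CVUnit.SAMPLE,
    sample_ids=None,
) -> CVResult:
    """Leave-one-out cross-validation of PLS1 over 1..max_lv components.

    Each held-out unit (one spectrum, or every replicate spectrum of one
    sample) is predicted by a model fitted on the remaining units only;
    centering and deflation never see the held-out rows.  RMSEcv is the
    root mean squared held-out error over all rows, r the Pearson
    correlation of held-out predictions with the truth.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    folds = _cv_folds(n, cv_unit, sample_ids)
    if len(folds) < 3:
        raise ValueError(f"need at least 3 cross-validation units, got {len(folds)}")
    min_train = min(n - f.size for f in folds)
    if max_lv > min_train - 1:
        raise ValueError(
            f"max_lv={max_lv} too large for {min_train}-row training folds"
        )

    preds = np.zeros((max_lv, n))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        Xtr, ytr = X[train], y[train]
        # one NIPALS pass at max_lv yields predictions for every smaller k
        x_mean = Xtr.mean(axis=0)
        y_mean = float(ytr.mean())
        E = Xtr - x_mean
        f = ytr - y_mean
        p_ch = X.shape[1]
        W = np.zeros((max_lv, p_ch))
        P = np.zeros((max_lv, p_ch))
        q = np.zeros(max_lv)
        for a in range(max_lv):
            w = E.T @ f
            norm = np.linalg.norm(w)
            if norm < 1e-14:
                W, P, q = W[:a], P[:a], q[:a]
                break
            w /= norm
            t = E @ w
            tt = float(t @ t)
            if tt < 1e-14:
                W, P, q = W[:a], P[:a], q[:a]
                break
            pvec = (E.T @ t) / tt
            qa = float(f @ t) / tt
            E -= np.outer(t, pvec)
            f -= qa * t
            W[a], P[a], q[a] = w, pvec, qa
        n_got = W.shape[0]
        Xc_test = X[fold] - x_mean
        for k in range(1, max_lv + 1):
            kk = min(k, n_got)
            b = W[:kk].T @ np.linalg.solve(P[:kk] @ W[:kk].T, q[:kk])
            preds[k - 1, fold] = Xc_test @ b + y_mean

    rmsecv = np.sqrt(np.mean((preds - y) ** 2, axis=1))
    r_by_lv = np.array(
        [
            np.corrcoef(preds[k], y)[0, 1] if np.std(preds[k]) > 0 else 0.0
            for k in range(max_lv)
        ]
    )
    chosen = select_latent_variables(rmsecv)
    return CVResult(
        rmsecv_by_lv=rmsecv,
        r_by_lv=r_by_lv,
        chosen_lv=chosen,
        cv_predictions=preds[chosen - 1].copy(),
        cv_unit=cv_unit,
        y_true=y.copy(),
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def plsda_fit(X: np.ndarray, labels, n_lv: int) -> PLSModel:
    """PLS regression against numeric class codes (CT -> 1, DMHBP -> 2)."""
    y = _codes_from_labels(labels)
    if np.all(y == y[0]):
        raise ValueError("PLS-DA needs both classes present")
    return pls_fit(X, y, n_lv)


def plsda_classify(m: PLSModel, X: np.ndarray) -> list[Group]:
    """Threshold PLS-DA scores at 1.5; scores >= 1.5 are called DMHBP."""
    scores = pls_predict(m, X)
    return [Group.DMHBP if s >= PLSDA_THRESHOLD else Group.CT for s in scores]


def _codes_from_labels(labels) -> np.ndarray:
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        g = Group(lab) if not isinstance(lab, Group) else lab
        out[i] = CLASS_CODES[g]
    return out


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


@dataclass
class LDAModel:
    """Two-class linear discriminant with pooled within-class covariance.

    A tiny ridge (lambda = 1e-6 * mean diagonal) keeps the pooled
    covariance invertible; priors are empirical class frequencies.
    """

    classes: tuple[Group, Group]
    class_means: np.ndarray  # (2, n_features)
    pooled_covariance: np.ndarray
    priors: np.ndarray  # (2,)
    ridge_lambda: float


def lda_fit(features: np.ndarray, labels) -> LDAModel:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    groups = [Group(lab) if not isinstance(lab, Group) else lab for lab in labels]
    classes = (Group.CT, Group.DMHBP)
    idx = {c: [i for i, g in enumerate(groups) if g == c] for c in classes}
    for c in classes:
        if len(idx[c]) < 2:
            raise ValueError(f"class {c.value} needs at least 2 units")
    n = X.shape[0]
    means = np.vstack([X[idx[c]].mean(axis=0) for c in classes])
    pooled = np.zeros((X.shape[1], X.shape[1]))
    for j, c in enumerate(classes):
        Xi = X[idx[c]] - means[j]
        pooled += Xi.T @ Xi
    pooled /= n - 2
    lam = 1e-6 * float(np.mean(np.diag(pooled))) if X.shape[1] else 0.0
    pooled += lam * np.eye(X.shape[1])
    priors = np.array([len(idx[c]) / n for c in classes])
    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_covariance=pooled,
        priors=priors,
        ridge_lambda=lam,
    )


def lda_classify(m: LDAModel, features: np.ndarray) -> list[Group]:
    """Assign each unit to the class maximizing the linear discriminant score
    (negative half Mahalanobis distance to the class mean plus log prior)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Sinv = np.linalg.inv(m.pooled_covariance)
    scores = np.zeros((X.shape[0], 2))
    for j in range(2):
        mu = m.class_means[j]
        # linear discriminant: x' S^-1 mu - mu' S^-1 mu / 2 + log prior
        scores[:, j] = (
            X @ Sinv @ mu - 0.5 * mu @ Sinv @ mu + np.log(m.priors[j])
        )
    return [m.classes[j] for j in np.argmax(scores, axis=1)]
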