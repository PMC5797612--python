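"""PCA-based atypical-sample detection via Q residuals and Hotelling's T2.

Samples whose preprocessed mean spectra lie far from the principal-component
model plane (large Q residual) or far from the model centre within the plane
(large Hotelling T2) are flagged as atypical and removed in a single pass.
The T2 confidence limit is the classical F-distribution bound

    T2_{p,n,alpha} = p (n - 1) / (n - p) * F_{p, n-p, alpha},

where p is the number of retained components and n the training sample
count; the Q limit uses the Jackson-Mudholkar approximation from the moments
of the discarded eigenvalues, falling back to the empirical training
quantile when those moments degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import CalibrationDataset

__all__ = [
    "PCAModel",
    "QCResult",
    "pca_fit",
    "scores_Q_T2",
    "hotelling_limit",
    "q_limit",
    "flag_and_remove",
    "fit_qc_model",
]


@dataclass
class PCAModel:
    """Mean-centered PCA model retained for diagnostics.

    ``loadings`` is (p x channels) with rows orthonormal; ``score_var``
    holds the per-component sample variance of the training scores
    (eigenvalues, ddof 1); ``residual_eigvals`` the discarded eigenvalues,
    used by the Q limit.
    """

    mean: np.ndarray
    loadings: np.ndarray
    score_var: np.ndarray
    residual_eigvals: np.ndarray
    n: int
    p: int
    alpha: float
    training_q: np.ndarray | None = None


def pca_fit(X: np.ndarray, p: int, alpha: float = 0.95) -> PCAModel:
    """Fit a mean-centered PCA by SVD.

    Deterministic up to component sign; the sign is fixed so each loading's
    largest-magnitude element is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if not (1 <= p < n):
        raise ValueError(f"component count p={p} must satisfy 1 <= p < n={n}")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    # sign convention: largest-|.| element of each loading positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    eig = s**2 / (n - 1)
    model = PCAModel(
        mean=mean,
        loadings=vt[:p],
        score_var=eig[:p],
        residual_eigvals=eig[p:],
        n=n,
        p=p,
        alpha=alpha,
    )
    model.training_q = scores_Q_T2(model, X).Q
    return model


@dataclass
class QCResult:
    """Per-sample diagnostics and (optionally) their confidence limits."""

    Q: np.ndarray
    T2: np.ndarray
    Q_limit: float | None = None
    T2_limit: float | None = None

    @property
    def outlier_mask(self) -> np.ndarray:
        if self.Q_limit is None or self.T2_limit is None:
            raise ValueError("limits not set on this QCResult")
        return (self.Q > self.Q_limit) | (self.T2 > self.T2_limit)


def scores_Q_T2(model: PCAModel, X: np.ndarray) -> QCResult:
    """Project samples onto the model; return Q residuals and T2 scores.

    ``t = (x - mean) @ loadings.T``; ``Q = ||(x - mean) - t @ loadings||^2``;
    ``T2 = sum_k t_k^2 / lambda_k`` with lambda_k the training score
    variance of component k.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"sample has {X.shape[1]} channels, model expects {model.mean.size}"
        )
    xc = X - model.mean
    t = xc @ model.loadings.T
    resid = xc - t @ model.loadings
    q = np.einsum("ij,ij->i", resid, resid)
    lam = np.where(model.score_var > 0, model.score_var, np.inf)
    t2 = (t**2 / lam).sum(axis=1)
    return QCResult(Q=q, T2=t2)


def hotelling_limit(p: int, n: int, alpha: float) -> float:
    """Hotelling T2 confidence limit ``p(n-1)/(n-p) * F_{p, n-p, alpha}``."""
    if p < 1:
        raise ValueError("p must be at least 1")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return p * (n - 1) / (n - p) * float(stats.f.ppf(alpha, p, n - p))


def q_limit(model: PCAModel, alpha: float | None = None) -> float:
    """Q-residual confidence limit (Jackson-Mudholkar approximation).

    Built from the first three moments of the discarded eigenvalues; when
    the moments degenerate (no residual variance, or an invalid ``h0``)
    falls back to the empirical ``alpha`` quantile of the training Q values.
    """
    alpha = model.alpha if alpha is None else alpha
    lam = model.residual_eigvals
    theta1 = float(lam.sum())
    theta2 = float((lam**2).sum())
    theta3 = float((lam**3).sum())
    if theta1 <= 0 or theta2 <= 0:
        return 0.0
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 <= 0:
        if model.training_q is None:
            raise ValueError("degenerate moments and no training Q available")
        return float(np.quantile(model.training_q, alpha))
    c = float(stats.norm.ppf(alpha))
    term = (
        c * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if term <= 0:
        if model.training_q is None:
            raise ValueError("degenerate limit and no training Q available")
        return float(np.quantile(model.training_q, alpha))
    return theta1 * term ** (1.0 / h0)


def fit_qc_model(
    X: np.ndarray,
    alpha: float = 0.95,
    var_capture: float = 0.95,
    max_components: int = 10,
) -> PCAModel:
    """Fit the QC PCA, retaining enough components for ``var_capture``
    cumulative variance (capped at ``max_components``)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    probe = pca_fit(X, p=min(n - 1, X.shape[1]), alpha=alpha)
    eig = np.concatenate([probe.score_var, probe.residual_eigvals])
    total = eig.sum()
    if total <= 0:
        raise ValueError("zero-variance data: QC model undefined")
    cum = np.cumsum(eig) / total
    p = int(np.searchsorted(cum, var_capture) + 1)
    p = max(1, min(p, max_components, n - 1))
    return pca_fit(X, p=p, alpha=alpha)


def flag_and_remove(
    dataset: CalibrationDataset, model: PCAModel, alpha: float | None = None
) -> tuple[CalibrationDataset, np.ndarray, QCResult]:
    """Remove samples exceeding either the Q or the T2 limit (single pass).

    Returns ``(clean dataset, removed row indices, full QC audit)``.
    """
    alpha = model.alpha if alpha is None else alpha
    qc = scores_Q_T2(model, dataset.X)
    qc.Q_limit = q_limit(model, alpha)
    qc.T2_limit = hotelling_limit(model.p, model.n, alpha)
    mask = qc.outlier_mask
    removed = np.flatnonzero(mask)
    return dataset.subset(~mask), removed, qc
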