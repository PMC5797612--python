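"""PLS1 regression by NIPALS, with latent-variable selection and metrics.

X and y are mean-centered (never variance-scaled: the inputs are derivative
spectra whose channel scales are already comparable).  For a single response
each NIPALS component is closed form:

    w_a = X_a' y_a / ||X_a' y_a||        (weights)
    t_a = X_a w_a                        (scores)
    p_a = X_a' t_a / t_a' t_a            (X loadings)
    q_a = y_a' t_a / t_a' t_a            (y loading)

followed by deflation ``X_{a+1} = X_a - t_a p_a'``, ``y_{a+1} = y_a - q_a
t_a``.  The regression vector for ``A`` components is
``B = W (P' W)^{-1} q`` so that ``yhat = (x - xbar) B + ybar``.

Model quality is reported as R^2 = 1 - SS_res / SS_tot (SS_tot about the
evaluation set's own mean) and RMSE = sqrt(mean((y - yhat)^2)); the
latent-variable count is chosen to minimize the cross-validated RMSE, ties
broken toward fewer components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "pls_fit", "predict", "metrics", "select_n_lv"]


@dataclass
class PLSModel:
    """Fitted PLS1 latent structure.

    ``weights``, ``x_loadings`` are (A x channels); ``y_loadings`` is (A,).
    ``coefficients(a)`` gives the regression vector truncated to the first
    ``a`` latent variables.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    n_lv: int
    meta: dict = field(default_factory=dict)

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        a = self.n_lv if n_lv is None else n_lv
        if not (1 <= a <= self.weights.shape[0]):
            raise ValueError(f"n_lv={a} outside the fitted range")
        W = self.weights[:a].T
        P = self.x_loadings[:a].T
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self, path=None) -> str:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "n_lv": self.n_lv,
            "meta": self.meta,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        elif hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            x_mean=np.array(payload["x_mean"]),
            y_mean=float(payload["y_mean"]),
            weights=np.array(payload["weights"]),
            x_loadings=np.array(payload["x_loadings"]),
            y_loadings=np.array(payload["y_loadings"]),
            n_lv=int(payload["n_lv"]),
            meta=payload.get("meta", {}),
        )


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int, meta: dict | None = None) -> PLSModel:
    """Fit a mean-centered NIPALS PLS1 model with ``n_lv`` latent variables.

    Deterministic.  Extraction stops early (with a warning in ``meta``) if X
    or y deflates to numerical zero before ``n_lv`` components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if n < 2:
        raise ValueError("need at least two samples")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(
            f"n_lv={n_lv} must lie in [1, min(n-1, channels)] = "
            f"[1, {min(n - 1, p)}]"
        )
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress on")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_mean
    ya = y - y_mean

    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    q = np.zeros(n_lv)
    eps = 1e-14 * max(1.0, float(np.abs(X).max()) ** 2)
    a_done = 0
    for a in range(n_lv):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= eps:
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        P[a] = Xa.T @ t / tt
        q[a] = float(ya @ t) / tt
        W[a] = w
        Xa = Xa - np.outer(t, P[a])
        ya = ya - q[a] * t
        a_done += 1
    if a_done == 0:
        raise ValueError("no latent variable could be extracted (X'y is zero)")
    meta = dict(meta or {})
    if a_done < n_lv:
        meta["truncated_at"] = a_done
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:a_done],
        x_loadings=P[:a_done],
        y_loadings=q[:a_done],
        n_lv=a_done,
        meta=meta,
    )


def predict(model: PLSModel, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Predict psi_s for new spectra: ``yhat = (x - xbar) B + ybar``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"spectra have {X_new.shape[1]} channels, model expects "
            f"{model.x_mean.size}"
        )
    b = model.coefficients(n_lv)
    return (X_new - model.x_mean) @ b + model.y_mean


def metrics(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """Return ``(R2, RMSE)`` of predictions against reference values.

    R2 = 1 - SS_res / SS_tot with SS_tot taken about the evaluation set's
    own mean, so external-set R2 can be negative for a bad model.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("length mismatch between y and predictions")
    if y.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R2 undefined for constant reference values")
    ss_res = float(((y - y_hat) ** 2).sum())
    rmse = float(np.sqrt(ss_res / y.size))
    return 1.0 - ss_res / ss_tot, rmse


def select_n_lv(cv_rmse_by_lv) -> int:
    """Latent-variable count minimizing CV-RMSE (1-based; ties -> fewer)."""
    curve = np.asarray(list(cv_rmse_by_lv), dtype=float)
    if curve.size == 0:
        raise ValueError("empty CV-RMSE curve")
    return int(np.argmin(curve)) + 1
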