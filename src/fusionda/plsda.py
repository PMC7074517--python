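"""PLS-DA: partial least squares regression of a binary dummy response.

A PLS1 model regresses a 0/1 class vector y on the fused predictor matrix
X by projecting onto a small number A of latent variables — directions of
maximum covariance between X and y — which sidesteps the collinearity and
n << p problems of small biomarker panels.  Classification thresholds the
predicted response: strictly above the threshold (default 0.5 under 0/1
coding) is called a case, otherwise a control.

The fitting algorithm is NIPALS PLS1 with X-deflation only: per component,
the weight vector is the X-y covariance direction normalized to unit
length, scores are the projection of the deflated X on it, and X is
deflated by its rank-one reconstruction.  The composite regression
coefficient vector is b = W (P'W)^{-1} q, and predictions through b agree
with the sequential latent-variable expansion to machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PLSDAModel", "fit_plsda", "predict_response", "predict_components", "classify"]


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model (0 = control, 1 = case coding)."""

    n_components: int
    x_mean: np.ndarray          # (p,)
    y_mean: float
    weights: np.ndarray         # W, (p, A), unit columns
    loadings: np.ndarray        # P, (p, A)
    y_loadings: np.ndarray      # q, (A,)
    scores: np.ndarray          # T, (n, A), training scores
    coef: np.ndarray            # b, (p,), composite coefficients
    intercept: float
    threshold: float = 0.5

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_plsda(
    X: np.ndarray, y: np.ndarray, n_components: int, threshold: float = 0.5
) -> PLSDAModel:
    """Fit NIPALS PLS1 of a binary response on X.

    X is column-centered and y mean-centered internally; the intercept
    restores the original response scale.  Requires
    ``n_components <= min(n - 1, p)`` and both classes present in y.  If
    the response covariance is exhausted before ``n_components`` components
    (X of low rank or y fit exactly), extraction stops early and the model
    records the number actually extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a nonempty 2-D array")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.size}, expected {n}")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    a = 0
    for _ in range(n_components):
        w = Xd.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-12:
            break  # covariance exhausted
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pl = Xd.T @ t / tt
        q[a] = float(yc @ t / tt)
        W[:, a], P[:, a], T[:, a] = w, pl, t
        Xd -= np.outer(t, pl)
        a += 1
    if a == 0:
        raise ValueError("X carries no covariance with y; nothing to fit")
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]

    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSDAModel(
        n_components=a,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        intercept=intercept,
        threshold=threshold,
    )


def predict_response(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous predicted response, ``intercept + X_new b`` (unbounded)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.coef.size}"
        )
    return model.intercept + X_new @ model.coef


def predict_components(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Cumulative predictions for every truncation 1..A of the model.

    Returns an (n_new, A) array whose column a-1 is the prediction of the
    model truncated to its first a latent variables — the sequential
    NIPALS expansion, useful for choosing A in cross-validation without
    refitting per candidate.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.size:
        raise ValueError("dimension mismatch")
    Xd = X_new - model.x_mean
    out = np.empty((X_new.shape[0], model.n_components))
    acc = np.full(X_new.shape[0], model.y_mean)
    for a in range(model.n_components):
        t = Xd @ model.weights[:, a]
        acc = acc + t * model.y_loadings[a]
        out[:, a] = acc
        Xd = Xd - np.outer(t, model.loadings[:, a])
    return out


def classify(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Binary labels: 1 iff the predicted response strictly exceeds the threshold.

    Ties at the threshold go to the control class.
    """
    return (predict_response(model, X_new) > model.threshold).astype(int)
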