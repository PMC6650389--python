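"""Partial Least Squares Discriminant Analysis (PLS-DA) for the binary
intact-vs-lysed decision.

The model is a single-response PLS (NIPALS formulation with deflation) on
autoscaled features, with the class coded ``y in {0, 1}`` and a decision
threshold of 0.5 on the predicted response.  Three latent components are the
screening default.  With all components retained, PLS1 reproduces the
least-squares regression on the autoscaled features — a closed-form
equivalence used as an oracle in the test-suite.

The fit is fully deterministic; autoscaling statistics come from the
training data only and are applied frozen at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSDAModel", "fit_plsda", "predict_plsda"]


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model (all arrays in the kept-feature space)."""

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, (p, a)
    x_loadings: np.ndarray  # P, (p, a)
    y_loadings: np.ndarray  # q, (a,)
    coef: np.ndarray  # regression vector in autoscaled space, (p,)
    kept: np.ndarray  # boolean mask of non-constant training columns
    threshold: float = 0.5
    classes: tuple = (0, 1)

    @property
    def n_features(self) -> int:
        return self.kept.size


def _autoscale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    kept = scale > 0
    return mean, scale, kept


def fit_plsda(
    X: np.ndarray, y: np.ndarray, n_components: int = 3, threshold: float = 0.5
) -> PLSDAModel:
    """Fit a PLS1 discriminant model.

    ``y`` must contain exactly two classes (coded to {0, 1} internally).
    Constant feature columns are dropped with a warning.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes in y, got {classes!r}")
    yb = (y == classes[1]).astype(float)

    mean, scale, kept = _autoscale_fit(X)
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} constant feature column(s)", stacklevel=2)
    Xs = (X[:, kept] - mean[kept]) / scale[kept]
    y_mean = yb.mean()
    f = yb - y_mean

    p = Xs.shape[1]
    a = min(n_components, p, len(X) - 1)
    if a < n_components:
        warnings.warn(f"n_components reduced from {n_components} to {a} (rank limit)", stacklevel=2)
    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    E = Xs.copy()
    for i in range(a):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            a = i
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= nw
        t = E @ w
        tt = t @ t
        if tt == 0:
            a = i
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        pv = E.T @ t / tt
        qi = f @ t / tt
        E = E - np.outer(t, pv)
        f = f - qi * t
        W[:, i], P[:, i], q[i] = w, pv, qi
    coef = W @ np.linalg.solve(P.T @ W, q) if a > 0 else np.zeros(p)

    return PLSDAModel(
        n_components=a,
        x_mean=mean[kept],
        x_scale=scale[kept],
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        kept=kept,
        threshold=threshold,
        classes=tuple(classes),
    )


def transform_plsda(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Latent component scores T = Xs W (P' W)^-1 for plotting."""
    Xs = _apply_scaling(model, X)
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    return Xs @ R


def _apply_scaling(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    return (X[:, model.kept] - model.x_mean) / model.x_scale


def predict_plsda(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class labels and continuous response scores.

    The continuous score is the predicted response in the {0, 1} coding; the
    label is ``classes[1]`` when the score >= threshold (ties go to the
    positive class by this convention).
    """
    Xs = _apply_scaling(model, X)
    score = Xs @ model.coef + model.y_mean
    labels = np.where(score >= model.threshold, model.classes[1], model.classes[0])
    return labels, score
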