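"""Soft Independent Modelling of Class Analogy (SIMCA) for the four target
morphology classes, with "deformed" as the rejection category.

One PCA is fitted per class on class-autoscaled data.  A new cell is scored
against each class with a combined distance mixing the Mahalanobis distance
in score space (``SD2``, scaled by its in-class training mean) and the
orthogonal residual (``OD2``, likewise scaled):

    d = SD2 / mean_train(SD2) + OD2 / mean_train(OD2)

The class acceptance limit is the empirical 95th percentile (alpha = 0.05)
of ``d`` over the class training set, so about 95% of in-class data is
accepted by construction.  A cell accepted by no class is labelled
``deformed``; a cell accepted by several classes goes to the class with the
smallest reduced distance ``d / limit`` (the ambiguity is logged).

Screening defaults follow the component counts 1 (elongated), 1 (normal),
3 (round) and 2 (small).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["SIMCAModel", "ClassSubModel", "fit_simca", "predict_simca", "DEFAULT_COMPONENTS"]

logger = logging.getLogger(__name__)

DEFAULT_COMPONENTS = {"elongated": 1, "normal": 1, "round": 3, "small": 2}
REJECT_LABEL = "deformed"


@dataclass
class ClassSubModel:
    """PCA class model: autoscaling stats, loadings, eigenvalues, limit."""

    name: str
    k: int
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (p, k)
    eigenvalues: np.ndarray  # (k,)
    sd2_norm: float  # training mean of the score distance
    od2_norm: float  # training mean of the orthogonal residual
    limit: float  # acceptance limit on the combined distance
    n_train: int

    def distances(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xs = (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.scale
        T = Xs @ self.loadings
        sd2 = np.sum(T**2 / self.eigenvalues, axis=1)
        resid = Xs - T @ self.loadings.T
        od2 = np.sum(resid**2, axis=1)
        return sd2, od2

    def combined(self, X: np.ndarray) -> np.ndarray:
        sd2, od2 = self.distances(X)
        return sd2 / self.sd2_norm + od2 / self.od2_norm


@dataclass
class SIMCAModel:
    classes: dict[str, ClassSubModel]
    alpha: float

    @property
    def n_features(self) -> int:
        return next(iter(self.classes.values())).mean.size


def _fit_class(name: str, X: np.ndarray, k: int, alpha: float) -> ClassSubModel:
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= k + 1:
        raise ValueError(f"class {name!r}: {n} cells cannot support k={k} components")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = (s**2) / (n - 1)
    loadings = Vt[:k].T
    sub = ClassSubModel(
        name=name,
        k=k,
        mean=mean,
        scale=scale,
        loadings=loadings,
        eigenvalues=eig[:k],
        sd2_norm=1.0,
        od2_norm=1.0,
        limit=np.inf,
        n_train=n,
    )
    sd2, od2 = sub.distances(X)
    sub.sd2_norm = float(sd2.mean()) or 1.0
    sub.od2_norm = float(od2.mean()) or np.finfo(float).eps
    combined = sd2 / sub.sd2_norm + od2 / sub.od2_norm
    # linear interpolation of order statistics at plotting positions i/(n+1)
    sub.limit = float(np.percentile(combined, 100 * (1 - alpha), method="weibull"))
    return sub


def fit_simca(
    X_by_class: dict[str, np.ndarray],
    k_by_class: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> SIMCAModel:
    """Fit one PCA class model per morphology class.

    ``X_by_class`` maps class name to its (n_c, p) training matrix;
    ``k_by_class`` gives the per-class component counts (defaults to the
    screening values in :data:`DEFAULT_COMPONENTS` where named).
    """
    if not X_by_class:
        raise ValueError("no classes given")
    if k_by_class is None:
        k_by_class = {c: DEFAULT_COMPONENTS.get(c, 2) for c in X_by_class}
    classes = {
        name: _fit_class(name, X, k_by_class[name], alpha) for name, X in X_by_class.items()
    }
    p = {sub.mean.size for sub in classes.values()}
    if len(p) != 1:
        raise ValueError("all classes must share the same feature count")
    return SIMCAModel(classes=classes, alpha=alpha)


def predict_simca(model: SIMCAModel, X: np.ndarray) -> np.ndarray:
    """Morphology label per row: an accepted class (smallest reduced
    distance on multi-acceptance) or the rejection label ``deformed``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    names = list(model.classes)
    reduced = np.column_stack(
        [model.classes[c].combined(X) / model.classes[c].limit for c in names]
    )
    accepted = reduced <= 1.0
    labels = np.empty(len(X), dtype=object)
    n_ambiguous = 0
    for i in range(len(X)):
        acc = np.flatnonzero(accepted[i])
        if acc.size == 0:
            labels[i] = REJECT_LABEL
        else:
            if acc.size > 1:
                n_ambiguous += 1
            labels[i] = names[int(acc[np.argmin(reduced[i, acc])])]
    if n_ambiguous:
        logger.info("%d cell(s) accepted by multiple classes; assigned by smallest reduced distance", n_ambiguous)
    return labels
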