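"""Two-stage cell labelling and cross-validated performance estimation.

A cell first passes the PLS-DA intact/lysed gate; intact cells are then
assigned a morphology by SIMCA (or rejected into "deformed").  The final
label set is a partition: every cell carries exactly one label from
{lysed, normal, small, elongated, round, deformed}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .plsda import PLSDAModel, fit_plsda, predict_plsda
from .simca import DEFAULT_COMPONENTS, SIMCAModel, fit_simca, predict_simca

__all__ = ["label_cells", "train_classifiers", "crossvalidate"]

LYSED = "lysed"


@dataclass
class CellClassifiers:
    """The fitted pair of models used by the screening pipeline."""

    plsda: PLSDAModel
    simca: SIMCAModel


def train_classifiers(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 3,
    k_by_class: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> CellClassifiers:
    """Train both models from one labelled cell table.

    ``labels`` are the six generator categories; the PLS-DA gate is trained
    on lysed-vs-rest, the SIMCA class models only on the four target
    morphology classes (deformed cells are never modelled — they are the
    rejection category).
    """
    labels = np.asarray(labels)
    y = (labels == LYSED).astype(int)
    plsda = fit_plsda(X, y, n_components=n_components)
    X_by_class = {
        c: X[labels == c] for c in DEFAULT_COMPONENTS if np.sum(labels == c) > 0
    }
    simca = fit_simca(X_by_class, k_by_class=k_by_class, alpha=alpha)
    return CellClassifiers(plsda=plsda, simca=simca)


def label_cells(clf: CellClassifiers, X: np.ndarray) -> np.ndarray:
    """Final per-cell labels (exactly one per cell)."""
    X = np.atleast_2d(np.asarray(X, float))
    is_lysed, _ = predict_plsda(clf.plsda, X)
    out = np.empty(len(X), dtype=object)
    out[is_lysed == 1] = LYSED
    intact_idx = np.flatnonzero(is_lysed == 0)
    if intact_idx.size:
        out[intact_idx] = predict_simca(clf.simca, X[intact_idx])
    return out


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, classes) -> pd.DataFrame:
    rows = []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        fp = np.sum((y_true != c) & (y_pred == c))
        tn = np.sum((y_true != c) & (y_pred != c))
        rows.append(
            {
                "class": c,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "accuracy": (tp + tn) / len(y_true),
                "n": int(tp + fn),
            }
        )
    return pd.DataFrame(rows)


def crossvalidate(
    classifier_spec: dict,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 7,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation of either classifier.

    ``classifier_spec`` is ``{"kind": "plsda", "n_components": 3}`` or
    ``{"kind": "simca", "k_by_class": {...}, "alpha": 0.05}`` or
    ``{"kind": "combined", ...}`` (both stages).  Fold assignment is
    reproducible from ``rng``; every sample is tested exactly once.
    Returns per-class sensitivity/specificity/accuracy.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    seed = int(rng) if isinstance(rng, (int, np.integer)) else (
        int(rng.integers(2**31 - 1)) if rng is not None else 0
    )
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"every class needs >= {folds} samples for stratified {folds}-fold CV; got {counts.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    kind = classifier_spec.get("kind", "combined")
    for train, test in skf.split(X, y):
        if kind == "plsda":
            m = fit_plsda(X[train], y[train], n_components=classifier_spec.get("n_components", 3))
            y_pred[test] = predict_plsda(m, X[test])[0]
        elif kind == "simca":
            Xc = {c: X[train][y[train] == c] for c in np.unique(y[train])}
            m = fit_simca(
                Xc,
                k_by_class=classifier_spec.get("k_by_class"),
                alpha=classifier_spec.get("alpha", 0.05),
            )
            y_pred[test] = predict_simca(m, X[test])
        elif kind == "combined":
            clf = train_classifiers(
                X[train],
                y[train],
                n_components=classifier_spec.get("n_components", 3),
                k_by_class=classifier_spec.get("k_by_class"),
                alpha=classifier_spec.get("alpha", 0.05),
            )
            y_pred[test] = label_cells(clf, X[test])
        else:
            raise ValueError(f"unknown classifier kind {kind!r}")
    return _metrics(y, y_pred, np.unique(y))
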