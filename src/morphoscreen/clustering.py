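"""k-means clustering of atypical phenotypic profiles with silhouette-based
selection of the number of clusters, plus a 2-D PCA embedding for plots.

k-means uses greedy spread-out (k-means++) seeding with 50 restarts and a
fixed seed; the solution with the lowest inertia wins.  The number of
clusters is the k maximizing the mean silhouette width over a scanned range;
if no k yields a positive mean silhouette the data is reported as having no
cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = ["ClusterResult", "kmeans", "select_k_by_silhouette", "pca_embed"]


@dataclass
class ClusterResult:
    k: int | None  # None = no cluster structure
    assignment: np.ndarray | None  # 1-based labels
    silhouette: np.ndarray | None  # per-sample widths
    mean_silhouette_by_k: dict[int, float] = field(default_factory=dict)
    inertia: float | None = None
    embedding: np.ndarray | None = None  # (n, 2) PCA coordinates


def kmeans(
    X: np.ndarray,
    k: int,
    n_restarts: int = 50,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float]:
    """Best-of-restarts k-means; returns (1-based assignment, inertia)."""
    X = np.asarray(X, float)
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} must be in [1, n={len(X)}]")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seed = int(rng) if isinstance(rng, (int, np.integer)) else (
        int(rng.integers(2**31 - 1)) if rng is not None else 0
    )
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed).fit(X)
    return km.labels_ + 1, float(km.inertia_)


def select_k_by_silhouette(
    X: np.ndarray,
    k_range=range(2, 9),
    n_restarts: int = 50,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Scan k over ``k_range``, pick the k with the largest mean silhouette.

    Returns a :class:`ClusterResult`; ``k is None`` (no cluster structure)
    when every scanned k has non-positive mean silhouette width.
    """
    X = np.asarray(X, float)
    ks = [k for k in k_range if 2 <= k <= len(X) - 1]
    if not ks:
        raise ValueError(f"no valid k in {list(k_range)!r} for n={len(X)}")
    results = {}
    curve = {}
    for k in ks:
        labels, inertia = kmeans(X, k, n_restarts=n_restarts, rng=rng)
        sil = silhouette_samples(X, labels)
        curve[k] = float(sil.mean())
        results[k] = (labels, inertia, sil)
    best_k = max(curve, key=curve.get)
    if curve[best_k] <= 0:
        return ClusterResult(
            k=None, assignment=None, silhouette=None, mean_silhouette_by_k=curve
        )
    labels, inertia, sil = results[best_k]
    return ClusterResult(
        k=best_k,
        assignment=labels,
        silhouette=sil,
        mean_silhouette_by_k=curve,
        inertia=inertia,
        embedding=pca_embed(X) if len(X) >= 3 else None,
    )


def pca_embed(profiles: np.ndarray) -> np.ndarray:
    """First two principal-component scores of the autoscaled profiles.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so embeddings are reproducible across runs.
    """
    X = np.asarray(profiles, float)
    if len(X) < 3:
        raise ValueError("need >= 3 profiles to embed")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    V = Vt[:2].T
    if V.shape[1] < 2:  # rank-1 data: pad a zero second axis
        V = np.column_stack([V, np.zeros(V.shape[0])])
    for j in range(2):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return Xs @ V
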