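"""Wild-type PCA reference model with Hotelling's T2 / SPE outlier flagging.

The batch-corrected wild-type profiles are autoscaled and decomposed by PCA.
For a new profile x (autoscaled with the training statistics) with scores
``t = V_k' x``:

* Hotelling's ``T2 = sum_j t_j^2 / lambda_j`` — the Mahalanobis distance of
  the projection within the model hyperplane.  Large values mean extreme but
  correlation-preserving profiles.
* ``SPE = ||x - V_k t||^2`` — the squared orthogonal distance from the
  hyperplane.  Large values mean the profile breaks the wild-type
  correlation structure.

The operative decision rule is empirical: a strain is flagged when either
statistic exceeds the corresponding percentile (default 99th) of the
wild-type sample distribution, computed by resubstitution on the training
profiles.  Theoretical limits (F-based for T2, weighted-chi-square for SPE)
are provided for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceModel",
    "Limits",
    "fit_reference",
    "score",
    "score_many",
    "empirical_limits",
    "theoretical_limits",
    "flag",
]

#: percentile method: linear interpolation of order statistics at plotting
#: positions i/(n+1), which makes the exceedance rate of a fresh in-control
#: profile unbiased (P(beyond q-th limit) ~= 1-q)
_PCTL_METHOD = "weibull"


@dataclass
class ReferenceModel:
    """PCA model of the in-control (wild-type) phenotypic profiles."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (p, k)
    eigenvalues: np.ndarray  # all p eigenvalues, non-increasing
    k: int
    n: int  # number of training profiles
    explained: float  # cumulative variance ratio of the k retained components

    @property
    def p(self) -> int:
        return self.mean.size

    @property
    def residual_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.k :]

    def theta(self, i: int) -> float:
        return float(np.sum(self.residual_eigenvalues**i))


@dataclass
class Limits:
    t2: dict[float, float] = field(default_factory=dict)  # percentile -> limit
    spe: dict[float, float] = field(default_factory=dict)
    kind: str = "empirical"


def fit_reference(
    wt_profiles: np.ndarray | pd.DataFrame,
    k_rule: float | int = 0.90,
    min_profiles: int = 30,
) -> ReferenceModel:
    """PCA on autoscaled wild-type profiles.

    ``k_rule``: a float in (0, 1) retains the smallest k explaining at least
    that cumulative variance fraction (default 0.90); an int fixes k
    directly.  Deterministic up to component sign (which cancels in T2/SPE).
    """
    X = _profiles_matrix(wt_profiles)
    n, p = X.shape
    if n < min_profiles:
        raise ValueError(f"need >= {min_profiles} wild-type profiles, got {n}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if (scale == 0).any():
        raise ValueError("degenerate covariance: zero-variance profile variable")
    Xs = (X - mean) / scale
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = np.zeros(p)
    eig[: len(s)] = s**2 / (n - 1)
    ratios = np.cumsum(eig) / eig.sum()
    if isinstance(k_rule, (int, np.integer)) and not isinstance(k_rule, bool):
        k = int(k_rule)
    else:
        k = int(np.searchsorted(ratios, float(k_rule)) + 1)
    if not 0 < k < p:
        raise ValueError(f"retained components k={k} must be in (0, {p})")
    return ReferenceModel(
        mean=mean,
        scale=scale,
        loadings=Vt[:k].T,
        eigenvalues=eig,
        k=k,
        n=n,
        explained=float(ratios[k - 1]),
    )


def _profiles_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        from .profiling import PROFILE_COLUMNS

        cols = [c for c in PROFILE_COLUMNS if c in profiles.columns]
        X = profiles[cols].to_numpy(float) if cols else profiles.to_numpy(float)
    else:
        X = np.asarray(profiles, float)
    return np.atleast_2d(X)


def score(model: ReferenceModel, profile: np.ndarray) -> tuple[float, float]:
    """(T2, SPE) of a single profile."""
    t2, spe = score_many(model, np.atleast_2d(np.asarray(profile, float)))
    return float(t2[0]), float(spe[0])


def score_many(model: ReferenceModel, profiles) -> tuple[np.ndarray, np.ndarray]:
    """(T2, SPE) arrays for a profile matrix."""
    X = _profiles_matrix(profiles)
    if X.shape[1] != model.p:
        raise ValueError(f"profile length {X.shape[1]} != model dimension {model.p}")
    Xs = (X - model.mean) / model.scale
    T = Xs @ model.loadings
    lam = model.eigenvalues[: model.k]
    t2 = np.sum(T**2 / lam, axis=1)
    resid = Xs - T @ model.loadings.T
    spe = np.sum(resid**2, axis=1)
    return t2, spe


def empirical_limits(
    wt_t2: np.ndarray, wt_spe: np.ndarray, percentiles=(95.0, 99.0)
) -> Limits:
    """Order-statistic percentiles of the wild-type score distributions.

    Interpolation is linear between order statistics (plotting positions
    i/(n+1)).  A warning is issued if the sample is too small to resolve the
    requested percentile.
    """
    wt_t2 = np.asarray(wt_t2, float)
    wt_spe = np.asarray(wt_spe, float)
    lim = Limits(kind="empirical")
    for q in percentiles:
        if len(wt_t2) < 100.0 / (100.0 - q):
            warnings.warn(
                f"only {len(wt_t2)} wild-type scores for the {q}th percentile",
                stacklevel=2,
            )
        lim.t2[q] = float(np.percentile(wt_t2, q, method=_PCTL_METHOD))
        lim.spe[q] = float(np.percentile(wt_spe, q, method=_PCTL_METHOD))
    return lim


def theoretical_limits(model: ReferenceModel, alpha: float = 0.01) -> Limits:
    """Distribution-based control limits at level ``alpha``.

    T2: scaled F quantile, ``k (n^2 - 1) / (n (n - k)) * F_{1-alpha}(k, n-k)``.
    SPE: weighted-chi-square approximation ``g * chi2_{1-alpha}(h)`` with
    ``g = theta2/theta1`` and ``h = theta1^2/theta2`` from the residual
    eigenvalues.
    """
    n, k = model.n, model.k
    q = 100.0 * (1 - alpha)
    t2_lim = k * (n**2 - 1) / (n * (n - k)) * stats.f.ppf(1 - alpha, k, n - k)
    th1, th2 = model.theta(1), model.theta(2)
    if th1 == 0:
        warnings.warn("perfect fit: residual eigenvalues all zero, SPE limit = 0", stacklevel=2)
        spe_lim = 0.0
    else:
        g = th2 / th1
        h = th1**2 / th2
        spe_lim = g * stats.chi2.ppf(1 - alpha, h)
    return Limits(t2={q: float(t2_lim)}, spe={q: float(spe_lim)}, kind="theoretical")


def flag(
    t2: np.ndarray,
    spe: np.ndarray,
    limits: Limits,
    percentile: float = 99.0,
    strain_ids=None,
) -> pd.DataFrame:
    """Categorize each strain as none / t2_only / spe_only / both.

    Flagging is strictly "beyond": a score exactly at the limit is not
    flagged.  A strain is a hit when either statistic exceeds its limit.
    """
    t2 = np.asarray(t2, float)
    spe = np.asarray(spe, float)
    t2_lim = limits.t2[percentile]
    spe_lim = limits.spe[percentile]
    over_t2 = t2 > t2_lim
    over_spe = spe > spe_lim
    cat = np.where(
        over_t2 & over_spe, "both", np.where(over_t2, "t2_only", np.where(over_spe, "spe_only", "none"))
    )
    return pd.DataFrame(
        {
            "strain_id": strain_ids if strain_ids is not None else np.arange(len(t2)),
            "t2": t2,
            "spe": spe,
            "t2_limit": t2_lim,
            "spe_limit": spe_lim,
            "flag": cat,
            "hit": over_t2 | over_spe,
        }
    )
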