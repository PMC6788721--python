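"""Stationarity and ensemble-diversity indices, and correlation similarity.

The stationarity index (SI) of one sound summarizes how much its
short-term correlation vector wanders over time:

    SI = 1 - < || c(t) - <c(t)> || > / || <c(t)> ||,

with <.> a time average and ||.|| the vector norm; SI = 1 for a
wide-sense-stationary texture, and it decreases as moment-to-moment
correlation structure varies.  The category diversity index (CDI)
applies the same normalized-deviation construction across the members of
a sound ensemble, using each member's time-averaged correlation vector:

    CDI = E_n[ || c_n - E[c_n] || ] / || E[c_n] ||.

Both are invariant to common scaling because the underlying correlations
are normalized.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .correlation import ShortTermCorrelation, decompose_correlation

__all__ = [
    "correlation_trajectory",
    "stationarity_index",
    "category_diversity_index",
    "correlation_similarity",
]


def correlation_trajectory(stc: ShortTermCorrelation) -> np.ndarray:
    """Vectorized short-term correlation c(t): (n_valid_times, M * L^2)."""
    x = decompose_correlation(stc, "spectrotemporal")
    if stc.valid is not None:
        x = x[stc.valid]
    return x


def stationarity_index(traj: np.ndarray) -> float:
    """SI in [0, 1] from a time-indexed correlation-vector trajectory.

    Parameters
    ----------
    traj : numpy.ndarray
        ``(n_times, dim)`` trajectory; use :func:`correlation_trajectory`
        to build it from a :class:`ShortTermCorrelation`.

    Raises
    ------
    ValueError
        With fewer than two time points, or when the time-averaged
        correlation vector has zero norm (the index is undefined).
    """
    x = np.asarray(traj, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_times >= 2, dim) trajectory")
    mean = x.mean(axis=0)
    denom = np.linalg.norm(mean)
    if denom == 0:
        raise ValueError("zero mean-correlation norm: SI undefined")
    dev = np.linalg.norm(x - mean, axis=1).mean()
    return float(np.clip(1.0 - dev / denom, 0.0, 1.0))


def category_diversity_index(category_means: np.ndarray) -> float:
    """CDI >= 0 from the members' time-averaged correlation vectors.

    ``category_means`` is ``(n_members, dim)``.  The ensemble expectation
    is taken of the deviation *norms* (mean deviation across members,
    normalized by the norm of the ensemble mean).
    """
    x = np.asarray(category_means, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("CDI requires >= 2 ensemble members")
    mean = x.mean(axis=0)
    denom = np.linalg.norm(mean)
    if denom == 0:
        raise ValueError("zero ensemble-mean norm: CDI undefined")
    return float(np.linalg.norm(x - mean, axis=1).mean() / denom)


def correlation_similarity(
    c_a: np.ndarray,
    c_b: np.ndarray,
    exclude_diagonal: bool = False,
    lags: np.ndarray | None = None,
) -> float:
    """Pearson correlation between two correlation structures.

    With ``exclude_diagonal`` and square-matrix inputs, the ``k = l``
    entries are dropped; with ``exclude_diagonal`` and a ``lags`` vector
    matching the leading axis, the zero-lag entries are dropped instead
    (the temporal-profile convention).

    Raises
    ------
    ValueError
        On shape mismatch or constant inputs (undefined coefficient).
    """
    a = np.asarray(c_a, dtype=float)
    b = np.asarray(c_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("correlation structures must have matching shapes")
    if exclude_diagonal:
        if lags is not None:
            keep = np.asarray(lags) != 0
            a, b = a[keep], b[keep]
        elif a.ndim >= 2 and a.shape[-1] == a.shape[-2]:
            L = a.shape[-1]
            off = ~np.eye(L, dtype=bool)
            a, b = a[..., off], b[..., off]
        else:
            raise ValueError("no diagonal to exclude for this shape")
    a, b = a.ravel(), b.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    return float(stats.pearsonr(a, b).statistic)
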