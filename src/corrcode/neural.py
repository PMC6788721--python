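"""Trial-shuffled signal/noise correlation estimators for neural ensembles.

Stimulus-driven (signal) correlation between two recording channels is the
mean windowed cross-correlation across *different* trials,

    Phi_stim_kl(t, tau) = 1/(N(N-1)) sum_{m != n} phi_kl,mn(t, tau),

implemented with the fast shuffled algorithm

    Phi_stim = [N^2 Phi_PSTH - sum_m phi_kl,mm] / (N (N - 1)),

which costs N + 1 windowed correlations per channel pair instead of
N(N-1).  The unshuffled correlogram averages same-trial correlations, and
the noise correlogram is their difference.  All three are normalized by
the trial-averaged windowed second moment of the (globally mean-removed)
responses, which makes

    c_total = c_stim + c_noise,   c_total_kk(t, 0) = 1

hold exactly wherever the channel carries power, while the diagonal
zero-lag entries of c_stim and c_noise individually stay below 1 whenever
trial-to-trial variability is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import (
    valid_time_range,
    windowed_cross_products,
    _windowed_power,
    _windowed_power_lagged,
)
from .synthetic import EnsembleRaster
from .windows import NeuralWindow

__all__ = [
    "CorrelationEstimate",
    "windowed_pair_correlation",
    "shuffled_correlation",
    "unshuffled_correlation",
    "noise_correlation",
    "normalize_correlation",
    "estimate_ensemble_correlations",
    "collapse_correlations",
    "single_trial_correlation",
    "default_lag_grid",
    "neural_centers",
]

DEFAULT_MAX_LAG = 0.1  # seconds; +-100 ms lag range


def default_lag_grid(rate: float, max_lag: float = DEFAULT_MAX_LAG) -> np.ndarray:
    """Symmetric integer lag grid, inclusive of ±max_lag (401 lags at 2 kHz)."""
    h = int(round(max_lag * rate))
    return np.arange(-h, h + 1)


def _centered(raster: EnsembleRaster) -> np.ndarray:
    """Responses with the per-channel, per-trial global mean removed."""
    r = raster.responses
    return r - r.mean(axis=2, keepdims=True)


def neural_centers(
    raster: EnsembleRaster,
    window: NeuralWindow,
    lags: np.ndarray,
    n_points: int | None = None,
    rng=None,
) -> np.ndarray:
    """Valid window-center indices: uniform grid, or random draws if rng given."""
    w2 = window.squared_samples(raster.rate)
    start, stop = valid_time_range(
        raster.responses.shape[2], w2.size, int(np.abs(lags).max())
    )
    if rng is not None:
        n_points = n_points or 100
        return rng.integers(start, stop, size=n_points)
    if n_points is None:
        return np.arange(start, stop, max(w2.size // 2, 1))
    return np.linspace(start, stop - 1, n_points).round().astype(int)


def windowed_pair_correlation(
    r_km: np.ndarray,
    r_ln: np.ndarray,
    window: NeuralWindow,
    rate: float,
    centers: np.ndarray,
    lags: np.ndarray,
) -> np.ndarray:
    """phi_kl,mn(t, tau) for one pair of single-trial responses.

    ``r_km`` and ``r_ln`` are 1-D mean-removed responses; returns an array
    of shape ``(n_centers, n_lags)``.
    """
    w2 = window.squared_samples(rate)
    start, stop = valid_time_range(r_km.size, w2.size, int(np.abs(lags).max()))
    centers = np.asarray(centers, dtype=int)
    if centers.min() < start or centers.max() >= stop:
        raise ValueError("window centers too near the record edges")
    phi = windowed_cross_products(
        r_km[None, :], r_ln[None, :], w2, centers, np.asarray(lags)
    )
    return phi[:, :, 0, 0]


def _same_trial_sum(r: np.ndarray, w2, centers, lags) -> np.ndarray:
    """sum_m phi_kl,mm(t, tau) over trials; r is (L, N, T) mean-removed."""
    out = None
    for m in range(r.shape[1]):
        p = windowed_cross_products(r[:, m], r[:, m], w2, centers, lags)
        out = p if out is None else out + p
    return out


def shuffled_correlation(
    raster: EnsembleRaster,
    window: NeuralWindow,
    centers: np.ndarray,
    lags: np.ndarray | None = None,
) -> np.ndarray:
    """Stimulus-driven correlogram Phi_stim via the fast shuffled algorithm.

    Returns shape ``(n_centers, n_lags, L, L)``.
    """
    n = raster.n_trials
    if n < 2:
        raise ValueError("shuffled correlation requires >= 2 trials")
    lags = default_lag_grid(raster.rate) if lags is None else np.asarray(lags)
    w2 = window.squared_samples(raster.rate)
    r = _centered(raster)
    psth = r.mean(axis=1)
    phi_psth = windowed_cross_products(psth, psth, w2, centers, lags)
    diag = _same_trial_sum(r, w2, centers, lags)
    return (n**2 * phi_psth - diag) / (n * (n - 1))


def unshuffled_correlation(
    raster: EnsembleRaster,
    window: NeuralWindow,
    centers: np.ndarray,
    lags: np.ndarray | None = None,
) -> np.ndarray:
    """Mean same-trial correlogram Phi_unshuffled = (1/N) sum_m phi_kl,mm."""
    lags = default_lag_grid(raster.rate) if lags is None else np.asarray(lags)
    w2 = window.squared_samples(raster.rate)
    r = _centered(raster)
    return _same_trial_sum(r, w2, centers, lags) / raster.n_trials


def noise_correlation(phi_unshuffled: np.ndarray, phi_stim: np.ndarray) -> np.ndarray:
    """Noise correlogram: unshuffled minus shuffled, entrywise."""
    if phi_unshuffled.shape != phi_stim.shape:
        raise ValueError("correlogram shapes do not match")
    return phi_unshuffled - phi_stim


def _response_variances(raster, window, centers, lags):
    """Trial-averaged windowed second moments sig_k^2(t) and sig_l^2(t, tau)."""
    w2 = window.squared_samples(raster.rate)
    r = _centered(raster)
    sig_k = np.zeros((len(centers), raster.n_channels))
    sig_l = np.zeros((len(centers), len(lags), raster.n_channels))
    for m in range(raster.n_trials):
        sig_k += _windowed_power(r[:, m], w2, np.asarray(centers, int))
        sig_l += _windowed_power_lagged(
            r[:, m], w2, np.asarray(centers, int), np.asarray(lags)
        )
    return sig_k / raster.n_trials, sig_l / raster.n_trials


def normalize_correlation(
    phi: np.ndarray,
    raster: EnsembleRaster,
    window: NeuralWindow,
    centers: np.ndarray,
    lags: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize a correlogram to a correlation coefficient.

    ``c = Phi / sqrt(sig_k^2(t) sig_l^2(t, tau))``; zero-variance points
    are set to 0.  Raises if the variance vanishes everywhere.
    """
    lags = default_lag_grid(raster.rate) if lags is None else np.asarray(lags)
    sig_k, sig_l = _response_variances(raster, window, centers, lags)
    denom = np.sqrt(sig_k[:, None, :, None] * sig_l[:, :, None, :])
    if not (denom > 0).any():
        raise ValueError("response variance is zero everywhere")
    c = np.zeros_like(phi)
    np.divide(phi, denom, out=c, where=denom > 0)
    return c


@dataclass
class CorrelationEstimate:
    """Shuffled/unshuffled/noise correlograms and their normalized forms."""

    phi_stim: np.ndarray
    phi_unshuffled: np.ndarray
    phi_noise: np.ndarray
    c_stim: np.ndarray
    c_noise: np.ndarray
    c_total: np.ndarray
    centers: np.ndarray
    lags: np.ndarray  # seconds
    rate: float
    window: NeuralWindow = field(default_factory=NeuralWindow)

    @property
    def zero_lag_index(self) -> int:
        return int(np.argmin(np.abs(self.lags)))


def estimate_ensemble_correlations(
    raster: EnsembleRaster,
    window: NeuralWindow | None = None,
    centers: np.ndarray | None = None,
    lags: np.ndarray | None = None,
    n_points: int | None = None,
) -> CorrelationEstimate:
    """Full signal/noise correlation decomposition of a raster."""
    window = window or NeuralWindow()
    lag_idx = default_lag_grid(raster.rate) if lags is None else np.asarray(lags)
    if centers is None:
        centers = neural_centers(raster, window, lag_idx, n_points)
    phi_stim = shuffled_correlation(raster, window, centers, lag_idx)
    phi_unsh = unshuffled_correlation(raster, window, centers, lag_idx)
    phi_noise = noise_correlation(phi_unsh, phi_stim)
    c_stim = normalize_correlation(phi_stim, raster, window, centers, lag_idx)
    c_total = normalize_correlation(phi_unsh, raster, window, centers, lag_idx)
    return CorrelationEstimate(
        phi_stim=phi_stim,
        phi_unshuffled=phi_unsh,
        phi_noise=phi_noise,
        c_stim=c_stim,
        c_noise=c_total - c_stim,
        c_total=c_total,
        centers=np.asarray(centers),
        lags=lag_idx / raster.rate,
        rate=raster.rate,
        window=window,
    )


def single_trial_correlation(
    raster: EnsembleRaster,
    trial: int,
    window: NeuralWindow,
    centers: np.ndarray,
    lags: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized single-trial correlogram c_total for one trial.

    The per-trial windowed second moments are used for normalization, so
    the result is bounded in [-1, 1] and the diagonal zero-lag entries
    equal 1 wherever the trial carries power.
    """
    lags = default_lag_grid(raster.rate) if lags is None else np.asarray(lags)
    w2 = window.squared_samples(raster.rate)
    r = _centered(raster)[:, trial]
    centers = np.asarray(centers, dtype=int)
    phi = windowed_cross_products(r, r, w2, centers, lags)
    sig_k = _windowed_power(r, w2, centers)
    sig_l = _windowed_power_lagged(r, w2, centers, lags)
    denom = np.sqrt(sig_k[:, None, :, None] * sig_l[:, :, None, :])
    c = np.zeros_like(phi)
    np.divide(phi, denom, out=c, where=denom > 0)
    return c


def collapse_correlations(c: np.ndarray, mode: str) -> np.ndarray:
    """Collapse correlation estimates along their principal dimension.

    ``mode="spectral"``: a channel x channel matrix (or stack of them) is
    averaged along its diagonals, giving a channel-offset profile of length
    L (offset 0 ... L-1, both signs pooled).

    ``mode="temporal"``: a ``(..., n_lags, L, L)`` tensor's same-channel
    correlations are averaged over channels, giving a lag profile.

    Collapsing enables averaging across ensembles whose frequency ranges
    differ.
    """
    c = np.asarray(c)
    if mode == "spectral":
        L = c.shape[-1]
        if c.shape[-2] != L:
            raise ValueError("spectral collapse needs a square channel grid")
        out = np.empty(c.shape[:-2] + (L,))
        ii, jj = np.indices((L, L))
        d = np.abs(ii - jj)
        for off in range(L):
            mask = d == off
            out[..., off] = c[..., mask].mean(axis=-1)
        return out
    if mode == "temporal":
        L = c.shape[-1]
        auto = c[..., np.arange(L), np.arange(L)]  # (..., n_lags, L)
        return auto.mean(axis=-1)
    raise ValueError(f"unknown mode {mode!r}")
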