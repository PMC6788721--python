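"""Correlation feature extraction for the decoders.

Sound-model features come from successive, non-overlapping short-term
analysis windows of a cochleogram; neural features come from windowed
shuffled (noiseless) or single-trial correlograms about randomly selected
time points — and, for the single-trial case, randomly selected trials.
"""

from __future__ import annotations

import numpy as np

from .cochlea import Cochleogram
from .correlation import decompose_correlation, short_term_correlation, valid_time_range
from .neural import (
    default_lag_grid,
    normalize_correlation,
    shuffled_correlation,
    single_trial_correlation,
)
from .synthetic import EnsembleRaster
from .windows import NeuralWindow, WindowSpec

__all__ = [
    "sound_features",
    "neural_features",
    "neural_spectrum_features",
    "draw_sample_points",
    "shuffle_tonotopy",
    "spectrum_features",
]


def _upper_triangle(c_zero_lag: np.ndarray) -> np.ndarray:
    L = c_zero_lag.shape[-1]
    iu = np.triu_indices(L)
    return c_zero_lag[..., iu[0], iu[1]]


def sound_features(
    coch: Cochleogram,
    window: WindowSpec,
    mode: str,
) -> tuple[np.ndarray, int]:
    """Per-sound observation matrix from non-overlapping analysis windows.

    Returns ``(X, obs_per_window)``.  Rows are ordered by window onset so
    a duration of ``N`` segments corresponds to the first
    ``N * obs_per_window`` rows.  ``obs_per_window`` is 1 for spectral,
    spectrum and spectro-temporal features and ``L`` for temporal features
    (each channel's lag profile is a separate observation, so temporal
    information is not tied to a particular frequency channel).
    """
    env = coch.envelopes
    rate = coch.envelope_rate
    w2 = window.squared_samples(rate)
    lag_max = int(window.lag_samples(rate).max())
    start, stop = valid_time_range(env.shape[0], w2.size, lag_max)
    centers = np.arange(start, stop, w2.size)  # non-overlapping segments
    if centers.size == 0:
        raise ValueError("window exceeds the record length")
    if mode == "spectrum":
        h0 = w2.size // 2
        w = w2 / w2.sum()
        X = np.stack(
            [w @ env[c - h0 : c - h0 + w2.size] for c in centers]
        )
        return X, 1
    stc = short_term_correlation(env, rate, window, centers=centers)
    X = decompose_correlation(stc, mode)
    per = coch.n_channels if mode == "temporal" else 1
    return X, per


def spectrum_features(
    coch: Cochleogram, window: WindowSpec
) -> tuple[np.ndarray, int]:
    """Windowed per-channel mean amplitude of the cochleogram (rate code)."""
    return sound_features(coch, window, "spectrum")


def _corr_to_features(c: np.ndarray, mode: str, lags: np.ndarray) -> np.ndarray:
    """Vectorize (n, n_lags, L, L) correlograms per neural feature mode."""
    n, m, L, _ = c.shape
    if mode == "spectral":
        j0 = int(np.argmin(np.abs(lags)))
        return _upper_triangle(c[:, j0])
    if mode == "temporal":
        auto = c[:, :, np.arange(L), np.arange(L)]  # (n, m, L)
        return auto.transpose(0, 2, 1).reshape(n, L * m)
    raise ValueError(f"unknown neural feature mode {mode!r}")


def draw_sample_points(
    raster: EnsembleRaster,
    window: NeuralWindow,
    n_samples: int,
    rng: np.random.Generator,
    max_lag: float = 0.1,
    time_range: tuple[float, float] = (0.0, 1.0),
    with_trials: bool = False,
):
    """Random valid window centers (and optionally trial indices).

    ``time_range`` restricts the draw to a fraction of the record — e.g.
    ``(0, 0.5)`` for model generation on the first half and ``(0.5, 1)``
    for validation on the second.
    """
    lags = default_lag_grid(raster.rate, max_lag)
    w2 = window.squared_samples(raster.rate)
    n_time = raster.responses.shape[2]
    start, stop = valid_time_range(n_time, w2.size, int(np.abs(lags).max()))
    lo = max(start, int(time_range[0] * n_time))
    hi = min(stop, int(time_range[1] * n_time))
    if hi <= lo:
        raise ValueError("time_range leaves no valid window centers")
    centers = rng.integers(lo, hi, size=n_samples)
    if with_trials:
        return centers, rng.integers(0, raster.n_trials, size=n_samples)
    return centers


def neural_features(
    raster: EnsembleRaster,
    mode: str,
    window: NeuralWindow,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
    centers: np.ndarray | None = None,
    trials: np.ndarray | None = None,
    provenance: str = "shuffled",
    max_lag: float = 0.1,
    time_range: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Correlation feature vectors about randomly selected time points.

    ``provenance="shuffled"`` draws noiseless (trial-shuffled,
    stimulus-driven) correlations; ``"single_trial"`` draws same-trial
    correlograms with the trial index randomized jointly with the time
    point.  ``mode`` is ``"spectral"`` (zero-lag upper triangle),
    ``"temporal"`` (per-channel lag profiles concatenated in tonotopic
    order), or ``"spectrum"`` (windowed per-channel mean response).

    Either pass ``rng`` and ``n_samples`` to draw sample points, or pass
    explicit ``centers`` (plus ``trials`` for single-trial provenance) —
    e.g. to evaluate spectral and temporal features at identical draws for
    the model-averaged decoder.
    """
    lags = default_lag_grid(raster.rate, max_lag)
    if centers is None:
        if rng is None or n_samples is None:
            raise ValueError("pass either centers or (rng, n_samples)")
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        centers, trials = draw_sample_points(
            raster, window, n_samples, rng, max_lag, time_range, with_trials=True
        )
    elif trials is None and provenance == "single_trial":
        if rng is None:
            raise ValueError("single-trial features need trials or rng")
        trials = rng.integers(0, raster.n_trials, size=len(centers))
    centers = np.asarray(centers, dtype=int)
    n_samples = len(centers)
    w2 = window.squared_samples(raster.rate)
    if mode == "spectrum":
        h0 = w2.size // 2
        w = w2 / w2.sum()
        if provenance == "single_trial":
            rows = [
                raster.responses[:, tr, c - h0 : c - h0 + w2.size] @ w
                for c, tr in zip(centers, trials)
            ]
        else:
            psth = raster.psth()
            rows = [psth[:, c - h0 : c - h0 + w2.size] @ w for c in centers]
        return np.stack(rows)
    if provenance == "shuffled":
        phi = shuffled_correlation(raster, window, centers, lags)
        c = normalize_correlation(phi, raster, window, centers, lags)
        return _corr_to_features(c, mode, lags)
    if provenance == "single_trial":
        rows = [None] * n_samples
        for tr in np.unique(trials):
            idx = np.flatnonzero(trials == tr)
            c = single_trial_correlation(raster, int(tr), window, centers[idx], lags)
            f = _corr_to_features(c, mode, lags)
            for j, i in enumerate(idx):
                rows[i] = f[j]
        return np.stack(rows)
    raise ValueError(f"unknown provenance {provenance!r}")


def neural_spectrum_features(
    raster: EnsembleRaster,
    window: NeuralWindow,
    rng: np.random.Generator,
    n_samples: int,
    provenance: str = "shuffled",
    **kwargs,
) -> np.ndarray:
    """Per-channel time-averaged response in random windows (rate code)."""
    return neural_features(
        raster, "spectrum", window, rng, n_samples, provenance=provenance, **kwargs
    )


def shuffle_tonotopy(
    features: np.ndarray, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomly permute the channel blocks of temporal feature vectors.

    Each observation gets an independent channel permutation; the
    within-channel lag profiles are preserved exactly.  Used on validation
    data only, to destroy tonotopic cues while keeping temporal ones.
    """
    X = np.asarray(features)
    n, d = X.shape
    if d % n_channels:
        raise ValueError(
            f"feature dimension {d} is not divisible into {n_channels} "
            "channel blocks"
        )
    blocks = X.reshape(n, n_channels, d // n_channels)
    out = np.empty_like(blocks)
    for i in range(n):
        out[i] = blocks[i, rng.permutation(n_channels)]
    return out.reshape(n, d)
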