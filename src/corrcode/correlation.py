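"""Short-term (time-varying) correlation statistics of cochleograms.

The central quantity is the running short-term correlation between two
envelope channels,

    Phi_kl(t, tau) = sum_g S_k(g) S_l(g - tau) W^2(t - g),

normalized by the windowed second moments

    sig_k^2(t)      = sum_g S_k(g)^2      W^2(t - g)
    sig_l^2(t, tau) = sum_g S_l(g - tau)^2 W^2(t - g)

so that c_kl = Phi / sqrt(sig_k^2 sig_l^2) is bounded in [-1, 1] by the
Cauchy-Schwarz inequality and c_kk(t, 0) = 1 wherever the channel carries
power.  Envelopes are *not* mean-removed: cochlear envelopes are
nonnegative, and the un-centered statistic is the one the downstream
stationarity/diversity indices and classifiers consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .windows import WindowSpec

__all__ = [
    "ShortTermCorrelation",
    "short_term_correlation",
    "decompose_correlation",
    "time_average_correlation",
    "windowed_cross_products",
    "valid_time_range",
]


def _sliding(x: np.ndarray, width: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, width, axis=-1)


def valid_time_range(n_time: int, n_window: int, max_lag: int) -> tuple[int, int]:
    """First and one-past-last valid window-center indices.

    A center ``t`` is valid when the window support and every lagged copy of
    the second channel lie fully inside the record.
    """
    h0 = n_window // 2
    start = h0 + max_lag
    stop = n_time - (n_window - 1 - h0) - max_lag
    if stop <= start:
        raise ValueError(
            f"record of {n_time} samples is too short for a {n_window}-sample "
            f"window with ±{max_lag}-sample lags"
        )
    return start, stop


def windowed_cross_products(
    a: np.ndarray,
    b: np.ndarray,
    w2: np.ndarray,
    centers: np.ndarray,
    lags: np.ndarray,
) -> np.ndarray:
    """Windowed lagged cross-products between two multichannel records.

    Computes ``Phi[i, j, k, l] = sum_g a_k(g) b_l(g - lags[j]) w2(c_i - g)``
    for every window center ``c_i`` via one BLAS matrix product per center.

    Parameters
    ----------
    a, b : numpy.ndarray
        Arrays of shape ``(n_channels, n_time)``.
    w2 : numpy.ndarray
        Squared-window samples (length ``n_window``).
    centers : numpy.ndarray
        Integer window-center indices (validated by the caller).
    lags : numpy.ndarray
        Integer lags, applied to ``b``.

    Returns
    -------
    numpy.ndarray
        Tensor of shape ``(n_centers, n_lags, n_channels_a, n_channels_b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    la, lb = a.shape[0], b.shape[0]
    nw = w2.size
    m = lags.size
    h0 = nw // 2
    sl = _sliding(b, nw)  # (lb, n_time - nw + 1, nw)
    out = np.empty((centers.size, m, la, lb))
    for i, c in enumerate(np.asarray(centers, dtype=int)):
        g0 = c - h0
        u = a[:, g0 : g0 + nw] * w2  # (la, nw)
        v = sl[:, g0 - lags, :].reshape(lb * m, nw)  # (lb*m, nw)
        out[i] = (u @ v.T).reshape(la, lb, m).transpose(2, 0, 1)
    return out


def _windowed_power(
    x: np.ndarray, w2: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """``sig[i, k] = sum_g x_k(g)^2 w2(c_i - g)`` — unlagged windowed power."""
    nw = w2.size
    h0 = nw // 2
    out = np.empty((centers.size, x.shape[0]))
    for i, c in enumerate(np.asarray(centers, dtype=int)):
        out[i] = (x[:, c - h0 : c - h0 + nw] ** 2) @ w2
    return out


def _windowed_power_lagged(
    x: np.ndarray, w2: np.ndarray, centers: np.ndarray, lags: np.ndarray
) -> np.ndarray:
    """``sig[i, j, l] = sum_g x_l(g - lags[j])^2 w2(c_i - g)``."""
    nw = w2.size
    h0 = nw // 2
    sl = _sliding(x, nw)
    out = np.empty((centers.size, lags.size, x.shape[0]))
    for i, c in enumerate(np.asarray(centers, dtype=int)):
        seg = sl[:, (c - h0) - lags, :]  # (L, M, nw)
        out[i] = ((seg**2) @ w2).T
    return out


@dataclass
class ShortTermCorrelation:
    """Normalized short-term correlation tensor with its sampling metadata.

    Attributes
    ----------
    values : numpy.ndarray
        ``c_kl(t, tau)`` with shape ``(n_times, n_lags, L, L)``; bounded in
        ``[-1, 1]``.
    times : numpy.ndarray
        Window-center times in seconds.
    lags : numpy.ndarray
        Correlation delays in seconds (symmetric about zero).
    rate : float
        Sample rate of the underlying envelopes in Hz.
    channel_freqs : numpy.ndarray or None
        Center frequencies of the channels, when known.
    window : WindowSpec
        The analysis window that produced the estimate.
    valid : numpy.ndarray
        Boolean mask per time point; False where a channel had zero windowed
        power (those entries of ``values`` are set to 0).
    """

    values: np.ndarray
    times: np.ndarray
    lags: np.ndarray
    rate: float
    channel_freqs: np.ndarray | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    valid: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    @property
    def n_lags(self) -> int:
        return self.values.shape[1]

    @property
    def zero_lag_index(self) -> int:
        return int(np.argmin(np.abs(self.lags)))


def short_term_correlation(
    envelopes: np.ndarray,
    rate: float,
    window: WindowSpec | None = None,
    hop: int | None = None,
    centers: np.ndarray | None = None,
    channel_freqs: np.ndarray | None = None,
) -> ShortTermCorrelation:
    """Normalized short-term spectro-temporal correlation of an envelope set.

    Parameters
    ----------
    envelopes : numpy.ndarray
        Cochleogram-like matrix, shape ``(n_time, n_channels)``; values are
        expected nonnegative but this is not enforced.
    rate : float
        Envelope sample rate in Hz (1 kHz for the cochlear model output).
    window : WindowSpec
        Analysis window; defaults to a Kaiser (beta 3.4) window of 100 ms
        resolution.
    hop : int, optional
        Stride, in samples, between evaluated window centers.  Defaults to a
        quarter of the window length.  Ignored when ``centers`` is given.
    centers : numpy.ndarray, optional
        Explicit window-center sample indices.

    Raises
    ------
    ValueError
        If fewer than two channels are provided or the record is shorter
        than the window plus its lag margins.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.ndim != 2 or env.shape[1] < 2:
        raise ValueError("envelopes must be (n_time, n_channels) with >= 2 channels")
    window = window or WindowSpec()
    w2 = window.squared_samples(rate)
    lag_idx = window.lag_samples(rate)
    x = env.T  # (L, T)
    start, stop = valid_time_range(x.shape[1], w2.size, int(lag_idx.max()))
    if centers is None:
        hop = hop or max(w2.size // 4, 1)
        centers = np.arange(start, stop, hop)
    else:
        centers = np.asarray(centers, dtype=int)
        if centers.min() < start or centers.max() >= stop:
            raise ValueError("requested centers fall outside the valid range")

    phi = windowed_cross_products(x, x, w2, centers, lag_idx)
    sig_k = _windowed_power(x, w2, centers)  # (nt, L)
    sig_l = _windowed_power_lagged(x, w2, centers, lag_idx)  # (nt, M, L)
    denom = np.sqrt(sig_k[:, None, :, None] * sig_l[:, :, None, :])
    ok = denom > 0
    c = np.zeros_like(phi)
    np.divide(phi, denom, out=c, where=ok)
    valid = ok.all(axis=(1, 2, 3))
    return ShortTermCorrelation(
        values=c,
        times=centers / rate,
        lags=lag_idx / rate,
        rate=rate,
        channel_freqs=channel_freqs,
        window=window,
        valid=valid,
    )


def decompose_correlation(stc: ShortTermCorrelation, mode: str) -> np.ndarray:
    """Extract a feature view from a short-term correlation tensor.

    Modes
    -----
    ``"spectral"``
        Zero-lag correlations ``c_kl(t, 0)``; the upper triangle including
        the diagonal is vectorized, giving ``L (L + 1) / 2`` features per
        time point.
    ``"temporal"``
        Same-channel correlations ``c_kk(t, tau)`` for ``tau >= 0``; each
        (time point, channel) pair is one observation, so the result has
        ``n_times * L`` rows.
    ``"spectrotemporal"``
        The full tensor vectorized, ``n_lags * L**2`` features per time
        point.
    """
    c = stc.values
    nt, m, L, _ = c.shape
    if mode == "spectral":
        iu = np.triu_indices(L)
        return c[:, stc.zero_lag_index][:, iu[0], iu[1]]
    if mode == "temporal":
        pos = stc.lags >= 0
        auto = c[:, :, np.arange(L), np.arange(L)]  # (nt, m, L)
        return auto[:, pos, :].transpose(0, 2, 1).reshape(nt * L, -1)
    if mode == "spectrotemporal":
        return c.reshape(nt, m * L * L)
    raise ValueError(f"unknown mode {mode!r}")


def time_average_correlation(
    stc: ShortTermCorrelation,
) -> tuple[np.ndarray, dict]:
    """Mean of ``c_kl(t, tau)`` over valid time points, plus width summaries.

    Returns the averaged ``(n_lags, L, L)`` tensor and a dict with the
    temporal-correlation half-widths: full widths (seconds) at 50% and 10%
    of the zero-lag maximum of the channel-averaged autocorrelation.
    """
    mask = stc.valid if stc.valid is not None else np.ones(len(stc.times), bool)
    if not mask.any():
        raise ValueError("no valid time points to average")
    avg = stc.values[mask].mean(axis=0)
    L = avg.shape[-1]
    auto = avg[:, np.arange(L), np.arange(L)].mean(axis=1)  # (n_lags,)
    widths = {
        "half_width_50": _full_width(stc.lags, auto, 0.5),
        "half_width_10": _full_width(stc.lags, auto, 0.1),
    }
    return avg, widths


def _full_width(lags: np.ndarray, profile: np.ndarray, frac: float) -> float:
    """Full width of a lag profile at ``frac`` of its peak-to-floor range.

    Un-centered envelope correlations decay to a positive floor rather
    than zero, so widths are measured on the range-normalized profile.
    """
    profile = profile - profile.min()
    peak = profile.max()
    if peak <= 0:
        return float("nan")
    thresh = frac * peak
    i0 = int(np.argmax(profile))
    # walk right from the peak
    right = lags[-1] - lags[i0]
    for i in range(i0, len(profile) - 1):
        if profile[i + 1] < thresh <= profile[i]:
            f = (profile[i] - thresh) / (profile[i] - profile[i + 1])
            right = (lags[i] + f * (lags[i + 1] - lags[i])) - lags[i0]
            break
    left = lags[i0] - lags[0]
    for i in range(i0, 0, -1):
        if profile[i - 1] < thresh <= profile[i]:
            f = (profile[i] - thresh) / (profile[i] - profile[i - 1])
            left = lags[i0] - (lags[i] - f * (lags[i] - lags[i - 1]))
            break
    return float(left + right)
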