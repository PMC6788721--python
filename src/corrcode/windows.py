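"""Analysis windows for short-term correlation estimation.

Two window families are used throughout the package:

* sound statistics use a Kaiser-squared window ``W^2`` whose *temporal
  resolution* ``tau_w`` is defined as twice the temporal standard deviation
  of the normalized window treated as a density;
* neural correlograms use a unit-amplitude rectangular window of duration
  ``T`` (for which ``W^2 = W``).

The engine in :mod:`corrcode.correlation` consumes the squared window
directly, so all functions here return ``W^2`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows


def _two_sigma_width(w2: np.ndarray) -> float:
    """2-SD width (in samples) of a nonnegative window treated as a density."""
    n = w2.size
    t = np.arange(n, dtype=float)
    p = w2 / w2.sum()
    mu = t @ p
    var = ((t - mu) ** 2) @ p
    return 2.0 * np.sqrt(var)


def kaiser_window_from_resolution(
    tau_w: float, beta: float = 3.4, sample_rate: float = 1000.0
) -> np.ndarray:
    """Return ``W^2`` samples of a Kaiser window with a given 2-SD resolution.

    The window length is solved numerically so that the temporal standard
    deviation of the normalized Kaiser(beta) window satisfies
    ``2 * SD = tau_w``.

    Parameters
    ----------
    tau_w : float
        Temporal resolution in seconds (two standard deviations of the
        window density).
    beta : float
        Kaiser shape parameter. The limit ``beta -> 0`` recovers a
        rectangular window of length ``sqrt(3) * tau_w``.
    sample_rate : float
        Rate at which the window is sampled, in Hz.

    Returns
    -------
    numpy.ndarray
        The squared-window samples ``W^2`` (the Kaiser window itself).

    Raises
    ------
    ValueError
        If the requested resolution is below four sample periods and is
        therefore unattainable at this rate.
    """
    target = tau_w * sample_rate
    if target < 4.0:
        raise ValueError(
            f"resolution tau_w={tau_w} s is below 4 sample periods at "
            f"{sample_rate} Hz; increase tau_w or the sample rate"
        )
    # 2-SD width grows monotonically with window length: bisect on length.
    lo, hi = 4, 8
    while _two_sigma_width(windows.kaiser(hi, beta)) < target:
        hi *= 2
        if hi > 10_000_000:  # pragma: no cover - absurd request
            raise ValueError("unattainable window resolution")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _two_sigma_width(windows.kaiser(mid, beta)) < target:
            lo = mid
        else:
            hi = mid
    # pick the closer of the two bracketing lengths
    wlo, whi = windows.kaiser(lo, beta), windows.kaiser(hi, beta)
    dlo = abs(_two_sigma_width(wlo) - target)
    dhi = abs(_two_sigma_width(whi) - target)
    return wlo if dlo <= dhi else whi


@dataclass
class WindowSpec:
    """Short-term analysis window for sound-correlation statistics.

    Attributes
    ----------
    kind : str
        ``"kaiser"`` or ``"rectangular"``.
    beta : float
        Kaiser shape parameter (ignored for rectangular windows).
    resolution : float
        Temporal resolution ``tau_w`` in seconds (the 2-SD width).
    max_lag : float or None
        Largest correlation delay in seconds; defaults to ``resolution / 2``.
    """

    kind: str = "kaiser"
    beta: float = 3.4
    resolution: float = 0.1
    max_lag: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.max_lag is None:
            self.max_lag = self.resolution / 2.0

    def squared_samples(self, sample_rate: float) -> np.ndarray:
        """``W^2`` sampled at ``sample_rate``."""
        if self.kind == "kaiser":
            return kaiser_window_from_resolution(
                self.resolution, self.beta, sample_rate
            )
        if self.kind == "rectangular":
            n = max(int(round(self.resolution * sample_rate)), 1)
            return np.ones(n)
        raise ValueError(f"unknown window kind {self.kind!r}")

    def lag_samples(self, sample_rate: float) -> np.ndarray:
        """Integer lag grid, strictly inside ``±max_lag``.

        At ``tau_w = 100`` ms and a 1 kHz envelope rate this yields 99 lags
        (−49 … +49 samples), the lag count used for the stationarity-index
        vectorization.
        """
        h = int(round(self.max_lag * sample_rate))
        h = max(h, 1)
        return np.arange(-(h - 1), h)


@dataclass
class NeuralWindow:
    """Unit-amplitude rectangular window for neural correlograms."""

    duration: float = 0.5  # seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def squared_samples(self, sample_rate: float) -> np.ndarray:
        n = max(int(round(self.duration * sample_rate)), 1)
        return np.ones(n)


def half_octave_ladder(lo: float, hi: float) -> np.ndarray:
    """Geometric ladder from ``lo`` to ``hi`` in half-octave (sqrt 2) steps."""
    n = int(np.floor(np.log2(hi / lo) * 2 + 1e-9)) + 1
    return lo * 2.0 ** (np.arange(n) / 2.0)
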