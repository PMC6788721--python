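"""Signal preprocessing: aMUA envelope extraction and 1/f equalization.

aMUA (analog multiunit activity) is the continuous envelope of the
band-passed extracellular voltage — band-pass 325–3000 Hz (the band
occupied by action potentials), full-wave rectify, low-pass at 475 Hz,
resample to 2 kHz.  All filters are linear-phase FIRs (125 Hz transition
bands, >= 60 dB stopband) with group delay compensated.

1/f equalization imposes a common 1/f *power* spectrum on a set of sounds
("equal power per octave"), removing spectral cues while preserving the
modulation structure.  The inversion filter is zero-phase, built from a
Welch estimate of each sound's magnitude spectrum, and gain-normalized so
the output RMS equals the input RMS.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

__all__ = ["extract_amua", "welch_spectrum", "equalize_spectrum_1f"]

AMUA_RATE = 2000.0  # Hz


def _fir(fs: float, cutoff, pass_zero, transition: float = 125.0,
         atten_db: float = 60.0) -> np.ndarray:
    ntaps, beta = signal.kaiserord(atten_db, transition / (fs / 2.0))
    ntaps |= 1
    return signal.firwin(ntaps, cutoff, window=("kaiser", beta),
                         pass_zero=pass_zero, fs=fs)


def _filtfir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Linear-phase FIR filtering with group delay removed."""
    d = (h.size - 1) // 2
    y = signal.fftconvolve(x, h)[d : d + x.size]
    if y.size < x.size:  # pragma: no cover
        y = np.pad(y, (0, x.size - y.size))
    return y


def extract_amua(
    trace: np.ndarray, fs: float, out_rate: float = AMUA_RATE
) -> np.ndarray:
    """aMUA envelope of a raw voltage trace, resampled to ``out_rate``.

    Raises
    ------
    ValueError
        If ``fs < 6000`` Hz (the 325–3000 Hz spike band would alias).
    """
    if fs < 6000:
        raise ValueError(f"fs={fs:g} Hz is too low; need >= 6 kHz")
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    bp = _fir(fs, [325.0, 3000.0], pass_zero=False)
    lp = _fir(fs, 475.0, pass_zero=True)
    env = _filtfir(np.abs(_filtfir(x, bp)), lp)
    q = fs / out_rate
    if abs(q - round(q)) < 1e-9:
        return env[:: int(round(q))]
    from fractions import Fraction

    frac = Fraction(int(round(out_rate)), int(round(fs)))
    return signal.resample_poly(env, frac.numerator, frac.denominator)


def welch_spectrum(
    sound: np.ndarray,
    fs: float,
    resolution: float = 10.0,
    sidelobe_db: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged magnitude spectrum at a given frequency resolution.

    Returns ``(freqs, magnitude)`` where ``magnitude`` is the square root
    of the Welch power spectral density; the window is a Kaiser achieving
    at least ``sidelobe_db`` of sidelobe suppression.

    Raises
    ------
    ValueError
        If the record is shorter than two analysis windows.
    """
    x = np.asarray(sound, dtype=float)
    nperseg = int(round(fs / resolution))
    if x.size < 2 * nperseg:
        raise ValueError(
            f"record too short: need >= {2 * nperseg} samples for a "
            f"{resolution:g} Hz resolution at fs={fs:g}"
        )
    beta = signal.kaiser_beta(sidelobe_db)
    f, pxx = signal.welch(
        x, fs=fs, window=("kaiser", beta), nperseg=nperseg,
        noverlap=nperseg // 2, scaling="density",
    )
    return f, np.sqrt(pxx)


def equalize_spectrum_1f(
    sound: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = None,
    resolution: float = 10.0,
) -> np.ndarray:
    """Equalize a sound to a 1/f power spectrum, preserving its RMS.

    A zero-phase inversion filter with amplitude response
    ``H(f) = C / (S(f) sqrt(f))`` — ``S(f)`` the sound's Welch magnitude
    spectrum — is applied by frequency-domain multiplication over the full
    record, so the output power spectrum is proportional to 1/f inside the
    equalized band (default 50 Hz to 0.45 fs; cosine roll-off outside).
    ``C`` is set so that the output RMS equals the input RMS.

    Spectral bins below ``max(S)/1e5`` inside the band are floored (with a
    warning) to keep the inversion bounded.
    """
    x = np.asarray(sound, dtype=float)
    lo, hi = band if band is not None else (50.0, 0.45 * fs)
    f_est, s_mag = welch_spectrum(x, fs, resolution)
    n = x.size
    f = np.fft.rfftfreq(n, 1.0 / fs)
    s = np.interp(f, f_est, s_mag)
    floor = s_mag.max() / 1e5
    in_band = (f >= lo) & (f <= hi)
    if np.any(s[in_band] < floor):
        warnings.warn(
            "near-zero spectral bins inside the equalized band were floored",
            stacklevel=2,
        )
    s = np.maximum(s, floor)
    h = np.zeros_like(f)
    fsafe = np.maximum(f, lo)
    h[in_band] = 1.0 / (s[in_band] * np.sqrt(fsafe[in_band]))
    # cosine roll-offs: one octave below `lo` and from `hi` to Nyquist
    ramp_lo = (f >= lo / 2) & (f < lo)
    h[ramp_lo] = (
        0.5 * (1 - np.cos(np.pi * (f[ramp_lo] - lo / 2) / (lo / 2)))
        / (s[ramp_lo] * np.sqrt(lo))
    )
    ramp_hi = (f > hi) & (f <= min(fs / 2, hi * 1.3))
    if np.any(ramp_hi):
        width = f[ramp_hi].max() - hi
        h[ramp_hi] = (
            0.5 * (1 + np.cos(np.pi * (f[ramp_hi] - hi) / max(width, 1e-9)))
            / (s[ramp_hi] * np.sqrt(f[ramp_hi]))
        )
    y = np.fft.irfft(np.fft.rfft(x) * h, n=n)
    rms_in = np.sqrt(np.mean(x**2))
    rms_out = np.sqrt(np.mean(y**2))
    if rms_out == 0:
        return y
    return y * (rms_in / rms_out)
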