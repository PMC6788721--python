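"""HDF5 and WAV persistence for cochleograms, rasters and correlograms."""

from __future__ import annotations

import numpy as np
import h5py
from scipy.io import wavfile

from .cochlea import Cochleogram
from .synthetic import EnsembleRaster

__all__ = [
    "read_wav",
    "write_wav",
    "save_cochleogram",
    "load_cochleogram",
    "save_raster",
    "load_raster",
]


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file; integer PCM is scaled to [-1, 1] floats."""
    fs, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim > 1:
        x = x.mean(axis=1)
    if np.issubdtype(x.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    return x.astype(float), float(fs)


def write_wav(path, waveform: np.ndarray, fs: float) -> None:
    wavfile.write(path, int(round(fs)), np.asarray(waveform, dtype=np.float32))


def save_cochleogram(path, coch: Cochleogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("envelopes", data=coch.envelopes)
        f.create_dataset("envelope_rate", data=coch.envelope_rate)
        if coch.channel_freqs is not None:
            f.create_dataset("channel_freqs", data=coch.channel_freqs)


def load_cochleogram(path) -> Cochleogram:
    with h5py.File(path, "r") as f:
        return Cochleogram(
            envelopes=f["envelopes"][()],
            envelope_rate=float(f["envelope_rate"][()]),
            channel_freqs=f["channel_freqs"][()] if "channel_freqs" in f else None,
        )


def save_raster(path, raster: EnsembleRaster) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raster", data=raster.responses)
        f.create_dataset("fs", data=raster.rate)
        if raster.channel_freqs is not None:
            f.create_dataset("channel_freqs", data=raster.channel_freqs)
        truth = f.create_group("truth")
        for key, val in raster.truth.items():
            truth.create_dataset(key, data=val)


def load_raster(path) -> EnsembleRaster:
    with h5py.File(path, "r") as f:
        truth = {k: f["truth"][k][()] for k in f["truth"]} if "truth" in f else {}
        return EnsembleRaster(
            responses=f["raster"][()],
            rate=float(f["fs"][()]),
            channel_freqs=f["channel_freqs"][()] if "channel_freqs" in f else None,
            truth=truth,
        )
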