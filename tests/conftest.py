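import numpy as np
import pytest

import corrcode as cc
from corrcode.synthetic import _banded_corr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bank():
    """Six-channel bank, 250 Hz - 2 kHz, cheap to filter at 16 kHz."""
    return cc.design_filterbank(250.0, 2000.0, step=0.5, max_channels=6)


@pytest.fixture(scope="session")
def texture_cochleogram():
    """A 20 s stationary 6-channel log-normal texture (banded correlation)."""
    spec = cc.TextureSpec(
        n_channels=6,
        duration=20.0,
        target_spectral_corr=_banded_corr(6, 2.0),
        temporal_kernel=cc.TemporalKernel("exponential", 0.01),
        seed=42,
    )
    return cc.gen_correlated_envelopes(spec)


@pytest.fixture(scope="session")
def small_raster():
    """4-channel, 6-trial raster over a fast texture with local noise."""
    spec = cc.TextureSpec(
        n_channels=4,
        duration=4.0,
        envelope_rate=2000.0,
        target_spectral_corr=_banded_corr(4, 2.0),
        temporal_kernel=cc.TemporalKernel("exponential", 0.01),
        seed=7,
    )
    sig = cc.gen_correlated_envelopes(spec).envelopes.T
    noise = cc.NoiseSpec(noise_gain=0.8, spatial_reach=1, temporal_width=0.003, seed=3)
    return cc.gen_ensemble_raster(sig, n_trials=6, noise=noise)
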