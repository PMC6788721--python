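import numpy as np
import pytest

import corrcode as cc
from corrcode.synthetic import (
    _banded_corr,
    gen_category_dataset,
    lognormal_envelope_correlation,
    neighbor_correlation_matrix,
)


def test_determinism_byte_identical():
    spec = cc.TextureSpec(n_channels=4, duration=2.0, seed=3)
    a = cc.gen_correlated_envelopes(spec).envelopes
    b = cc.gen_correlated_envelopes(spec).envelopes
    assert a.tobytes() == b.tobytes()


def test_identity_target_gives_independent_channels():
    spec = cc.TextureSpec(n_channels=6, duration=60.0, seed=1)
    env = cc.gen_correlated_envelopes(spec).envelopes
    corr = np.corrcoef(env.T)
    off = corr[~np.eye(6, dtype=bool)]
    assert np.abs(off).max() < 0.05
    assert env.min() >= 0


def test_rank_one_target_gives_common_modulator():
    spec = cc.TextureSpec(
        n_channels=5, duration=10.0, target_spectral_corr=np.ones((5, 5)), seed=2
    )
    env = cc.gen_correlated_envelopes(spec).envelopes
    corr = np.corrcoef(env.T)
    assert corr[~np.eye(5, dtype=bool)].min() > 0.95


def test_achieved_correlation_matches_monte_carlo_oracle():
    """Adjacent-pair rho = 0.5 against an MC oracle that applies the same
    exponential nonlinearity to bivariate normals of correlation 0.5."""
    rho, s = 0.5, 0.5
    rng = np.random.default_rng(0)
    z1 = rng.standard_normal(400_000)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(400_000)
    oracle = np.corrcoef(np.exp(s * z1), np.exp(s * z2))[0, 1]

    C = np.eye(8)
    for i in range(7):
        C[i, i + 1] = C[i + 1, i] = rho
    spec = cc.TextureSpec(
        n_channels=8, duration=60.0, target_spectral_corr=C, log_std=s, seed=7
    )
    env = cc.gen_correlated_envelopes(spec).envelopes
    corr = np.corrcoef(env.T)
    adj = np.mean([corr[i, i + 1] for i in range(7)])
    assert abs(adj - oracle) < 0.05
    # and the closed form agrees with the MC oracle
    assert abs(lognormal_envelope_correlation(rho, s) - oracle) < 0.01


def test_non_psd_target_raises_with_eigenvalue():
    C = np.eye(3)
    C[0, 1] = C[1, 0] = 0.9
    C[1, 2] = C[2, 1] = 0.9
    C[0, 2] = C[2, 0] = -0.9  # impossible triple
    spec = cc.TextureSpec(n_channels=3, duration=1.0, target_spectral_corr=C)
    with pytest.raises(ValueError, match="eigenvalue"):
        cc.gen_correlated_envelopes(spec)


def test_switching_texture_alternates_regimes():
    base = dict(n_channels=4, duration=0.5, envelope_rate=1000.0)
    fast = cc.TextureSpec(**base, temporal_kernel=cc.TemporalKernel("exponential", 0.003))
    slow = cc.TextureSpec(**base, temporal_kernel=cc.TemporalKernel("exponential", 0.1))
    spec = cc.TextureSpec(
        n_channels=4, duration=4.0, switch_period=0.5, regimes=(fast, slow), seed=5
    )
    env = cc.gen_correlated_envelopes(spec).envelopes
    assert env.shape == (4000, 4)
    # fast segments decorrelate over 30 ms; slow segments do not
    def lag_corr(seg):
        return np.corrcoef(seg[:-30, 0], seg[30:, 0])[0, 1]

    fast_r = np.mean([lag_corr(env[i * 1000 : i * 1000 + 500]) for i in (0, 2)])
    slow_r = np.mean([lag_corr(env[i * 1000 + 500 : (i + 1) * 1000]) for i in (0, 2)])
    assert slow_r > fast_r + 0.3


# --- waveforms -------------------------------------------------------------

def test_single_channel_energy_lands_in_right_band(small_bank):
    env = np.zeros((2000, small_bank.n_channels))
    env[:, 2] = 1.0
    x = cc.gen_waveform_from_envelopes(env, 1000.0, small_bank, 16000.0, seed=0)
    coch = cc.compute_cochleogram(x, 16000.0, small_bank)
    power = (coch.envelopes**2).mean(axis=0)
    assert np.argmax(power) == 2


def test_shared_envelope_raises_cochleogram_correlation(small_bank):
    rates = {"shared": [], "independent": []}
    for seed in range(5):
        rng = np.random.default_rng(seed)
        e = np.exp(0.5 * rng.standard_normal((3000, 2)))
        env_shared = np.zeros((3000, small_bank.n_channels))
        env_shared[:, 1] = e[:, 0]
        env_shared[:, 4] = e[:, 0]
        env_indep = np.zeros_like(env_shared)
        env_indep[:, 1] = e[:, 0]
        env_indep[:, 4] = e[:, 1]
        for name, env in (("shared", env_shared), ("independent", env_indep)):
            x = cc.gen_waveform_from_envelopes(env, 1000.0, small_bank, 16000.0,
                                               seed=seed)
            coch = cc.compute_cochleogram(x, 16000.0, small_bank)
            r = np.corrcoef(coch.envelopes[:, 1], coch.envelopes[:, 4])[0, 1]
            rates[name].append(r)
    diffs = np.array(rates["shared"]) - np.array(rates["independent"])
    assert np.all(diffs > 0)  # every paired seed
    assert diffs.mean() > 0.1


def test_silent_envelopes_give_zero_waveform(small_bank):
    env = np.zeros((1000, small_bank.n_channels))
    x = cc.gen_waveform_from_envelopes(env, 1000.0, small_bank, 16000.0, seed=0)
    assert np.all(x == 0)


def test_waveform_aliasing_guard(small_bank):
    env = np.ones((1000, small_bank.n_channels))
    with pytest.raises(ValueError, match="alias"):
        cc.gen_waveform_from_envelopes(env, 1000.0, small_bank, 2000.0, seed=0)


# --- rasters ---------------------------------------------------------------

def test_zero_noise_gain_gives_identical_trials():
    sig = np.exp(np.random.default_rng(0).standard_normal((4, 3000)) * 0.5)
    raster = cc.gen_ensemble_raster(sig, 5, cc.NoiseSpec(noise_gain=0.0))
    for m in range(5):
        assert np.array_equal(raster.responses[:, m, :], sig)


def test_zero_reach_noise_is_channel_independent():
    raster = cc.gen_ensemble_raster(
        np.zeros((6, 20000)), 20, cc.NoiseSpec(noise_gain=1.0, spatial_reach=0,
                                               seed=2)
    )
    resid = raster.responses - raster.responses.mean(axis=1, keepdims=True)
    flat = resid.reshape(6, -1)
    corr = np.corrcoef(flat)
    assert np.abs(corr[~np.eye(6, dtype=bool)]).max() < 0.05


def test_neighbor_truth_matrix():
    m = neighbor_correlation_matrix(4, 1)
    assert np.allclose(np.diag(m), 1.0)
    assert np.allclose(m[0], [1.0, 0.5, 0.0, 0.0])


def test_raster_trial_guard():
    with pytest.raises(ValueError, match="trials"):
        cc.gen_ensemble_raster(np.zeros((2, 100)), 1, cc.NoiseSpec())


# --- category datasets ------------------------------------------------------

def test_dataset_determinism_and_structure():
    a = gen_category_dataset(3, 2, 0.1, duration=1.0, n_channels=4, seed=9)
    b = gen_category_dataset(3, 2, 0.1, duration=1.0, n_channels=4, seed=9)
    assert len(a) == 6
    for ra, rb in zip(a, b):
        assert ra["envelopes"].envelopes.tobytes() == rb["envelopes"].envelopes.tobytes()
    labels = sorted({r["label"] for r in a})
    assert labels == ["fire", "speech", "water"]


def test_category_means_are_separated():
    records = gen_category_dataset(3, 3, 0.05, duration=4.0, n_channels=6, seed=1)
    means = {}
    for r in records:
        corr = np.corrcoef(r["envelopes"].envelopes.T)
        means.setdefault(r["category"], []).append(corr)
    centroids = {c: np.mean(v, axis=0) for c, v in means.items()}
    for i in range(3):
        for j in range(i + 1, 3):
            dist = np.linalg.norm(centroids[i] - centroids[j])
            assert dist > 0.1  # pairwise category distances all positive


def test_zero_jitter_exemplars_share_parameters():
    records = gen_category_dataset(2, 3, 0.0, duration=1.0, n_channels=4, seed=0)
    fire = [r for r in records if r["category"] == 0]
    corrs = [r["spec"].target_spectral_corr for r in fire]
    for c in corrs[1:]:
        assert np.allclose(c, corrs[0])
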