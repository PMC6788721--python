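import numpy as np
import pytest

import corrcode as cc
from corrcode.neural import (
    collapse_correlations,
    default_lag_grid,
    estimate_ensemble_correlations,
    noise_correlation,
    normalize_correlation,
    shuffled_correlation,
    single_trial_correlation,
    unshuffled_correlation,
    windowed_pair_correlation,
)
from corrcode.windows import NeuralWindow


def _brute_phi(r, k, l, m, n, w2, t, tau):
    """Direct-sum windowed pair correlation (the oracle)."""
    h0 = w2.size // 2
    return sum(
        r[k, m, g] * r[l, n, g - tau] * w2[i]
        for i, g in enumerate(range(t - h0, t - h0 + w2.size))
    )


@pytest.fixture(scope="module")
def toy_raster(rng=None):
    rng = np.random.default_rng(99)
    resp = rng.lognormal(size=(3, 5, 1200))
    return cc.EnsembleRaster(resp, rate=2000.0)


def test_pair_correlation_matches_triple_loop(toy_raster):
    win = NeuralWindow(0.05)
    w2 = win.squared_samples(2000.0)
    lags = np.array([-7, 0, 5])
    r = toy_raster.responses - toy_raster.responses.mean(axis=2, keepdims=True)
    phi = windowed_pair_correlation(r[1, 2], r[2, 4], win, 2000.0,
                                    np.array([600]), lags)
    for j, tau in enumerate(lags):
        brute = _brute_phi(r, 1, 2, 2, 4, w2, 600, tau)
        assert abs(phi[0, j] - brute) <= 1e-12 * max(abs(brute), 1.0)


def test_autocorrelation_identity_full_window(toy_raster):
    """Same trial with itself at zero lag equals windowed energy."""
    win = NeuralWindow(0.05)
    r = toy_raster.responses - toy_raster.responses.mean(axis=2, keepdims=True)
    phi = windowed_pair_correlation(r[0, 0], r[0, 0], win, 2000.0,
                                    np.array([600]), np.array([0]))
    w2 = win.squared_samples(2000.0)
    h0 = w2.size // 2
    energy = (r[0, 0, 600 - h0 : 600 - h0 + w2.size] ** 2) @ w2
    assert np.isclose(phi[0, 0], energy, rtol=1e-12)


def test_orthogonal_sinusoids_have_zero_correlation():
    rate = 2000.0
    t = np.arange(4000) / rate
    # window covering an integer number of cycles of both
    resp = np.stack([np.sin(2 * np.pi * 40 * t), np.cos(2 * np.pi * 40 * t)])
    raster = cc.EnsembleRaster(np.stack([resp, resp], axis=1), rate=rate)
    win = NeuralWindow(0.1)  # 4 cycles of 40 Hz
    phi = shuffled_correlation(raster, win, np.array([2000]), np.array([0]))
    assert abs(phi[0, 0, 0, 1]) < 1e-8 * abs(phi[0, 0, 0, 0])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fast_shuffled_equals_double_sum(seed):
    rng = np.random.default_rng(seed)
    n_tr = rng.integers(2, 9)
    resp = rng.lognormal(size=(4, n_tr, 900))
    raster = cc.EnsembleRaster(resp, rate=2000.0)
    win = NeuralWindow(0.04)
    w2 = win.squared_samples(2000.0)
    lags = np.arange(-10, 11)
    centers = np.array([300, 550])
    fast = shuffled_correlation(raster, win, centers, lags)
    r = resp - resp.mean(axis=2, keepdims=True)
    for ci, t in enumerate(centers):
        for j, tau in enumerate([-10, 0, 7]):
            jj = list(lags).index(tau)
            for k, l in [(0, 1), (2, 3), (1, 1)]:
                brute = np.mean(
                    [
                        _brute_phi(r, k, l, m, n, w2, t, tau)
                        for m in range(n_tr)
                        for n in range(n_tr)
                        if m != n
                    ]
                )
                assert abs(fast[ci, jj, k, l] - brute) <= 1e-10 * max(
                    abs(brute), 1e-6
                )


def test_identical_trials_shuffled_equals_unshuffled(toy_raster):
    resp = np.repeat(toy_raster.responses[:, :1], 4, axis=1)
    raster = cc.EnsembleRaster(resp, rate=2000.0)
    win = NeuralWindow(0.05)
    centers, lags = np.array([600]), np.arange(-5, 6)
    stim = shuffled_correlation(raster, win, centers, lags)
    unsh = unshuffled_correlation(raster, win, centers, lags)
    assert np.allclose(stim, unsh, rtol=1e-10)
    assert np.allclose(noise_correlation(unsh, stim), 0.0, atol=1e-10 * unsh.max())


def test_unshuffled_single_trial_is_that_trials_correlogram(toy_raster):
    win = NeuralWindow(0.05)
    centers, lags = np.array([600]), np.arange(-3, 4)
    raster1 = cc.EnsembleRaster(
        np.repeat(toy_raster.responses[:, :1], 2, axis=1), rate=2000.0
    )
    unsh = unshuffled_correlation(raster1, win, centers, lags)
    r = raster1.responses - raster1.responses.mean(axis=2, keepdims=True)
    direct = windowed_pair_correlation(r[0, 0], r[1, 0], win, 2000.0, centers, lags)
    assert np.allclose(unsh[:, :, 0, 1], direct, rtol=1e-12)


def test_pure_noise_shuffled_vanishes():
    rng = np.random.default_rng(4)
    raster = cc.gen_ensemble_raster(
        np.zeros((4, 8000)), 40, cc.NoiseSpec(noise_gain=1.0, seed=8)
    )
    win = NeuralWindow(0.25)
    centers = np.array([2000, 4000, 6000])
    stim = shuffled_correlation(raster, win, centers, np.array([0]))
    unsh = unshuffled_correlation(raster, win, centers, np.array([0]))
    diag_ratio = np.abs(stim[:, 0, np.arange(4), np.arange(4)]) / np.abs(
        unsh[:, 0, np.arange(4), np.arange(4)]
    )
    assert diag_ratio.max() < 0.1


def test_total_correlation_identities(small_raster):
    est = estimate_ensemble_correlations(
        small_raster, NeuralWindow(0.25), lags=np.arange(-50, 51), n_points=5
    )
    L = small_raster.n_channels
    j0 = est.zero_lag_index
    diag_total = est.c_total[:, j0, np.arange(L), np.arange(L)]
    assert np.allclose(diag_total, 1.0, atol=1e-6)
    # with trial noise present the stimulus-driven diagonal stays below 1
    assert est.c_stim[:, j0, np.arange(L), np.arange(L)].max() < 1.0
    assert np.allclose(est.c_total, est.c_stim + est.c_noise, atol=1e-12)
    assert np.abs(est.c_total).max() <= 1.0 + 1e-9
    assert np.abs(est.c_stim).max() <= 1.0 + 1e-9


def test_estimator_consistency_with_trials():
    """Phi_stim converges to the noise-free signal correlation as N grows."""
    spec = cc.TextureSpec(
        n_channels=4, duration=5.0, envelope_rate=2000.0,
        temporal_kernel=cc.TemporalKernel("exponential", 0.01), seed=21,
    )
    sig = cc.gen_correlated_envelopes(spec).envelopes.T
    win = NeuralWindow(0.25)
    centers = np.array([2000, 5000, 8000])
    lags = np.array([0])
    clean = cc.gen_ensemble_raster(sig, 2, cc.NoiseSpec(noise_gain=0.0, seed=0))
    ref = shuffled_correlation(clean, win, centers, lags)
    rmse = {}
    for n_tr in (5, 40):
        noisy = cc.gen_ensemble_raster(
            sig, n_tr, cc.NoiseSpec(noise_gain=1.0, seed=55)
        )
        est = shuffled_correlation(noisy, win, centers, lags)
        rmse[n_tr] = np.sqrt(np.mean((est - ref) ** 2)) / np.sqrt(np.mean(ref**2))
    # variance ~ 1/(N(N-1)): an 8x trial increase should far more than halve it
    assert rmse[40] < 0.6 * rmse[5]


def test_noise_recovery_spatial_reach():
    raster = cc.gen_ensemble_raster(
        np.zeros((8, 40000)), 40,
        cc.NoiseSpec(noise_gain=1.0, spatial_reach=1, temporal_width=0.003,
                     seed=13),
    )
    win = NeuralWindow(0.5)
    centers = np.linspace(2000, 38000, 6).astype(int)
    lags = np.arange(-30, 31)
    est = estimate_ensemble_correlations(raster, win, centers=centers, lags=lags)
    j0 = est.zero_lag_index
    cn = est.c_noise[:, j0].mean(axis=0)
    prof = collapse_correlations(cn, "spectral")
    truth = raster.truth["spatial_corr"][0]  # (reach+1-d)/(reach+1)
    assert abs(prof[1] - truth[1]) < 0.05  # adjacent channels: 0.5
    assert np.abs(prof[3:]).max() < 0.05  # beyond the reach: zero


def test_noise_recovery_temporal_width():
    from corrcode.correlation import _full_width

    raster = cc.gen_ensemble_raster(
        np.zeros((4, 40000)), 40,
        cc.NoiseSpec(noise_gain=1.0, spatial_reach=0, temporal_width=0.003,
                     seed=14),
    )
    win = NeuralWindow(0.5)
    centers = np.linspace(2000, 38000, 6).astype(int)
    lags = np.arange(-40, 41)
    est = estimate_ensemble_correlations(raster, win, centers=centers, lags=lags)
    prof = collapse_correlations(est.c_noise.mean(axis=0), "temporal")
    width = _full_width(est.lags, prof, 0.5)
    assert abs(width - 0.003) < 0.001


def test_single_trial_diagonal_is_one(small_raster):
    c = single_trial_correlation(
        small_raster, 2, NeuralWindow(0.25), np.array([2000]), np.arange(-20, 21)
    )
    L = small_raster.n_channels
    j0 = 20
    assert np.allclose(c[:, j0, np.arange(L), np.arange(L)], 1.0, atol=1e-9)
    assert np.abs(c).max() <= 1.0 + 1e-9


def test_collapse_profiles(rng):
    eye = np.eye(5)
    prof = collapse_correlations(eye, "spectral")
    assert np.allclose(prof, [1, 0, 0, 0, 0])
    # Toeplitz with value v at offset d
    from scipy.linalg import toeplitz

    col = np.array([1.0, 0.3, 0.1, 0.0, 0.0])
    prof = collapse_correlations(toeplitz(col), "spectral")
    assert np.allclose(prof, col)
    # random symmetric vs brute-force diagonal means
    A = rng.standard_normal((6, 6))
    A = (A + A.T) / 2
    prof = collapse_correlations(A, "spectral")
    for d in range(6):
        vals = [A[i, j] for i in range(6) for j in range(6) if abs(i - j) == d]
        assert np.isclose(prof[d], np.mean(vals))


def test_errors():
    with pytest.raises(ValueError, match="2 trials"):
        cc.EnsembleRaster(np.zeros((3, 1, 100)))
    raster = cc.EnsembleRaster(np.random.default_rng(0).lognormal(size=(2, 3, 500)))
    win = NeuralWindow(0.05)
    with pytest.raises(ValueError, match="edges"):
        windowed_pair_correlation(
            raster.responses[0, 0], raster.responses[1, 0], win, 2000.0,
            np.array([10]), np.arange(-5, 6),
        )
    a = np.zeros((1, 3, 2, 2))
    with pytest.raises(ValueError, match="match"):
        noise_correlation(a, np.zeros((1, 3, 2, 3)))


def test_zero_variance_normalization_raises():
    resp = np.ones((2, 3, 1000))  # constant: zero variance after centering
    raster = cc.EnsembleRaster(resp, rate=2000.0)
    win = NeuralWindow(0.1)
    centers, lags = np.array([500]), np.array([0])
    phi = unshuffled_correlation(raster, win, centers, lags)
    with pytest.raises(ValueError, match="variance"):
        normalize_correlation(phi, raster, win, centers, lags)


def test_default_lag_grid_has_401_lags_at_2khz():
    assert default_lag_grid(2000.0, 0.1).size == 401
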