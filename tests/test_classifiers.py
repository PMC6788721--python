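import numpy as np
import pytest
from scipy import stats

from corrcode.bayes import (
    GaussianBayesClassifier,
    GMMBayesClassifier,
    classify_loo,
    map_classify,
    model_average_classify,
    model_average_log_posterior,
    optimize_alpha,
    performance_curve,
    segment_ladder,
)


def _two_class_data(rng, n=60, d=5, sep=8.0):
    X0 = rng.standard_normal((n, d))
    X1 = rng.standard_normal((n, d)) + sep / np.sqrt(d)
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n)
    return X, y


def test_separated_classes_train_perfectly(rng):
    X, y = _two_class_data(rng)
    clf = GaussianBayesClassifier(n_components=3).fit(X, y)
    assert np.mean(clf.predict(X) == y) == 1.0
    assert clf.n_components_ == 3
    assert np.allclose(clf.priors_, 0.5)


def test_matches_sklearn_gaussian_nb(rng):
    """Dual route: our Gaussian fit against sklearn's GaussianNB on
    whitened-by-identity (full-dimensional PCA) data."""
    from sklearn.naive_bayes import GaussianNB

    X, y = _two_class_data(rng, n=40, d=4, sep=2.0)
    ours = GaussianBayesClassifier(n_components=4, var_floor=0.0).fit(X, y)
    Xp = ours.pca_.transform(X)  # same rotation for both routes
    ref = GaussianNB(var_smoothing=0.0).fit(Xp, y)
    assert np.allclose(ours.theta_, ref.theta_)
    assert np.allclose(ours.var_, ref.var_, rtol=1e-6)
    assert np.array_equal(ours.predict(X), ref.predict(Xp))


def test_one_dimensional_closed_form_boundary():
    """In 1-D the decision reduces to a quadratic discriminant."""
    rng = np.random.default_rng(0)
    mu0, s0, mu1, s1 = 0.0, 1.0, 3.0, 2.0
    X = np.concatenate([rng.normal(mu0, s0, 500), rng.normal(mu1, s1, 500)])
    y = np.repeat([0, 1], 500)
    clf = GaussianBayesClassifier(n_components=1).fit(X[:, None], y)
    grid = np.linspace(-4, 8, 200)[:, None]
    pred = clf.predict(grid)
    m0, v0 = clf.theta_[0, 0], clf.var_[0, 0]
    m1, v1 = clf.theta_[1, 0], clf.var_[1, 0]
    g = clf.pca_.transform(grid)[:, 0]
    closed = (
        -0.5 * (g - m1) ** 2 / v1 - 0.5 * np.log(v1)
        > -0.5 * (g - m0) ** 2 / v0 - 0.5 * np.log(v0)
    ).astype(int)
    assert np.array_equal(pred, closed)


def test_identical_distributions_classify_at_chance(rng):
    n_classes = 4
    X = rng.standard_normal((200, 6))
    y = np.tile(np.arange(n_classes), 50)
    clf = GaussianBayesClassifier(n_components=4).fit(X, y)
    fresh = rng.standard_normal((4000, 6))
    truth = rng.integers(0, n_classes, 4000)
    acc = np.mean(clf.predict(fresh) == truth)
    se = np.sqrt(0.25 * 0.75 / 4000)
    assert abs(acc - 1.0 / n_classes) < 4 * se


def test_map_classify_blocks(rng):
    X, y = _two_class_data(rng)
    clf = GaussianBayesClassifier(n_components=2).fit(X, y)
    labels1, ll1 = map_classify(clf, X[:10], combine_n=1)
    assert labels1.shape == (10,)
    # duplicating an observation never changes the argmax
    xdup = np.vstack([X[3], X[3]])
    lab2, _ = map_classify(clf, xdup, combine_n=2)
    assert lab2[0] == labels1[3]
    assert clf.predict_joint(xdup) == labels1[3]


def test_sweep_selects_informative_subspace(rng):
    # only the first latent direction separates the classes
    n = 80
    X = rng.standard_normal((2 * n, 10)) * 0.3
    X[n:, 0] += 4.0
    y = np.repeat([0, 1], n)
    clf = GaussianBayesClassifier(n_components="sweep", random_state=0).fit(X, y)
    assert clf.n_components_ <= 3
    assert np.mean(clf.predict(X) == y) > 0.95


# --- model averaging --------------------------------------------------------

def _planted_pair(rng, informative="spec"):
    n, d = 50, 4
    Xs = rng.standard_normal((2 * n, d))
    Xt = rng.standard_normal((2 * n, d))
    y = np.repeat([0, 1], n)
    if informative == "spec":
        Xs[n:] += 3.0
    else:
        Xt[n:] += 3.0
    ms = GaussianBayesClassifier(n_components=d).fit(Xs, y)
    mt = GaussianBayesClassifier(n_components=d).fit(Xt, y)
    return ms, mt, Xs, Xt, y


def test_alpha_degenerate_limits(rng):
    ms, mt, Xs, Xt, y = _planted_pair(rng)
    pred_spec = ms.predict(Xs)
    assert np.array_equal(
        model_average_classify(ms, mt, 1.0, Xs, Xt), pred_spec
    )
    assert np.array_equal(
        model_average_classify(ms, mt, 0.0, Xs, Xt), mt.predict(Xt)
    )
    with pytest.raises(ValueError, match="alpha"):
        model_average_log_posterior(ms, mt, 1.2, Xs, Xt)


def test_alpha_optimization_follows_information(rng):
    ms, mt, Xs, Xt, y = _planted_pair(rng, informative="spec")
    assert optimize_alpha(ms, mt, Xs, Xt, y) >= 0.8
    ms2, mt2, Xs2, Xt2, y2 = _planted_pair(rng, informative="temp")
    assert optimize_alpha(ms2, mt2, Xs2, Xt2, y2) <= 0.2


# --- GMM classifier ---------------------------------------------------------

def test_single_component_reduces_to_gaussian(rng):
    X, y = _two_class_data(rng, n=50, d=4, sep=3.0)
    gmm = GMMBayesClassifier(
        n_components_grid=(1,), pca_variance=0.999, random_state=0
    ).fit(X, y)
    gauss = GaussianBayesClassifier(n_components=4).fit(X, y)
    agree = np.mean(gmm.predict(X) == gauss.predict(X))
    assert agree > 0.97
    assert all(k == 1 for k in gmm.n_components_.values())


def test_gmm_component_count_recovery():
    """Well-separated 3-component diagonal mixtures are identified, and the
    held-out likelihood does not keep improving past the true count."""
    hits = 0
    for seed in range(6):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        X = np.vstack(
            [rng.standard_normal((150, 2)) * 0.7 + c for c in centers]
        )
        clf = GMMBayesClassifier(
            n_components_grid=tuple(range(1, 7)), pca_variance=0.999,
            cv=5, n_init=3, random_state=seed,
        ).fit(X, np.zeros(len(X), dtype=int))
        hits += clf.n_components_[0] == 3
    assert hits >= 5


# --- LOO and performance curves ---------------------------------------------

def test_classify_loo_on_separable_features(rng):
    sets, labels = [], []
    for cat in range(3):
        for _ in range(3):
            X = rng.standard_normal((12, 4)) * 0.3
            X[:, cat] += 3.0
            sets.append(X)
            labels.append(f"cat{cat}")
    res = classify_loo(
        sets, labels, obs_per_segment=1,
        classifier_factory=lambda: GMMBayesClassifier(
            n_components_grid=(1,), pca_variance=0.999, random_state=0
        ),
    )
    assert res["accuracy"][int(res["n_segments"][-1])] == 100.0
    assert list(res["n_segments"]) == [1, 2, 3, 4, 6, 8, 11]


def test_classify_loo_duration_truncation_warns(rng):
    sets = [rng.standard_normal((4, 3)) + (i // 2) * 3 for i in range(4)]
    labels = ["a", "a", "b", "b"]
    with pytest.warns(UserWarning, match="truncat"):
        res = classify_loo(
            sets, labels, n_segments=[1, 10],
            classifier_factory=lambda: GaussianBayesClassifier(n_components=2),
        )
    assert max(res["n_segments"]) == 4


def test_segment_ladder():
    assert list(segment_ladder(1)) == [1]
    lad = segment_ladder(100)
    assert lad[0] == 1 and lad[-1] <= 100
    ratios = lad[2:] / lad[1:-1]
    assert np.all(ratios < 1.6)


def test_performance_curve_closed_form():
    tau = 0.4
    d = 0.0625 * 2 ** (np.arange(9) / 2.0)
    acc = 100 * (1 - np.exp(-d / tau))
    res = performance_curve(d, acc)
    # analytic 90%-of-asymptote time
    a_inf = acc[-1]
    t90 = -tau * np.log(1 - 0.9 * a_inf / 100.0)
    grid_step = np.sqrt(2.0)
    assert res["tau_c"] <= t90 * grid_step and res["tau_c"] >= t90 / grid_step


def test_performance_curve_degenerate_cases():
    d = [0.1, 0.2, 0.4]
    assert performance_curve(d, [80, 80, 80])["tau_c"] == 0.1  # flat
    assert performance_curve(d, [90, 90, 90])["asymptote"] == 90
    with pytest.warns(UserWarning, match="monotone"):
        res = performance_curve(d, [50, 40, 60])
    assert res["tau_c"] <= 0.4
    with pytest.raises(ValueError):
        performance_curve([1, 2], [10, 20])
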