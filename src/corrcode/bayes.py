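"""Bayesian decoders over reduced correlation features.

Two MAP classifiers share the same machinery — PCA for dimensionality
reduction, per-class likelihood models, equiprobable priors, and decisions
by summed log-likelihood over conditionally independent observations:

* :class:`GaussianBayesClassifier` — a naive-Bayes classifier whose
  per-class likelihood is an axis-aligned multivariate Gaussian over
  principal-component scores (the neural decoder);
* :class:`GMMBayesClassifier` — per-class diagonal-covariance Gaussian
  mixtures with the component count selected by cross-validated held-out
  log-likelihood (the sound-category decoder).

Both follow the scikit-learn estimator protocol (``fit`` / ``predict`` /
``get_params``) and compose with its model-selection tools.  A
``predict_joint`` method implements the MAP decision from several
observations of the same source, ``argmax_m sum_n log P(x_n | m)``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import log_softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold, StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GaussianBayesClassifier",
    "GMMBayesClassifier",
    "map_classify",
    "optimize_alpha",
    "model_average_log_posterior",
    "model_average_classify",
    "classify_loo",
    "performance_curve",
    "segment_ladder",
]

_LOG2PI = np.log(2.0 * np.pi)


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x features)")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return X, y


class GaussianBayesClassifier(ClassifierMixin, BaseEstimator):
    """Naive-Bayes MAP classifier on principal-component scores.

    Parameters
    ----------
    n_components : int, float or "sweep"
        PCA retention rule: an int keeps that many components, a float in
        (0, 1) keeps the highest-ranked components explaining that variance
        fraction, and ``"sweep"`` selects the count (1 ... min(40, n-1))
        that maximizes accuracy on a nested stratified split.
    var_floor : float
        Relative floor on the per-dimension class variances, as a fraction
        of the mean score variance; guards degenerate dimensions.
    random_state : int or None
        Seed for the nested split used by the sweep.

    Attributes
    ----------
    classes_ : numpy.ndarray
    pca_ : sklearn.decomposition.PCA
    theta_, var_ : numpy.ndarray
        Per-class, per-dimension means and (floored) variances,
        ``(n_classes, n_components)``.
    n_components_ : int
    """

    def __init__(
        self,
        n_components: int | float | str = "sweep",
        var_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.var_floor = var_floor
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def _sweep_components(self, X: np.ndarray, y: np.ndarray, pca: PCA) -> int:
        max_k = pca.n_components_
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=0.3, random_state=self.random_state
        )
        (tr, te), = splitter.split(X, y)
        sc_tr = pca.transform(X[tr])
        sc_te = pca.transform(X[te])
        best_k, best_acc = 1, -1.0
        for k in range(1, max_k + 1):
            theta, var = self._fit_gauss_at(sc_tr[:, :k], y[tr])
            ll = self._loglik(sc_te[:, :k], theta, var)
            acc = np.mean(self.classes_[np.argmax(ll, axis=1)] == y[te])
            if acc > best_acc:
                best_k, best_acc = k, acc
        return best_k

    def _fit_gauss_at(self, scores, y):
        floor = self.var_floor * max(scores.var(), np.finfo(float).tiny)
        theta = np.stack([scores[y == c].mean(axis=0) for c in self.classes_])
        var = np.stack(
            [np.maximum(scores[y == c].var(axis=0), floor) for c in self.classes_]
        )
        return theta, var

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 observations")
        if isinstance(self.n_components, str) and self.n_components == "sweep":
            cap = min(40, X.shape[0] - 1, X.shape[1])
            pca = PCA(n_components=cap).fit(X)
            k = self._sweep_components(X, y, pca)
        elif isinstance(self.n_components, float):
            if not 0 < self.n_components < 1:
                raise ValueError("fractional n_components must be in (0, 1)")
            pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1])).fit(X)
            frac = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(frac, self.n_components) + 1)
        else:
            k = int(self.n_components)
            if k < 1:
                raise ValueError("n_components must be >= 1")
            pca = PCA(n_components=min(k, X.shape[0] - 1, X.shape[1])).fit(X)
            k = pca.n_components_
        self.pca_ = pca
        self.n_components_ = k
        scores = pca.transform(X)[:, :k]
        self.theta_, self.var_ = self._fit_gauss_at(scores, y)
        self.priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
        return self

    # -- inference ---------------------------------------------------------
    @staticmethod
    def _loglik(scores, theta, var):
        # (n, 1, d) vs (1, c, d) -> (n, c)
        d2 = (scores[:, None, :] - theta[None]) ** 2 / var[None]
        return -0.5 * (d2 + np.log(var)[None] + _LOG2PI).sum(axis=-1)

    def _scores(self, X):
        check_is_fitted(self, "pca_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.pca_.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fitted on "
                f"{self.pca_.n_features_in_}"
            )
        return self.pca_.transform(X)[:, : self.n_components_]

    def predict_log_likelihood(self, X) -> np.ndarray:
        """Per-observation class-conditional log-likelihoods, (n, n_classes)."""
        return self._loglik(self._scores(X), self.theta_, self.var_)

    def predict_log_posterior(self, X) -> np.ndarray:
        """Per-observation log P(m | x) under equiprobable priors."""
        return log_softmax(self.predict_log_likelihood(X), axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_log_likelihood(X), axis=1)]

    def predict_joint(self, X):
        """MAP class from the summed log-likelihood of all rows of X."""
        ll = self.predict_log_likelihood(X).sum(axis=0)
        return self.classes_[int(np.argmax(ll))]


class GMMBayesClassifier(ClassifierMixin, BaseEstimator):
    """MAP classifier with per-class diagonal-covariance Gaussian mixtures.

    PCA retains the highest-ranked components explaining ``pca_variance``
    of the training variance; each class likelihood is a diagonal GMM fit
    by EM with k-means initialization and ``n_init`` restarts, and its
    component count is selected from ``n_components_grid`` by ``cv``-fold
    cross-validated held-out log-likelihood.
    """

    def __init__(
        self,
        n_components_grid=tuple(range(1, 21)),
        pca_variance: float = 0.9,
        cv: int = 5,
        n_init: int = 5,
        reg_covar: float = 1e-6,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.n_components_grid = n_components_grid
        self.pca_variance = pca_variance
        self.cv = cv
        self.n_init = n_init
        self.reg_covar = reg_covar
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _make_gmm(self, n_components: int, scale: float, seed) -> GaussianMixture:
        return GaussianMixture(
            n_components=n_components,
            covariance_type="diag",
            reg_covar=self.reg_covar * scale,
            tol=self.tol,
            max_iter=self.max_iter,
            n_init=self.n_init,
            init_params="kmeans",
            random_state=seed,
        )

    def _select_n_components(self, scores: np.ndarray, scale: float, rng) -> int:
        grid = [k for k in self.n_components_grid if k <= scores.shape[0]]
        if len(grid) <= 1:
            return grid[0] if grid else 1
        n_splits = min(self.cv, scores.shape[0])
        kf = KFold(n_splits=n_splits, shuffle=True,
                   random_state=int(rng.integers(2**31)))
        best_k, best_ll = grid[0], -np.inf
        for k in grid:
            lls = []
            for tr, te in kf.split(scores):
                if k > len(tr):
                    lls = None
                    break
                gmm = self._make_gmm(k, scale, int(rng.integers(2**31)))
                try:
                    gmm.fit(scores[tr])
                except ValueError:
                    lls = None
                    break
                lls.append(gmm.score(scores[te]))
            if lls is not None and np.mean(lls) > best_ll:
                best_k, best_ll = k, float(np.mean(lls))
        return best_k

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        self.pca_ = PCA(n_components=min(X.shape) - 1).fit(X)
        frac = np.cumsum(self.pca_.explained_variance_ratio_)
        self.n_components_pca_ = int(np.searchsorted(frac, self.pca_variance) + 1)
        scores = self.pca_.transform(X)[:, : self.n_components_pca_]
        scale = max(scores.var(), np.finfo(float).tiny)
        self.models_ = {}
        self.n_components_ = {}
        for c in self.classes_:
            sc = scores[y == c]
            if sc.shape[0] < 2:
                raise ValueError(f"class {c!r} has fewer than 2 observations")
            k = self._select_n_components(sc, scale, rng)
            gmm = self._make_gmm(k, scale, int(rng.integers(2**31)))
            gmm.fit(sc)
            self.models_[c] = gmm
            self.n_components_[c] = k
        self.priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
        return self

    def _scores(self, X):
        check_is_fitted(self, "pca_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.pca_.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fitted on "
                f"{self.pca_.n_features_in_}"
            )
        return self.pca_.transform(X)[:, : self.n_components_pca_]

    def predict_log_likelihood(self, X) -> np.ndarray:
        sc = self._scores(X)
        return np.column_stack(
            [self.models_[c].score_samples(sc) for c in self.classes_]
        )

    def predict_log_posterior(self, X) -> np.ndarray:
        return log_softmax(self.predict_log_likelihood(X), axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_log_likelihood(X), axis=1)]

    def predict_joint(self, X):
        ll = self.predict_log_likelihood(X).sum(axis=0)
        return self.classes_[int(np.argmax(ll))]


def map_classify(model, X, combine_n: int = 1):
    """MAP decisions from blocks of ``combine_n`` consecutive observations.

    Returns ``(labels, log_likelihoods)`` where ``log_likelihoods`` has one
    row of per-class summed log-likelihood per block.  Ties break toward
    the lowest class index (argmax convention).
    """
    ll = model.predict_log_likelihood(X)
    n_blocks = ll.shape[0] // combine_n
    if n_blocks * combine_n != ll.shape[0]:
        ll = ll[: n_blocks * combine_n]
    summed = ll.reshape(n_blocks, combine_n, -1).sum(axis=1)
    return model.classes_[np.argmax(summed, axis=1)], summed


# --- model averaging (joint spectro-temporal decoder) ----------------------

def model_average_log_posterior(model_spec, model_temp, alpha, X_spec, X_temp):
    """``L = alpha log P_spec(m|x) + (1 - alpha) log P_temp(m|x)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    ls = model_spec.predict_log_posterior(X_spec)
    lt = model_temp.predict_log_posterior(X_temp)
    if ls.shape != lt.shape:
        raise ValueError("spectral and temporal observations do not align")
    return alpha * ls + (1.0 - alpha) * lt


def optimize_alpha(
    model_spec, model_temp, X_spec, X_temp, y, grid=None
) -> float:
    """Mixing coefficient maximizing the true-class log-posterior.

    Grid-searched on the supplied (training) data; ties break toward the
    smaller alpha.
    """
    grid = np.arange(0.0, 1.0 + 1e-12, 0.05) if grid is None else np.asarray(grid)
    ls = model_spec.predict_log_posterior(X_spec)
    lt = model_temp.predict_log_posterior(X_temp)
    classes = list(model_spec.classes_)
    idx = np.array([classes.index(c) for c in y])
    rows = np.arange(len(y))
    scores = [
        (a * ls + (1 - a) * lt)[rows, idx].sum() for a in grid
    ]
    return float(grid[int(np.argmax(scores))])


def model_average_classify(
    model_spec, model_temp, alpha, X_spec, X_temp, combine_n: int = 1
):
    """Joint spectro-temporal MAP decisions from aligned feature pairs."""
    L = model_average_log_posterior(model_spec, model_temp, alpha, X_spec, X_temp)
    n_blocks = L.shape[0] // combine_n
    summed = L[: n_blocks * combine_n].reshape(n_blocks, combine_n, -1).sum(axis=1)
    return model_spec.classes_[np.argmax(summed, axis=1)]


# --- leave-one-out over sounds ---------------------------------------------

def segment_ladder(n_max: int) -> np.ndarray:
    """Segment counts in half-octave steps: 1, 1.41, 2, ... capped at n_max."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    k = np.arange(0, int(np.ceil(2 * np.log2(n_max))) + 1)
    vals = np.unique(np.round(2.0 ** (k / 2.0)).astype(int))
    return vals[vals <= n_max]


def classify_loo(
    feature_sets: list[np.ndarray],
    labels: list,
    obs_per_segment: int = 1,
    n_segments: np.ndarray | None = None,
    classifier_factory=None,
):
    """Leave-one-out classification of sounds versus observation duration.

    Parameters
    ----------
    feature_sets : list of numpy.ndarray
        One matrix per sound; rows are time-ordered observations from
        non-overlapping segments.
    labels : list
        Category label per sound.
    obs_per_segment : int
        Observations contributed by one segment (``L`` for temporal
        features, 1 otherwise).
    n_segments : array of int, optional
        Ladder of segment counts; defaults to half-octave steps up to the
        shortest sound.
    classifier_factory : callable
        Zero-argument callable returning an unfitted classifier; defaults
        to :class:`GMMBayesClassifier` with a small component grid.

    Returns
    -------
    dict
        ``accuracy`` mapping segment count -> percent correct,
        ``predictions`` mapping segment count -> predicted label list, and
        ``n_segments``.
    """
    if len(feature_sets) != len(labels):
        raise ValueError("one label per sound is required")
    labels = np.asarray(labels)
    if min(np.bincount(np.unique(labels, return_inverse=True)[1])) < 2:
        raise ValueError("need >= 2 sounds per category for leave-one-out")
    if classifier_factory is None:
        classifier_factory = lambda: GMMBayesClassifier(
            n_components_grid=(1, 2, 3), random_state=0
        )
    max_seg = min(x.shape[0] // obs_per_segment for x in feature_sets)
    if n_segments is None:
        n_segments = segment_ladder(max_seg)
    else:
        n_segments = np.asarray(n_segments, dtype=int)
        if n_segments.max() > max_seg:
            warnings.warn(
                "requested duration exceeds the shortest sound; truncating",
                stacklevel=2,
            )
            n_segments = np.unique(np.minimum(n_segments, max_seg))
    preds = {int(n): [] for n in n_segments}
    for i in range(len(feature_sets)):
        X_tr = np.concatenate(
            [x for j, x in enumerate(feature_sets) if j != i], axis=0
        )
        y_tr = np.concatenate(
            [
                np.repeat(labels[j], feature_sets[j].shape[0])
                for j in range(len(feature_sets))
                if j != i
            ]
        )
        clf = classifier_factory()
        clf.fit(X_tr, y_tr)
        for n in n_segments:
            X_te = feature_sets[i][: int(n) * obs_per_segment]
            preds[int(n)].append(clf.predict_joint(X_te))
    accuracy = {
        n: 100.0 * np.mean(np.asarray(p) == labels) for n, p in preds.items()
    }
    return {"accuracy": accuracy, "predictions": preds, "n_segments": n_segments}


def performance_curve(durations, accuracies) -> dict:
    """Asymptote and integration rise time of an accuracy-vs-duration curve.

    The asymptote is the accuracy at the longest duration; the rise time
    ``tau_c`` is the first duration at which the curve reaches 90% of the
    asymptote, log-linearly interpolated between grid points.  Non-monotone
    curves use the first crossing and emit a warning.
    """
    d = np.asarray(durations, dtype=float)
    a = np.asarray(accuracies, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 duration points")
    if np.any(np.diff(a) < 0):
        warnings.warn("non-monotone performance curve; using first crossing",
                      stacklevel=2)
    asymptote = a[-1]
    target = 0.9 * asymptote
    if a[0] >= target:
        tau_c = d[0]
    else:
        tau_c = d[-1]
        for i in range(d.size - 1):
            if a[i] < target <= a[i + 1]:
                f = (target - a[i]) / (a[i + 1] - a[i])
                tau_c = float(
                    np.exp(np.log(d[i]) + f * (np.log(d[i + 1]) - np.log(d[i])))
                )
                break
    return {"asymptote": float(asymptote), "tau_c": float(tau_c)}
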