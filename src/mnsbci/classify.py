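"""Binary sensorimotor classification: CSP, Riemannian MDM and tangent space.

Four methods are compared, all operating on 8-30 Hz band-passed trial
windows:

``CSP+LDA``
    log-variance features from the first and last 4 common-spatial-pattern
    filters, classified with linear discriminant analysis;
``MDM``
    minimum distance to the Riemannian mean of each class's trial
    covariances, under the affine-invariant metric;
``CSP+MDM``
    MDM on the covariances of CSP-filtered signals (8 surrogate channels);
``TS+LR``
    trial covariances projected onto the tangent space at their Riemannian
    barycenter and classified with a regularized linear model (logistic by
    default, a least-squares head optionally).

Everything is packaged as scikit-learn estimators so the methods compose
with ``sklearn`` pipelines and model selection; the module-level functions
(`csp_fit`, `mdm_classify`, `train_eval_cv`, ...) are thin wrappers kept for
script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

from .containers import EMG_LABEL, MI, MI_MNS, MNS, RM, EpochSet
from .spd import check_spd, riemann_distance, riemann_mean, tangent_project

CLASSIFIER_BAND = (8.0, 30.0)
CLASSIFIER_FILTER_ORDER = 5
METHODS = ("CSP+LDA", "MDM", "CSP+MDM", "TS+LR")

#: Classification paradigms: (name, positive-class window spec).
MI_VS_REST = "MI_vs_Rest"
RM_VS_REST = "RM_vs_Rest"
MNS_PAIR = "MNS_pair"
PARADIGMS = (MI_VS_REST, RM_VS_REST, MNS_PAIR)

TASK_WINDOW = (0.5, 3.0)    # seconds after the go cue
REST_WINDOW = (-3.0, -0.5)  # seconds before the go cue
MNS_WINDOW = (-0.5, 2.5)    # seconds around the stimulation pulse


# ---------------------------------------------------------------------------
# covariance estimation


def covariance(window: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Shrunk sample covariance of one channels x samples window.

    The sample covariance is blended toward a scaled identity,
    ``(1 - s) C + s tr(C)/n I``, which guarantees positive definiteness for
    any ``s > 0``; with ``s = 0`` a rank-deficient window raises.
    """
    X = np.asarray(window, dtype=float)
    if X.ndim != 2:
        raise ValueError("window must be channels x samples")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / max(X.shape[1] - 1, 1)
    n = C.shape[0]
    C = (1.0 - shrinkage) * C + shrinkage * (np.trace(C) / n) * np.eye(n)
    w = np.linalg.eigvalsh(C)
    if w.min() <= 0:
        raise ValueError(
            "covariance is singular (constant or collinear channels); "
            "use a positive shrinkage")
    return C


class Covariances(TransformerMixin, BaseEstimator):
    """Stack of shrunk trial covariances: (n, ch, t) -> (n, ch, ch)."""

    def __init__(self, shrinkage: float = 0.01):
        self.shrinkage = shrinkage

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([covariance(x, self.shrinkage) for x in X])


@dataclass
class SPDSet:
    """Covariance features with labels and the shrinkage used to build them."""

    matrices: np.ndarray
    labels: np.ndarray
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrices.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per matrix required")
        for i, C in enumerate(self.matrices):
            check_spd(C, f"matrix {i}")


# ---------------------------------------------------------------------------
# common spatial patterns


@dataclass
class CSPFilters:
    """Spatial filters (rows) with their generalized eigenvalues in (0, 1)."""

    filters: np.ndarray
    eigenvalues: np.ndarray


def csp_fit(class_covs: Sequence[np.ndarray], n_pairs: int = 4) -> CSPFilters:
    """Solve ``C1 w = lambda (C1 + C2) w`` and keep the extreme filters.

    Returns the ``n_pairs`` eigenvectors with the largest eigenvalues
    followed by the ``n_pairs`` with the smallest — the directions whose
    variance ratio between the two classes is most extreme.  Eigenvector
    signs are fixed by making each filter's largest-magnitude coefficient
    positive.
    """
    if len(class_covs) != 2:
        raise ValueError("CSP is defined for exactly two classes")
    C1 = check_spd(class_covs[0], "class-1 covariance")
    C2 = check_spd(class_covs[1], "class-2 covariance")
    comp = C1 + C2
    if np.linalg.eigvalsh(comp).min() <= 1e-12 * np.trace(comp):
        raise ValueError(
            "composite covariance is rank deficient; add shrinkage")
    evals, evecs = linalg.eigh(C1, comp)   # ascending eigenvalues in (0, 1)
    n_ch = C1.shape[0]
    if 2 * n_pairs > n_ch:
        raise ValueError(
            f"{n_pairs} pairs require at least {2 * n_pairs} channels")
    order = np.concatenate([np.arange(n_ch - 1, n_ch - 1 - n_pairs, -1),
                            np.arange(n_pairs)])
    W = evecs[:, order].T
    flip = np.sign(W[np.arange(W.shape[0]),
                     np.argmax(np.abs(W), axis=1)])
    W = W * flip[:, None]
    return CSPFilters(filters=W, eigenvalues=evals[order])


def csp_features(filters: CSPFilters, window: np.ndarray) -> np.ndarray:
    """Log of the normalized variance of each spatially filtered signal."""
    Y = filters.filters @ np.asarray(window, dtype=float)
    var = Y.var(axis=1, ddof=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance CSP projection")
    return np.log(var / var.sum())


class CSP(TransformerMixin, BaseEstimator):
    """Common-spatial-pattern transformer.

    ``transform_into='features'`` yields the 2*n_pairs log-variance features;
    ``'signals'`` yields the spatially filtered window (for CSP+MDM).
    Class-mean covariances are arithmetic means of shrunk trial covariances.
    """

    def __init__(self, n_pairs: int = 4, shrinkage: float = 0.01,
                 transform_into: str = "features"):
        self.n_pairs = n_pairs
        self.shrinkage = shrinkage
        self.transform_into = transform_into

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("CSP requires exactly two classes")
        covs = np.stack([covariance(x, self.shrinkage) for x in X])
        means = [covs[y == c].mean(axis=0) for c in classes]
        fitted = csp_fit(means, n_pairs=self.n_pairs)
        self.filters_ = fitted.filters
        self.eigenvalues_ = fitted.eigenvalues
        self.classes_ = classes
        return self

    def transform(self, X):
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        if self.transform_into == "signals":
            return np.einsum("fc,ncs->nfs", self.filters_, X)
        flt = CSPFilters(self.filters_, self.eigenvalues_)
        return np.stack([csp_features(flt, x) for x in X])


# ---------------------------------------------------------------------------
# Riemannian classifiers


class MDM(ClassifierMixin, BaseEstimator):
    """Minimum distance to the Riemannian mean of each class.

    Ties are broken toward the lowest class index.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("MDM needs at least two classes")
        self.means_ = []
        for c in self.classes_:
            members = X[y == c]
            if members.shape[0] == 0:
                raise ValueError(f"class {c!r} has no training matrices")
            self.means_.append(
                riemann_mean(members, tol=self.tol, max_iter=self.max_iter,
                             validate=False))
        return self

    def decision_distances(self, X):
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        return np.stack([
            [riemann_distance(x, m) for m in self.means_] for x in X])

    def predict(self, X):
        d = self.decision_distances(X)
        # ties (within numerical noise) go to the lowest class index
        tol = 1e-9 * (1.0 + d.min(axis=1, keepdims=True))
        near = d <= d.min(axis=1, keepdims=True) + tol
        return self.classes_[near.argmax(axis=1)]


class TangentSpace(TransformerMixin, BaseEstimator):
    """Project covariances to the tangent space at their Riemannian barycenter."""

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.reference_ = riemann_mean(X, tol=self.tol,
                                       max_iter=self.max_iter, validate=False)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        return tangent_project(np.asarray(X, dtype=float), self.reference_)


class LeastSquaresClassifier(ClassifierMixin, BaseEstimator):
    """Ordinary least squares on 0/1 targets, thresholded at 0.5."""

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary targets required")
        self.model_ = LinearRegression().fit(X, (y == self.classes_[1]))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return np.where(self.model_.predict(X) >= 0.5,
                        self.classes_[1], self.classes_[0])


def fit_linear_head(kind: str, X, y, shrinkage: Optional[str | float] = None):
    """Fit an LDA / logistic / least-squares head on feature vectors."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes to fit a classifier")
    if kind == "LDA":
        if shrinkage is not None:
            model = LinearDiscriminantAnalysis(solver="lsqr",
                                               shrinkage=shrinkage)
        else:
            model = LinearDiscriminantAnalysis()
    elif kind == "logistic":
        model = LogisticRegression(C=1.0, max_iter=1000)
    elif kind == "least_squares":
        model = LeastSquaresClassifier()
    else:
        raise ValueError(f"unknown head {kind!r}")
    return model.fit(X, y)


def mdm_classify(train: SPDSet, test_matrices, tol: float = 1e-8,
                 max_iter: int = 200) -> np.ndarray:
    """Functional MDM: fit class means on ``train``, label ``test_matrices``."""
    clf = MDM(tol=tol, max_iter=max_iter)
    clf.fit(train.matrices, train.labels)
    return clf.predict(np.asarray(test_matrices, dtype=float))


# ---------------------------------------------------------------------------
# pipelines and evaluation


def build_pipeline(method: str, shrinkage: float = 0.01, n_pairs: int = 4,
                   ts_head: str = "logistic") -> Pipeline:
    """Assemble the sklearn pipeline for one of the four methods."""
    if method == "CSP+LDA":
        return Pipeline([
            ("csp", CSP(n_pairs=n_pairs, shrinkage=shrinkage)),
            ("lda", LinearDiscriminantAnalysis()),
        ])
    if method == "MDM":
        return Pipeline([
            ("cov", Covariances(shrinkage=shrinkage)),
            ("mdm", MDM()),
        ])
    if method == "CSP+MDM":
        return Pipeline([
            ("csp", CSP(n_pairs=n_pairs, shrinkage=shrinkage,
                        transform_into="signals")),
            ("cov", Covariances(shrinkage=shrinkage)),
            ("mdm", MDM()),
        ])
    if method == "TS+LR":
        head = (LogisticRegression(C=1.0, max_iter=1000)
                if ts_head == "logistic" else LeastSquaresClassifier())
        return Pipeline([
            ("cov", Covariances(shrinkage=shrinkage)),
            ("ts", TangentSpace()),
            ("head", head),
        ])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def extract_windows(epochs: EpochSet, paradigm: str) -> EpochSet:
    """Cut the paradigm's classification windows out of cue-aligned epochs.

    ``MI_vs_Rest`` / ``RM_vs_Rest``: the 2.5 s task window [0.5, 3.0) s after
    the go cue (class 1) against the same trials' 2.5 s pre-cue rest window
    [-3.0, -0.5) s (class 0).  ``MNS_pair``: one 3 s window [-0.5, 2.5) s
    around the stimulation pulse, MI+MNS trials as class 1 against MNS-only
    trials as class 0.
    """
    if paradigm in (MI_VS_REST, RM_VS_REST):
        cond = MI if paradigm == MI_VS_REST else RM
        sub = epochs.select_condition(cond)
        task = sub.data[:, :, sub.time_slice(*TASK_WINDOW)]
        rest = sub.data[:, :, sub.time_slice(*REST_WINDOW)]
        data = np.concatenate([rest, task], axis=0)
        y = np.concatenate([np.zeros(rest.shape[0], dtype=int),
                            np.ones(task.shape[0], dtype=int)])
        names = np.array(["Rest"] * rest.shape[0] + [cond] * task.shape[0],
                         dtype=object)
        tmin = 0.0
    elif paradigm == MNS_PAIR:
        lo = MNS_WINDOW[0] + 0.75   # stimulation is 750 ms after the cue
        hi = MNS_WINDOW[1] + 0.75
        neg = epochs.select_condition(MNS)
        pos = epochs.select_condition(MI_MNS)
        if neg.n_trials == 0 or pos.n_trials == 0:
            raise ValueError("MNS_pair needs both MI+MNS and MNS trials")
        data = np.concatenate([neg.data[:, :, neg.time_slice(lo, hi)],
                               pos.data[:, :, pos.time_slice(lo, hi)]], axis=0)
        y = np.concatenate([np.zeros(neg.n_trials, dtype=int),
                            np.ones(pos.n_trials, dtype=int)])
        names = np.array([MNS] * neg.n_trials + [MI_MNS] * pos.n_trials,
                         dtype=object)
        tmin = MNS_WINDOW[0]
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return EpochSet(data=data, rate=epochs.rate,
                    channels=list(epochs.channels), labels=names, tmin=tmin,
                    align=epochs.align, band=epochs.band,
                    meta={"y": y, "paradigm": paradigm})


@dataclass
class AccuracyResult:
    """Cross-validated accuracy for one subject x method x paradigm x band."""

    method: str
    paradigm: str
    fold_accuracies: list[float]
    seed: int
    band: Optional[tuple] = None
    subject: Optional[int] = None
    extras: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def train_eval_cv(windows: EpochSet, method: str, k: int = 4, seed: int = 0,
                  shrinkage: float = 0.01, ts_head: str = "logistic",
                  exclude_emg: bool = True) -> AccuracyResult:
    """Stratified k-fold accuracy; all fitting happens inside training folds."""
    y = np.asarray(windows.meta["y"])
    X = windows.data
    if exclude_emg and EMG_LABEL in windows.channels:
        X = X[:, windows.eeg_picks, :]
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} trials; needs >= k={k}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pipe = build_pipeline(method, shrinkage=shrinkage, ts_head=ts_head)
    folds, fold_indices = [], []
    for train_idx, test_idx in cv.split(X, y):
        model = clone(pipe)
        model.fit(X[train_idx], y[train_idx])
        folds.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
        fold_indices.append((train_idx.copy(), test_idx.copy()))
    band = windows.band[:2] if windows.band else None
    return AccuracyResult(method=method, paradigm=windows.meta.get("paradigm", ""),
                          fold_accuracies=folds, seed=seed, band=band,
                          extras={"folds": fold_indices})


DEFAULT_BANDS = ((7.0, 13.0), (15.0, 30.0), (8.0, 30.0))


def select_band(epochs: EpochSet, paradigm: str,
                bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
                method: str = "TS+LR", k: int = 4, seed: int = 0,
                shrinkage: float = 0.01) -> dict:
    """Evaluate each band and keep the best; ties go to the widest band.

    ``epochs`` must be unfiltered — each band is applied with the 5th-order
    classification filter before windowing.
    """
    from .preprocess import bandpass

    if len(bands) == 0:
        raise ValueError("band list must not be empty")
    results = {}
    for band in bands:
        filtered = bandpass(epochs, band, order=CLASSIFIER_FILTER_ORDER)
        windows = extract_windows(filtered, paradigm)
        results[band] = train_eval_cv(windows, method, k=k, seed=seed,
                                      shrinkage=shrinkage)
    # argmax; on ties prefer the widest band
    best = max(results,
               key=lambda b: (results[b].accuracy, b[1] - b[0]))
    return {"per_band": results, "best_band": best,
            "best_accuracy": results[best].accuracy}


def paired_ttest(acc_a: Sequence[float], acc_b: Sequence[float]
                 ) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
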