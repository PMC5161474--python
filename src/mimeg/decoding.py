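"""Classifiers, feature selection, cross-validated and inter-session
evaluation of the feature-extraction pipelines, and the online feedback
mapping.

Ten named pipelines are evaluated (plus ``ONLINE``, the fixed pipeline used
for real-time feedback): sensor-space time-frequency features (``STFT``,
``Morlet``, ``PSD``), spatial filtering with log-variance features
(``CSP``, ``FBCSP``, ``SSD``, ``SSD+CSP``) and time-frequency features on
CSP components (``CSP+STFT``, ``CSP+Morlet``, ``CSP+PSD``).

Two tasks are supported: ``LR`` discriminates left- from right-hand
imagery; ``MI_REST`` discriminates imagery (both hands pooled) from
rest-class epochs cut from the pre-cue interval of the same trials.  In
cross-validation, *all* data-dependent steps — spatial filters, the SSD
peak frequency, chi-square feature selection and the classifier — are
fitted on the training partitions only.  Band-pass filtering with a fixed
band is a per-trial operation and is cached per session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .preprocessing import (LEFT, MI, REST, RIGHT, BandSpec, EpochSet,
                            ParameterError, concatenate, crop_window)
from .spatial import (DataError, apply_filters, find_suppression_peak,
                      fit_csp, fit_fbcsp, fit_ssd_csp, fit_ssd,
                      logvar_features, ssd_bands)
from .spectral import (FeatureMatrix, morlet_features,
                       multitaper_psd_features, stft_features)

__all__ = [
    "ClassifierSpec", "CVResult", "TaskSpec", "Session",
    "LR_TASK", "MI_REST_TASK", "METHODS",
    "chi2_scores", "select_k_best", "train_classifier",
    "DecodingPipeline", "evaluate_cv5", "evaluate_intersession",
    "feedback_level", "online_pipeline", "binomial_threshold",
]

#: the broad analysis band shared by most pipelines
WIDE_BAND = BandSpec(8.0, 30.0, transition=0.5)

METHODS = ("STFT", "Morlet", "PSD", "FBCSP", "SSD", "CSP", "SSD+CSP",
           "CSP+STFT", "CSP+Morlet", "CSP+PSD", "ONLINE")

#: feature sets wider than this get chi-square top-k selection (the rule
#: the online pipeline uses)
MAX_FEATURES = 50


# ---------------------------------------------------------------------------
# task geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    """Window geometry and class pair of a classification task."""

    name: str
    classes: tuple[str, str]
    tf_windows: tuple            # 1-s windows for STFT/Morlet features
    psd_window: tuple[float, float]
    logvar_window: tuple[float, float]
    ssd_n_keep: int
    #: guard margin (s) kept around imagery/rest crops for wavelet edges
    guard: float = 0.5
    #: trace-normalize trial covariances in CSP fits; kept off when total
    #: band power is the class contrast (imagery versus rest)
    csp_trace_normalize: bool = True


LR_TASK = TaskSpec("LR", (LEFT, RIGHT),
                   tf_windows=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0),
                               (3.0, 4.0)),
                   psd_window=(0.0, 3.0), logvar_window=(0.5, 3.0),
                   ssd_n_keep=20)
# rest epochs are only 3 s, so this task uses three 1-s windows
MI_REST_TASK = TaskSpec("MI_REST", (MI, REST),
                        tf_windows=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)),
                        psd_window=(0.0, 3.0), logvar_window=(0.5, 3.0),
                        ssd_n_keep=30, csp_trace_normalize=False)

_TASKS = {"LR": LR_TASK, "MI_REST": MI_REST_TASK}


def get_task(task) -> TaskSpec:
    if isinstance(task, TaskSpec):
        return task
    try:
        return _TASKS[str(task).upper().replace("-", "_")]
    except KeyError:
        raise ParameterError(f"unknown task {task!r}; expected LR or MI_REST")


def split_mi_rest(epochs: EpochSet, guard: float = 0.0,
                  mi_stop: float = 3.0,
                  rest_window: tuple[float, float] = (-4.0, -1.0)
                  ) -> EpochSet:
    """Imagery-vs-rest epochs from full-span trials.

    Each trial yields an imagery epoch ``[0, mi_stop)`` (label ``MI``) and
    a rest epoch cut from the pre-cue ``rest_window`` (label ``REST``),
    re-referenced to the same ``[-guard, mi_stop + guard)`` time axis.
    """
    mi = crop_window(epochs, -guard, mi_stop + guard)
    mi = mi.copy(labels=np.asarray([MI] * mi.n_trials, dtype=object))
    rest = crop_window(epochs, rest_window[0] - guard,
                       rest_window[1] + guard)
    rest = rest.copy(t0=-guard,
                     labels=np.asarray([REST] * rest.n_trials, dtype=object))
    return concatenate([mi, rest])


class Session:
    """One recording session plus a cache of band-filtered versions.

    Filtering with a fixed band is per-trial and data-independent, so the
    cache can be shared between cross-validation folds without leakage;
    everything fitted (filters, selections, classifiers) is computed on
    training trial indices only.
    """

    def __init__(self, epochs: EpochSet, task) -> None:
        self.epochs = epochs
        self.task = get_task(task)
        self._bands: dict[tuple, EpochSet] = {}

    def band(self, band: BandSpec | None) -> EpochSet:
        if band is None:
            return self.epochs
        key = (band.f_lo, band.f_hi, band.transition)
        if key not in self._bands:
            from .preprocessing import fir_bandpass
            self._bands[key] = fir_bandpass(self.epochs, band)
        return self._bands[key]

    def task_epochs(self, band: BandSpec | None = None,
                    idx=None, guard: float = 0.0) -> EpochSet:
        """Task-labelled epochs (optionally band-filtered, trial subset).

        For ``LR`` these are the full-span trials (labels LEFT/RIGHT);
        for ``MI_REST`` the imagery/rest split of the same trials.
        """
        src = self.band(band)
        if idx is not None:
            src = src.subset(idx)
        if self.task.name == "LR":
            return src
        return split_mi_rest(src, guard=guard)

    @property
    def n_trials(self) -> int:
        return self.epochs.n_trials


# ---------------------------------------------------------------------------
# feature selection and classifiers
# ---------------------------------------------------------------------------

def chi2_scores(X: np.ndarray, y) -> np.ndarray:
    """Chi-square relevance of each feature against the class labels.

    Continuous features are min-max rescaled to [0, 1] (chi-square needs
    non-negative values); constant features score 0.
    """
    from sklearn.feature_selection import chi2

    X = np.asarray(X, float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    Xs = (X - lo) / span
    if Xs.min() < -1e-12:
        raise ValueError("features negative after rescaling")
    with np.errstate(invalid="ignore", divide="ignore"):
        scores, _ = chi2(np.clip(Xs, 0.0, None), np.asarray(y, dtype=object))
    return np.nan_to_num(scores, nan=0.0)


def select_k_best(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, ties broken by lower index."""
    if not 0 <= k <= len(scores):
        raise ParameterError(f"k={k} out of range for {len(scores)} features")
    order = np.argsort(-np.asarray(scores), kind="stable")
    return np.sort(order[:k])


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family and hyperparameters.

    ``kind`` is one of LDA, LINEAR_SVM, RBF_SVM, NAIVE_BAYES.  SVM
    regularization defaults to C=1 and the RBF width to scikit-learn's
    ``1 / (n_features * Var(X))``; there is no tuning loop.
    """

    kind: str = "LDA"
    C: float = 1.0
    gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.kind not in ("LDA", "LINEAR_SVM", "RBF_SVM", "NAIVE_BAYES"):
            raise ParameterError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0:
            raise ParameterError("SVM C must be positive")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ParameterError("RBF gamma must be positive")


def train_classifier(X: np.ndarray, y, spec: ClassifierSpec = ClassifierSpec()):
    """Fit the requested classifier; deterministic given fixed inputs."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    y = np.asarray(y, dtype=object).astype(str)
    if len(np.unique(y)) < 2:
        raise DataError("need at least two classes to train a classifier")
    if spec.kind == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif spec.kind == "LINEAR_SVM":
        clf = SVC(kernel="linear", C=spec.C, probability=True,
                  random_state=0)
    elif spec.kind == "RBF_SVM":
        clf = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma, probability=True,
                  random_state=0)
    else:
        clf = GaussianNB()
    return clf.fit(np.asarray(X, float), y)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

class DecodingPipeline:
    """One named feature-extraction pipeline, fitted per training set.

    ``fit`` learns every data-dependent transformation (spatial filters,
    SSD peak frequency, chi-square selection); ``transform`` applies the
    stored transformations unchanged to any trial subset.
    """

    def __init__(self, method: str, task) -> None:
        if method not in METHODS:
            raise ParameterError(f"unknown method {method!r}")
        self.method = method
        self.task = get_task(task)
        self._selection: np.ndarray | None = None
        self._model = None
        self._f_star: float | None = None
        # ONLINE always selects exactly 50 features; other wide feature
        # sets are capped at the same budget
        self._n_select = MAX_FEATURES

    # -- raw (pre-selection) features ------------------------------------
    def _tf_features(self, sess: Session, idx, kind: str) -> FeatureMatrix:
        task = self.task
        eps = sess.task_epochs(WIDE_BAND, idx, guard=task.guard)
        if kind == "stft":
            return stft_features(eps, WIDE_BAND, windows=task.tf_windows)
        return morlet_features(eps, WIDE_BAND.f_lo, WIDE_BAND.f_hi,
                               windows=task.tf_windows)

    def _psd_features(self, sess: Session, idx) -> FeatureMatrix:
        eps = sess.task_epochs(None, idx, guard=0.0)
        return multitaper_psd_features(
            crop_window(eps, *self.task.psd_window))

    def _csp_component_epochs(self, sess: Session, idx) -> EpochSet:
        eps = sess.task_epochs(WIDE_BAND, idx, guard=self.task.guard)
        return apply_filters(self._model, eps)

    def _raw_features(self, sess: Session, idx) -> FeatureMatrix:
        m, task = self.method, self.task
        if m == "STFT":
            return self._tf_features(sess, idx, "stft")
        if m == "Morlet":
            return self._tf_features(sess, idx, "morlet")
        if m in ("PSD", "ONLINE"):
            return self._psd_features(sess, idx)
        if m == "CSP":
            return logvar_features(self._csp_component_epochs(sess, idx),
                                   task.logvar_window)
        if m == "FBCSP":
            band_eps = [sess.task_epochs(b, idx, guard=0.0)
                        for b in self._model.bands]
            return self._model.features(band_eps, select=True)
        if m == "SSD":
            comp = apply_filters(self._model,
                                 sess.task_epochs(self._model.signal_band,
                                                  idx, guard=0.0))
            return logvar_features(comp, task.logvar_window)
        if m == "SSD+CSP":
            comp = apply_filters(
                self._model.composite,
                sess.task_epochs(self._model.ssd.signal_band, idx,
                                 guard=0.0))
            return logvar_features(comp, task.logvar_window)
        if m in ("CSP+STFT", "CSP+Morlet", "CSP+PSD"):
            comp = self._csp_component_epochs(sess, idx)
            if m == "CSP+STFT":
                return stft_features(comp, WIDE_BAND,
                                     windows=task.tf_windows)
            if m == "CSP+Morlet":
                return morlet_features(comp, WIDE_BAND.f_lo, WIDE_BAND.f_hi,
                                       windows=task.tf_windows)
            return multitaper_psd_features(
                crop_window(comp, *task.psd_window))
        raise AssertionError(m)

    # -- fitting ----------------------------------------------------------
    def fit(self, sess: Session, train_idx) -> "DecodingPipeline":
        task = self.task
        m = self.method
        if m in ("CSP", "CSP+STFT", "CSP+Morlet", "CSP+PSD"):
            eps = sess.task_epochs(WIDE_BAND, train_idx, guard=task.guard)
            self._model = fit_csp(eps, task.classes, band=WIDE_BAND,
                                  cov_window=task.logvar_window,
                                  trace_normalize=task.csp_trace_normalize)
        elif m == "FBCSP":
            from .spatial import FBCSP_BANDS
            band_eps = [sess.task_epochs(b, train_idx, guard=0.0)
                        for b in FBCSP_BANDS]
            self._model, _ = fit_fbcsp(
                sess.epochs.subset(train_idx), task.classes,
                cov_window=task.logvar_window,
                logvar_window=task.logvar_window, prefiltered=band_eps,
                trace_normalize=task.csp_trace_normalize)
        elif m in ("SSD", "SSD+CSP"):
            train_full = sess.epochs.subset(train_idx)
            self._f_star = find_suppression_peak(train_full)
            sig, lo, hi = ssd_bands(self._f_star, sess.epochs.sfreq)
            pre = tuple(sess.band(b).subset(train_idx)
                        for b in (sig, lo, hi))
            if m == "SSD":
                self._model = fit_ssd(train_full, self._f_star,
                                      n_keep=task.ssd_n_keep,
                                      prefiltered=pre)
            else:
                csp_eps = sess.task_epochs(sig, train_idx, guard=0.0)
                self._model = fit_ssd_csp(
                    train_full, task.classes, self._f_star,
                    n_keep=task.ssd_n_keep,
                    cov_window=task.logvar_window,
                    csp_epochs=csp_eps, prefiltered=pre,
                    trace_normalize=task.csp_trace_normalize)
        fm = self._raw_features(sess, train_idx)
        if m == "ONLINE" or fm.n_features > self._n_select:
            scores = chi2_scores(fm.X, fm.labels)
            self._selection = select_k_best(
                scores, min(self._n_select, fm.n_features))
        else:
            self._selection = None
        # power features are heavy-tailed; classifiers see log power
        # (log-variance pipelines are already on a log scale)
        self._log_transform = m not in ("CSP", "FBCSP", "SSD", "SSD+CSP")
        return self

    def transform(self, sess: Session, idx) -> FeatureMatrix:
        fm = self._raw_features(sess, idx)
        if self._selection is not None:
            fm = fm.select(self._selection)
        if self._log_transform:
            fm = FeatureMatrix(np.log(np.maximum(fm.X, 1e-300)),
                               fm.feature_desc, fm.labels)
        return fm


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-session cross-validation outcome of one method."""

    task: str
    method: str
    session_id: str
    fold_accuracies: np.ndarray
    mean_accuracy: float

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, float)
        if np.any((self.fold_accuracies < 0) | (self.fold_accuracies > 1)):
            raise ValueError("fold accuracies must lie in [0, 1]")
        if abs(self.mean_accuracy - self.fold_accuracies.mean()) > 1e-12:
            raise ValueError("mean_accuracy inconsistent with folds")


def _fit_predict(pipe: DecodingPipeline, spec: ClassifierSpec,
                 sess_fit: Session, fit_idx,
                 sess_eval: Session, eval_idx) -> float:
    pipe.fit(sess_fit, fit_idx)
    train = pipe.transform(sess_fit, fit_idx)
    clf = train_classifier(train.X, train.labels, spec)
    test = pipe.transform(sess_eval, eval_idx)
    pred = clf.predict(test.X)
    return float(np.mean(pred == test.labels.astype(str)))


def evaluate_cv5(epochs: EpochSet, task, method_name: str,
                 spec: ClassifierSpec = ClassifierSpec(),
                 n_folds: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of one pipeline on one session.

    Folds are over *trials* (for imagery-vs-rest both epochs derived from a
    trial share its fold), stratified by the trial labels with a fixed,
    configurable shuffling seed.
    """
    from sklearn.model_selection import StratifiedKFold

    task = get_task(task)
    sess = Session(epochs, task)
    y = epochs.labels.astype(str)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < n_folds:
        raise DataError(
            f"class imbalance prevents stratified {n_folds}-fold CV "
            f"(min class count {counts.min()})")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        pipe = DecodingPipeline(method_name, task)
        accs.append(_fit_predict(pipe, spec, sess, train_idx,
                                 sess, test_idx))
    accs = np.asarray(accs)
    return CVResult(task=task.name, method=method_name,
                    session_id=epochs.session_id,
                    fold_accuracies=accs, mean_accuracy=float(accs.mean()))


def evaluate_intersession(train: EpochSet, test: EpochSet, task,
                          method_name: str,
                          spec: ClassifierSpec = ClassifierSpec()
                          ) -> tuple[float, float]:
    """Train on one session, test on the other, both directions (A->B,
    B->A)."""
    if train.session_id == test.session_id:
        raise ParameterError("inter-session evaluation needs distinct "
                             "session ids")
    if train.channel_names != test.channel_names:
        raise ParameterError("sessions have mismatched channel sets")
    task = get_task(task)
    out = []
    for a, b in ((train, test), (test, train)):
        sa, sb = Session(a, task), Session(b, task)
        pipe = DecodingPipeline(method_name, task)
        out.append(_fit_predict(pipe, spec, sa, np.arange(a.n_trials),
                                sb, np.arange(b.n_trials)))
    return tuple(out)


def online_pipeline(epochs: EpochSet, seed: int = 0,
                    spec: ClassifierSpec = ClassifierSpec()) -> CVResult:
    """The fixed real-time pipeline: multitaper PSD over the 3-s imagery
    epoch, chi-square top-50 features, LDA; evaluated with 5-fold CV."""
    return evaluate_cv5(epochs, "LR", "ONLINE", spec=spec, seed=seed)


def feedback_level(p: float) -> int:
    """Map a class probability to the 20-level grip display: a linear
    transformation with level = floor(20 p) + 1, capped at 20."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability {p} outside [0, 1]")
    return min(int(np.floor(p * 20)) + 1, 20)


def binomial_threshold(n_trials: int, alpha: float = 0.05,
                       chance: float = 0.5) -> float:
    """Smallest accuracy whose exceedance probability under chance-level
    binomial performance is <= alpha."""
    c = int(sstats.binom.isf(alpha, n_trials, chance)) + 1
    return c / n_trials
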