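"""Session decoding: model-pair training, ROC cross-validation, controls.

The classifier is a pair of Gaussian-emission HMMs, one fitted to each
recording session (day1, day2).  A trial is scored by the *discrimination
function*: the log-likelihood under the day-2 model minus that under the
day-1 model; positive scores favor day 2.  Accuracy is summarized as the
area under the ROC of that score (the Mann-Whitney probability that a
random day-2 trial outscores a random day-1 trial, ties counting one half),
estimated over repeated stratified 90/10 train/test splits.

Controls mirror the study design: the same session-trained models score the
pseudo-random control condition (no retraining), and a one-dimensional
Gaussian classifier on reaction times alone provides the trial-duration
baseline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.utils import check_random_state

from .hmm import GaussianHMM

__all__ = [
    "HmmPairClassifier",
    "RtGaussianClassifier",
    "RocResult",
    "CvReport",
    "roc_area",
    "split_90_10",
    "holdout_split",
    "cross_validate_pair",
    "select_q_pair",
    "fixed_prior_accuracy",
    "rt_baseline",
    "evaluate_control",
    "score_rt_correlation",
    "compare_area_distributions",
]


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Threshold sweep and area for one score/label set."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    area: float


def roc_area(scores, labels, pos_label=None) -> RocResult:
    """ROC of the discrimination scores.

    The area equals the Mann-Whitney U statistic divided by n1*n2: the
    probability that a randomly drawn positive-class trial outscores a
    randomly drawn negative-class one, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"roc_area needs exactly two classes, got {classes!r}")
    if pos_label is None:
        pos_label = classes[1]
    y = (labels == pos_label).astype(int)
    fpr, tpr, thr = roc_curve(y, scores)
    area = float(roc_auc_score(y, scores))
    return RocResult(scores=scores, labels=labels, fpr=fpr, tpr=tpr, thresholds=thr, area=area)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_90_10(
    y,
    n_splits: int = 10,
    seed: int | None = 0,
    test_size: float = 0.1,
    mode: str = "shuffle",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified 90/10 train/test splits, reproducible from ``seed``.

    ``mode='shuffle'`` (default) draws ``n_splits`` independent random
    splits with ~``test_size`` of each class held out; ``mode='kfold'``
    partitions the trials into ``n_splits`` disjoint stratified folds and
    holds each out in turn (statistically preferable when the distribution
    of the per-split areas itself is the object of study, since the test
    sets do not overlap)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need two classes to split")
    small = counts.min()
    if small < 10:
        lacking = classes[counts < 10]
        raise ValueError(
            f"class(es) {list(lacking)} have fewer than 10 trials; "
            "a 90/10 stratified split would starve the test set"
        )
    if mode == "shuffle":
        sss = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=test_size, random_state=seed
        )
    elif mode == "kfold":
        sss = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return [(tr.copy(), te.copy()) for tr, te in sss.split(np.zeros(len(y)), y)]


def holdout_split(
    y, fraction: float = 0.15, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Remove a stratified validation fraction before any model selection."""
    if fraction <= 0:
        return np.arange(len(y)), np.array([], dtype=int)
    sss = StratifiedShuffleSplit(n_splits=1, test_size=fraction, random_state=seed)
    work, held = next(sss.split(np.zeros(len(y)), np.asarray(y)))
    return work, held


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class HmmPairClassifier(ClassifierMixin, BaseEstimator):
    """Two-session classifier: one Gaussian-emission HMM per class.

    ``fit`` takes a list of (L_i, N) trial matrices and a label vector; each
    class's model runs the full K-means -> GMM -> Baum-Welch pipeline on its
    own trials.  ``decision_function`` is the discrimination function
    (log-likelihood under ``classes_[1]`` minus under ``classes_[0]``);
    ``predict`` applies the fixed-prior rule, adding the log of the training
    class proportions to the log-likelihoods.
    """

    def __init__(
        self,
        n_states_1: int = 3,
        n_states_2: int = 4,
        *,
        max_iter: int = 100,
        tol: float = 1e-6,
        reg_covar: float = 1e-6,
        gmm_max_iter: int = 200,
        gmm_tol: float = 1e-6,
        kmeans_restarts: int = 5,
        random_state=None,
    ) -> None:
        self.n_states_1 = n_states_1
        self.n_states_2 = n_states_2
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.gmm_max_iter = gmm_max_iter
        self.gmm_tol = gmm_tol
        self.kmeans_restarts = kmeans_restarts
        self.random_state = random_state

    def fit(self, X, y) -> "HmmPairClassifier":
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("HmmPairClassifier is a two-class model")
        rng = check_random_state(self.random_state)
        self.models_ = []
        for cls, q in zip(self.classes_, (self.n_states_1, self.n_states_2)):
            seqs = [x for x, lab in zip(X, y) if lab == cls]
            model = GaussianHMM(
                n_states=q,
                max_iter=self.max_iter,
                tol=self.tol,
                reg_covar=self.reg_covar,
                gmm_max_iter=self.gmm_max_iter,
                gmm_tol=self.gmm_tol,
                kmeans_restarts=self.kmeans_restarts,
                random_state=rng.randint(2**31 - 1),
            ).fit(seqs)
            self.models_.append(model)
        self.train_proportions_ = np.array(
            [np.mean(y == c) for c in self.classes_], dtype=float
        )
        return self

    def log_likelihoods(self, X) -> np.ndarray:
        """(n_trials, 2) forward log-likelihoods under the two models."""
        return np.column_stack([m.score_sequences(X) for m in self.models_])

    def decision_function(self, X) -> np.ndarray:
        ll = self.log_likelihoods(X)
        return ll[:, 1] - ll[:, 0]

    def predict(self, X) -> np.ndarray:
        ll = self.log_likelihoods(X) + np.log(self.train_proportions_)
        return self.classes_[np.argmax(ll, axis=1)]

    @property
    def selected_q(self) -> tuple[int, int]:
        if hasattr(self, "models_"):
            return tuple(int(m.means_.shape[0]) for m in self.models_)
        return int(self.n_states_1), int(self.n_states_2)


class RtGaussianClassifier(ClassifierMixin, BaseEstimator):
    """Reaction-time-only baseline: one 1-D Gaussian per class.

    The score is the log-density difference, directly comparable to the HMM
    discrimination function but using trial duration alone.  Degenerate
    (constant) training RTs get their variance floored at ``var_floor``
    (1 ms^2 by default).
    """

    def __init__(self, var_floor: float = 1.0) -> None:
        self.var_floor = var_floor

    def fit(self, rt, y) -> "RtGaussianClassifier":
        rt = np.asarray(rt, dtype=float)
        y = np.asarray(y)
        if np.any(rt <= 0):
            raise ValueError("reaction times must be positive")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("RtGaussianClassifier is a two-class model")
        self.means_ = np.array([rt[y == c].mean() for c in self.classes_])
        var = np.array([rt[y == c].var() for c in self.classes_])
        if np.any(var < self.var_floor):
            warnings.warn("near-constant training RTs; variance floored", stacklevel=2)
        self.vars_ = np.maximum(var, self.var_floor)
        return self

    def decision_function(self, rt) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        ll = np.column_stack(
            [
                stats.norm.logpdf(rt, self.means_[k], np.sqrt(self.vars_[k]))
                for k in range(2)
            ]
        )
        return ll[:, 1] - ll[:, 0]

    def predict(self, rt) -> np.ndarray:
        return self.classes_[(self.decision_function(rt) > 0).astype(int)]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-split ROC areas and fixed-prior accuracies for one (Q1, Q2)."""

    areas: list[float]
    accuracies: list[float]
    q1: int
    q2: int
    seed: int | None = None
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    models: list["HmmPairClassifier"] = field(default_factory=list)

    @property
    def n_splits(self) -> int:
        return len(self.areas)

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))

    @property
    def sd_area(self) -> float:
        return float(np.std(self.areas, ddof=1)) if len(self.areas) > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def summary(self) -> dict:
        return {
            "q1": self.q1,
            "q2": self.q2,
            "n_splits": self.n_splits,
            "mean_area": self.mean_area,
            "sd_area": self.sd_area,
            "mean_accuracy": self.mean_accuracy,
        }


def fixed_prior_accuracy(clf, X, y) -> float:
    """Fraction of trials assigned to the correct session when the training
    class proportions enter as log-priors."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty trial list")
    return float(np.mean(clf.predict(X) == y))


def cross_validate_pair(
    X,
    y,
    n_states_1: int,
    n_states_2: int,
    *,
    n_splits: int = 10,
    test_size: float = 0.1,
    seed: int | None = 0,
    keep_models: bool = False,
    split_mode: str = "shuffle",
    **fit_kwargs,
) -> CvReport:
    """Repeated stratified 90/10 cross-validation of a model pair.

    Per split: both HMMs are retrained on the training trials and the test
    trials are scored by the discrimination function; the report carries the
    per-split ROC areas and fixed-prior accuracies (and, optionally, the
    fitted pairs for control-condition evaluation).  ``split_mode`` chooses
    between repeated random draws and disjoint stratified folds (see
    :func:`split_90_10`).
    """
    y = np.asarray(y)
    X = list(X)
    splits = split_90_10(
        y, n_splits=n_splits, seed=seed, test_size=test_size, mode=split_mode
    )
    rng = check_random_state(seed)
    areas: list[float] = []
    accs: list[float] = []
    models: list[HmmPairClassifier] = []
    for train, test in splits:
        clf = HmmPairClassifier(
            n_states_1=n_states_1,
            n_states_2=n_states_2,
            random_state=rng.randint(2**31 - 1),
            **fit_kwargs,
        ).fit([X[i] for i in train], y[train])
        scores = clf.decision_function([X[i] for i in test])
        areas.append(roc_area(scores, y[test], pos_label=clf.classes_[1]).area)
        accs.append(fixed_prior_accuracy(clf, [X[i] for i in test], y[test]))
        if keep_models:
            models.append(clf)
    return CvReport(
        areas=areas,
        accuracies=accs,
        q1=n_states_1,
        q2=n_states_2,
        seed=seed,
        splits=splits,
        models=models,
    )


def select_q_pair(
    X,
    y,
    q_grid=range(3, 9),
    *,
    n_splits: int = 10,
    test_size: float = 0.1,
    seed: int | None = 0,
    **fit_kwargs,
) -> tuple[dict[tuple[int, int], CvReport], tuple[int, int]]:
    """Grid search over (Q1, Q2) state-count pairs.

    Every cell of the Cartesian product of ``q_grid`` with itself is
    cross-validated with the same split stream; the pair with the largest
    mean ROC area wins, ties broken toward the smaller Q1+Q2 (then lexical
    order).  Failed cells are recorded as None-area reports and excluded
    from the argmax.
    """
    grid = list(q_grid)
    if not grid:
        raise ValueError("empty Q grid")
    reports: dict[tuple[int, int], CvReport] = {}
    for q1, q2 in itertools.product(grid, grid):
        try:
            reports[(q1, q2)] = cross_validate_pair(
                X,
                y,
                q1,
                q2,
                n_splits=n_splits,
                test_size=test_size,
                seed=seed,
                **fit_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - cell marked failed, run continues
            warnings.warn(f"Q pair ({q1},{q2}) failed: {exc}", stacklevel=2)
            reports[(q1, q2)] = CvReport(areas=[], accuracies=[], q1=q1, q2=q2, seed=seed)
    ok = {k: r for k, r in reports.items() if r.areas}
    if not ok:
        raise RuntimeError("every Q-grid cell failed")
    best = min(ok, key=lambda k: (-ok[k].mean_area, k[0] + k[1], k))
    return reports, best


def rt_baseline(
    rts, y, *, n_splits: int = 10, test_size: float = 0.1, seed: int | None = 0
) -> CvReport:
    """Cross-validated session classification from reaction times alone."""
    rts = np.asarray(rts, dtype=float)
    y = np.asarray(y)
    splits = split_90_10(y, n_splits=n_splits, seed=seed, test_size=test_size)
    areas, accs = [], []
    for train, test in splits:
        clf = RtGaussianClassifier().fit(rts[train], y[train])
        scores = clf.decision_function(rts[test])
        areas.append(roc_area(scores, y[test], pos_label=clf.classes_[1]).area)
        accs.append(float(np.mean(clf.predict(rts[test]) == y[test])))
    return CvReport(areas=areas, accuracies=accs, q1=0, q2=0, seed=seed, splits=splits)


def evaluate_control(
    models: list[HmmPairClassifier],
    control_X,
    control_y,
    *,
    test_size: float = 0.1,
    seed: int | None = 0,
) -> CvReport:
    """Score control-condition trials with already-trained session models.

    One stratified split of the control set per trained pair; the pair
    scores its split's test portion.  No retraining occurs — the models are
    used exactly as fitted on the structured-sequence trials.
    """
    if not models:
        raise ValueError("no trained model pairs supplied")
    control_y = np.asarray(control_y)
    if len(control_y) == 0:
        raise ValueError("control set is empty")
    control_X = list(control_X)
    splits = split_90_10(
        control_y, n_splits=len(models), seed=seed, test_size=test_size
    )
    areas, accs = [], []
    for clf, (_, test) in zip(models, splits):
        scores = clf.decision_function([control_X[i] for i in test])
        areas.append(roc_area(scores, control_y[test], pos_label=clf.classes_[1]).area)
        accs.append(fixed_prior_accuracy(clf, [control_X[i] for i in test], control_y[test]))
    q1, q2 = models[0].selected_q
    return CvReport(areas=areas, accuracies=accs, q1=q1, q2=q2, seed=seed, splits=splits)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def score_rt_correlation(scores, rts) -> tuple[float, float]:
    """Trial-by-trial Pearson correlation between the discrimination scores
    and the reaction times, with its two-sided p-value."""
    scores = np.asarray(scores, dtype=float)
    rts = np.asarray(rts, dtype=float)
    if scores.shape != rts.shape or scores.size < 3:
        raise ValueError("need equal-length vectors of at least 3 trials")
    if np.std(scores) == 0 or np.std(rts) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(scores, rts)
    return float(r), float(p)


def compare_area_distributions(a, b) -> tuple[float, float]:
    """Welch two-sample t-test on per-split ROC-area lists; returns (t, p).

    Two identical (or jointly constant) lists are reported as p = 1 with a
    warning rather than the 0/0 form of the t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per distribution")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            warnings.warn("identical constant distributions; p set to 1", stacklevel=2)
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
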