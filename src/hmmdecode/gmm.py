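"""Frame pooling and Gaussian-mixture estimation of instantaneous voltages.

The first stage of the decoder ignores time entirely: the N-dimensional
voltage vectors of every frame of every trial in one (day, condition) cell
are pooled into a single cloud, and a Q-component full-covariance Gaussian
mixture is fitted to it by EM, seeded by K-means.  The fitted mixture later
initializes the emission densities (and priors) of a Q-state hidden Markov
model.

:class:`FrameGMM` follows the scikit-learn estimator protocol.  The EM loop
is implemented here rather than delegated because downstream checks need the
per-iteration log-likelihood trace and a scale-aware covariance ridge; the
module-level helpers (:func:`pool_frames`, :func:`kmeans_seed`,
:func:`initial_covariances`) expose the individual initialization steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils import check_random_state

from ._emissions import component_logpdfs, regularize_covariance
from .io import EpochSet

__all__ = [
    "FramePool",
    "pool_frames",
    "kmeans_seed",
    "initial_covariances",
    "FrameGMM",
    "fit_frame_gmm",
]


@dataclass
class FramePool:
    """Pooled instantaneous voltage vectors with per-vector provenance."""

    vectors: np.ndarray  # (n_frames_total, n_contacts)
    source: list[tuple[str, int]]  # (trial_id, frame index) per vector

    def __len__(self) -> int:
        return self.vectors.shape[0]


def pool_frames(
    es: EpochSet, day: str | None = None, condition: str | None = None
) -> FramePool:
    """Pool every frame of the selected (day, condition) trials, regardless
    of within-trial timing.  The pool size equals the summed trial lengths."""
    sub = es.subset(day=day, condition=condition)
    if len(sub) == 0:
        raise ValueError(f"no trials in cell (day={day!r}, condition={condition!r})")
    vectors = np.concatenate([t.data for t in sub], axis=0)
    source = [(t.trial_id, f) for t in sub for f in range(t.n_frames)]
    return FramePool(vectors=vectors, source=source)


def kmeans_seed(
    X: np.ndarray | FramePool, Q: int, seed: int | None = None, n_restarts: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """K-means clustering of the pooled frames (k-means++ seeding,
    ``n_restarts`` restarts, best inertia kept).

    Returns (means (Q, N), assignments (n,)).  Empty clusters are relocated
    to far points by the underlying solver.
    """
    if isinstance(X, FramePool):
        X = X.vectors
    X = np.asarray(X, dtype=float)
    if X.shape[0] < Q:
        raise ValueError(f"pool of {X.shape[0]} vectors cannot seed Q={Q} clusters")
    km = KMeans(n_clusters=Q, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    # report the actual cluster means of the final assignment (exact nearest-
    # mean geometry is asserted downstream on the returned pair)
    return km.cluster_centers_.copy(), labels


def initial_covariances(
    X: np.ndarray | FramePool,
    means: np.ndarray,
    assignments: np.ndarray,
    reg: float = 1e-6,
) -> np.ndarray:
    """Per-cluster sample covariance (divisor n) of the vectors assigned to
    each mean, plus the diagonal ridge.  Singleton or empty clusters fall
    back to the global-scale ridge alone, with a warning."""
    if isinstance(X, FramePool):
        X = X.vectors
    X = np.asarray(X, dtype=float)
    Q, n_dim = means.shape
    covs = np.empty((Q, n_dim, n_dim))
    for k in range(Q):
        members = X[assignments == k]
        if members.shape[0] <= 1:
            warnings.warn(
                f"cluster {k} has {members.shape[0]} member(s); covariance is "
                "the regularization ridge only",
                stacklevel=2,
            )
            covs[k] = regularize_covariance(np.zeros((n_dim, n_dim)), reg)
            continue
        diff = members - means[k]
        cov = diff.T @ diff / members.shape[0]
        covs[k] = regularize_covariance(cov, reg)
    return covs


class FrameGMM(BaseEstimator):
    """Full-covariance Gaussian mixture fitted by EM with K-means seeding.

    Parameters
    ----------
    n_components : int
        Mixture size Q.
    max_iter, tol : int, float
        EM stops when the relative log-likelihood change drops below ``tol``
        or after ``max_iter`` iterations.
    reg_covar : float
        Scale-aware diagonal ridge ``reg_covar * trace(C)/N`` added to every
        covariance update.
    n_restarts : int
        K-means restarts for the seeding step.
    random_state : int, RandomState or None
        Seeds the K-means initialization; EM itself is deterministic.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, covariances_ : mixture parameters.
    loglik_trace_ : per-iteration total data log-likelihood (non-decreasing).
    converged_, n_iter_ : convergence report.
    """

    def __init__(
        self,
        n_components: int = 3,
        *,
        max_iter: int = 200,
        tol: float = 1e-6,
        reg_covar: float = 1e-6,
        n_restarts: int = 5,
        random_state=None,
    ) -> None:
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- estimation ----------------------------------------------------------
    def fit(self, X, y=None, init: tuple | None = None) -> "FrameGMM":
        """Fit on pooled frames ``X`` (n_samples, n_contacts).

        ``init`` optionally supplies (means, covariances, weights) and skips
        the K-means seeding.
        """
        if isinstance(X, FramePool):
            X = X.vectors
        X = np.asarray(X, dtype=float)
        Q = int(self.n_components)
        if X.ndim != 2 or X.shape[0] < Q:
            raise ValueError("need a 2-D pool with at least n_components rows")
        if init is None:
            seed = check_random_state(self.random_state).randint(2**31 - 1)
            means, labels = kmeans_seed(X, Q, seed=seed, n_restarts=self.n_restarts)
            covs = initial_covariances(X, means, labels, reg=self.reg_covar)
            counts = np.bincount(labels, minlength=Q).astype(float)
            weights = np.maximum(counts, 1e-12)
            weights /= weights.sum()
        else:
            means, covs, weights = (np.asarray(a, dtype=float) for a in init)
            means = means.copy()
            covs = covs.copy()
            weights = weights / weights.sum()

        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E step
            logp = component_logpdfs(X, means, covs) + np.log(weights)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logp - norm[:, None])
            if prev_ll > -np.inf and abs(ll - prev_ll) <= self.tol * abs(ll):
                converged = True
                break
            prev_ll = ll
            # M step
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            weights = nk / nk.sum()
            means = (resp.T @ X) / nk[:, None]
            for k in range(Q):
                diff = X - means[k]
                cov = (resp[:, k, None] * diff).T @ diff / nk[k]
                covs[k] = regularize_covariance(cov, self.reg_covar)

        self.weights_ = weights
        self.means_ = means
        self.covariances_ = covs
        self.loglik_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    # -- densities -----------------------------------------------------------
    def score_samples(self, X) -> np.ndarray:
        """Per-sample mixture log-density."""
        logp = component_logpdfs(X, self.means_, self.covariances_) + np.log(
            self.weights_
        )
        return logsumexp(logp, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibilities (rows sum to 1)."""
        logp = component_logpdfs(X, self.means_, self.covariances_) + np.log(
            self.weights_
        )
        return np.exp(logp - logsumexp(logp, axis=1)[:, None])

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "Q": int(self.n_components),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covariances_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameGMM":
        est = cls(n_components=int(d["Q"]))
        est.weights_ = np.asarray(d["weights"], dtype=float)
        est.means_ = np.asarray(d["means"], dtype=float)
        est.covariances_ = np.asarray(d["covariances"], dtype=float)
        est.loglik_trace_ = np.asarray(d.get("loglik_trace", []), dtype=float)
        est.converged_ = True
        return est

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FrameGMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_frame_gmm(
    X, Q: int, seed: int | None = None, **kwargs
) -> FrameGMM:
    """Thin functional wrapper: K-means -> initial covariances -> EM."""
    return FrameGMM(n_components=Q, random_state=seed, **kwargs).fit(X)
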