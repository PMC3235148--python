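"""Gaussian-emission hidden Markov model for variable-length trials.

Each hidden state is a quasi-stable multichannel voltage configuration: a
single N-dimensional Gaussian (mean topography + full covariance).  A trial
is modeled as a Markov chain over Q such states observed through those
Gaussians.  Estimation follows the classical two-stage recipe: the emissions
(and the state priors) come from a Q-component Gaussian mixture fitted to
the pooled frames, the transition matrix starts uniform, and Baum-Welch
re-estimates everything on the full set of trials, pooling expected
sufficient statistics across sequences of different lengths.

All recursions run in log space (log-sum-exp), batched across trials, so
epochs of up to thousands of frames are handled without underflow.  The
transition matrix is stored row-stochastic — ``transmat_[i, j] =
P(next = j | current = i)`` — and converted to/from the column-stochastic
convention ``a_ij = P(current = i | previous = j)`` only at the
serialization boundary.

Tie-breaking: Viterbi resolves equal-probability predecessors (and equal
terminal states) toward the lowest state index, so decoding is
deterministic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from ._emissions import component_logpdfs, regularize_covariance
from .gmm import FrameGMM

__all__ = ["GaussianHMM", "init_from_gmm", "save_model", "load_model"]

_EPS = 1e-300


def _as_sequences(X) -> list[np.ndarray]:
    """Accept a single (L, N) array or a list of them."""
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return [np.asarray(X, dtype=float)]
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in X]
    if not seqs:
        raise ValueError("need at least one sequence")
    widths = {s.shape[1] for s in seqs}
    if len(widths) > 1:
        raise ValueError(f"sequences disagree on dimension: {sorted(widths)}")
    return seqs


def _pad_logB(logB_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trial emission log-probs into (T, Lmax, Q) with -inf-free
    padding (padded entries are 0 and never read through the masks)."""
    T = len(logB_list)
    Lmax = max(b.shape[0] for b in logB_list)
    Q = logB_list[0].shape[1]
    out = np.zeros((T, Lmax, Q))
    lengths = np.empty(T, dtype=int)
    for i, b in enumerate(logB_list):
        out[i, : b.shape[0]] = b
        lengths[i] = b.shape[0]
    return out, lengths


def _batched_forward(
    logB: np.ndarray, lengths: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-space forward pass over a padded batch.

    Returns (log_alpha (T, Lmax, Q), loglik (T,)).  For frames beyond a
    trial's length the alpha row is frozen at its final value.
    """
    T, Lmax, Q = logB.shape
    log_alpha = np.empty((T, Lmax, Q))
    la = log_pi[None, :] + logB[:, 0]
    log_alpha[:, 0] = la
    for t in range(1, Lmax):
        x = la[:, :, None] + log_A[None, :, :]  # (T, i, j)
        m = x.max(axis=1)
        with np.errstate(divide="ignore"):
            s = m + np.log(np.exp(x - m[:, None, :]).sum(axis=1))
        la_new = s + logB[:, t]
        active = t < lengths
        la = np.where(active[:, None], la_new, la)
        log_alpha[:, t] = la
    loglik = logsumexp(la, axis=1)
    return log_alpha, loglik


def _batched_backward(
    logB: np.ndarray, lengths: np.ndarray, log_A: np.ndarray
) -> np.ndarray:
    """Log-space backward pass; beta is 0 at each trial's last frame."""
    T, Lmax, Q = logB.shape
    log_beta = np.zeros((T, Lmax, Q))
    lb = np.zeros((T, Q))
    for t in range(Lmax - 2, -1, -1):
        x = log_A[None, :, :] + (logB[:, t + 1] + lb)[:, None, :]  # (T, i, j)
        m = x.max(axis=2)
        with np.errstate(divide="ignore"):
            lb_new = m + np.log(np.exp(x - m[:, :, None]).sum(axis=2))
        active = (t + 1) < lengths
        lb = np.where(active[:, None], lb_new, lb)
        log_beta[:, t] = lb
    return log_beta


class GaussianHMM(BaseEstimator):
    """Hidden Markov model with one full-covariance Gaussian per state.

    Parameters
    ----------
    n_states : int
        Number of hidden states Q.
    max_iter, tol : int, float
        Baum-Welch stops when the relative change of the total training
        log-likelihood drops below ``tol`` or after ``max_iter`` iterations.
    reg_covar : float
        Diagonal ridge ``reg_covar * trace(C)/N`` on every covariance update.
    gmm_max_iter, gmm_tol, kmeans_restarts :
        Forwarded to the K-means -> GMM initialization stage.
    min_occupancy : float
        States whose total expected occupancy falls below this many frames
        keep their previous emission parameters for that iteration instead
        of being re-estimated (prevents state deletion by collapse).
    random_state : int, RandomState or None
        Seeds the K-means initialization only.

    Attributes (after ``fit`` or ``from_params``)
    ---------------------------------------------
    startprob_ : (Q,) state priors pi.
    transmat_ : (Q, Q) row-stochastic transition matrix.
    means_, covars_ : (Q, N), (Q, N, N) emission parameters.
    loglik_trace_ : per-Baum-Welch-iteration total log-likelihood.
    """

    def __init__(
        self,
        n_states: int = 3,
        *,
        max_iter: int = 100,
        tol: float = 1e-6,
        reg_covar: float = 1e-6,
        gmm_max_iter: int = 200,
        gmm_tol: float = 1e-6,
        kmeans_restarts: int = 5,
        min_occupancy: float = 1.0,
        random_state=None,
    ) -> None:
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.gmm_max_iter = gmm_max_iter
        self.gmm_tol = gmm_tol
        self.kmeans_restarts = kmeans_restarts
        self.min_occupancy = min_occupancy
        self.random_state = random_state

    # -- construction --------------------------------------------------------
    @classmethod
    def from_params(cls, startprob, transmat, means, covars, **kwargs) -> "GaussianHMM":
        """Build a model from explicit parameters (row-stochastic transmat)."""
        m = cls(n_states=np.asarray(means).shape[0], **kwargs)
        m._set_params_checked(
            np.asarray(startprob, dtype=float),
            np.asarray(transmat, dtype=float),
            np.asarray(means, dtype=float),
            np.asarray(covars, dtype=float),
        )
        m.loglik_trace_ = np.asarray([])
        return m

    def _set_params_checked(self, pi, A, means, covars) -> None:
        Q = means.shape[0]
        if pi.shape != (Q,) or A.shape != (Q, Q):
            raise ValueError("parameter shapes inconsistent with n_states")
        if not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise ValueError("priors must sum to 1")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.startprob_ = pi
        self.transmat_ = A
        self.means_ = means
        self.covars_ = covars

    # -- estimation ----------------------------------------------------------
    def fit(self, X, y=None, init: FrameGMM | None = None) -> "GaussianHMM":
        """K-means -> GMM -> Baum-Welch on a list of (L_i, N) trials.

        ``init`` may supply a fitted :class:`FrameGMM` to skip the pooled
        initialization; otherwise one is fitted to the concatenated frames.
        Warm-started models (parameters already set and ``init='params'``
        not needed — just pass the same instance) are re-estimated from
        their current parameters when ``self`` already carries parameters
        and ``init`` is the string ``"self"``.
        """
        seqs = _as_sequences(X)
        Q = int(self.n_states)
        pool = np.concatenate(seqs, axis=0)
        if init == "self":
            if not hasattr(self, "means_"):
                raise ValueError("init='self' requires existing parameters")
        else:
            if init is None:
                seed = check_random_state(self.random_state).randint(2**31 - 1)
                init = FrameGMM(
                    n_components=Q,
                    max_iter=self.gmm_max_iter,
                    tol=self.gmm_tol,
                    reg_covar=self.reg_covar,
                    n_restarts=self.kmeans_restarts,
                    random_state=seed,
                ).fit(pool)
            pi, A, means, covars = _gmm_to_hmm_params(init)
            self._set_params_checked(pi, A, means, covars)

        trace: list[float] = []
        prev_ll = -np.inf
        lengths = np.array([s.shape[0] for s in seqs])
        offsets = np.cumsum(lengths)[:-1]
        for _ in range(self.max_iter):
            logB_list = np.split(
                component_logpdfs(pool, self.means_, self.covars_), offsets
            )
            logB, _ = _pad_logB(logB_list)
            with np.errstate(divide="ignore"):
                log_pi = np.log(np.maximum(self.startprob_, _EPS))
                log_A = np.log(np.maximum(self.transmat_, _EPS))
            log_alpha, loglik = _batched_forward(logB, lengths, log_pi, log_A)
            if not np.all(np.isfinite(loglik)):
                raise FloatingPointError(
                    f"non-finite likelihood at Baum-Welch iteration {len(trace)}"
                )
            ll = float(loglik.sum())
            trace.append(ll)
            if prev_ll > -np.inf and abs(ll - prev_ll) <= self.tol * abs(ll):
                break
            prev_ll = ll

            log_beta = _batched_backward(logB, lengths, log_A)
            log_gamma = log_alpha + log_beta - loglik[:, None, None]
            gamma = np.exp(log_gamma)
            frame_mask = np.arange(logB.shape[1])[None, :] < lengths[:, None]
            gamma *= frame_mask[:, :, None]

            # transition counts
            xi_sum = np.zeros((Q, Q))
            for t in range(logB.shape[1] - 1):
                act = (t + 1) < lengths
                if not act.any():
                    continue
                lx = (
                    log_alpha[:, t, :, None]
                    + log_A[None, :, :]
                    + (logB[:, t + 1] + log_beta[:, t + 1])[:, None, :]
                    - loglik[:, None, None]
                )
                xi_sum += np.einsum("tij,t->ij", np.exp(lx), act.astype(float))

            # M step
            pi_new = gamma[:, 0, :].sum(axis=0)
            pi_new /= pi_new.sum()
            row = xi_sum.sum(axis=1, keepdims=True)
            A_new = np.where(row > 0, xi_sum / np.maximum(row, _EPS), 1.0 / Q)

            gamma_flat = gamma[frame_mask]  # (n_frames_total, Q)
            occ = gamma_flat.sum(axis=0)
            means_new = self.means_.copy()
            covars_new = self.covars_.copy()
            for k in range(Q):
                if occ[k] < self.min_occupancy:
                    continue  # freeze starving state's emission this round
                mu = gamma_flat[:, k] @ pool / occ[k]
                diff = pool - mu
                cov = (gamma_flat[:, k, None] * diff).T @ diff / occ[k]
                means_new[k] = mu
                covars_new[k] = regularize_covariance(cov, self.reg_covar)

            self.startprob_ = pi_new
            self.transmat_ = A_new
            self.means_ = means_new
            self.covars_ = covars_new

        self.loglik_trace_ = np.asarray(trace)
        return self

    # -- inference -----------------------------------------------------------
    def score(self, X) -> float:
        """log p(trial | model) by the forward recursion (one sequence)."""
        return float(self.score_sequences([np.asarray(X, dtype=float)])[0])

    def score_sequences(self, X) -> np.ndarray:
        """Forward log-likelihood of each sequence, batched."""
        seqs = _as_sequences(X)
        if seqs[0].shape[1] != self.means_.shape[1]:
            raise ValueError(
                f"trial has {seqs[0].shape[1]} contacts, model expects "
                f"{self.means_.shape[1]}"
            )
        lengths = np.array([s.shape[0] for s in seqs])
        logB_list = np.split(
            component_logpdfs(np.concatenate(seqs, axis=0), self.means_, self.covars_),
            np.cumsum(lengths)[:-1],
        )
        logB, lengths = _pad_logB(logB_list)
        with np.errstate(divide="ignore"):
            log_pi = np.log(np.maximum(self.startprob_, _EPS))
            log_A = np.log(np.maximum(self.transmat_, _EPS))
        _, loglik = _batched_forward(logB, lengths, log_pi, log_A)
        return loglik

    def posteriors(self, X) -> np.ndarray:
        """Per-frame posterior state marginals gamma for one sequence."""
        seq = np.atleast_2d(np.asarray(X, dtype=float))
        logB = component_logpdfs(seq, self.means_, self.covars_)[None]
        lengths = np.array([seq.shape[0]])
        with np.errstate(divide="ignore"):
            log_pi = np.log(np.maximum(self.startprob_, _EPS))
            log_A = np.log(np.maximum(self.transmat_, _EPS))
        log_alpha, loglik = _batched_forward(logB, lengths, log_pi, log_A)
        log_beta = _batched_backward(logB, lengths, log_A)
        return np.exp(log_alpha[0] + log_beta[0] - loglik[0])

    def decode(self, X, method: str = "viterbi") -> np.ndarray:
        """Most likely state path for one sequence.

        ``viterbi`` (default) returns the joint MAP path; ``posterior``
        returns the per-frame argmax of the posterior marginals.
        """
        if method == "posterior":
            return np.argmax(self.posteriors(X), axis=1)
        if method != "viterbi":
            raise ValueError(f"unknown decode method {method!r}")
        seq = np.atleast_2d(np.asarray(X, dtype=float))
        logB = component_logpdfs(seq, self.means_, self.covars_)
        with np.errstate(divide="ignore"):
            log_pi = np.log(np.maximum(self.startprob_, _EPS))
            log_A = np.log(np.maximum(self.transmat_, _EPS))
        L, Q = logB.shape
        delta = log_pi + logB[0]
        psi = np.empty((L, Q), dtype=int)
        for t in range(1, L):
            m = delta[:, None] + log_A  # (i, j)
            psi[t] = np.argmax(m, axis=0)  # first (lowest-index) max on ties
            delta = m[psi[t], np.arange(Q)] + logB[t]
        path = np.empty(L, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(L - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        return path

    def sample(self, n_frames: int, random_state=None) -> tuple[np.ndarray, np.ndarray]:
        """Draw one sequence: returns (data (L, N), hidden path (L,))."""
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        Q, n_dim = self.means_.shape
        chols = [np.linalg.cholesky(self.covars_[k]) for k in range(Q)]
        path = np.empty(n_frames, dtype=int)
        data = np.empty((n_frames, n_dim))
        state = int(rng.choice(Q, p=self.startprob_))
        for t in range(n_frames):
            if t > 0:
                state = int(rng.choice(Q, p=self.transmat_[state]))
            path[t] = state
            data[t] = self.means_[state] + chols[state] @ rng.standard_normal(n_dim)
        return data, path

    # -- identity ------------------------------------------------------------
    @property
    def fingerprint(self) -> str:
        """Stable hash of the model parameters (used to enforce same-model
        comparisons downstream)."""
        h = hashlib.sha256()
        for arr in (self.startprob_, self.transmat_, self.means_, self.covars_):
            h.update(np.ascontiguousarray(np.round(arr, 12)).tobytes())
        return h.hexdigest()[:16]

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-compatible parameters.  The transition matrix is written in
        the column-stochastic convention a_ij = P(current=i | previous=j)."""
        return {
            "Q": int(self.means_.shape[0]),
            "priors": self.startprob_.tolist(),
            "transition_matrix_colstochastic": self.transmat_.T.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covars_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        A = np.asarray(d["transition_matrix_colstochastic"], dtype=float).T
        return cls.from_params(d["priors"], A, d["means"], d["covariances"])


def _gmm_to_hmm_params(g: FrameGMM):
    Q = g.means_.shape[0]
    pi = g.weights_ / g.weights_.sum()
    A = np.full((Q, Q), 1.0 / Q)
    return pi, A, g.means_.copy(), g.covariances_.copy()


def init_from_gmm(g: FrameGMM, **kwargs) -> GaussianHMM:
    """HMM with emissions/priors taken from a fitted mixture and a uniform
    transition matrix — the starting point for Baum-Welch."""
    pi, A, means, covars = _gmm_to_hmm_params(g)
    return GaussianHMM.from_params(pi, A, means, covars, **kwargs)


def save_model(model: GaussianHMM, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.to_dict()))
    return path


def load_model(path: str | Path) -> GaussianHMM:
    d = json.loads(Path(path).read_text())
    return GaussianHMM.from_dict(d)
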