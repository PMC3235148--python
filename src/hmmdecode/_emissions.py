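"""Multivariate-Gaussian log-density kernels shared by the GMM and HMM."""

from __future__ import annotations

import numpy as np
from scipy import linalg

_LOG2PI = np.log(2.0 * np.pi)


def regularize_covariance(cov: np.ndarray, eps: float) -> np.ndarray:
    """Scale-aware ridge: add ``eps * trace(C)/N`` to the diagonal.

    Falls back to ``eps`` itself when the trace is not positive (all-zero
    scatter), so the result is always positive definite for eps > 0.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    ridge = eps * float(np.trace(cov)) / n
    if not np.isfinite(ridge) or ridge <= 0.0:
        ridge = eps
    return cov + ridge * np.eye(n)


def gaussian_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x; mean, cov) for every row of X, via Cholesky."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        chol = linalg.cholesky(regularize_covariance(cov, 1e-6), lower=True)
    diff = X - mean
    sol = linalg.solve_triangular(chol, diff.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (n * _LOG2PI + logdet + maha)


def component_logpdfs(
    X: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> np.ndarray:
    """Per-component Gaussian log-densities: (n_samples, n_components)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Q = means.shape[0]
    out = np.empty((X.shape[0], Q))
    for k in range(Q):
        out[:, k] = gaussian_logpdf(X, means[k], covariances[k])
    return out
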