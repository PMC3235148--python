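"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

from hmmdecode._emissions import component_logpdfs
from hmmdecode.io import EpochSet, Trial


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's recursions)
# ---------------------------------------------------------------------------

def brute_force_loglik(pi, A, means, covs, X):
    """log p(X) by explicit summation over all Q^L state paths."""
    from scipy.special import logsumexp

    logB = component_logpdfs(X, np.asarray(means), np.asarray(covs))
    L, Q = logB.shape
    lps = []
    for path in itertools.product(range(Q), repeat=L):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, L):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        lps.append(lp)
    return float(logsumexp(lps))


def brute_force_viterbi(pi, A, means, covs, X):
    """argmax path by exhaustive enumeration (first maximum on ties)."""
    logB = component_logpdfs(X, np.asarray(means), np.asarray(covs))
    L, Q = logB.shape
    best, best_lp = None, -np.inf
    for path in itertools.product(range(Q), repeat=L):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, L):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best_lp:  # strict: ties keep the earlier (lexicographically
            best, best_lp = path, lp  # smaller) path, matching the tie-break
    return np.array(best)


def random_hmm_params(rng, q_max=3, n_max=2):
    """A random valid parameter set for oracle comparisons."""
    Q = int(rng.integers(1, q_max + 1))
    N = int(rng.integers(1, n_max + 1))
    pi = rng.dirichlet(np.ones(Q))
    A = rng.dirichlet(np.ones(Q), size=Q)
    means = rng.normal(0.0, 2.0, size=(Q, N))
    covs = np.stack(
        [np.diag(rng.uniform(0.5, 2.0, size=N)) for _ in range(Q)]
    )
    return pi, A, means, covs


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_epochs(rng):
    """A small labeled EpochSet (2 contacts, 2 days x S/C) for plumbing tests."""
    trials = []
    k = 0
    for day in ("day1", "day2"):
        for cond in ("S", "C"):
            for _ in range(12):
                L = int(rng.integers(5, 12))
                shift = 1.0 if day == "day2" else 0.0
                data = rng.normal(shift, 1.0, size=(L, 2))
                trials.append(
                    Trial(data, day, cond, rt_ms=L * 1000 / 128.0,
                          trial_id=f"t{k:03d}")
                )
                k += 1
    return EpochSet(trials, sampling_rate_hz=128.0)
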