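"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's forward/backward code paths: the
likelihood is computed by exhaustively enumerating all m^T state paths and
summing the joint density over them, and posteriors by accumulating the
same per-path weights.  Feasible only for tiny chains (T <= 8, m <= 3).
"""

import itertools

import numpy as np
from scipy.stats import norm


def _density_table(y, observed, means, sds):
    """D[t, j] = P(y_t | S_t = j), with 1 at missing epochs."""
    D = norm.pdf(y[:, None], np.asarray(means)[None, :], np.asarray(sds)[None, :])
    D[~np.asarray(observed)] = 1.0
    return D


def _enumerate(delta, A, means, sds, y, observed):
    y = np.asarray(y, dtype=float)
    if observed is None:
        observed = ~np.isnan(y)
    yy = np.where(np.asarray(observed), y, 0.0)
    D = _density_table(yy, observed, means, sds)
    m, T = len(delta), len(y)
    A_for_step = A if callable(A) else (lambda t: A)
    A_tab = [None] + [np.asarray(A_for_step(t)) for t in range(1, T)]
    for path in itertools.product(range(m), repeat=T):
        w = delta[path[0]] * D[0, path[0]]
        for t in range(1, T):
            w *= A_tab[t][path[t - 1], path[t]] * D[t, path[t]]
        yield path, w


def enum_loglik(delta, A, means, sds, y, observed=None):
    """Log-likelihood by summation over all state paths.

    ``A`` is either a single m×m matrix or a callable ``t -> matrix``
    giving the matrix for the transition into epoch t (t >= 1).
    """
    return np.log(sum(w for _, w in _enumerate(delta, A, means, sds, y, observed)))


def enum_posterior(delta, A, means, sds, y, observed=None):
    """Smoothing probabilities P(S_t = j | Y) by path enumeration."""
    T, m = len(y), len(delta)
    post = np.zeros((T, m))
    total = 0.0
    for path, w in _enumerate(delta, A, means, sds, y, observed):
        total += w
        for t, j in enumerate(path):
            post[t, j] += w
    return post / total


def random_instance(rng, max_T=8, max_m=3, p_missing=0.25):
    """Random small HMM + data, with missing epochs."""
    m = int(rng.integers(1, max_m + 1))
    T = int(rng.integers(1, max_T + 1))
    delta = rng.dirichlet(np.ones(m))
    A = rng.dirichlet(np.ones(m), size=m)
    means = np.sort(rng.normal(0, 3, size=m))
    sds = rng.uniform(0.3, 2.0, size=m)
    y = rng.normal(0, 3, size=T)
    missing = rng.random(T) < p_missing
    y[missing] = np.nan
    return delta, A, means, sds, y
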