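"""Scaled forward/backward recursions (numba-compiled).

The recursions use per-step normalisation (each forward vector is rescaled
to sum to one and the log of the scale factor accumulated), which keeps the
arithmetic in the well-conditioned range without resorting to log-sum-exp.

Missing observations enter through the emission-likelihood matrix ``B``:
a missing epoch contributes a row of ones (the identity conditional
probability matrix), which marginalises the observation exactly and
propagates the transition matrix across the gap.

Time-varying transitions are passed as a bank of unique matrices ``A``
(shape ``(U, m, m)``) plus an index array ``aidx`` mapping each step to its
matrix; a homogeneous chain uses ``U = 1`` with a zero index.  ``aidx[t]``
selects the matrix governing the transition *into* epoch ``t``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward", "backward", "emission_likelihoods", "transition_counts"]

_TINY = 1e-300


@njit(cache=True)
def forward(delta, A, aidx, B):
    """Scaled forward pass.

    Returns ``(loglik, alpha, c)`` where ``alpha[t]`` is the normalised
    forward vector P(S_t | Y^(t)) and ``c[t]`` the per-step scale factor;
    ``loglik = sum(log c)``.
    """
    T, m = B.shape
    alpha = np.empty((T, m))
    c = np.empty(T)
    a = delta * B[0]
    s = a.sum()
    if s < _TINY:
        s = _TINY
    c[0] = s
    alpha[0] = a / s
    for t in range(1, T):
        At = A[aidx[t]]
        a = np.zeros(m)
        for j in range(m):
            aj = alpha[t - 1, j]
            if aj > 0.0:
                for k in range(m):
                    a[k] += aj * At[j, k]
        a *= B[t]
        s = a.sum()
        if s < _TINY:
            s = _TINY
        c[t] = s
        alpha[t] = a / s
    return np.log(c).sum(), alpha, c


@njit(cache=True)
def backward(A, aidx, B, c):
    """Scaled backward pass matching :func:`forward`'s normalisation, so
    that ``alpha[t] * beta[t]`` are the smoothing probabilities."""
    T, m = B.shape
    beta = np.empty((T, m))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        At = A[aidx[t + 1]]
        nxt = B[t + 1] * beta[t + 1]
        for j in range(m):
            acc = 0.0
            for k in range(m):
                acc += At[j, k] * nxt[k]
            beta[t, j] = acc / c[t + 1]
    return beta


@njit(cache=True)
def emission_likelihoods(y, observed, means, sds):
    """Gaussian emission likelihood matrix B (T×m); ones at missing epochs."""
    T = y.shape[0]
    m = means.shape[0]
    B = np.empty((T, m))
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * sds)
    for t in range(T):
        if observed[t]:
            for j in range(m):
                z = (y[t] - means[j]) / sds[j]
                B[t, j] = norm[j] * np.exp(-0.5 * z * z)
        else:
            for j in range(m):
                B[t, j] = 1.0
    return B


@njit(cache=True)
def transition_counts(alpha, beta, c, A, B):
    """Expected homogeneous transition counts Σ_t ξ_t (m×m) for the E-step."""
    T, m = B.shape
    xi = np.zeros((m, m))
    for t in range(1, T):
        w = B[t] * beta[t] / c[t]
        for j in range(m):
            aj = alpha[t - 1, j]
            if aj > 0.0:
                for k in range(m):
                    xi[j, k] += aj * A[j, k] * w[k]
    return xi
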