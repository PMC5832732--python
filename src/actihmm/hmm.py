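"""Homogeneous Gaussian hidden Markov model for activity series.

The observed series :math:`Y_t` (square-root scale) is modelled as
conditionally Gaussian given an unobserved activity state
:math:`S_t \\in \\{1,\\dots,m\\}` that follows a first-order Markov chain
with transition matrix :math:`\\Gamma` and initial distribution
:math:`\\delta`:

.. math::

    L = \\delta\\, P(y_1)\\, \\Gamma P(y_2) \\cdots \\Gamma P(y_T)\\, 1',

where :math:`P(y_t)` is the diagonal matrix of state-conditional Gaussian
densities.  Missing epochs replace :math:`P(y_t)` by the identity, which
marginalises the observation and simply propagates the transition matrix
across the gap.

Fitting is by the Baum–Welch (EM) algorithm with multiple seeded starts
(the likelihood can be multimodal).  States are always relabelled in order
of ascending emission mean, so state 0 is the inactive (IA) state, and for
the conventional ``n_states = 3`` states 1 and 2 are the moderately (MA)
and highly active (HA) states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from . import _kernels
from .series import SCALE_SQRT, ActivitySeries

__all__ = [
    "GaussianHMM",
    "StateProbabilities",
    "fit_homogeneous",
    "log_likelihood",
    "smooth",
    "local_decode",
    "information_criteria",
    "pseudo_residuals",
    "load_fit",
]

SD_FLOOR = 1e-4  # on the sqrt-count scale; prevents emission collapse


class _DegenerateStart(RuntimeError):
    pass


@dataclass
class StateProbabilities:
    """Smoothed state probabilities P(S_t = j | Y^(T)), one row per epoch."""

    probs: np.ndarray
    time_grid: Optional[pd.DatetimeIndex] = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a T×m matrix")

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]


def _extract(series: Union[ActivitySeries, np.ndarray]):
    """Return (values, observed-mask, time grid) from a series or array.

    Arrays use NaN to mark missing epochs and carry no time grid.
    """
    if isinstance(series, ActivitySeries):
        if series.scale_tag != SCALE_SQRT:
            raise ValueError(
                "HMM operates on the sqrt_mean_counts scale; got "
                f"{series.scale_tag!r} (run preprocess.prepare first)"
            )
        y = series.values.copy()
        observed = ~series.missing_mask
        grid = series.timestamps
    else:
        y = np.asarray(series, dtype=float).ravel().copy()
        observed = ~np.isnan(y)
        grid = None
    if y.size == 0:
        raise ValueError("series is empty")
    y[~observed] = 0.0  # value is never read at missing epochs
    return y, observed, grid


_HOMOG_IDX_CACHE: dict[int, np.ndarray] = {}


def _zero_idx(T: int) -> np.ndarray:
    idx = _HOMOG_IDX_CACHE.get(T)
    if idx is None or idx.size != T:
        idx = np.zeros(T, dtype=np.int64)
        _HOMOG_IDX_CACHE[T] = idx
    return idx


class GaussianHMM(BaseEstimator):
    """Homogeneous Gaussian HMM fitted by Baum–Welch EM.

    Parameters
    ----------
    n_states : int
        Number of latent activity states ``m`` (the field convention for
        actigraphy is 3: IA / MA / HA).
    n_starts : int
        Number of EM initialisations.  The first start places state means
        on the (2j−1)/(2m) empirical quantiles with a common sd and a
        0.9-diagonal transition matrix; further starts jitter the means
        with seeded noise.
    tol : float
        Relative log-likelihood change below which EM stops.
    max_iter : int
        Iteration cap per start.
    random_state : int
        Seed for the start jitter.
    count_delta_in_params : bool
        Whether the ``m − 1`` free entries of the initial distribution are
        counted in ``n_params_`` (and hence penalised by AIC/BIC).

    Attributes
    ----------
    means_, sds_ : ndarray (m,)
        Emission parameters on the sqrt-count scale, means ascending.
    transmat_ : ndarray (m, m)
        Estimated transition matrix Γ.
    startprob_ : ndarray (m,)
        Estimated initial distribution δ (often degenerate: the chain
        starts in whichever state the first observations favour).
    loglik_, n_params_, converged_, n_iter_ : fit metadata.
    """

    def __init__(
        self,
        n_states: int = 3,
        n_starts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 500,
        random_state: int = 0,
        count_delta_in_params: bool = True,
    ):
        self.n_states = n_states
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.count_delta_in_params = count_delta_in_params

    # ------------------------------------------------------------------
    @classmethod
    def from_params(
        cls,
        delta,
        means,
        sds,
        transmat,
        *,
        sort_states: bool = False,
        **init_kwargs,
    ) -> "GaussianHMM":
        """Construct a ready-to-use model from explicit parameters."""
        means = np.asarray(means, dtype=float)
        est = cls(n_states=means.size, **init_kwargs)
        est.startprob_ = np.asarray(delta, dtype=float)
        est.means_ = means
        est.sds_ = np.asarray(sds, dtype=float)
        est.transmat_ = np.asarray(transmat, dtype=float)
        est._validate_params_()
        if sort_states:
            est._sort_states_()
        est.loglik_ = np.nan
        est.n_params_ = est._n_params()
        est.converged_ = True
        est.n_iter_ = 0
        return est

    def _validate_params_(self) -> None:
        m = self.n_states
        if self.startprob_.shape != (m,) or self.means_.shape != (m,) or self.sds_.shape != (m,):
            raise ValueError("parameter shapes inconsistent with n_states")
        if self.transmat_.shape != (m, m):
            raise ValueError("transition matrix must be m×m")
        if np.any(self.sds_ <= 0):
            raise ValueError("emission sds must be strictly positive")
        if abs(self.startprob_.sum() - 1) > 1e-8 or np.any(self.startprob_ < -1e-12):
            raise ValueError("delta must be a probability vector")
        if np.any(np.abs(self.transmat_.sum(axis=1) - 1) > 1e-8) or np.any(
            self.transmat_ < -1e-12
        ):
            raise ValueError("transition matrix rows must sum to 1")

    def _n_params(self) -> int:
        m = self.n_states
        n = 2 * m + m * (m - 1)
        if self.count_delta_in_params:
            n += m - 1
        return n

    def _sort_states_(self) -> None:
        order = np.argsort(self.means_, kind="stable")
        self.means_ = self.means_[order]
        self.sds_ = self.sds_[order]
        self.startprob_ = self.startprob_[order]
        self.transmat_ = self.transmat_[np.ix_(order, order)]

    # ------------------------------------------------------------------
    def _emissions(self, y, observed):
        return _kernels.emission_likelihoods(y, observed, self.means_, self.sds_)

    def _forward(self, y, observed):
        B = self._emissions(y, observed)
        A = self.transmat_[None, :, :]
        return _kernels.forward(self.startprob_, A, _zero_idx(y.size), B), B

    def score(self, series) -> float:
        """Log-likelihood of ``series`` under the fitted model."""
        y, observed, _ = _extract(series)
        (ll, _, _), _ = self._forward(y, observed)
        return float(ll)

    # ------------------------------------------------------------------
    def fit(self, series, y=None) -> "GaussianHMM":
        yv, observed, _ = _extract(series)
        m = int(self.n_states)
        obs = yv[observed]
        if m < 1:
            raise ValueError("n_states must be >= 1")
        if obs.size < 2 * m:
            raise ValueError(f"need at least {2 * m} non-missing observations")
        if np.unique(obs).size < m:
            raise ValueError(
                "number of states exceeds the number of distinct observations"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        n_failed = 0
        for s in range(int(self.n_starts)):
            init = self._initial_params(obs, m, rng, jitter=s > 0)
            try:
                result = self._em(yv, observed, *init)
            except _DegenerateStart:
                n_failed += 1
                warnings.warn(
                    "EM start discarded: an emission sd collapsed below the floor",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            if best is None or result[0] > best[0]:
                best = result
        if best is None:
            raise RuntimeError(f"all {self.n_starts} EM starts degenerated")
        ll, delta, means, sds, A, n_iter, converged, trace = best
        self.loglik_trace_ = trace
        self.startprob_, self.means_, self.sds_, self.transmat_ = delta, means, sds, A
        self._sort_states_()
        self.loglik_ = float(ll)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_params_ = self._n_params()
        return self

    def _initial_params(self, obs, m, rng, jitter):
        qs = (2 * np.arange(1, m + 1) - 1) / (2 * m)
        means = np.quantile(obs, qs)
        sd = max(obs.std(), 10 * SD_FLOOR)
        if jitter:
            means = means + rng.normal(scale=0.25 * sd, size=m)
        sds = np.full(m, sd)
        A = np.full((m, m), 0.1 / max(m - 1, 1))
        np.fill_diagonal(A, 0.9 if m > 1 else 1.0)
        delta = np.full(m, 1.0 / m)
        return delta, means, sds, A

    def _em(self, y, observed, delta, means, sds, A):
        T = y.size
        idx = _zero_idx(T)
        obs_col = observed[:, None].astype(float)
        ll_prev = -np.inf
        converged = False
        n_iter = 0
        trace = []
        for it in range(1, int(self.max_iter) + 1):
            n_iter = it
            B = _kernels.emission_likelihoods(y, observed, means, sds)
            ll, alpha, c = _kernels.forward(delta, A[None], idx, B)
            trace.append(ll)
            beta = _kernels.backward(A[None], idx, B, c)
            gamma = alpha * beta
            # E-step quantities
            xi = _kernels.transition_counts(alpha, beta, c, A, B)
            # M-step
            delta = np.clip(gamma[0], 0.0, None)
            delta /= delta.sum()
            rows = xi.sum(axis=1, keepdims=True)
            A_new = np.where(rows > 0, xi / np.where(rows > 0, rows, 1.0), A)
            A = A_new / A_new.sum(axis=1, keepdims=True)
            w = gamma * obs_col
            sw = w.sum(axis=0)
            if np.any(sw <= 1e-12):
                raise _DegenerateStart
            means = w.T @ y / sw
            var = (w * (y[:, None] - means[None, :]) ** 2).sum(axis=0) / sw
            sds = np.sqrt(var)
            if np.any(sds < SD_FLOOR):
                raise _DegenerateStart
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * (1 + abs(ll_prev)):
                converged = True
                break
            ll_prev = ll
        # final log-likelihood at the returned parameter values
        B = _kernels.emission_likelihoods(y, observed, means, sds)
        ll, _, _ = _kernels.forward(delta, A[None], idx, B)
        trace.append(ll)
        return ll, delta, means, sds, A, n_iter, converged, np.asarray(trace)

    # ------------------------------------------------------------------
    def predict_proba(self, series) -> StateProbabilities:
        """Forward–backward smoothing: P(S_t = j | Y^(T)) for every epoch."""
        y, observed, grid = _extract(series)
        (ll, alpha, c), B = self._forward(y, observed)
        beta = _kernels.backward(self.transmat_[None], _zero_idx(y.size), B, c)
        probs = alpha * beta
        probs /= probs.sum(axis=1, keepdims=True)
        return StateProbabilities(probs=probs, time_grid=grid)

    def predict(self, series) -> np.ndarray:
        """Locally decoded state sequence (argmax of the smoothed posterior)."""
        return local_decode(self.predict_proba(series))

    def information_criteria(self, series) -> dict:
        """AIC/BIC with the BIC sample size taken as the number of
        non-missing epochs."""
        _, observed, _ = _extract(series)
        ll = self.loglik_ if np.isfinite(getattr(self, "loglik_", np.nan)) else self.score(series)
        t_obs = int(observed.sum())
        return {
            "aic": -2.0 * ll + 2.0 * self.n_params_,
            "bic": -2.0 * ll + self.n_params_ * np.log(t_obs),
        }

    def pseudo_residuals(self, series) -> np.ndarray:
        """One-step-ahead forecast pseudo-residuals at observed epochs.

        ``z_t = Φ⁻¹(F_t(y_t))`` where ``F_t`` is the forecast CDF — the
        Gaussian-mixture CDF weighted by the forward-predicted state
        probabilities given ``Y^(t−1)``.  Standard normal and serially
        independent when the model is correct.
        """
        y, observed, _ = _extract(series)
        (ll, alpha, c), B = self._forward(y, observed)
        T = y.size
        w = np.empty((T, self.n_states))
        w[0] = self.startprob_
        w[1:] = alpha[:-1] @ self.transmat_
        z = ndtr((y[:, None] - self.means_[None, :]) / self.sds_[None, :])
        u = np.clip((w * z).sum(axis=1), 1e-15, 1 - 1e-15)
        return ndtri(u[observed])

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": "gaussian_hmm",
            "m": int(self.n_states),
            "delta": self.startprob_.tolist(),
            "means": self.means_.tolist(),
            "sds": self.sds_.tolist(),
            "transition": {"type": "homogeneous", "gamma": self.transmat_.tolist()},
            "loglik": float(self.loglik_),
            "n_params": int(self.n_params_),
            "converged": bool(self.converged_),
            "n_iter": int(self.n_iter_),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        est = cls.from_params(
            d["delta"], d["means"], d["sds"], d["transition"]["gamma"]
        )
        est.loglik_ = d["loglik"]
        est.n_params_ = d["n_params"]
        est.converged_ = d["converged"]
        est.n_iter_ = d["n_iter"]
        return est


# ----------------------------------------------------------------------
# thin functional wrappers over the estimator surface
def fit_homogeneous(
    series,
    m: int = 3,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GaussianHMM:
    """Fit a homogeneous Gaussian HMM (best of ``n_starts`` EM runs)."""
    return GaussianHMM(
        n_states=m, n_starts=n_starts, random_state=seed, tol=tol, max_iter=max_iter
    ).fit(series)


def log_likelihood(fit: GaussianHMM, series) -> float:
    return fit.score(series)


def smooth(fit: GaussianHMM, series) -> StateProbabilities:
    return fit.predict_proba(series)


def local_decode(probs: StateProbabilities) -> np.ndarray:
    """Most probable state per epoch; ties resolve to the lowest index."""
    p = probs.probs if isinstance(probs, StateProbabilities) else np.asarray(probs)
    return np.argmax(p, axis=1)


def information_criteria(fit: GaussianHMM, series) -> dict:
    return fit.information_criteria(series)


def pseudo_residuals(fit: GaussianHMM, series) -> np.ndarray:
    return fit.pseudo_residuals(series)


def load_fit(path):
    """Load a fit JSON written by ``to_json`` (homogeneous or harmonic)."""
    with open(path) as fh:
        d = json.load(fh)
    if d["transition"]["type"] == "homogeneous":
        return GaussianHMM.from_dict(d)
    from .harmonic import HarmonicHMM

    return HarmonicHMM.from_dict(d)
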