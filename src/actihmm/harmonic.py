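"""Circadian harmonic HMM: 24-h periodic transition probabilities.

The homogeneous transition matrix is replaced by a multinomial-logistic
(row-wise softmax) link driven by a 24-h harmonic covariate
:math:`X_t = (\\cos 2\\pi h_t/24,\\ \\sin 2\\pi h_t/24)` where ``h_t`` is
clock time in hours since local midnight:

.. math::

    \\Gamma_{j,k}(t) \\propto
        \\exp\\!\\big(\\gamma^0_{j,k} + \\gamma^1_{j,k}\\cdot X_t\\big),
    \\qquad \\gamma^0_{k,k} = 0,\\ \\gamma^1_{k,k} = 0 ,

the diagonal coefficients being fixed to zero for identification.  Even
with a single harmonic, the induced oscillation of each transition
probability can be markedly non-sinusoidal (squarish), which suits the
abrupt rest/activity switches seen in actigraphy.

A treatment-window extension doubles the basis with indicator-gated
terms :math:`(I_t\\cos, I_t\\sin)`, :math:`I_t = 1` inside a configured
window (e.g. days on chemotherapy), so amplitude and phase of the
circadian modulation may differ during treatment.

There is no closed-form EM for this model; fitting maximises the
missing-aware forward log-likelihood numerically (L-BFGS-B), warm-started
from the homogeneous EM solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from . import _kernels
from .hmm import SD_FLOOR, GaussianHMM, StateProbabilities, _extract, local_decode
from .series import ActivitySeries

__all__ = [
    "CovariateBasis",
    "HarmonicTransition",
    "HarmonicHMM",
    "covariate_at",
    "transition_matrix_at",
    "fit_harmonic",
]


@dataclass
class CovariateBasis:
    """Harmonic covariate specification for the transition link.

    ``include_sine=True`` (default) gives the first harmonic a free phase;
    with treatment windows configured the basis is extended by the
    indicator-gated pair, giving dimension d = 2 (or 4 with windows).
    """

    period_hours: float = 24.0
    include_sine: bool = True
    treatment_windows: List[Tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.treatment_windows = [
            (pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.treatment_windows
        ]
        self.treatment_windows.sort(key=lambda w: w[0])
        for (a, b) in self.treatment_windows:
            if b <= a:
                raise ValueError("treatment window end must be after start")
        for (_, b), (a2, _) in zip(self.treatment_windows, self.treatment_windows[1:]):
            if a2 < b:
                raise ValueError("treatment windows must be disjoint")

    @property
    def n_harmonic_terms(self) -> int:
        return 2 if self.include_sine else 1

    @property
    def dim(self) -> int:
        mult = 2 if self.treatment_windows else 1
        return self.n_harmonic_terms * mult

    # ------------------------------------------------------------------
    def in_treatment(self, timestamps) -> np.ndarray:
        ts = pd.DatetimeIndex(timestamps)
        ind = np.zeros(len(ts), dtype=bool)
        for a, b in self.treatment_windows:
            ind |= (ts >= a) & (ts < b)
        return ind

    def design(self, hours, treated=None) -> np.ndarray:
        """Covariate matrix X (T×d) for clock hours and treatment flags."""
        h = np.atleast_1d(np.asarray(hours, dtype=float))
        ang = 2.0 * np.pi * h / self.period_hours
        cols = [np.cos(ang)]
        if self.include_sine:
            cols.append(np.sin(ang))
        if self.treatment_windows:
            if treated is None:
                treated = np.zeros(h.size, dtype=bool)
            ind = np.asarray(treated, dtype=float)
            cols += [c * ind for c in cols[: self.n_harmonic_terms]]
        return np.column_stack(cols)

    def covariate_at(self, t) -> np.ndarray:
        """Covariate vector at a timestamp (or plain clock hours)."""
        if isinstance(t, (int, float, np.floating)):
            hours, treated = float(t) % self.period_hours, np.array([False])
        else:
            ts = pd.Timestamp(t)
            hours = (ts - ts.normalize()).total_seconds() / 3600.0
            treated = self.in_treatment([ts])
        return self.design([hours], treated)[0]


@dataclass
class HarmonicTransition:
    """Coefficient arrays of the logistic transition link.

    ``gamma0`` is m×m with zero diagonal (intercepts), ``gamma1`` is
    m×m×d with zero diagonal slices (harmonic slopes).
    """

    gamma0: np.ndarray
    gamma1: np.ndarray
    basis: CovariateBasis = field(default_factory=CovariateBasis)

    def __post_init__(self) -> None:
        self.gamma0 = np.asarray(self.gamma0, dtype=float)
        self.gamma1 = np.asarray(self.gamma1, dtype=float)
        m = self.gamma0.shape[0]
        if self.gamma0.shape != (m, m):
            raise ValueError("gamma0 must be square")
        if self.gamma1.shape[:2] != (m, m) or self.gamma1.ndim != 3:
            raise ValueError("gamma1 must be m×m×d")
        if self.gamma1.shape[2] != self.basis.dim:
            raise ValueError("gamma1 last axis must match the basis dimension")
        if np.any(np.abs(np.diagonal(self.gamma0)) > 0) or np.any(
            np.abs(np.diagonal(self.gamma1, axis1=0, axis2=1)) > 0
        ):
            raise ValueError("diagonal coefficients are fixed to 0 for identification")

    @property
    def m(self) -> int:
        return self.gamma0.shape[0]

    def matrices(self, X: np.ndarray) -> np.ndarray:
        """Row-stochastic transition matrices for covariate rows X (n×d)."""
        X = np.atleast_2d(X)
        logits = self.gamma0[None, :, :] + np.einsum("jkd,nd->njk", self.gamma1, X)
        logits -= logits.max(axis=2, keepdims=True)  # overflow guard
        e = np.exp(logits)
        return e / e.sum(axis=2, keepdims=True)

    def at(self, t) -> np.ndarray:
        """Transition matrix at a timestamp (or plain clock hours)."""
        return self.matrices(self.basis.covariate_at(t)[None, :])[0]


def covariate_at(basis: CovariateBasis, t) -> np.ndarray:
    return basis.covariate_at(t)


def transition_matrix_at(ht: HarmonicTransition, t) -> np.ndarray:
    return ht.at(t)


def gamma0_from_transmat(transmat: np.ndarray) -> np.ndarray:
    """Intercepts reproducing a homogeneous Γ exactly (slopes zero)."""
    G = np.clip(np.asarray(transmat, dtype=float), 1e-10, None)
    g0 = np.log(G) - np.log(np.diagonal(G))[:, None]
    np.fill_diagonal(g0, 0.0)
    return g0


# ----------------------------------------------------------------------
class HarmonicHMM(BaseEstimator):
    """Gaussian HMM with 24-h periodic logistic transition probabilities.

    Parameters
    ----------
    n_states : int
        Number of latent states m.
    basis : CovariateBasis, optional
        Harmonic covariate spec (default: cosine+sine, period 24 h, no
        treatment windows).
    n_starts : int
        Number of optimiser starts.  The first is warm-started from the
        homogeneous EM solution with zero slopes; further starts jitter
        the parameter vector with seeded noise.
    l2_penalty : float
        Ridge penalty on the γ coefficients; keeps them finite when a
        transition type is (nearly) absent from the data.  Set to 0 to
        disable.
    fit_slopes : bool
        With ``False`` the harmonic slopes are frozen at zero, which
        reduces the model to the homogeneous HMM (nesting check).

    Attributes
    ----------
    means_, sds_, startprob_ : emission and initial-state estimates.
    transition_ : HarmonicTransition
        Fitted γ⁰/γ¹ coefficient arrays.
    loglik_, n_params_, converged_, n_iter_ : fit metadata.
    """

    def __init__(
        self,
        n_states: int = 3,
        basis: Optional[CovariateBasis] = None,
        n_starts: int = 3,
        random_state: int = 0,
        max_iter: int = 500,
        l2_penalty: float = 1e-6,
        fit_slopes: bool = True,
        init: Union[GaussianHMM, "HarmonicHMM", None] = None,
        homogeneous_starts: int = 5,
        count_delta_in_params: bool = True,
    ):
        self.n_states = n_states
        self.basis = basis
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_iter = max_iter
        self.l2_penalty = l2_penalty
        self.fit_slopes = fit_slopes
        self.init = init
        self.homogeneous_starts = homogeneous_starts
        self.count_delta_in_params = count_delta_in_params

    # ------------------------------------------------------------------
    @classmethod
    def from_params(
        cls, delta, means, sds, transition: HarmonicTransition, **init_kwargs
    ) -> "HarmonicHMM":
        means = np.asarray(means, dtype=float)
        est = cls(n_states=means.size, basis=transition.basis, **init_kwargs)
        est.startprob_ = np.asarray(delta, dtype=float)
        est.means_ = means
        est.sds_ = np.asarray(sds, dtype=float)
        est.transition_ = transition
        est.loglik_ = np.nan
        est.n_params_ = est._n_params(transition.basis.dim)
        est.converged_ = True
        est.n_iter_ = 0
        return est

    def _n_params(self, d: int) -> int:
        m = self.n_states
        n = 2 * m + (1 + d) * m * (m - 1)
        if self.count_delta_in_params:
            n += m - 1
        return n

    # -- parameter vector packing --------------------------------------
    def _offdiag_index(self, m):
        return ~np.eye(m, dtype=bool)

    def _pack(self, delta, means, sds, g0, g1):
        m = self.n_states
        off = self._offdiag_index(m)
        dl = np.log(np.clip(delta, 1e-8, None))
        dl = dl[1:] - dl[0]
        parts = [means, np.log(sds), np.clip(dl, -30, 30), g0[off]]
        if self.fit_slopes:
            parts.append(g1[off].ravel())
        return np.concatenate(parts)

    def _unpack(self, p, d):
        m = self.n_states
        off = self._offdiag_index(m)
        i = 0
        means = p[i : i + m]
        i += m
        sds = np.exp(p[i : i + m])
        i += m
        logits = np.concatenate([[0.0], p[i : i + m - 1]])
        i += m - 1
        e = np.exp(logits - logits.max())
        delta = e / e.sum()
        g0 = np.zeros((m, m))
        g0[off] = p[i : i + m * (m - 1)]
        i += m * (m - 1)
        g1 = np.zeros((m, m, d))
        if self.fit_slopes:
            g1[off] = p[i :].reshape(m * (m - 1), d)
        return delta, means, sds, g0, g1

    # ------------------------------------------------------------------
    def _series_design(self, series: ActivitySeries, basis: CovariateBasis):
        if not isinstance(series, ActivitySeries):
            raise TypeError("HarmonicHMM requires an ActivitySeries (needs clock time)")
        treated = (
            basis.in_treatment(series.timestamps) if basis.treatment_windows else None
        )
        X = basis.design(series.hours, treated)
        Xu, aidx = np.unique(X, axis=0, return_inverse=True)
        return Xu, aidx.astype(np.int64)

    def _nll_factory(self, y, observed, Xu, aidx, basis):
        d = basis.dim
        pen = float(self.l2_penalty)

        def nll(p):
            delta, means, sds, g0, g1 = self._unpack(p, d)
            ht = HarmonicTransition.__new__(HarmonicTransition)
            ht.gamma0, ht.gamma1, ht.basis = g0, g1, basis
            A = ht.matrices(Xu)
            B = _kernels.emission_likelihoods(y, observed, means, sds)
            ll, _, _ = _kernels.forward(delta, A, aidx, B)
            return -ll + pen * (np.sum(g0 * g0) + np.sum(g1 * g1))

        return nll

    def fit(self, series: ActivitySeries, y=None) -> "HarmonicHMM":
        basis = self.basis if self.basis is not None else CovariateBasis()
        yv, observed, _ = _extract(series)
        if series.n_epochs * series.epoch_seconds < 2 * 86_400:
            warnings.warn(
                "fewer than 2 full days of data: circadian coefficients are "
                "weakly identified",
                RuntimeWarning,
                stacklevel=2,
            )
        Xu, aidx = self._series_design(series, basis)
        m, d = int(self.n_states), basis.dim

        init = self.init
        if init is None:
            init = GaussianHMM(
                n_states=m,
                n_starts=self.homogeneous_starts,
                random_state=self.random_state,
            ).fit(series)
        if isinstance(init, HarmonicHMM):
            g0, g1 = init.transition_.gamma0, init.transition_.gamma1
            if g1.shape[2] != d:  # e.g. warm start without treatment terms
                g1 = np.concatenate(
                    [g1, np.zeros((m, m, d - g1.shape[2]))], axis=2
                )
            p0 = self._pack(init.startprob_, init.means_, init.sds_, g0, g1)
        else:
            g0 = gamma0_from_transmat(init.transmat_)
            p0 = self._pack(
                init.startprob_, init.means_, init.sds_, g0, np.zeros((m, m, d))
            )

        nll = self._nll_factory(yv, observed, Xu, aidx, basis)
        n_gamma = m * (m - 1) * (1 + (d if self.fit_slopes else 0))
        bounds = (
            [(None, None)] * m
            + [(np.log(SD_FLOOR), 5.0)] * m
            + [(-30.0, 30.0)] * (m - 1)
            + [(-20.0, 20.0)] * n_gamma
        )
        rng = np.random.default_rng(self.random_state)
        best = None
        for s in range(int(self.n_starts)):
            p_init = p0 if s == 0 else p0 + rng.normal(scale=0.3, size=p0.size)
            res = minimize(
                nll,
                p_init,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": int(self.max_iter), "maxfun": 200_000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success:
            warnings.warn(
                f"harmonic optimiser did not report convergence: {best.message}",
                RuntimeWarning,
                stacklevel=2,
            )
        delta, means, sds, g0, g1 = self._unpack(best.x, d)
        order = np.argsort(means, kind="stable")
        self.startprob_ = delta[order]
        self.means_ = means[order]
        self.sds_ = sds[order]
        self.transition_ = HarmonicTransition(
            gamma0=g0[np.ix_(order, order)],
            gamma1=g1[np.ix_(order, order)],
            basis=basis,
        )
        self.loglik_ = float(-best.fun + self.l2_penalty * (np.sum(g0**2) + np.sum(g1**2)))
        self.n_params_ = self._n_params(d)
        self.converged_ = bool(best.success)
        self.n_iter_ = int(best.nit)
        return self

    # ------------------------------------------------------------------
    def _forward(self, series):
        y, observed, grid = _extract(series)
        Xu, aidx = self._series_design(series, self.transition_.basis)
        A = self.transition_.matrices(Xu)
        B = _kernels.emission_likelihoods(y, observed, self.means_, self.sds_)
        ll, alpha, c = _kernels.forward(self.startprob_, A, aidx, B)
        return y, observed, grid, A, aidx, B, ll, alpha, c

    def score(self, series) -> float:
        return float(self._forward(series)[6])

    def predict_proba(self, series) -> StateProbabilities:
        y, observed, grid, A, aidx, B, ll, alpha, c = self._forward(series)
        beta = _kernels.backward(A, aidx, B, c)
        probs = alpha * beta
        probs /= probs.sum(axis=1, keepdims=True)
        return StateProbabilities(probs=probs, time_grid=grid)

    def predict(self, series) -> np.ndarray:
        return local_decode(self.predict_proba(series))

    def information_criteria(self, series) -> dict:
        _, observed, _ = _extract(series)
        ll = self.loglik_ if np.isfinite(getattr(self, "loglik_", np.nan)) else self.score(series)
        t_obs = int(observed.sum())
        return {
            "aic": -2.0 * ll + 2.0 * self.n_params_,
            "bic": -2.0 * ll + self.n_params_ * np.log(t_obs),
        }

    def pseudo_residuals(self, series) -> np.ndarray:
        y, observed, grid, A, aidx, B, ll, alpha, c = self._forward(series)
        T = y.size
        w = np.empty((T, self.n_states))
        w[0] = self.startprob_
        for t in range(1, T):
            w[t] = alpha[t - 1] @ A[aidx[t]]
        z = ndtr((y[:, None] - self.means_[None, :]) / self.sds_[None, :])
        u = np.clip((w * z).sum(axis=1), 1e-15, 1 - 1e-15)
        return ndtri(u[observed])

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        basis = self.transition_.basis
        return {
            "model": "harmonic_hmm",
            "m": int(self.n_states),
            "delta": self.startprob_.tolist(),
            "means": self.means_.tolist(),
            "sds": self.sds_.tolist(),
            "transition": {
                "type": "harmonic",
                "gamma0": self.transition_.gamma0.tolist(),
                "gamma1": self.transition_.gamma1.tolist(),
                "basis": {
                    "period_hours": basis.period_hours,
                    "include_sine": basis.include_sine,
                    "treatment_windows": [
                        [a.isoformat(), b.isoformat()]
                        for a, b in basis.treatment_windows
                    ],
                },
            },
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
    def from_dict(cls, d: dict) -> "HarmonicHMM":
        tb = d["transition"]
        basis = CovariateBasis(
            period_hours=tb["basis"]["period_hours"],
            include_sine=tb["basis"]["include_sine"],
            treatment_windows=[tuple(w) for w in tb["basis"]["treatment_windows"]],
        )
        ht = HarmonicTransition(
            gamma0=np.array(tb["gamma0"]), gamma1=np.array(tb["gamma1"]), basis=basis
        )
        est = cls.from_params(d["delta"], d["means"], d["sds"], ht)
        est.loglik_ = d["loglik"]
        est.n_params_ = d["n_params"]
        est.converged_ = d["converged"]
        est.n_iter_ = d["n_iter"]
        return est


def fit_harmonic(
    series: ActivitySeries,
    m: int = 3,
    basis: Optional[CovariateBasis] = None,
    init=None,
    n_starts: int = 3,
    seed: int = 0,
    max_iter: int = 500,
) -> HarmonicHMM:
    """Fit the circadian harmonic HMM (best of ``n_starts`` optimiser runs)."""
    return HarmonicHMM(
        n_states=m,
        basis=basis,
        init=init,
        n_starts=n_starts,
        random_state=seed,
        max_iter=max_iter,
    ).fit(series)
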