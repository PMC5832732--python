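"""Circadian summary statistics derived from a fitted HMM.

From the harmonic HMM the 24-h periodic profile of the state probabilities
is obtained by propagating a state-probability vector through the periodic
transition matrices until the profile converges to its limit cycle.  From
the inactive-state (IA) curve :math:`P(h) = P(S = \\mathrm{IA}\\mid h)` on
clock time :math:`h \\in [0, 24)` the following are derived:

rest amount
    :math:`a = \\int_0^{24} P(h)\\,dh` (hours);
centre of rest
    :math:`c` = circular centre of mass of :math:`P` (clock time);
rhythm index
    :math:`RI = \\dfrac{\\int_{I_c} P(h)\\,dh - a^2/24}{a - a^2/24}`
    with :math:`I_c = [c - a/2,\\ c + a/2]` taken circularly.  RI is 1
    for a perfectly regular rectangular rest profile (P = 1 on I_c, 0
    elsewhere) and 0 for a flat profile :math:`P \\equiv a/24` (no
    circadian rhythm); it is the unique affine normalisation of
    :math:`\\int_{I_c} P` with those two anchor points.

The dichotomy index I<O — the percentage of rest-span epochs whose
activity lies strictly below the median activity of wakefulness — is
computed from locally decoded rest spans on the count (mean_counts)
scale; 100% corresponds to an undisrupted rest pattern.

All profile integrals use the rectangle rule at epoch resolution, with
each grid cell represented by its midpoint (this makes the Fig.-style
rectangular worked example exact on a 5-min grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .harmonic import HarmonicHMM
from .hmm import GaussianHMM, local_decode
from .series import SCALE_MEAN, ActivitySeries

__all__ = [
    "CircadianProfile",
    "CircadianSummary",
    "periodic_profile",
    "rectangular_profile",
    "flat_profile",
    "rest_amount",
    "rest_centre",
    "rhythm_index",
    "rest_spans",
    "dichotomy_index",
    "state_means_count_scale",
    "summarize",
]


@dataclass
class CircadianProfile:
    """Periodic state-probability curves on a 24-h grid.

    ``grid_hours`` holds the *start* of each grid cell; integrals and the
    circular centre of mass evaluate each cell at its midpoint
    ``grid_hours + spacing/2``.
    """

    grid_hours: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.grid_hours = np.asarray(self.grid_hours, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != self.grid_hours.size:
            raise ValueError("probs rows must match the grid length")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("profile rows must sum to 1")

    @property
    def spacing_hours(self) -> float:
        return 24.0 / self.grid_hours.size

    @property
    def midpoints(self) -> np.ndarray:
        return self.grid_hours + self.spacing_hours / 2.0

    @property
    def ia_curve(self) -> np.ndarray:
        return self.probs[:, 0]


@dataclass
class CircadianSummary:
    """Per-subject circadian parameters (NaN where undefined)."""

    rest_amount_h: float
    rest_centre: float
    rhythm_index: float
    dichotomy_index: float
    state_means_count_scale: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        d = {
            "rest_amount_h": self.rest_amount_h,
            "rest_centre": self.rest_centre,
            "rhythm_index": self.rhythm_index,
            "dichotomy_index": self.dichotomy_index,
        }
        for j, v in enumerate(self.state_means_count_scale):
            d[f"state{j + 1}_mean_counts"] = float(v)
        return d


# ----------------------------------------------------------------------
def periodic_profile(
    fit: HarmonicHMM,
    treatment: bool = False,
    epoch_seconds: int = 300,
    tol: float = 1e-10,
    max_cycles: int = 1000,
) -> CircadianProfile:
    """Limit-cycle 24-h profile of the state probabilities.

    Propagates a state-probability vector through the periodic transition
    matrices, cycling over whole days until the profile changes by less
    than ``tol`` in sup-norm between cycles.  ``treatment=True`` evaluates
    the treatment-regime coefficients (indicator on) instead of the base
    regime.
    """
    if isinstance(fit, GaussianHMM):
        raise TypeError("periodic_profile requires a harmonic fit")
    ht = fit.transition_
    basis = ht.basis
    n = 86_400 // int(epoch_seconds)  # grid at the analysis epoch (5 min -> 288)
    grid = np.arange(n) * (24.0 / n)
    treated = np.full(n, bool(treatment and basis.treatment_windows))
    X = basis.design(grid, treated if basis.treatment_windows else None)
    A = ht.matrices(X)  # A[i] governs the transition *into* cell i
    pi = np.asarray(fit.startprob_, dtype=float).copy()
    profile = np.empty((n, fit.n_states))
    prev = None
    for _ in range(max_cycles):
        for i in range(n):
            pi = pi @ A[i]
            profile[i] = pi
        if prev is not None and np.max(np.abs(profile - prev)) < tol:
            return CircadianProfile(grid_hours=grid, probs=profile.copy())
        prev = profile.copy()
    raise RuntimeError("periodic profile did not converge")  # pragma: no cover


def rectangular_profile(
    a: float, c: float, epoch_seconds: int = 300, n_states: int = 2
) -> CircadianProfile:
    """Reference profile: IA probability 1 on the window of width ``a``
    hours centred at clock time ``c``, 0 elsewhere (perfectly regular
    rest)."""
    n = 86_400 // int(epoch_seconds)
    grid = np.arange(n) * (24.0 / n)
    mid = grid + 12.0 / n
    dist = np.abs((mid - c + 12.0) % 24.0 - 12.0)
    ia = (dist <= a / 2.0).astype(float)
    return _with_complement(grid, ia, n_states)


def flat_profile(
    a: float, epoch_seconds: int = 300, n_states: int = 2
) -> CircadianProfile:
    """Reference profile: IA probability constant at ``a/24`` (no
    circadian rhythm)."""
    n = 86_400 // int(epoch_seconds)
    grid = np.arange(n) * (24.0 / n)
    ia = np.full(n, a / 24.0)
    return _with_complement(grid, ia, n_states)


def _with_complement(grid, ia, n_states):
    rest = np.repeat(((1.0 - ia) / max(n_states - 1, 1))[:, None], n_states - 1, axis=1)
    return CircadianProfile(grid_hours=grid, probs=np.column_stack([ia, rest]))


# ----------------------------------------------------------------------
def rest_amount(profile: CircadianProfile) -> float:
    """Integral of the IA-probability curve over the day, in hours."""
    return float(profile.ia_curve.sum() * profile.spacing_hours)


def rest_centre(profile: CircadianProfile, min_resultant: float = 1e-8) -> float:
    """Circular centre of mass of the IA curve (clock time in [0, 24)).

    NaN (with a warning) when the resultant length is negligible — the
    rest probability then has no circadian localisation.
    """
    ang = 2.0 * np.pi * profile.midpoints / 24.0
    w = profile.ia_curve
    z = np.sum(w * np.exp(1j * ang))
    if np.abs(z) < min_resultant * max(w.sum(), 1.0):
        warnings.warn(
            "rest probability has no circadian localisation; centre undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float((np.angle(z) / (2.0 * np.pi) * 24.0) % 24.0)


def rhythm_index(profile: CircadianProfile) -> float:
    """Rest–activity rhythm index RI in [0, 1].

    NaN (with a warning) when the rest amount is 0 or 24 h, where the
    normalisation degenerates.  A profile with undefined centre of rest is
    anchored at an arbitrary c (the integral over I_c is then
    location-independent for the flat profile, giving RI = 0).
    """
    a = rest_amount(profile)
    if a <= 0.0 or a >= 24.0:
        warnings.warn(
            f"rhythm index undefined for rest amount {a:.3g} h",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c = rest_centre(profile)
    if np.isnan(c):
        c = 0.0
    mid = profile.midpoints
    dist = np.abs((mid - c + 12.0) % 24.0 - 12.0)
    in_window = dist <= a / 2.0
    integral = float(profile.ia_curve[in_window].sum() * profile.spacing_hours)
    ri = (integral - a * a / 24.0) / (a - a * a / 24.0)
    return float(np.clip(ri, 0.0, 1.0))


# ----------------------------------------------------------------------
def rest_spans(
    decoded: np.ndarray,
    time_grid,
    min_span_hours: float = 3.0,
    merge_gap_hours: float = 1.0,
    rest_state: int = 0,
) -> List[Tuple[pd.Timestamp, pd.Timestamp]]:
    """Nightly rest spans from a locally decoded state sequence.

    Maximal runs of the IA state are merged when separated by gaps shorter
    than ``merge_gap_hours``; merged runs shorter than ``min_span_hours``
    are dropped; within each noon-to-noon 24-h window the longest
    remaining span is kept as that night's rest span.  Days without a
    qualifying span are omitted with a warning.
    """
    decoded = np.asarray(decoded)
    ts = pd.DatetimeIndex(time_grid)
    if decoded.size != len(ts):
        raise ValueError("decoded and time_grid must have equal length")
    if len(ts) < 2:
        return []
    epoch = (ts[1] - ts[0]).total_seconds()
    is_rest = decoded == rest_state
    # maximal runs
    runs = []
    i = 0
    T = decoded.size
    while i < T:
        if is_rest[i]:
            j = i
            while j < T and is_rest[j]:
                j += 1
            runs.append([ts[i], ts[j - 1] + pd.Timedelta(seconds=epoch)])
            i = j
        else:
            i += 1
    # merge across short gaps
    merged: List[List[pd.Timestamp]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]).total_seconds() < merge_gap_hours * 3600:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    spans = [
        (a, b)
        for a, b in merged
        if (b - a).total_seconds() >= min_span_hours * 3600
    ]
    # one span per noon-to-noon window: keep the longest
    by_window: dict = {}
    for a, b in spans:
        midpoint = a + (b - a) / 2
        window = (midpoint - pd.Timedelta(hours=12)).normalize()
        cur = by_window.get(window)
        if cur is None or (b - a) > (cur[1] - cur[0]):
            by_window[window] = (a, b)
    first_win = (ts[0] - pd.Timedelta(hours=12)).normalize()
    last_win = (ts[-1] - pd.Timedelta(hours=12)).normalize()
    n_windows = (last_win - first_win).days + 1
    if len(by_window) < n_windows:
        warnings.warn(
            f"no qualifying rest span in {n_windows - len(by_window)} of "
            f"{n_windows} days",
            RuntimeWarning,
            stacklevel=2,
        )
    return [by_window[k] for k in sorted(by_window)]


def dichotomy_index(
    series: ActivitySeries, spans: List[Tuple[pd.Timestamp, pd.Timestamp]]
) -> float:
    """Dichotomy index I<O, in percent.

    Percentage of non-missing in-span (rest) epochs whose activity is
    strictly below the median activity of the non-missing out-of-span
    (wake) epochs.  Defined on the count scale (mean_counts), not its
    square root; missing epochs are excluded on both sides.
    """
    if series.scale_tag != SCALE_MEAN:
        raise ValueError("dichotomy_index expects a mean_counts series")
    ts = series.timestamps
    in_span = np.zeros(series.n_epochs, dtype=bool)
    for a, b in spans:
        in_span |= (ts >= a) & (ts < b)
    obs = ~series.missing_mask
    wake = series.values[obs & ~in_span]
    rest = series.values[obs & in_span]
    if rest.size == 0 or wake.size == 0:
        warnings.warn(
            "dichotomy index undefined: empty rest span or all-missing wake",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(100.0 * np.mean(rest < np.median(wake)))


def state_means_count_scale(fit) -> np.ndarray:
    """Per-state means on the original count scale.

    For Y ~ N(μ, σ²) on the sqrt scale, Y² is noncentral chi-squared with
    mean μ² + σ² — the state's expected activity count.  The HA-state
    value serves as an amplitude estimate.
    """
    return np.asarray(fit.means_) ** 2 + np.asarray(fit.sds_) ** 2


# ----------------------------------------------------------------------
def summarize(
    fit,
    series_sqrt: Optional[ActivitySeries] = None,
    series_counts: Optional[ActivitySeries] = None,
    min_span_hours: float = 3.0,
    merge_gap_hours: float = 1.0,
    treatment: bool = False,
) -> CircadianSummary:
    """Full circadian summary for one subject.

    Profile-based parameters (a, c, RI) require a harmonic fit; the
    dichotomy index additionally requires the sqrt-scale series (for
    decoding) and the matching count-scale series.
    """
    a = c = ri = ilo = float("nan")
    if isinstance(fit, HarmonicHMM):
        prof = periodic_profile(fit, treatment=treatment)
        a = rest_amount(prof)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            c = rest_centre(prof)
            ri = rhythm_index(prof)
    if series_sqrt is not None and series_counts is not None:
        probs = fit.predict_proba(series_sqrt)
        spans = rest_spans(
            local_decode(probs),
            probs.time_grid,
            min_span_hours=min_span_hours,
            merge_gap_hours=merge_gap_hours,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ilo = dichotomy_index(series_counts, spans)
    return CircadianSummary(
        rest_amount_h=a,
        rest_centre=c,
        rhythm_index=ri,
        dichotomy_index=ilo,
        state_means_count_scale=state_means_count_scale(fit),
    )
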