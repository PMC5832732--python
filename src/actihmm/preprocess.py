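"""Pre-processing chain: epoch aggregation, square-root transform,
temperature-based off-wrist marking.

The analysis pipeline mirrors standard actigraphy practice: 1-min PA counts
are averaged over 5-min analysis epochs and square-root transformed, after
which Gaussian observational densities are a reasonable working assumption
(equivalently, a mixture of non-central chi-squared distributions on the
count scale, which respects non-negativity and positive skewness).

Off-wrist periods (the subject removes the device, e.g. to shower) are
visible in the skin-temperature channel as a sustained drop towards room
temperature; :func:`mark_missing_by_temperature` flags them as missing.
Missing epochs are never imputed — the HMM likelihood marginalises them.
"""

from __future__ import annotations

import numpy as np

from .series import (
    SCALE_MEAN,
    SCALE_RAW,
    SCALE_SQRT,
    ActivitySeries,
    ValidationError,
    load_activity,
    write_activity,
)

__all__ = [
    "aggregate_epochs",
    "sqrt_transform",
    "square_back",
    "mark_missing_by_temperature",
    "prepare",
    "load_activity",
    "write_activity",
]


def aggregate_epochs(
    series: ActivitySeries,
    target_epoch_seconds: int = 300,
    max_missing_fraction: float = 0.5,
) -> ActivitySeries:
    """Average counts over coarser windows.

    Each output value is the arithmetic mean of the *non-missing* input
    values in its window.  A window is marked missing iff the fraction of
    missing input epochs exceeds ``max_missing_fraction`` (default 0.5 — a
    window keeps a value as long as at least half of its minutes are
    observed).  A trailing partial window is padded with missing epochs.
    """
    target_epoch_seconds = int(target_epoch_seconds)
    if target_epoch_seconds % series.epoch_seconds != 0:
        raise ValueError(
            f"target epoch {target_epoch_seconds}s is not a multiple of the "
            f"series epoch {series.epoch_seconds}s"
        )
    k = target_epoch_seconds // series.epoch_seconds
    T = series.n_epochs
    n_win = -(-T // k)
    vals = np.full(n_win * k, np.nan)
    vals[:T] = series.values
    vals = vals.reshape(n_win, k)
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=1)
    missing = (k - n_obs) / k > max_missing_fraction
    with np.errstate(invalid="ignore"):
        means = np.where(n_obs > 0, np.nansum(vals, axis=1) / np.maximum(n_obs, 1), np.nan)
    means[missing] = np.nan
    return series.copy(
        epoch_seconds=target_epoch_seconds,
        values=means,
        missing_mask=missing,
        scale_tag=SCALE_MEAN,
    )


def sqrt_transform(series: ActivitySeries) -> ActivitySeries:
    """Elementwise square root of mean counts; missing propagates."""
    if series.scale_tag != SCALE_MEAN:
        raise ValidationError(
            f"sqrt_transform expects mean_counts, got {series.scale_tag!r}"
        )
    return series.copy(values=np.sqrt(series.values), scale_tag=SCALE_SQRT)


def square_back(series: ActivitySeries) -> ActivitySeries:
    """Inverse of :func:`sqrt_transform` (sqrt scale back to mean counts)."""
    if series.scale_tag != SCALE_SQRT:
        raise ValidationError(
            f"square_back expects sqrt_mean_counts, got {series.scale_tag!r}"
        )
    return series.copy(values=np.square(series.values), scale_tag=SCALE_MEAN)


def mark_missing_by_temperature(
    series: ActivitySeries,
    temp_drop_threshold: float = 30.0,
    min_block_epochs: int = 2,
) -> ActivitySeries:
    """Flag off-wrist blocks detected from the skin-temperature channel.

    Maximal runs of at least ``min_block_epochs`` consecutive temperature
    samples below ``temp_drop_threshold`` (°C) are taken as off-wrist; all
    activity epochs covered by such runs are flagged missing in addition to
    any existing flags.  Skin temperature sits near 32-35 °C when the
    device is worn, so the 30 °C default separates wear from room
    temperature conservatively.
    """
    if series.temperature is None:
        raise ValueError("series has no temperature channel")
    temp = series.temperature
    t_epoch = series.temperature_epoch_seconds
    below = temp < temp_drop_threshold
    mask = series.missing_mask.copy()
    T = series.n_epochs
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_block_epochs:
                # temperature samples i..j-1 cover activity epochs in
                # [i*t_epoch, j*t_epoch) seconds from series start
                a = (i * t_epoch) // series.epoch_seconds
                b = -(-(j * t_epoch) // series.epoch_seconds)
                mask[max(a, 0) : min(b, T)] = True
            i = j
        else:
            i += 1
    vals = series.values.copy()
    vals[mask] = np.nan
    return series.copy(values=vals, missing_mask=mask)


def prepare(
    series: ActivitySeries,
    analysis_epoch_seconds: int = 300,
    temp_drop_threshold: float = 30.0,
    min_block_epochs: int = 2,
) -> ActivitySeries:
    """Full default chain: temperature marking (when a channel exists) →
    aggregation to the analysis epoch → square-root transform."""
    if series.temperature is not None:
        series = mark_missing_by_temperature(
            series, temp_drop_threshold, min_block_epochs
        )
    if series.scale_tag == SCALE_RAW or series.epoch_seconds != analysis_epoch_seconds:
        series = aggregate_epochs(series, analysis_epoch_seconds)
    return sqrt_transform(series)
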