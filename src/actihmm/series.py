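"""Container and CSV I/O for epoch-level activity-count series.

Actigraphy devices accumulate a physical-activity (PA) count per fixed
*epoch* (typically 1 min).  :class:`ActivitySeries` holds such a series on a
strictly regular grid together with a missing-data mask and, optionally, a
parallel skin-temperature channel recorded at its own (coarser) epoch.

Scales
------
A series carries a ``scale_tag`` recording where it sits in the standard
pre-processing chain:

``raw_counts``
    counts as read from the device (non-negative integers, 1-min epochs);
``mean_counts``
    window means after aggregation to the analysis epoch (default 5 min);
``sqrt_mean_counts``
    square roots of the window means — the scale on which the Gaussian
    hidden Markov models operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "ParseError",
    "ValidationError",
    "load_activity",
    "write_activity",
    "SCALE_RAW",
    "SCALE_MEAN",
    "SCALE_SQRT",
]

SCALE_RAW = "raw_counts"
SCALE_MEAN = "mean_counts"
SCALE_SQRT = "sqrt_mean_counts"
_SCALES = (SCALE_RAW, SCALE_MEAN, SCALE_SQRT)


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as an activity series."""


class ValidationError(ValueError):
    """Raised when series content violates its invariants."""


@dataclass
class ActivitySeries:
    """Fixed-epoch activity series with missing mask.

    Parameters
    ----------
    start_time : pandas.Timestamp
        Start of the first epoch, in local clock time (no DST adjustment;
        circadian phase is referenced to the local social clock).
    epoch_seconds : int
        Epoch length; must divide 86 400 so that epochs tile the day.
    values : ndarray of float
        Length-T values; entries at missing epochs are ignored (stored as
        NaN internally).
    missing_mask : ndarray of bool
        True marks a missing epoch.
    scale_tag : str
        One of ``raw_counts``, ``mean_counts``, ``sqrt_mean_counts``.
    temperature : ndarray of float, optional
        Skin temperature channel (°C) on its own epoch grid starting at
        ``start_time``.
    temperature_epoch_seconds : int, optional
        Epoch length of the temperature channel (default 300 s when a
        channel is present).

    Notes
    -----
    All epochs are half-open intervals ``[start, start + epoch)``.
    """

    start_time: pd.Timestamp
    epoch_seconds: int
    values: np.ndarray
    missing_mask: np.ndarray
    scale_tag: str = SCALE_RAW
    temperature: Optional[np.ndarray] = None
    temperature_epoch_seconds: Optional[int] = field(default=None)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float).copy()
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool).copy()
        if self.values.ndim != 1 or self.values.shape != self.missing_mask.shape:
            raise ValidationError("values and missing_mask must be 1-d and of equal length")
        if self.values.size < 1:
            raise ValidationError("series must contain at least one epoch")
        if self.scale_tag not in _SCALES:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        self.epoch_seconds = int(self.epoch_seconds)
        if self.epoch_seconds <= 0 or 86_400 % self.epoch_seconds != 0:
            raise ValidationError("epoch_seconds must be positive and divide 86400")
        # NaN at masked epochs is allowed on input; normalise to NaN storage.
        self.missing_mask |= np.isnan(self.values)
        self.values[self.missing_mask] = np.nan
        obs = self.values[~self.missing_mask]
        if self.scale_tag in (SCALE_RAW, SCALE_MEAN) and obs.size and np.any(obs < 0):
            raise ValidationError("negative activity counts are not allowed")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if self.temperature_epoch_seconds is None:
                self.temperature_epoch_seconds = 300

    # ------------------------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_seconds, unit="s"
        )

    @property
    def hours(self) -> np.ndarray:
        """Clock time of each epoch start, in hours since local midnight."""
        midnight = self.start_time.normalize()
        offset = (self.start_time - midnight).total_seconds()
        sec = offset + np.arange(self.n_epochs) * self.epoch_seconds
        return (sec / 3600.0) % 24.0

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())

    def copy(self, **changes) -> "ActivitySeries":
        return replace(self, **changes)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "count": self.values,
                "missing": self.missing_mask.astype(int),
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ActivitySeries(T={self.n_epochs}, epoch={self.epoch_seconds}s, "
            f"scale={self.scale_tag}, missing={self.missing_fraction:.2%}, "
            f"start={self.start_time})"
        )


# ----------------------------------------------------------------------
def load_activity(
    path,
    timestamp_col: str = "timestamp",
    count_col: str = "count",
    temperature_path=None,
    temp_col: str = "temp_c",
) -> ActivitySeries:
    """Read an activity CSV into an :class:`ActivitySeries`.

    The file must have a timestamp column (ISO-8601) and a numeric count
    column.  Timestamps must be strictly increasing on a regular grid;
    internal gaps that are whole multiples of the modal spacing are filled
    with missing epochs.  An optional ``missing`` 0/1 column (as written by
    :func:`write_activity`) is honoured.

    Raises
    ------
    ParseError
        Non-monotone timestamps, or spacing that is not a multiple of the
        modal epoch.
    ValidationError
        Negative counts.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (timestamp_col, count_col):
        if col not in df.columns:
            raise ParseError(f"{path}: required column {col!r} not found")
    try:
        ts = pd.to_datetime(df[timestamp_col])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: cannot parse timestamps: {exc}") from exc
    counts = pd.to_numeric(df[count_col], errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(counts) & df[count_col].notna().to_numpy()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ParseError(f"{path}: non-numeric count at line {line}")
    if len(ts) < 1:
        raise ParseError(f"{path}: empty file")

    dt = np.diff(ts.to_numpy().astype("datetime64[s]").astype(np.int64))
    if len(dt) and np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 2
        raise ParseError(f"{path}: timestamps not strictly increasing at line {line + 1}")
    if len(dt):
        vals, cnts = np.unique(dt, return_counts=True)
        epoch = int(vals[np.argmax(cnts)])
        if np.any(dt % epoch != 0):
            line = int(np.flatnonzero(dt % epoch != 0)[0]) + 2
            raise ParseError(
                f"{path}: irregular spacing (not a multiple of the {epoch}s epoch) "
                f"at line {line + 1}"
            )
    else:
        epoch = 60

    start = pd.Timestamp(ts.iloc[0])
    idx = ((ts - start).dt.total_seconds().to_numpy() / epoch).astype(int)
    T = int(idx[-1]) + 1
    values = np.full(T, np.nan)
    mask = np.ones(T, dtype=bool)
    values[idx] = counts
    mask[idx] = False
    if "missing" in df.columns:
        mask[idx] |= df["missing"].to_numpy().astype(bool)
        values[mask] = np.nan

    temperature = None
    temp_epoch = None
    if temperature_path is not None:
        tdf = pd.read_csv(temperature_path)
        if temp_col not in tdf.columns:
            raise ParseError(f"{temperature_path}: required column {temp_col!r} not found")
        tts = pd.to_datetime(tdf[timestamp_col])
        temperature = tdf[temp_col].to_numpy(dtype=float)
        tdt = np.diff(tts.to_numpy().astype("datetime64[s]").astype(np.int64))
        temp_epoch = int(tdt[0]) if len(tdt) else 300

    return ActivitySeries(
        start_time=start,
        epoch_seconds=epoch,
        values=values,
        missing_mask=mask,
        scale_tag=SCALE_RAW,
        temperature=temperature,
        temperature_epoch_seconds=temp_epoch,
    )


def write_activity(series: ActivitySeries, path) -> None:
    """Write the series as CSV (`timestamp,count,missing`); exact inverse
    of :func:`load_activity` for fully regular series."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")
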