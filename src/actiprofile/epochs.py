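"""Epoch-level representation of accelerometer data.

Raw tri-axial acceleration (in gravitational units, g) is reduced to the
Euclidean Norm Minus One g (ENMO), expressed in milli-gravitational units
(mg), and averaged over fixed-length epochs (5 s by default).  The epoch
series is the universal intermediate of the package: wear-time screening,
imputation and every activity metric operate on it.

Conventions
-----------
* ENMO is truncated at zero per sample before epoch averaging, so a
  stationary, calibrated device reads 0 mg.
* Epochs are aligned to local-clock boundaries (an epoch starts at a whole
  multiple of ``epoch_len_s`` from midnight); partial leading/trailing
  epochs are discarded.  Days run midnight to midnight, local clock.
* Timestamps are timezone-naive local time; daylight-saving transitions
  are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawTriaxial",
    "EpochSeries",
    "compute_enmo",
    "aggregate_epochs",
    "read_epoch_csv",
    "write_epoch_csv",
    "WEAR_WORN",
    "WEAR_NONWEAR",
    "WEAR_IMPUTED",
]

#: wear-flag codes used throughout the package and in epoch CSV files
WEAR_WORN = "W"
WEAR_NONWEAR = "N"
WEAR_IMPUTED = "I"
_WEAR_CODES = frozenset({WEAR_WORN, WEAR_NONWEAR, WEAR_IMPUTED})

SECONDS_PER_DAY = 86_400


@dataclass
class RawTriaxial:
    """Uniformly sampled tri-axial acceleration in gravitational units.

    Parameters
    ----------
    start : pandas.Timestamp
        Timestamp of the first sample (timezone-naive local time).
    rate_hz : float
        Sampling rate in samples per second; must be positive.
    x, y, z : numpy.ndarray
        Per-axis acceleration in g, equal length.  Input is assumed
        autocalibrated (gravity reads 1 g on a stationary device).
    """

    start: pd.Timestamp
    rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start.tz is not None:
            raise ValueError("timestamps must be timezone-naive local time")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise ValueError("x, y, z must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class EpochSeries:
    """Per-epoch ENMO values (mg) with wear flags.

    ``values[i]`` covers the half-open interval
    ``[start + i * epoch_len_s, start + (i + 1) * epoch_len_s)``.
    Wear flags are ``'W'`` (worn), ``'N'`` (non-wear) or ``'I'`` (imputed).
    """

    start: pd.Timestamp
    epoch_len_s: int
    values: np.ndarray
    wear: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start.tz is not None:
            raise ValueError("timestamps must be timezone-naive local time")
        self.epoch_len_s = int(self.epoch_len_s)
        if self.epoch_len_s <= 0 or SECONDS_PER_DAY % self.epoch_len_s != 0:
            raise ValueError(
                f"epoch_len_s must be a positive divisor of 86400, got {self.epoch_len_s}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values) | (self.values < 0))[0])
            raise ValueError(f"epoch values must be finite and >= 0; offending epoch {bad}")
        if self.wear is None:
            self.wear = np.full(self.values.shape, WEAR_WORN, dtype="<U1")
        else:
            self.wear = np.asarray(self.wear, dtype="<U1")
        if self.wear.shape != self.values.shape:
            raise ValueError("wear flags must match values in length")
        bad_codes = set(np.unique(self.wear)) - _WEAR_CODES
        if bad_codes:
            raise ValueError(f"unknown wear codes {sorted(bad_codes)}; expected W/N/I")
        # clock alignment: start must fall on an epoch boundary
        offset = (self.start - self.start.normalize()).total_seconds()
        if offset % self.epoch_len_s != 0:
            raise ValueError(
                f"series start {self.start} is not aligned to the {self.epoch_len_s}-s epoch grid"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_len_s

    def timestamps(self) -> pd.DatetimeIndex:
        """Epoch start instants."""
        return self.start + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_len_s, unit="s"
        )

    def copy(self) -> "EpochSeries":
        return EpochSeries(self.start, self.epoch_len_s, self.values.copy(), self.wear.copy())


def compute_enmo(raw: RawTriaxial) -> np.ndarray:
    """Per-sample ENMO in mg: ``max(0, sqrt(x² + y² + z²) − 1) × 1000``.

    The magnitude can dip below 1 g (device noise, imperfect calibration,
    free-fall phases); such samples are truncated to 0 mg per sample, before
    any epoch averaging.

    Raises
    ------
    ValueError
        If any sample is non-finite; the error names the first offending
        sample index.
    """
    mag = np.sqrt(raw.x**2 + raw.y**2 + raw.z**2)
    if not np.all(np.isfinite(mag)):
        bad = int(np.flatnonzero(~np.isfinite(mag))[0])
        raise ValueError(f"non-finite acceleration at sample {bad}")
    return np.maximum(mag - 1.0, 0.0) * 1000.0


def aggregate_epochs(
    enmo_mg: np.ndarray,
    start: pd.Timestamp,
    rate_hz: float,
    epoch_len_s: int = 5,
) -> EpochSeries:
    """Average a per-sample ENMO series (mg) into fixed-length epochs.

    The first epoch starts at the first clock-aligned boundary at or after
    ``start``; partial leading and trailing epochs are dropped.  Each epoch
    value is the arithmetic mean of its samples.

    Parameters
    ----------
    enmo_mg : array of per-sample ENMO values in mg (e.g. from
        :func:`compute_enmo`).
    start : timestamp of the first sample.
    rate_hz : sampling rate; ``epoch_len_s * rate_hz`` must be a whole
        number of samples >= 1.
    epoch_len_s : epoch length in seconds (default 5, must divide 86400).
    """
    start = pd.Timestamp(start)
    enmo_mg = np.asarray(enmo_mg, dtype=float)
    n_per_epoch = epoch_len_s * rate_hz
    if n_per_epoch < 1 or abs(n_per_epoch - round(n_per_epoch)) > 1e-9:
        raise ValueError(
            f"epoch of {epoch_len_s}s at {rate_hz} Hz does not hold a whole "
            "number of samples (and must hold at least one)"
        )
    n_per_epoch = int(round(n_per_epoch))

    # align to the clock grid: skip samples before the next epoch boundary
    offset_s = (start - start.normalize()).total_seconds()
    lead_s = (-offset_s) % epoch_len_s
    skip = int(round(lead_s * rate_hz))
    usable = enmo_mg[skip:]
    n_epochs = usable.size // n_per_epoch
    if n_epochs == 0:
        raise ValueError("input too short for a single aligned epoch")
    usable = usable[: n_epochs * n_per_epoch]
    values = usable.reshape(n_epochs, n_per_epoch).mean(axis=1)
    epoch_start = start + pd.Timedelta(seconds=lead_s)
    return EpochSeries(epoch_start, epoch_len_s, values)


def read_epoch_csv(path) -> EpochSeries:
    """Read an epoch CSV (columns ``timestamp,enmo_mg[,wear]``).

    Timestamps must be ISO-8601, strictly increasing, with constant spacing
    equal to the epoch length.  The optional ``wear`` column holds W/N/I
    codes; absent, every epoch is treated as worn.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "enmo_mg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) < 2:
        raise ValueError(f"{path}: need at least two epochs to infer epoch length")
    steps = ts.diff().dropna().dt.total_seconds().to_numpy()
    if np.any(steps <= 0):
        row = int(np.flatnonzero(steps <= 0)[0]) + 1
        raise ValueError(f"{path}: non-monotone timestamp at row {row + 1} (0-based data row {row})")
    if np.any(steps != steps[0]):
        row = int(np.flatnonzero(steps != steps[0])[0]) + 1
        raise ValueError(
            f"{path}: inconsistent epoch spacing at row {row + 1} "
            f"(expected {steps[0]:g}s, got {steps[row - 1]:g}s)"
        )
    wear = df["wear"].to_numpy(dtype="<U1") if "wear" in df.columns else None
    return EpochSeries(ts.iloc[0], int(steps[0]), df["enmo_mg"].to_numpy(float), wear)


def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write an epoch series as ``timestamp,enmo_mg,wear`` CSV.

    Round-trips through :func:`read_epoch_csv` bit-for-bit at float repr
    precision.
    """
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
            "enmo_mg": np.asarray(series.values).astype(np.float64),
            "wear": series.wear,
        }
    )
    df.to_csv(path, index=False)  # default formatting is shortest round-trip repr
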