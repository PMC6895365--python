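"""Wear-time screening, day/participant validity and imputation.

A calendar day is *valid* when it holds strictly more than 16 h of worn
data.  A participant is *included* when they have at least three valid
days and worn data covering every 15-min period of the 24-h cycle, pooled
across all recorded days.  Non-worn epochs of included participants are
imputed with the mean of worn epochs at the same clock position on the
participant's other days, so every metric is computed on a complete 24-h
series.

Non-wear detection follows the rolling-window heuristic widely used for
raw wrist accelerometry: 60-min windows evaluated every 15 min, a window
counting as non-wear when the signal is essentially flat, with the verdict
written to the window's central 15-min block.  Two signal paths are
provided:

* **raw path** — per-epoch per-axis standard deviations (computed from the
  raw signal) are supplied; a window is non-wear when at least 2 of 3 axes
  are still (axis SD < 13 mg and, if per-axis ranges are supplied, axis
  range < 50 mg) throughout the window.
* **epoch-only fallback** — no raw signal available; a window is non-wear
  when every epoch ENMO value in it is below 13 mg and the window's value
  range is below 50 mg.  This is deliberately conservative: genuine sleep
  can be this flat, so the fallback is for data without raw access.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import (
    SECONDS_PER_DAY,
    WEAR_IMPUTED,
    WEAR_NONWEAR,
    WEAR_WORN,
    EpochSeries,
)

__all__ = [
    "DayRecord",
    "ParticipantRecord",
    "detect_nonwear",
    "split_days",
    "day_validity",
    "participant_inclusion",
    "impute",
    "qc_report",
    "N_COVERAGE_SLOTS",
    "MIN_WEAR_HOURS",
    "MIN_VALID_DAYS",
]

#: number of 15-min clock slots in 24 h used for the coverage criterion
N_COVERAGE_SLOTS = 96
#: a day is valid when worn for strictly more than this many hours
MIN_WEAR_HOURS = 16.0
#: a participant is included with at least this many valid days
MIN_VALID_DAYS = 3


@dataclass
class DayRecord:
    """One calendar day (midnight to midnight) of epoch data."""

    date: datetime.date
    epochs: EpochSeries
    wear_hours: float = float("nan")
    valid: bool = False


@dataclass
class ParticipantRecord:
    """A participant's recorded days plus the inclusion verdict."""

    id: str
    days: list[DayRecord]
    included: bool = False
    slot_coverage: np.ndarray = field(
        default_factory=lambda: np.zeros(N_COVERAGE_SLOTS, dtype=bool)
    )

    @property
    def valid_days(self) -> list[DayRecord]:
        return [d for d in self.days if d.valid]


def detect_nonwear(
    series: EpochSeries,
    raw_sd_per_axis: np.ndarray | None = None,
    raw_range_per_axis: np.ndarray | None = None,
    *,
    window_min: float = 60.0,
    step_min: float = 15.0,
    sd_mg: float = 13.0,
    range_mg: float = 50.0,
    min_still_axes: int = 2,
) -> EpochSeries:
    """Flag non-wear epochs with a rolling flatness heuristic.

    Every ``step_min`` minutes a ``window_min`` window centred on the
    current 15-min block is examined (clipped at the series edges); if it
    is flat by the active criterion the central block is flagged ``N``.
    Existing flags are overwritten.

    Parameters
    ----------
    series : epoch series to screen.
    raw_sd_per_axis : optional ``(n_epochs, 3)`` per-epoch per-axis SD of
        the raw signal, in mg.  Supplying it activates the raw path.
    raw_range_per_axis : optional ``(n_epochs, 3)`` per-epoch per-axis
        value range of the raw signal, in mg (raw path only).
    window_min, step_min, sd_mg, range_mg, min_still_axes :
        heuristic parameters; the defaults are the published 60/15-min,
        13-mg SD, 50-mg range convention.

    Returns
    -------
    A new :class:`EpochSeries` with wear flags in {W, N}.
    """
    n = len(series)
    epd_step = int(round(step_min * 60 / series.epoch_len_s))
    epd_win = int(round(window_min * 60 / series.epoch_len_s))
    out = series.copy()
    if n < epd_win:
        warnings.warn(
            f"series of {n} epochs is shorter than one {window_min:g}-min "
            "window; flagging all epochs worn",
            stacklevel=2,
        )
        out.wear = np.full(n, WEAR_WORN, dtype="<U1")
        return out

    if raw_sd_per_axis is not None:
        raw_sd_per_axis = np.asarray(raw_sd_per_axis, dtype=float)
        if raw_sd_per_axis.shape != (n, 3):
            raise ValueError("raw_sd_per_axis must have shape (n_epochs, 3)")
        if raw_range_per_axis is not None:
            raw_range_per_axis = np.asarray(raw_range_per_axis, dtype=float)
            if raw_range_per_axis.shape != (n, 3):
                raise ValueError("raw_range_per_axis must have shape (n_epochs, 3)")

    flags = np.full(n, WEAR_WORN, dtype="<U1")
    half = epd_win // 2
    for block_start in range(0, n, epd_step):
        block_end = min(block_start + epd_step, n)
        centre = block_start + (block_end - block_start) // 2
        lo = max(0, centre - half)
        hi = min(n, lo + epd_win)
        lo = max(0, hi - epd_win)  # keep a full window at the right edge
        if raw_sd_per_axis is not None:
            still = np.all(raw_sd_per_axis[lo:hi] < sd_mg, axis=0)
            if raw_range_per_axis is not None:
                still &= np.all(raw_range_per_axis[lo:hi] < range_mg, axis=0)
            nonwear = still.sum() >= min_still_axes
        else:
            vals = series.values[lo:hi]
            nonwear = bool(np.all(vals < sd_mg) and (vals.max() - vals.min()) < range_mg)
        if nonwear:
            flags[block_start:block_end] = WEAR_NONWEAR
    out.wear = flags
    return out


def split_days(series: EpochSeries) -> list[DayRecord]:
    """Split an epoch series into midnight-aligned calendar days.

    Partial first/last days are padded to a full 24 h with zero-valued
    non-wear epochs, so each returned day holds exactly
    ``86400 / epoch_len_s`` epochs.  Day validity is evaluated on the
    result.
    """
    epd = series.epochs_per_day
    offset = int(
        (series.start - series.start.normalize()).total_seconds() // series.epoch_len_s
    )
    total = offset + len(series)
    n_days = -(-total // epd)
    values = np.zeros(n_days * epd)
    wear = np.full(n_days * epd, WEAR_NONWEAR, dtype="<U1")
    values[offset : offset + len(series)] = series.values
    wear[offset : offset + len(series)] = series.wear
    day0 = series.start.normalize()
    days = []
    for i in range(n_days):
        start = day0 + pd.Timedelta(days=i)
        day_series = EpochSeries(
            start, series.epoch_len_s, values[i * epd : (i + 1) * epd], wear[i * epd : (i + 1) * epd]
        )
        days.append(day_validity(DayRecord(date=start.date(), epochs=day_series)))
    return days


def day_validity(day: DayRecord) -> DayRecord:
    """Compute worn hours and the validity verdict (worn > 16 h, strict)."""
    worn = int(np.count_nonzero(day.epochs.wear == WEAR_WORN))
    wear_hours = worn * day.epochs.epoch_len_s / 3600.0
    return replace(day, wear_hours=wear_hours, valid=wear_hours > MIN_WEAR_HOURS)


def participant_inclusion(p: ParticipantRecord) -> ParticipantRecord:
    """Apply the participant-level inclusion criteria.

    Included iff (a) at least three valid days and (b) every 15-min clock
    slot is covered by worn data on at least one day (slots pooled over
    all recorded days, valid or not).
    """
    days = [day_validity(d) if np.isnan(d.wear_hours) else d for d in p.days]
    coverage = np.zeros(N_COVERAGE_SLOTS, dtype=bool)
    slot_s = SECONDS_PER_DAY // N_COVERAGE_SLOTS
    for d in days:
        worn = d.epochs.wear == WEAR_WORN
        step = d.epochs.epoch_len_s
        if step <= slot_s and slot_s % step == 0:
            coverage |= worn.reshape(N_COVERAGE_SLOTS, slot_s // step).any(axis=1)
        elif step > slot_s and step % slot_s == 0:
            coverage |= np.repeat(worn, step // slot_s)
        else:  # epoch grid not commensurate with the 15-min grid: overlap scan
            starts = np.arange(len(worn)) * step
            for s in range(N_COVERAGE_SLOTS):
                lo, hi = s * slot_s, (s + 1) * slot_s
                overlap = (starts < hi) & (starts + step > lo)
                coverage[s] |= bool(worn[overlap].any())
    n_valid = sum(d.valid for d in days)
    included = n_valid >= MIN_VALID_DAYS and bool(coverage.all())
    return replace(p, days=days, included=included, slot_coverage=coverage)


def impute(p: ParticipantRecord, donor_mode: str = "all_days") -> ParticipantRecord:
    """Replace non-worn epochs with time-of-day means from other days.

    Every epoch flagged ``N`` is replaced by the mean of worn (``W``)
    epochs at the same clock position on the participant's other days and
    re-flagged ``I``.  Worn epochs are never altered, and the operation is
    idempotent (already-imputed epochs are left alone).

    Parameters
    ----------
    donor_mode : ``"all_days"`` (default) pools donors over every recorded
        day; ``"weekday_weekend"`` restricts donors to days of the same
        weekday/weekend class.

    Raises
    ------
    ValueError
        If some clock position needing imputation is worn on no day (such
        a participant fails the coverage criterion and should already be
        excluded); the error names the position.
    """
    if donor_mode not in ("all_days", "weekday_weekend"):
        raise ValueError(f"unknown donor_mode {donor_mode!r}")
    if not p.days:
        return p
    epd = p.days[0].epochs.epochs_per_day
    vals = np.stack([d.epochs.values for d in p.days])  # (n_days, epd)
    flags = np.stack([d.epochs.wear for d in p.days])
    worn = flags == WEAR_WORN
    is_weekend = np.array([d.date.weekday() >= 5 for d in p.days])

    new_days = []
    for i, day in enumerate(p.days):
        need = flags[i] == WEAR_NONWEAR
        if not need.any():
            new_days.append(day)
            continue
        donors = worn if donor_mode == "all_days" else worn & (is_weekend == is_weekend[i])[:, None]
        n_donors = donors.sum(axis=0)
        missing = need & (n_donors == 0)
        if missing.any():
            pos = int(np.flatnonzero(missing)[0])
            t = pd.Timedelta(seconds=pos * day.epochs.epoch_len_s)
            raise ValueError(
                f"participant {p.id}: clock position {pos} ({t}) is worn on no "
                f"{'matching ' if donor_mode != 'all_days' else ''}day; cannot impute"
            )
        with np.errstate(invalid="ignore"):
            slot_mean = np.where(donors, vals, 0.0).sum(axis=0) / np.maximum(n_donors, 1)
        series = day.epochs.copy()
        series.values[need] = slot_mean[need]
        series.wear[need] = WEAR_IMPUTED
        new_days.append(day_validity(replace(day, epochs=series)))
    return replace(p, days=new_days)


def qc_report(p: ParticipantRecord) -> pd.DataFrame:
    """Per-day QC table: date, wear hours, validity, percent imputed."""
    rows = []
    for d in p.days:
        d = day_validity(d) if np.isnan(d.wear_hours) else d
        pct = 100.0 * np.count_nonzero(d.epochs.wear == WEAR_IMPUTED) / len(d.epochs)
        rows.append(
            {"id": p.id, "date": d.date, "wear_hours": d.wear_hours, "valid": d.valid,
             "pct_imputed": pct}
        )
    return pd.DataFrame(rows)
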