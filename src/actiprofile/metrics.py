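"""Analytical and translational activity metrics.

Three families of metrics summarise a complete (imputed) 24-h epoch day:

* **average acceleration** — the mean epoch ENMO over the day (mg); a
  proxy for the volume of activity.
* **intensity gradient** — the slope of the ordinary-least-squares
  regression of ln(time accumulated per intensity bin, min) on
  ln(bin midpoint, mg).  Free-living activity time drops steeply with
  intensity, so the gradient is negative; a less negative gradient means
  more time spread across mid and high intensities.
* **MX metrics** — the acceleration above which the most active X minutes
  of the day are accumulated; with 5-s epochs M60 is the 720th-largest
  epoch value.  MX is computed as a nearest-rank order statistic (no
  interpolation) so the verbal definition holds exactly on the discrete
  epoch multiset: at least X minutes of the day have values >= MX.

All three are distributional statistics: they are invariant to the
arrangement of epochs within a day.  Metrics are computed per day on the
imputed series (imputed epochs included) and averaged, unweighted, across
a participant's valid days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .wear import DayRecord, ParticipantRecord

__all__ = [
    "DEFAULT_MX_DURATIONS",
    "IntensityBinTable",
    "GradientFit",
    "MetricSet",
    "average_acceleration",
    "bin_intensity",
    "intensity_gradient",
    "mx",
    "mx_suite",
    "day_metrics",
    "participant_summary",
]

#: default MX durations in minutes; 480 min is the most active 1/3 (8 h) of the day
DEFAULT_MX_DURATIONS = (2, 5, 10, 15, 30, 60, 120, 480)


@dataclass
class IntensityBinTable:
    """Time accumulated per acceleration-intensity bin over one day.

    Uniform ``width_mg`` bins from 0 mg with half-open intervals
    ``[edge, edge + w)``; the final bin is open-ended ``[max_edge, inf)``
    with nominal midpoint ``max_edge + w/2``.
    """

    bin_edges: np.ndarray  # left edges, mg
    width_mg: float
    time_min: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return self.bin_edges + self.width_mg / 2.0


@dataclass
class GradientFit:
    """Log-log regression of accumulated time on bin intensity."""

    slope: float
    intercept: float
    r_squared: float
    n_bins_used: int


@dataclass
class MetricSet:
    """Average acceleration, intensity-gradient fit and MX vector."""

    avg_accel_mg: float
    gradient: GradientFit
    mx: dict[int, float] = field(default_factory=dict)
    scope: str = "single_day"  # or "participant_mean"


def _require_complete_day(day: DayRecord) -> np.ndarray:
    epochs = day.epochs
    if len(epochs) != epochs.epochs_per_day:
        raise ValueError(
            f"day {day.date} has {len(epochs)} epochs; a complete day holds "
            f"{epochs.epochs_per_day} (impute before computing metrics)"
        )
    return epochs.values


def average_acceleration(day: DayRecord) -> float:
    """Mean epoch ENMO (mg) over a complete 24-h day."""
    return float(_require_complete_day(day).mean())


def bin_intensity(
    day: DayRecord, width_mg: float = 25.0, max_edge_mg: float = 4000.0
) -> IntensityBinTable:
    """Accumulate epoch time (min) into uniform intensity bins.

    An epoch with value v falls in bin ``[edge, edge + w)``; values at or
    above ``max_edge_mg`` fall in the open-ended final bin.  For a
    complete day the times sum to 1440 min.
    """
    values = _require_complete_day(day)
    edges = np.arange(0.0, max_edge_mg + width_mg, width_mg)  # left edges incl. final bin
    idx = np.minimum((values // width_mg).astype(int), edges.size - 1)
    counts = np.bincount(idx, minlength=edges.size)
    time_min = counts * day.epochs.epoch_len_s / 60.0
    return IntensityBinTable(bin_edges=edges, width_mg=width_mg, time_min=time_min)


def intensity_gradient(bins: IntensityBinTable) -> GradientFit:
    """OLS fit of ln(time) on ln(midpoint) over non-empty bins.

    Empty bins carry no time and are excluded (their log is undefined).
    At least three non-empty bins are required for a meaningful slope.
    """
    mask = bins.time_min > 0
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"intensity gradient undefined: only {n} non-empty bin(s), need >= 3")
    x = np.log(bins.midpoints[mask])
    y = np.log(bins.time_min[mask])
    fit = stats.linregress(x, y)
    return GradientFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_bins_used=n,
    )


def mx(day: DayRecord, x_min: float) -> float:
    """Acceleration (mg) above which the most active ``x_min`` minutes accumulate.

    Nearest-rank order statistic: with k = x_min * 60 / epoch_len_s, MX is
    the k-th largest epoch value, so at least X minutes of the day sit at
    values >= MX.  ``x_min`` must map to a whole number of epochs and lie
    in (0, 1440].
    """
    values = _require_complete_day(day)
    k_exact = x_min * 60.0 / day.epochs.epoch_len_s
    k = int(round(k_exact))
    if abs(k_exact - k) > 1e-9:
        raise ValueError(
            f"X = {x_min} min is not a whole number of {day.epochs.epoch_len_s}-s epochs"
        )
    if not 1 <= k <= values.size:
        raise ValueError(f"X = {x_min} min out of range (0, 1440]")
    return float(np.partition(values, values.size - k)[values.size - k])


def mx_suite(
    day: DayRecord, durations: tuple[int, ...] = DEFAULT_MX_DURATIONS
) -> dict[int, float]:
    """MX for each duration; the result is non-increasing in X."""
    return {int(x): mx(day, x) for x in durations}


def day_metrics(
    day: DayRecord,
    durations: tuple[int, ...] = DEFAULT_MX_DURATIONS,
    width_mg: float = 25.0,
    max_edge_mg: float = 4000.0,
) -> MetricSet:
    """All metrics for one complete day."""
    return MetricSet(
        avg_accel_mg=average_acceleration(day),
        gradient=intensity_gradient(bin_intensity(day, width_mg, max_edge_mg)),
        mx=mx_suite(day, durations),
        scope="single_day",
    )


def participant_summary(
    p: ParticipantRecord,
    day_filter: str = "all",
    durations: tuple[int, ...] = DEFAULT_MX_DURATIONS,
    width_mg: float = 25.0,
    max_edge_mg: float = 4000.0,
) -> MetricSet:
    """Per-day metrics averaged, unweighted, over the valid days.

    ``day_filter`` selects ``"all"`` valid days, ``"weekday"`` (Mon-Fri)
    or ``"weekend"`` (Sat-Sun).  Within a stratum the mean is unweighted,
    so weekday and weekend summaries recombine to the all-day summary
    only under explicit 5:2-style weighting.
    """
    if day_filter not in ("all", "weekday", "weekend"):
        raise ValueError(f"unknown day_filter {day_filter!r}")
    days = p.valid_days
    if day_filter == "weekday":
        days = [d for d in days if d.date.weekday() < 5]
    elif day_filter == "weekend":
        days = [d for d in days if d.date.weekday() >= 5]
    if not days:
        raise ValueError(f"participant {p.id}: no valid days in stratum {day_filter!r}")
    per_day = [day_metrics(d, durations, width_mg, max_edge_mg) for d in days]
    return MetricSet(
        avg_accel_mg=float(np.mean([m.avg_accel_mg for m in per_day])),
        gradient=GradientFit(
            slope=float(np.mean([m.gradient.slope for m in per_day])),
            intercept=float(np.mean([m.gradient.intercept for m in per_day])),
            r_squared=float(np.mean([m.gradient.r_squared for m in per_day])),
            n_bins_used=int(round(np.mean([m.gradient.n_bins_used for m in per_day]))),
        ),
        mx={x: float(np.mean([m.mx[x] for m in per_day])) for x in durations},
        scope="participant_mean",
    )
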