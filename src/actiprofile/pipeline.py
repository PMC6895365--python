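"""End-to-end glue: epoch files -> screened participants -> metrics table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import wear as _wear
from .epochs import WEAR_WORN, EpochSeries, read_epoch_csv
from .metrics import DEFAULT_MX_DURATIONS, MetricSet
from .wear import ParticipantRecord

__all__ = ["process_participant", "load_cohort_dir", "cohort_metrics", "metric_columns"]


def process_participant(
    pid: str,
    series: EpochSeries,
    detect: bool | None = None,
    donor_mode: str = "all_days",
    **nonwear_kwargs,
) -> ParticipantRecord:
    """Screen one participant: non-wear detection, validity, imputation.

    ``detect=None`` auto-detects only when the series carries no non-worn
    flags already (a file with a wear column is trusted as screened).
    Excluded participants are returned un-imputed with ``included=False``.
    """
    if detect is None:
        detect = bool(np.all(series.wear == WEAR_WORN))
    if detect:
        series = _wear.detect_nonwear(series, **nonwear_kwargs)
    p = _wear.participant_inclusion(ParticipantRecord(id=pid, days=_wear.split_days(series)))
    if p.included:
        p = _wear.impute(p, donor_mode=donor_mode)
    return p


def load_cohort_dir(epochs_dir: str | Path, **kwargs) -> list[ParticipantRecord]:
    """Process every ``*.csv`` epoch file in a directory (except truth.csv)."""
    epochs_dir = Path(epochs_dir)
    paths = sorted(q for q in epochs_dir.glob("*.csv") if q.name != "truth.csv")
    if not paths:
        raise FileNotFoundError(f"no epoch CSV files in {epochs_dir}")
    return [process_participant(q.stem, read_epoch_csv(q), **kwargs) for q in paths]


def metric_columns(durations=DEFAULT_MX_DURATIONS) -> list[str]:
    return ["avg_accel_mg", "ig_slope", "ig_intercept", "ig_r2"] + [
        f"m{x}" for x in durations
    ]


def _row(pid: str, stratum: str, n_days: int, m: MetricSet) -> dict:
    row = {
        "id": pid,
        "stratum": stratum,
        "n_valid_days": n_days,
        "avg_accel_mg": m.avg_accel_mg,
        "ig_slope": m.gradient.slope,
        "ig_intercept": m.gradient.intercept,
        "ig_r2": m.gradient.r_squared,
    }
    row.update({f"m{x}": v for x, v in m.mx.items()})
    return row


def cohort_metrics(
    participants: list[ParticipantRecord],
    strata: tuple[str, ...] = ("all",),
    durations=DEFAULT_MX_DURATIONS,
) -> pd.DataFrame:
    """Participant-mean metrics, one row per included participant × stratum.

    A stratum with no qualifying valid days for a participant (e.g. no
    weekend day) is silently omitted for that participant.
    """
    rows = []
    for p in participants:
        if not p.included:
            continue
        for stratum in strata:
            try:
                m = _metrics.participant_summary(p, day_filter=stratum, durations=durations)
            except ValueError:
                continue
            n_days = len(
                [
                    d
                    for d in p.valid_days
                    if stratum == "all"
                    or (stratum == "weekday") == (d.date.weekday() < 5)
                ]
            )
            rows.append(_row(p.id, stratum, n_days, m))
    return pd.DataFrame(rows)
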