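"""Synthetic epoch-level cohorts with known ground truth.

Free-living activity time falls off with intensity roughly as a power
law, which is exactly the structure the intensity gradient measures (a
log-log slope).  The generator therefore allocates each day's epochs to
25-mg intensity bins in proportion to ``midpoint^(-g)`` — making the true
gradient ``-g`` by construction — draws epoch values uniformly within
their bin, arranges the lowest-intensity epochs into a contiguous sleep
block and shuffles the rest across waking hours.  Optional non-wear gaps
and an overall volume rescaling complete the emulation of multi-day
wrist-accelerometer recordings.

Because every quantity is known by construction the generator doubles as
the test bed: gradient recovery, MX order-statistic checks and
wear/imputation behaviour are all verifiable against the truth table.
:func:`fixture_with_mx` additionally builds days whose nearest-rank MX
values equal requested targets bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import SECONDS_PER_DAY, WEAR_NONWEAR, WEAR_WORN, EpochSeries, write_epoch_csv
from .wear import DayRecord, ParticipantRecord, day_validity

__all__ = [
    "GeneratorConfig",
    "largest_remainder",
    "generate_day",
    "generate_participant",
    "generate_cohort",
    "concat_days",
    "fixture_with_mx",
    "generate_raw_triaxial",
]


@dataclass
class GeneratorConfig:
    """Study-design knobs for the synthetic cohort.

    ``g`` and ``target_volume_mg`` may be scalars (shared by all
    participants) or ``(lo, hi)`` ranges sampled uniformly per
    participant.  ``nonwear_gap_rate`` is the expected fraction of each
    day overwritten by non-wear gaps (30-120-min blocks on the 15-min
    grid).  A fixed ``seed`` makes the output bit-reproducible.
    """

    n_participants: int = 10
    n_days: int = 7
    epoch_len_s: int = 5
    sleep_hours: float = 8.0
    g: float | tuple[float, float] = 2.0
    target_volume_mg: float | tuple[float, float] | None = None
    nonwear_gap_rate: float = 0.0
    bin_width_mg: float = 25.0
    max_edge_mg: float = 4000.0
    start_date: str = "2024-01-01"  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        g_lo = self.g[0] if isinstance(self.g, tuple) else self.g
        if not g_lo > 0:
            raise ValueError(f"power-law exponent g must be positive, got {self.g}")
        if SECONDS_PER_DAY % self.epoch_len_s != 0:
            raise ValueError("epoch_len_s must divide 86400")
        if not 0 <= self.nonwear_gap_rate < 1:
            raise ValueError("nonwear_gap_rate must be in [0, 1)")


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``.

    Floors the exact shares, then hands the leftover units to the largest
    fractional remainders (ties broken by lowest index).  Sums exactly to
    ``total``.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    if short:
        remainders = exact - counts
        top = np.argsort(-remainders, kind="stable")[:short]
        counts[top] += 1
    return counts


def _sample(rng: np.random.Generator, value):
    if isinstance(value, tuple):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def generate_day(
    cfg: GeneratorConfig,
    g: float,
    rng: np.random.Generator,
    date: str | pd.Timestamp = None,
    target_volume_mg: float | None = None,
) -> EpochSeries:
    """Generate one full synthetic day (midnight-aligned, fully worn).

    Bin occupation times follow ``midpoint^(-g)`` over ``bin_width_mg``
    bins up to ``max_edge_mg`` (largest-remainder rounding to exactly
    86400/epoch_len epochs); epoch values are uniform within their bin.
    The allocation support is truncated to bins whose exact share is at
    least one epoch: a day cannot hold fractional epochs, and force-
    rounding far-tail shares up to single epochs would flatten the
    realised log-log distribution and bias the recovered gradient.
    If ``target_volume_mg`` is given, values are rescaled to that mean —
    a power law is scale-free, so the gradient is essentially preserved.
    The lowest epochs form a contiguous sleep block from midnight; the
    rest are shuffled across waking hours.  Non-wear gaps are inserted by
    :func:`generate_participant`, not here.
    """
    if date is None:
        date = cfg.start_date
    epd = SECONDS_PER_DAY // cfg.epoch_len_s
    edges = np.arange(0.0, cfg.max_edge_mg, cfg.bin_width_mg)
    mids = edges + cfg.bin_width_mg / 2.0
    weights = mids ** (-g)
    keep = np.ones(weights.size, dtype=bool)  # shrink support until every share >= 1 epoch
    for _ in range(weights.size):
        shares = np.where(keep, weights, 0.0)
        shares = shares / shares.sum() * epd
        new_keep = shares >= 1.0
        if not new_keep.any():
            raise ValueError(f"infeasible allocation: no bin can hold an epoch (g={g})")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    counts = largest_remainder(np.where(keep, weights, 0.0), epd)
    values = np.concatenate(
        [rng.uniform(e, e + cfg.bin_width_mg, c) for e, c in zip(edges, counts) if c]
    )
    if target_volume_mg is not None:
        mean = values.mean()
        if mean <= 0:
            raise ValueError("cannot rescale an all-zero day to a target volume")
        values = values * (target_volume_mg / mean)
    values.sort()
    n_sleep = int(round(cfg.sleep_hours * 3600 / cfg.epoch_len_s))
    day = np.empty(epd)
    day[:n_sleep] = values[:n_sleep]  # sleep block: contiguous low-intensity epochs
    waking = values[n_sleep:]
    day[n_sleep:] = rng.permutation(waking)
    return EpochSeries(pd.Timestamp(date), cfg.epoch_len_s, day)


def _insert_gaps(series: EpochSeries, rate: float, rng: np.random.Generator) -> None:
    """Overwrite wear flags with non-wear gaps totalling ≈ rate of the day."""
    if rate <= 0:
        return
    epd = len(series)
    slot = int(round(15 * 60 / series.epoch_len_s))  # 15-min grid
    target = rate * epd
    flagged = 0
    for _ in range(100):
        if flagged >= target:
            break
        gap_slots = int(rng.integers(2, 9))  # 30-120 min
        start_slot = int(rng.integers(0, epd // slot - gap_slots + 1))
        lo, hi = start_slot * slot, (start_slot + gap_slots) * slot
        flagged += np.count_nonzero(series.wear[lo:hi] == WEAR_WORN)
        series.wear[lo:hi] = WEAR_NONWEAR


def generate_participant(
    cfg: GeneratorConfig, pid: str, rng: np.random.Generator
) -> tuple[ParticipantRecord, dict]:
    """Generate one participant's days plus their ground truth."""
    g = _sample(rng, cfg.g)
    volume = None if cfg.target_volume_mg is None else _sample(rng, cfg.target_volume_mg)
    start = pd.Timestamp(cfg.start_date)
    days = []
    for i in range(cfg.n_days):
        series = generate_day(cfg, g, rng, date=start + pd.Timedelta(days=i),
                              target_volume_mg=volume)
        _insert_gaps(series, cfg.nonwear_gap_rate, rng)
        days.append(day_validity(DayRecord(date=series.start.date(), epochs=series)))
    truth = {"id": pid, "g": g, "target_volume_mg": volume}
    return ParticipantRecord(id=pid, days=days), truth


def generate_cohort(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Generate the full cohort; optionally write epoch CSVs and truth.csv.

    Deterministic under ``cfg.seed``: the same config yields identical
    series and files byte-for-byte.
    """
    rng = np.random.default_rng(cfg.seed)
    participants, truth_rows = [], []
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:03d}"
        p, truth = generate_participant(cfg, pid, rng)
        participants.append(p)
        truth_rows.append(truth)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for p in participants:
            write_epoch_csv(concat_days(p.days), out_dir / f"{p.id}.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return participants, truth


def concat_days(days: list[DayRecord]) -> EpochSeries:
    """Concatenate consecutive full days into one epoch series."""
    if not days:
        raise ValueError("no days to concatenate")
    days = sorted(days, key=lambda d: d.date)
    for a, b in zip(days, days[1:]):
        if (b.date - a.date).days != 1:
            raise ValueError(f"days {a.date} and {b.date} are not consecutive")
    return EpochSeries(
        pd.Timestamp(days[0].date),
        days[0].epochs.epoch_len_s,
        np.concatenate([d.epochs.values for d in days]),
        np.concatenate([d.epochs.wear for d in days]),
    )


def fixture_with_mx(
    targets: dict[int, float],
    epoch_len_s: int = 5,
    date: str | pd.Timestamp = "2024-01-01",
) -> EpochSeries:
    """Build a day whose nearest-rank MX equals each target exactly.

    ``targets`` maps duration X (min) to the desired MX value (mg), and
    must be non-increasing in X.  With k_i = X_i·60/epoch_len, the epochs
    ranked (k_{i-1}, k_i] (largest first, k_0 = 0) are set to the i-th
    target, so the k_i-th largest epoch is exactly targets[X_i]; the
    remainder of the day sits strictly below the smallest target.
    """
    if not targets:
        raise ValueError("no MX targets given")
    xs = sorted(targets)
    vals = [float(targets[x]) for x in xs]
    if any(b > a for a, b in zip(vals, vals[1:])):
        raise ValueError(f"MX targets must be non-increasing in X, got {targets}")
    if any(v < 0 for v in vals):
        raise ValueError("MX targets must be non-negative")
    epd = SECONDS_PER_DAY // epoch_len_s
    ks = []
    for x in xs:
        k_exact = x * 60.0 / epoch_len_s
        k = int(round(k_exact))
        if abs(k - k_exact) > 1e-9 or not 1 <= k <= epd:
            raise ValueError(f"X = {x} min infeasible on a {epoch_len_s}-s epoch grid")
        ks.append(k)
    day = np.empty(epd)
    prev = 0
    for k, v in zip(ks, vals):
        day[prev:k] = v
        prev = k
    day[prev:] = vals[-1] / 2.0  # strictly below the smallest positive target
    return EpochSeries(pd.Timestamp(date), epoch_len_s, day)


def generate_raw_triaxial(
    duration_s: float,
    rate_hz: float = 100.0,
    amplitude_g: float = 0.3,
    freq_hz: float = 2.0,
    noise_g: float = 0.02,
    rng: np.random.Generator | None = None,
    start: str | pd.Timestamp = "2024-01-01",
):
    """Simple sinusoid-plus-noise raw signal for exercising the ENMO path.

    Gravity sits on the z axis; x carries a sinusoid of ``amplitude_g`` at
    ``freq_hz`` emulating rhythmic movement.  Not a biomechanical model.
    """
    from .epochs import RawTriaxial

    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = amplitude_g * np.sin(2 * np.pi * freq_hz * t) + rng.normal(0, noise_g, n)
    y = rng.normal(0, noise_g, n)
    z = 1.0 + rng.normal(0, noise_g, n)
    return RawTriaxial(pd.Timestamp(start), rate_hz, x, y, z)
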