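"""Post-hoc translation of MX metrics.

The central tenet of the MX approach is that acceleration thresholds
(cut-points) are applied only *after* analysis: the metrics stay
continuous, and any cut-point — an MVPA threshold, the acceleration of a
brisk walk — can be laid against them afterwards.  A child with an M60 of
210 mg meets a 60-min MVPA guideline read against a 200-mg cut-point but
not against a stricter 250-mg one; the data themselves are never
collapsed.

This module also provides the cohort-level translations used for the
radar plots: empirical percentiles and individual percentile ranks,
within-metric z-standardisation, tertile profiling (fixing volume while
contrasting intensity gradient), and affine between-device harmonisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CutPoint",
    "DEFAULT_CUTPOINTS",
    "load_cutpoints",
    "meets_cutpoint",
    "cohort_percentiles",
    "percentile_of",
    "standardize",
    "tertile_assign",
    "tertile_profiles",
    "harmonize",
    "ACTIGRAPH_SCALE",
]

#: approximate multiplicative correction for ActiGraph devices, whose
#: average accelerations run about 10% below GENEActiv/Axivity values
ACTIGRAPH_SCALE = 1.0 / 0.9


@dataclass(frozen=True)
class CutPoint:
    """A labelled acceleration threshold used post-hoc for interpretation."""

    label: str
    threshold_mg: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.threshold_mg > 0:
            raise ValueError(f"cut-point threshold must be positive, got {self.threshold_mg}")


#: registry of commonly used wrist cut-points (mg).  Applied only at the
#: translation stage, never before metric computation.
DEFAULT_CUTPOINTS: dict[str, CutPoint] = {
    "mvpa_200": CutPoint("mvpa_200", 200.0, "MVPA, wrist"),
    "mvpa_250": CutPoint("mvpa_250", 250.0, "MVPA, wrist, more stringent"),
    "vig_700": CutPoint("vig_700", 700.0, "vigorous, wrist"),
    "very_vig_1200": CutPoint("very_vig_1200", 1200.0, "very vigorous, wrist"),
}


def load_cutpoints(path) -> dict[str, CutPoint]:
    """Load a cut-point registry from YAML (label -> {threshold_mg, ...})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for label, entry in raw.items():
        if isinstance(entry, dict):
            out[label] = CutPoint(label, float(entry["threshold_mg"]), str(entry.get("note", "")))
        else:
            out[label] = CutPoint(label, float(entry))
    return out


def meets_cutpoint(mx_value_mg: float, cp: CutPoint) -> bool:
    """Whether an MX value meets (>=) a cut-point.

    A boundary-exact profile counts as meeting: an M60 equal to the MVPA
    cut-point means the most active 60 min all sit at or above it.
    """
    return bool(mx_value_mg >= cp.threshold_mg)


def cohort_percentiles(
    table: pd.DataFrame, metrics: list[str], probs: np.ndarray
) -> pd.DataFrame:
    """Empirical cohort quantiles (linear interpolation) per metric.

    Parameters
    ----------
    table : one row per included participant, metric columns complete.
    metrics : column names to summarise (e.g. ``["m5", "m60", "m480"]``).
    probs : probabilities in [0, 1] (0.5 is the median).

    Returns
    -------
    DataFrame indexed by probability with one column per metric.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    probs = np.asarray(probs, dtype=float)
    data = {m: np.quantile(table[m].to_numpy(float), probs) for m in metrics}
    return pd.DataFrame(data, index=pd.Index(probs, name="prob"))


def percentile_of(value: float, table: pd.DataFrame, metric: str) -> float:
    """Mid-rank percentile (0-100) of an individual value within the cohort.

    ``100 * (count below + 0.5 * count equal) / n`` — symmetric in ties,
    so a cohort-median value in an odd cohort sits at exactly the 50th
    percentile.
    """
    col = table[metric].to_numpy(float)
    if col.size == 0:
        raise ValueError("empty cohort table")
    below = np.count_nonzero(col < value)
    equal = np.count_nonzero(col == value)
    return 100.0 * (below + 0.5 * equal) / col.size


def standardize(table: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Within-metric z-scores across the cohort (sample SD, ddof=1).

    Each selected column is transformed to mean 0 and SD 1, so profiles of
    different overall scale can be compared shape-to-shape.  Non-selected
    columns pass through unchanged.
    """
    if metrics is None:
        metrics = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(table) < 2:
        raise ValueError("standardisation needs at least two participants")
    out = table.copy()
    for m in metrics:
        col = table[m].to_numpy(float)
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"metric {m!r} has zero variance; cannot standardise")
        out[m] = (col - col.mean()) / sd
    return out


def tertile_assign(values: np.ndarray) -> np.ndarray:
    """Rank-based tertile labels (0 = low, 1 = mid, 2 = high).

    Cuts fall at ranks ceil(n/3) and ceil(2n/3); ties are broken by stable
    input order, so equal values are assigned deterministically.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    c1 = -(-n // 3)
    c2 = -(-2 * n // 3)
    labels = np.empty(n, dtype=int)
    labels[order[:c1]] = 0
    labels[order[c1:c2]] = 1
    labels[order[c2:]] = 2
    return labels


def tertile_profiles(
    table: pd.DataFrame,
    mx_columns: list[str],
    volume_metric: str = "avg_accel_mg",
    split_metric: str = "ig_slope",
) -> pd.DataFrame:
    """Mean MX profiles for intensity-gradient tertiles at matched volume.

    Restricts the cohort to the mid-tertile of ``volume_metric`` (similar
    activity volume), splits it by tertiles of ``split_metric`` (low/mid/
    high intensity gradient), and returns per-group mean MX vectors —
    the comparison that isolates the intensity distribution from volume.

    Returns a DataFrame indexed by ``("low", "mid", "high")`` with mean MX
    columns and an ``n`` column of group sizes.
    """
    if len(table) < 9:
        raise ValueError(f"tertile profiling needs >= 9 participants, got {len(table)}")
    vol_tert = tertile_assign(table[volume_metric].to_numpy(float))
    mid = table.loc[vol_tert == 1].copy()
    split_tert = tertile_assign(mid[split_metric].to_numpy(float))
    names = np.array(["low", "mid", "high"])
    mid["_group"] = names[split_tert]
    rows = []
    for name in names:
        grp = mid.loc[mid["_group"] == name]
        if grp.empty:
            raise ValueError(f"{split_metric} tertile {name!r} is empty")
        row = {m: grp[m].mean() for m in mx_columns}
        row["n"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(names, name="ig_tertile"))


def harmonize(values_mg, scale: float, offset: float = 0.0):
    """Affine between-device harmonisation: ``v' = scale * v + offset``.

    Positive affine maps commute with order statistics, so harmonising
    epoch values and then computing MX equals computing MX and then
    harmonising.  ``ACTIGRAPH_SCALE`` (≈ 1/0.9) is an approximate preset
    lifting ActiGraph values onto the GENEActiv/Axivity scale.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    arr = np.asarray(values_mg, dtype=float) * scale + offset
    return float(arr) if np.isscalar(values_mg) else arr
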