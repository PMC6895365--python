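"""Radar plots of MX activity profiles.

One radial axis per MX duration, by default running clockwise from the
top through M1/3DAY (480 min), M120, M60, M30, M15 and M5.  The joined
points of a group form a closed polygon: overall polygon size tracks the
volume of activity (average acceleration), while the area covered on the
short-duration side tracks the intensity gradient.  Three plot modes are
provided: raw mg profiles with cut-point/walk reference circles,
within-metric standardised profiles (mean 0, SD 1, with a dashed circle at
z = 0), and cohort-percentile fans with an optional individual overlay.

The geometric core (:func:`polar_map`) is a pure function and is what the
tests exercise; the render functions are thin matplotlib wrappers that
always write a companion CSV of plotted values next to each figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["RadarSpec", "mx_label", "polar_map", "render_profile", "render_percentile_plot"]

#: default clockwise axis order (minutes), most active 8 h first
DEFAULT_AXES = (480, 120, 60, 30, 15, 5)


def mx_label(duration_min: int) -> str:
    """Axis label for an MX duration (480 min is the most active 1/3 day)."""
    return "M1/3DAY" if duration_min == 480 else f"M{duration_min}"


@dataclass
class RadarSpec:
    """Declarative description of a radar plot.

    Parameters
    ----------
    axes : ordered MX durations (min), plotted clockwise from the top.
    mode : ``"raw_mg"`` or ``"standardized"``.
    radial_max : outer radius in mg (raw mode).  ``None`` auto-scales to
        the plotted maximum rounded up to a clean step.
    z_range : radial span in SD units (standardised mode).
    reference_bands : ``(label, threshold)`` pairs drawn as dashed
        circles — cut-points or slow/brisk-walk accelerations in raw
        mode, z-values in standardised mode.
    """

    axes: tuple[int, ...] = DEFAULT_AXES
    mode: str = "raw_mg"
    radial_max: float | None = None
    z_range: tuple[float, float] = (-3.0, 3.0)
    reference_bands: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axes = tuple(int(a) for a in self.axes)
        if len(self.axes) < 3:
            raise ValueError("a radar plot needs at least 3 axes")
        if len(set(self.axes)) != len(self.axes):
            raise ValueError("radar axes must be distinct")
        if self.mode not in ("raw_mg", "standardized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "raw_mg" and self.radial_max is not None and not self.radial_max > 0:
            raise ValueError("radial_max must be positive in raw mode")
        if not self.z_range[1] > self.z_range[0]:
            raise ValueError("z_range must be increasing")

    def angles(self) -> np.ndarray:
        """Axis angles in radians: top (π/2), then clockwise."""
        k = np.arange(len(self.axes))
        return -2.0 * math.pi * k / len(self.axes) + math.pi / 2.0

    def to_radius(self, value: float, radial_max: float) -> float:
        if self.mode == "raw_mg":
            return min(max(value / radial_max, 0.0), 1.0)
        lo, hi = self.z_range
        return min(max((value - lo) / (hi - lo), 0.0), 1.0)


def _clean_ceiling(x: float) -> float:
    """Round up to a clean step (one significant decade below x)."""
    if x <= 0:
        return 1.0
    step = 10.0 ** math.floor(math.log10(x))
    if x / step < 2:
        step /= 5
    return math.ceil(x / step) * step


def _resolve_radial_max(spec: RadarSpec, vectors) -> float:
    if spec.mode != "raw_mg":
        return 1.0
    if spec.radial_max is not None:
        return float(spec.radial_max)
    peak = max(max(v.values()) for v in vectors)
    for _, thr in spec.reference_bands:
        peak = max(peak, thr)
    return _clean_ceiling(peak)


def polar_map(
    spec: RadarSpec, mx_vector: dict[int, float], radial_max: float | None = None
) -> list[tuple[float, float]]:
    """Map an MX vector onto closed-polygon polar coordinates.

    Returns ``(angle_rad, radius)`` pairs, one per axis in spec order with
    the first point repeated to close the polygon.  Radii are normalised
    to [0, 1]: ``value / radial_max`` in raw mode, position within
    ``z_range`` in standardised mode.

    Raises
    ------
    KeyError
        If the vector lacks a value for some axis.
    """
    missing = [a for a in spec.axes if a not in mx_vector]
    if missing:
        raise KeyError(f"MX vector missing value(s) for axes {missing}")
    if radial_max is None:
        radial_max = _resolve_radial_max(spec, [mx_vector])
    pts = [
        (float(ang), spec.to_radius(float(mx_vector[a]), radial_max))
        for a, ang in zip(spec.axes, spec.angles())
    ]
    return pts + [pts[0]]


def _setup_axes(spec: RadarSpec, radial_max: float):
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # clockwise, matching the axis listing
    k = np.arange(len(spec.axes))
    ax.set_xticks(2.0 * math.pi * k / len(spec.axes))
    ax.set_xticklabels([mx_label(a) for a in spec.axes])
    ax.set_ylim(0, 1)
    if spec.mode == "raw_mg":
        ticks = np.linspace(0, 1, 5)
        ax.set_yticks(ticks)
        ax.set_yticklabels([f"{t * radial_max:g}" for t in ticks])
    else:
        lo, hi = spec.z_range
        ticks = np.linspace(0, 1, 7)
        ax.set_yticks(ticks)
        ax.set_yticklabels([f"{lo + t * (hi - lo):+.1f}" for t in ticks])
    return fig, ax


def _theta_for_plot(spec: RadarSpec) -> np.ndarray:
    # with theta zero at N and clockwise direction, axis k sits at 2πk/K
    k = np.arange(len(spec.axes) + 1) % len(spec.axes)
    return 2.0 * math.pi * k / len(spec.axes)


def _draw_reference_bands(ax, spec: RadarSpec, radial_max: float) -> None:
    theta = np.linspace(0, 2 * math.pi, 181)
    for label, thr in spec.reference_bands:
        r = spec.to_radius(thr, radial_max)
        ax.plot(theta, np.full_like(theta, r), "--", color="red", linewidth=1, label=label)
    if spec.mode == "standardized":
        r0 = spec.to_radius(0.0, radial_max)
        ax.plot(
            theta, np.full_like(theta, r0), "--", color="black", linewidth=1,
            label="cohort mean (z = 0)",
        )


def _write_outputs(fig, values: pd.DataFrame, out) -> list[Path]:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for suffix in (".png", ".svg"):
        p = out.with_suffix(suffix)
        fig.savefig(p, bbox_inches="tight")
        written.append(p)
    csv_path = out.with_suffix(".csv")
    values.to_csv(csv_path)
    written.append(csv_path)
    return written


def render_profile(
    spec: RadarSpec,
    vectors: dict[str, dict[int, float]],
    out=None,
    annotations: dict[str, str] | None = None,
):
    """Render group/individual MX profiles as overlaid polygons.

    Parameters
    ----------
    vectors : mapping of overlay label to MX vector (duration -> value,
        mg in raw mode, z-scores in standardised mode).
    out : optional output path; the figure is written as ``.png`` and
        ``.svg`` plus a companion ``.csv`` of the plotted values.
    annotations : optional extra legend text per label (e.g. average
        acceleration and intensity gradient of the group).

    Returns the matplotlib Figure.
    """
    if not vectors:
        raise ValueError("need at least one MX vector to plot")
    radial_max = _resolve_radial_max(spec, vectors.values())
    fig, ax = _setup_axes(spec, radial_max)
    theta = _theta_for_plot(spec)
    for label, vec in vectors.items():
        radii = [r for _, r in polar_map(spec, vec, radial_max)]
        text = label if not annotations or label not in annotations else (
            f"{label} ({annotations[label]})"
        )
        ax.plot(theta, radii, marker="o", linewidth=1.5, label=text)
        ax.fill(theta, radii, alpha=0.10)
    _draw_reference_bands(ax, spec, radial_max)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=8)
    if out is not None:
        values = pd.DataFrame(
            {label: [vec[a] for a in spec.axes] for label, vec in vectors.items()},
            index=pd.Index([mx_label(a) for a in spec.axes], name="metric"),
        )
        _write_outputs(fig, values, out)
    return fig


def render_percentile_plot(
    spec: RadarSpec,
    percentiles: pd.DataFrame,
    individual: dict[int, float] | None = None,
    out=None,
):
    """Render nested cohort-percentile polygons with optional individual overlay.

    Parameters
    ----------
    percentiles : DataFrame indexed by probability (ascending) with one
        column per axis duration (column keys are the durations in
        minutes), e.g. from ``translation.cohort_percentiles``.
    individual : optional MX vector drawn on top of the fan.

    Shading runs white at the lowest percentile to dark grey at the
    highest; polygons are nested because quantiles are monotone in
    probability.
    """
    cols = {int(c) for c in percentiles.columns}
    missing = [a for a in spec.axes if a not in cols]
    if missing:
        raise ValueError(f"percentile table missing axes {missing}")
    probs = percentiles.index.to_numpy(float)
    if np.any(np.diff(probs) <= 0):
        raise ValueError("percentile probabilities must be strictly increasing")
    vectors = [
        {a: float(percentiles.loc[p, a]) for a in spec.axes} for p in percentiles.index
    ]
    all_vecs = vectors + ([individual] if individual else [])
    radial_max = _resolve_radial_max(spec, all_vecs)
    fig, ax = _setup_axes(spec, radial_max)
    theta = _theta_for_plot(spec)
    # fill from the outermost (darkest) down so lighter bands overlay
    for i in range(len(vectors) - 1, -1, -1):
        radii = [r for _, r in polar_map(spec, vectors[i], radial_max)]
        shade = 1.0 - 0.8 * (i + 1) / len(vectors)  # white -> dark grey
        ax.fill(theta, radii, color=str(shade), zorder=1 + (len(vectors) - i))
        ax.plot(
            theta, radii, color="0.4", linewidth=0.6,
            zorder=1 + (len(vectors) - i), label=f"p{100 * probs[i]:g}",
        )
    if individual:
        radii = [r for _, r in polar_map(spec, individual, radial_max)]
        ax.plot(theta, radii, color="tab:blue", marker="o", linewidth=1.8,
                zorder=50, label="individual")
    _draw_reference_bands(ax, spec, radial_max)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=7)
    if out is not None:
        values = percentiles.copy()
        values.columns = [mx_label(int(c)) for c in percentiles.columns]
        if individual:
            values.loc["individual"] = [individual[int(c)] for c in percentiles.columns]
        _write_outputs(fig, values, out)
    return fig
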