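# Methods

## Signal model and units

Input is tri-axial acceleration in gravitational units (g) from a
calibrated body-worn device, or an already epoch-summarised series. The
per-sample magnitude metric is ENMO (Euclidean norm minus one g),
truncated at zero per sample and expressed in mg:
`enmo = max(0, sqrt(x² + y² + z²) − 1) × 1000`. Truncation happens before
epoch averaging (the convention of the widely used processing tools; the
alternative — truncating the epoch mean — differs only when a sub-1-g dip
and movement share an epoch). Epochs are aligned to local-clock
boundaries, partial leading/trailing epochs are dropped, and days run
midnight to midnight in timezone-naive local time; daylight-saving
transitions are a documented limitation.

The 5-s default epoch matters: longer epochs smooth out short
high-intensity bursts, deflating short-duration MX metrics and the
intensity gradient. Epoch length must therefore match across datasets
being compared; functions take `epoch_len_s` explicitly and never resample.

## Wear screening, validity, imputation

Non-wear is detected with the rolling flatness heuristic standard for raw
wrist accelerometry: 60-min windows evaluated every 15 min, the verdict
written to the window's central 15-min block (windows are centred on the
block and clipped at the series edges). With per-epoch per-axis raw SDs
available, a window is non-wear when ≥ 2 of 3 axes are still (SD < 13 mg,
range < 50 mg when ranges are supplied). Without raw access an epoch-only
fallback flags windows whose ENMO values all sit below 13 mg with range
< 50 mg; this is conservative — quiet sleep can be that flat — and is
intended for data lacking raw signals. All thresholds are parameters. The
central-block rule means a flat span's detected edges are resolved only
to `window/2 − step/2` = 22.5 min.

A day is valid with strictly more than 16 h worn. A participant is
included with ≥ 3 valid days and worn data, pooled over all recorded
days, in each of the 96 15-min clock slots. (The alternative reading —
coverage required within every single day — would exclude almost any
day with a gap; the pooled reading is the one consistent with imputation
from other days.) Non-worn epochs of included participants are then
imputed with the mean of worn values at the same clock position on the
other days; `donor_mode="weekday_weekend"` optionally restricts donors to
the same weekday/weekend class. Imputation is idempotent, never touches
worn epochs, and fails loudly if a position has no donor (such
participants fail the coverage criterion anyway). Metrics are computed on
the imputed 24-h series, imputed epochs included.

## Metrics

*Average acceleration* is the mean over the complete day's epochs (mg).

*Intensity gradient*: epoch time is accumulated into uniform 25-mg bins
`[edge, edge + 25)` from 0 mg with an open-ended final bin at 4000 mg
(midpoint 4012.5), then `ln(time_min)` is regressed on `ln(midpoint_mg)`
by ordinary least squares over the non-empty bins (empty bins carry no
information and their log is undefined; ≥ 3 non-empty bins are required).
Natural logs; `r²` is the squared Pearson correlation of the fit. The
open-ended bin is included when occupied. Bin width, ceiling and the
open-bin choice are exposed as parameters. Per-day gradients are fitted
and then averaged across days, not fitted on a pooled histogram.

*MX*: with `k = X·60/epoch_len_s`, MX is the k-th largest epoch value
(nearest-rank order statistic, no interpolation). This makes the verbal
definition exact on the discrete epoch multiset: at least X minutes sit
at values ≥ MX, and MX is the largest such threshold. Consequences used
by the tests: MX is non-increasing in X, permutation-invariant, and
commutes with positive affine maps (so device harmonisation can be
applied before or after metric computation).

*Participant summaries* are unweighted means over valid days, optionally
restricted to weekdays (Mon–Fri) or weekend days; the two strata
recombine to the all-day mean only under explicit day-count weighting.

## Translation

Cut-points (e.g. 200- and 250-mg MVPA, 700-mg vigorous, 1200-mg very
vigorous, wrist) live in a registry and are compared with MX values only
after analysis. The boundary counts as meeting (`≥`): a profile whose
most active X minutes sit exactly at the threshold has accumulated X
minutes at that intensity. Cohort percentiles use linearly interpolated
empirical quantiles; individual percentile ranks use the mid-rank
convention `100·(#below + ½·#equal)/n`, symmetric under ties.
Standardisation is within-metric z-scoring with sample SD (ddof = 1).
Tertile cuts fall at ranks ⌈n/3⌉ and ⌈2n/3⌉ with ties broken by stable
input order. Between-device harmonisation is affine (`v' = s·v + b`); the
ActiGraph preset `s = 1/0.9` reflects the ≈ 10% lower average
accelerations that brand records relative to GENEActiv/Axivity and is
marked approximate.

## Radar plots

Axes are MX durations, by default clockwise from the top:
M1/3DAY, M120, M60, M30, M15, M5. Radii are linear from 0; raw mode
scales by `radial_max` (auto: the plotted maximum rounded up to a clean
step), standardised mode maps a configurable z-range (default ±3 SD) onto
the radius, with a dashed black circle at z = 0 marking the cohort mean.
Reference circles (cut-points, slow/brisk-walk accelerations) are dashed.
Percentile plots draw nested polygons shaded white (lowest percentile) to
dark grey (highest), with an optional individual overlay. Rendering is
deterministic, and every figure is written as PNG + SVG alongside a CSV
of the exact plotted values. The geometry lives in the pure function
`polar_map`, which is what the tests assert on.

## Synthetic cohorts

The generator emulates multi-day epoch recordings with truth known by
construction. Each day's 86400/epoch_len epochs are allocated to 25-mg
bins proportionally to `midpoint^(−g)` (largest-remainder rounding, which
sums exactly to a 1440-min day), so the true intensity gradient is −g;
values are uniform within their bin. The allocation support is truncated
to bins whose exact share is at least one epoch: a day cannot hold
fractional epochs, and force-rounding far-tail shares up to whole epochs
would flatten the realised distribution and bias the recovered gradient
(with the truncation, per-day fits recover −g within ±0.1 for
g ∈ [1.5, 2.5] at 5-s epochs). An optional target mean rescales values
multiplicatively — a power law is scale-free, so the gradient is
essentially preserved — allowing volume and intensity to be varied
independently, as in tertile-profile analyses. The lowest-intensity
epochs form a contiguous 8-h sleep block from midnight; the rest are
shuffled across waking hours. Non-wear gaps are 30–120-min blocks on the
15-min grid inserted until the requested fraction of the day is flagged
(default rate 0, cohort examples use 3–5%, typical of compliant wrist
protocols). Per-participant `g` is drawn uniformly from a configurable
range; everything is driven by one seed and is byte-reproducible.

What the generator does not emulate: autocorrelated bout structure,
diurnal intensity rhythms beyond the sleep block, device noise or
calibration error, and weekday/weekend behavioural differences. Passing
tests therefore validate the metric definitions and pipeline mechanics,
not behavioural realism; conclusions about real cohorts still require
real data. `fixture_with_mx` builds days whose nearest-rank MX equals
requested targets exactly (ranks `(k_{i−1}, k_i]` set to the i-th target),
used for boundary-exact checks such as the M60 = 210 mg example.

## Problem sizes and numerical choices

The test suite and acceptance script use 200 synthetic days for the MX
oracle comparison, 1000 days for monotonicity, a 30-participant cohort
for gradient rank-correlation, and a 50-participant × 7-day cohort for
the end-to-end run — sizes at which every stochastic check is stable
across seeds while the whole suite stays fast. Order statistics use
`numpy.partition`; the gradient fit uses `scipy.stats.linregress`;
quantiles use linear interpolation; all tolerances asserted in tests are
stated there explicitly. Degenerate inputs raise: incomplete days,
fewer than 3 non-empty gradient bins, zero-variance standardisation
columns, non-monotone MX fixture targets, unimputable clock positions.

## Known limitations

Local-time day boundaries ignore daylight-saving shifts; the epoch-only
non-wear fallback can misclassify very quiet sleep as non-wear; the
ActiGraph harmonisation preset is a population-level approximation, not a
per-device calibration; raw-signal support covers CSV input only (no
device binary formats) and assumes prior autocalibration.
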