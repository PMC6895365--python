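# actiprofile

Analytical and translational metrics for raw-acceleration wearable data,
with radar-plot visualisation of 24-h activity profiles.

## The problem

Cut-point analysis of accelerometer data — counting minutes above a fixed
acceleration threshold such as "200 mg = moderate-to-vigorous physical
activity (MVPA)" — collapses the signal into categories *before* analysis.
Results produced with different cut-points cannot be compared, and most of
the measured intensity spectrum is discarded. `actiprofile` implements the
alternative: analyse the data with continuous, data-driven metrics, and
bring thresholds in only afterwards, at the translation stage.

It is aimed at physical-activity and epidemiology researchers working with
epoch-summarised wrist/hip/thigh accelerometer data (ENMO in
milli-gravitational units, mg).

## The metrics

For each complete (imputed) 24-h day of epoch values $a_1,\dots,a_n$
(default 5-s epochs, $n = 17{,}280$):

* **Average acceleration** (volume): $\bar a = \tfrac1n\sum_i a_i$ (mg).
* **Intensity gradient** (intensity distribution): accumulate the time
  $t_b$ (min) spent in 25-mg intensity bins with midpoints $m_b$, and fit
  $\ln t_b = \beta_0 + \beta \ln m_b$ by OLS over non-empty bins. The
  slope $\beta$ is the intensity gradient; free-living data give
  $\beta < 0$, and a less negative $\beta$ means more time at mid/high
  intensities.
* **MX metrics** (translational): the acceleration above which the most
  active X minutes of the day are accumulated — with 5-s epochs, MX is
  the $k$-th largest epoch value where $k = 60X/5$. M60 is the minimum
  acceleration of the most active accumulated 60 min; M1/3DAY (X = 480)
  covers the most active 8 h. Defaults: X ∈ {2, 5, 10, 15, 30, 60, 120, 480}.

Days with ≤ 16 h of wear are invalid; participants need ≥ 3 valid days and
worn data in every 15-min slot of the 24-h cycle; non-worn epochs are
imputed from the same clock time on other days; metrics are computed per
day and averaged over valid days. MX values are then *translated*
post-hoc: compared against any cut-point or typical-activity acceleration,
ranked against cohort percentiles, or standardised within metric and drawn
on radar plots.

## Worked example

```python
import actiprofile as ap

# a day engineered so the 720th-largest 5-s epoch is 210 mg
series = ap.fixture_with_mx({60: 210.0})
day = ap.day_validity(ap.DayRecord(date=series.start.date(), epochs=series))

m60 = ap.mx(day, 60)
print(f"M60 = {m60:.0f} mg")
print("meets 200-mg MVPA guideline:", ap.meets_cutpoint(m60, ap.DEFAULT_CUTPOINTS["mvpa_200"]))
print("meets 250-mg MVPA guideline:", ap.meets_cutpoint(m60, ap.DEFAULT_CUTPOINTS["mvpa_250"]))
```

prints

```
M60 = 210 mg
meets 200-mg MVPA guideline: True
meets 250-mg MVPA guideline: False
```

i.e. this person accumulated their most active 60 min at accelerations of
at least 210 mg: enough for a 60-min MVPA guideline read against a 200-mg
cut-point, but short of a stricter 250-mg one — the same number translated
against both thresholds, with no re-processing.

The command-line pipeline mirrors the library:

```bash
actiprofile synth    --config gen.yml --out epochs/
actiprofile metrics  --epochs epochs/ --out metrics.csv --strata all,weekday,weekend
actiprofile translate --metrics metrics.csv --out translation.csv
actiprofile plot     --metrics metrics.csv --mode percentile --out fig.png
```

`metrics.csv` holds one row per participant × stratum (`avg_accel_mg`,
`ig_slope`, `ig_r2`, `m2` … `m480`); every figure is written as PNG + SVG
with a companion CSV of the exact plotted values.

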