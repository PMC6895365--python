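import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actiprofile.metrics import (
    DEFAULT_MX_DURATIONS,
    IntensityBinTable,
    average_acceleration,
    bin_intensity,
    day_metrics,
    intensity_gradient,
    mx,
    mx_suite,
    participant_summary,
)
from actiprofile.synth import GeneratorConfig, generate_day
from actiprofile.wear import ParticipantRecord, participant_inclusion

from conftest import EPD_5S, make_day


def brute_force_mx(values, x_min, epoch_len_s=5):
    """Independent oracle: largest threshold c in the value multiset with
    at least X minutes accumulated at values >= c."""
    values = np.asarray(values)
    best = None
    for c in np.unique(values)[::-1]:
        minutes = np.count_nonzero(values >= c) * epoch_len_s / 60.0
        if minutes >= x_min:
            best = c
            break
    return best


class TestAverageAcceleration:
    def test_constant_day(self):
        assert average_acceleration(make_day(np.full(EPD_5S, 30.0))) == 30.0

    def test_half_and_half(self):
        vals = np.r_[np.zeros(EPD_5S // 2), np.full(EPD_5S // 2, 100.0)]
        assert average_acceleration(make_day(vals)) == pytest.approx(50.0)

    def test_matches_bruteforce_mean(self, random_day):
        vals = random_day.epochs.values
        assert average_acceleration(random_day) == pytest.approx(
            sum(vals) / len(vals), abs=1e-9
        )

    def test_incomplete_day_rejected(self):
        with pytest.raises(ValueError, match="complete day"):
            average_acceleration(make_day(np.zeros(100)))


class TestBinIntensity:
    def test_single_low_bin(self):
        table = bin_intensity(make_day(np.full(EPD_5S, 10.0)))
        assert table.time_min[0] == pytest.approx(1440.0)
        assert table.time_min[1:].sum() == 0.0

    def test_boundary_value_goes_to_upper_bin(self):
        vals = np.full(EPD_5S, 10.0)
        vals[0] = 25.0  # exactly on the first edge: half-open [25, 50)
        table = bin_intensity(make_day(vals))
        assert table.time_min[1] == pytest.approx(5.0 / 60.0)

    def test_matches_histogram_oracle(self, random_day):
        table = bin_intensity(random_day)
        vals = random_day.epochs.values
        edges = np.r_[np.arange(0.0, 4025.0, 25.0), np.inf]
        expected = np.histogram(vals, bins=edges)[0] * 5 / 60.0
        np.testing.assert_allclose(table.time_min, expected, atol=1e-12)
        assert table.time_min.sum() == pytest.approx(1440.0)

    def test_values_above_ceiling_land_in_open_bin(self):
        vals = np.full(EPD_5S, 10.0)
        vals[:12] = 9999.0
        table = bin_intensity(make_day(vals))
        assert table.time_min[-1] == pytest.approx(1.0)
        assert table.midpoints[-1] == pytest.approx(4012.5)


class TestIntensityGradient:
    def test_exact_power_law_recovers_slope(self):
        edges = np.arange(0.0, 4025.0, 25.0)
        mids = edges + 12.5
        table = IntensityBinTable(edges, 25.0, 100.0 * mids**-2.0)
        fit = intensity_gradient(table)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.n_bins_used == len(mids)

    def test_uniform_time_gives_zero_slope(self):
        edges = np.arange(0.0, 4025.0, 25.0)
        table = IntensityBinTable(edges, 25.0, np.full(edges.size, 5.0))
        assert intensity_gradient(table).slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_bins_rejected(self):
        edges = np.arange(0.0, 4025.0, 25.0)
        time_min = np.zeros(edges.size)
        time_min[:2] = 700.0
        with pytest.raises(ValueError, match="non-empty"):
            intensity_gradient(IntensityBinTable(edges, 25.0, time_min))

    def test_generator_day_recovery_and_regression_oracle(self, rng):
        day = make_day(generate_day(GeneratorConfig(), 2.5, rng).values)
        fit = intensity_gradient(bin_intensity(day))
        assert fit.slope == pytest.approx(-2.5, abs=0.1)
        # independent OLS oracle on the same bin table
        table = bin_intensity(day)
        mask = table.time_min > 0
        x = np.log(table.midpoints[mask])
        y = np.log(table.time_min[mask])
        slope_oracle, intercept_oracle = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope_oracle, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept_oracle, abs=1e-9)

    def test_free_living_style_day_has_negative_slope(self, rng):
        for g in (0.5, 1.5, 3.0):
            day = make_day(generate_day(GeneratorConfig(), g, rng).values)
            assert intensity_gradient(bin_intensity(day)).slope < 0


class TestMX:
    def test_constant_day_all_durations(self):
        day = make_day(np.full(EPD_5S, 50.0))
        assert all(v == 50.0 for v in mx_suite(day).values())

    def test_step_day_m60_m120(self):
        vals = np.r_[np.full(720, 300.0), np.full(EPD_5S - 720, 20.0)]
        day = make_day(vals)
        assert mx(day, 60) == 300.0  # 720 x 5 s = exactly 60 min at 300 mg
        assert mx(day, 120) == 20.0
        assert mx(day, 60) == brute_force_mx(vals, 60)
        assert mx(day, 120) == brute_force_mx(vals, 120)

    def test_worked_example_m60_210(self, rng):
        # a day whose 720th-largest epoch is 210 mg: the child accumulated
        # 60 min at accelerations above 210 mg
        vals = np.r_[
            rng.uniform(211.0, 900.0, 719),
            [210.0],
            rng.uniform(0.0, 209.0, EPD_5S - 720),
        ]
        day = make_day(rng.permutation(vals))
        assert mx(day, 60) == 210.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            vals = np.round(rng.lognormal(2.5, 1.5, EPD_5S), 1)
            day = make_day(vals)
            for x in DEFAULT_MX_DURATIONS:
                assert mx(day, x) == brute_force_mx(vals, x)

    def test_extremes(self, random_day):
        vals = random_day.epochs.values
        assert mx(random_day, 1440) == vals.min()
        assert mx(random_day, 5 / 60) == vals.max()  # single epoch

    def test_out_of_range_rejected(self, random_day):
        with pytest.raises(ValueError):
            mx(random_day, 0)
        with pytest.raises(ValueError):
            mx(random_day, 1441)
        with pytest.raises(ValueError, match="whole number"):
            mx(random_day, 0.07)

    def test_suite_non_increasing_and_complete(self, random_day):
        suite = mx_suite(random_day)
        assert list(suite) == [2, 5, 10, 15, 30, 60, 120, 480]
        vals = list(suite.values())
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_permutation_invariance(self, rng, random_day):
        vals = random_day.epochs.values
        shuffled = make_day(rng.permutation(vals))
        assert mx_suite(shuffled) == mx_suite(random_day)
        assert average_acceleration(shuffled) == average_acceleration(random_day)
        assert intensity_gradient(bin_intensity(shuffled)).slope == pytest.approx(
            intensity_gradient(bin_intensity(random_day)).slope
        )


@settings(deadline=None, max_examples=100)
@given(st.data())
def test_mx_oracle_equivalence_small_days(data):
    # 1-h epochs: 24 per day, X a whole number of hours
    values = data.draw(
        st.lists(
            st.floats(min_value=0, max_value=2000, allow_nan=False, width=32),
            min_size=24, max_size=24,
        )
    )
    x = data.draw(st.sampled_from([60, 120, 720, 1440]))
    day = make_day(values, epoch_len_s=3600)
    assert mx(day, x) == brute_force_mx(values, x, epoch_len_s=3600)


class TestParticipantSummary:
    def _participant(self, day_values, start="2024-01-01"):
        days = [
            make_day(v, date=pd.Timestamp(start) + pd.Timedelta(days=i))
            for i, v in enumerate(day_values)
        ]
        return participant_inclusion(ParticipantRecord(id="P1", days=days))

    def test_identical_days_equal_single_day(self, rng):
        vals = rng.lognormal(2.0, 1.5, EPD_5S)
        p = self._participant([vals, vals, vals])
        summary = participant_summary(p)
        single = day_metrics(p.days[0])
        assert summary.avg_accel_mg == pytest.approx(single.avg_accel_mg)
        assert summary.gradient.slope == pytest.approx(single.gradient.slope)
        assert summary.mx == pytest.approx(single.mx)
        assert summary.scope == "participant_mean"

    def test_mean_of_per_day_mx(self):
        base = np.r_[np.full(720, 60.0), np.full(720, 30.0), np.ones(EPD_5S - 1440)]
        d1, d2 = base.copy(), base.copy()
        d1[:720] = 100.0
        d2[:720] = 200.0
        p = self._participant([d1, d2, d1])  # need 3 valid days for inclusion
        assert participant_summary(p).mx[60] == pytest.approx((100 + 200 + 100) / 3)

    def test_weekday_weekend_strata_recombine_with_5_2_weights(self, rng):
        # start on a Monday: 5 weekdays then 2 weekend days
        day_values = [rng.lognormal(2.0, 1.2, EPD_5S) for _ in range(7)]
        p = self._participant(day_values, start="2024-01-01")
        full = participant_summary(p, "all")
        wd = participant_summary(p, "weekday")
        we = participant_summary(p, "weekend")
        pooled = (5 * wd.avg_accel_mg + 2 * we.avg_accel_mg) / 7
        assert full.avg_accel_mg == pytest.approx(pooled, abs=1e-9)
        # the unweighted mean of the two strata is generally different
        assert full.avg_accel_mg != pytest.approx((wd.avg_accel_mg + we.avg_accel_mg) / 2,
                                                  abs=1e-12)

    def test_no_qualifying_days_rejected(self, rng):
        day_values = [rng.lognormal(2.0, 1.2, EPD_5S) for _ in range(3)]
        p = self._participant(day_values, start="2024-01-01")  # Mon-Wed only
        with pytest.raises(ValueError, match="weekend"):
            participant_summary(p, "weekend")

    def test_constant_metric_mean_is_constant(self):
        vals = np.r_[np.full(720, 300.0), np.full(720, 60.0), np.full(EPD_5S - 1440, 10.0)]
        p = self._participant([vals, vals, vals, vals])
        assert participant_summary(p).avg_accel_mg == pytest.approx(vals.mean())
        assert participant_summary(p).mx[60] == 300.0
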