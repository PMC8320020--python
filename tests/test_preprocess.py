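"""Resampling, RCH, resting heart rate, sleep features, eligibility."""

import numpy as np
import pytest

from wearcast.synthetic import (
    HeartRateSeries, StepSeries, SleepNight, SeizureDiary, MIN_PER_DAY,
)
from wearcast import preprocess as pp


def hr_from_minutes(minute_values, missing=None):
    """Build a 5 s series whose per-minute means equal ``minute_values``."""
    vals = np.repeat(np.asarray(minute_values, dtype=float), 12)
    mask = np.zeros(vals.size, dtype=bool)
    if missing is not None:
        for m in missing:
            mask[m * 12:(m + 1) * 12] = True
            vals[m * 12:(m + 1) * 12] = np.nan
    return HeartRateSeries(vals, mask, step_seconds=5)


class TestResample:
    def test_no_gaps_identity_path(self):
        rng = np.random.default_rng(0)
        raw_vals = rng.normal(70, 5, 50 * 12)
        raw = HeartRateSeries(raw_vals, np.zeros(600, bool), 5)
        out = pp.resample_heart_rate(raw)
        assert out.n == 50 and not out.missing_mask.any()
        assert np.allclose(out.bpm, raw_vals.reshape(50, 12).mean(axis=1))

    def test_short_gap_linear_fill(self):
        # 60-min gap between minutes valued 60 and 120 BPM
        minutes = [60.0] + [np.nan] * 60 + [120.0]
        raw = hr_from_minutes(np.nan_to_num(minutes, nan=0.0),
                              missing=range(1, 61))
        out = pp.resample_heart_rate(raw)
        assert out.bpm[31] == pytest.approx(90.0, abs=1.0)   # midpoint
        assert np.all(np.diff(out.bpm) > 0)
        assert out.missing_mask[1:61].all()

    def test_long_gap_mean_fill(self):
        # 3 h gap in a series whose non-missing mean is 70
        minutes = [70.0] * 100 + [0.0] * 180 + [70.0] * 100
        raw = hr_from_minutes(minutes, missing=range(100, 280))
        out = pp.resample_heart_rate(raw)
        assert np.allclose(out.bpm[100:280], 70.0)

    def test_causal_fill_uses_only_past_data(self):
        minutes = [60.0] * 100 + [0.0] * 180 + [90.0] * 100
        raw = hr_from_minutes(minutes, missing=range(100, 280))
        out = pp.resample_heart_rate(raw, causal=True)
        assert np.allclose(out.bpm[100:280], 60.0)   # pre-gap mean, not 75

    def test_resampling_conserves_hourly_mass(self):
        rng = np.random.default_rng(1)
        raw_vals = rng.normal(70, 8, 60 * 12)
        raw = HeartRateSeries(raw_vals, np.zeros(720, bool), 5)
        out = pp.resample_heart_rate(raw)
        assert out.bpm.mean() == pytest.approx(raw_vals.mean(), abs=1e-9)

    def test_empty_and_all_missing_rejected(self):
        with pytest.raises(ValueError):
            pp.resample_heart_rate(HeartRateSeries(np.empty(0), np.empty(0, bool), 5))
        allmiss = hr_from_minutes([0.0] * 10, missing=range(10))
        with pytest.raises(ValueError, match="entirely missing"):
            pp.resample_heart_rate(allmiss)


class TestRCH:
    def test_per_minute_definition(self):
        hr = HeartRateSeries(np.array([60.0, 62.0]), np.zeros(2, bool), 60)
        assert pp.per_minute_rch(hr)[0] == pytest.approx(2.0)

    def test_constant_series_is_zero(self):
        hr = HeartRateSeries(np.full(200, 70.0), np.zeros(200, bool), 60)
        assert np.allclose(pp.compute_rch(hr, "hourly").to_numpy(), 0.0)
        assert np.allclose(pp.compute_rch(hr, "daily").to_numpy(), 0.0)

    def test_mean_absolute_aggregation(self):
        hr = HeartRateSeries(np.array([60.0, 62.0, 58.0]), np.zeros(3, bool), 60)
        out = pp.compute_rch(hr, "hourly")
        # per-minute RCH = [+2, -4]; mean absolute = 3
        assert out.iloc[-1] == pytest.approx(3.0)

    def test_too_short_input_empty(self):
        hr = HeartRateSeries(np.array([60.0]), np.zeros(1, bool), 60)
        assert pp.compute_rch(hr, "hourly").empty


class TestRHR:
    @staticmethod
    def _day(bpm_minutes, step_minutes):
        hr = HeartRateSeries(np.asarray(bpm_minutes, float),
                             np.zeros(len(bpm_minutes), bool), 60)
        return hr, StepSeries(np.asarray(step_minutes, np.int64))

    def test_bottom_quintile_arithmetic(self):
        assert pp.bottom_quintile_mean([50, 51, 52, 53, 54, 55, 56, 57, 58, 59]) \
            == pytest.approx(50.5)

    def test_constant_day(self):
        bpm = np.full(MIN_PER_DAY, 70.0)
        hr, st = self._day(bpm, np.zeros(MIN_PER_DAY))
        assert pp.compute_daily_rhr(hr, st).iloc[0] == pytest.approx(70.0)

    def test_all_moving_day_carries_forward(self):
        bpm = np.full(2 * MIN_PER_DAY, 70.0)
        bpm[MIN_PER_DAY:] = 80.0
        steps = np.zeros(2 * MIN_PER_DAY)
        steps[MIN_PER_DAY:] = 5               # day 2: never at rest
        hr, st = self._day(bpm, steps)
        out = pp.compute_daily_rhr(hr, st)
        assert out.iloc[0] == pytest.approx(70.0)
        assert out.iloc[1] == pytest.approx(70.0)   # carried forward

    def test_rhr_monotone_under_elementwise_increase(self):
        # raising any pool value never lowers RHR, and values above the
        # quintile cut leave it untouched (the fraction-based quintile can
        # grow with pool size, so RHR is monotone in values, not pool size)
        rng = np.random.default_rng(2)
        base = rng.normal(65, 5, 200)
        lo = pp.bottom_quintile_mean(base)
        raised = base + rng.uniform(0, 3, base.size)
        assert pp.bottom_quintile_mean(raised) >= lo
        untouched = base.copy()
        untouched[np.argmax(untouched)] += 50.0
        assert pp.bottom_quintile_mean(untouched) == pytest.approx(lo)


class TestStepFeatures:
    def test_prior_hour_and_day_sums(self):
        steps = StepSeries(np.full(2 * MIN_PER_DAY, 1, dtype=np.int64))
        t = np.array([MIN_PER_DAY + 300.0])
        assert pp.steps_previous_hour(steps, t)[0] == 60.0
        assert pp.steps_previous_day(steps, t)[0] == 1440.0
        zero = StepSeries(np.zeros(2 * MIN_PER_DAY, dtype=np.int64))
        assert pp.steps_previous_hour(zero, t)[0] == 0.0
        assert pp.steps_previous_day(zero, t)[0] == 0.0

    def test_exact_prior_hour_block(self):
        arr = np.zeros(300, dtype=np.int64)
        arr[120:180] = 10                      # 10 steps/min for one hour
        steps = StepSeries(arr)
        assert pp.steps_previous_hour(steps, np.array([180.0]))[0] == 600.0


class TestSleepFeatures:
    @staticmethod
    def _night(day, onset_clock=1380, rem=100, deep=120, light=240, wake=20):
        onset = day * MIN_PER_DAY + onset_clock
        stages = np.array(
            ["rem"] * rem + ["deep"] * deep + ["light"] * light + ["wake"] * wake,
            dtype=object)
        return SleepNight(onset, onset + len(stages), stages)

    def test_stage_counting_excludes_wake(self):
        nights = [self._night(0)]
        hr = HeartRateSeries(np.full(3 * MIN_PER_DAY, 60.0),
                             np.zeros(3 * MIN_PER_DAY, bool), 60)
        df = pp.compute_sleep_features(nights, hr)
        row = df.iloc[0]
        assert row.total_sleep == 460 and row.rem == 100
        assert row.deep == 120 and row.light == 240
        assert row.mean_overnight_hr == pytest.approx(60.0)

    def test_identical_nights_zero_deviation_after_warmup(self):
        nights = [self._night(d) for d in range(30)]
        n = 31 * MIN_PER_DAY
        hr = HeartRateSeries(np.full(n, 60.0), np.zeros(n, bool), 60)
        df = pp.compute_sleep_features(nights, hr)
        assert (df.sleep_onset_deviation == 0).all()
        assert (df.wake_time_deviation == 0).all()
        assert df.deviation_warmup.iloc[14] == False  # noqa: E712
        assert df.deviation_warmup.iloc[13] == True   # noqa: E712


class TestEligibility:
    def test_filters_and_reasons(self, default_participant):
        import dataclasses
        p = default_participant
        rec = pp.eligibility_filter([p])[0]
        assert rec.eligible
        few = dataclasses.replace(
            p, diary=SeizureDiary(p.diary.times_min[:19], p.diary.types[:19]))
        rec2 = pp.eligibility_filter([few])[0]
        assert not rec2.eligible and "seizure count" in rec2.reasons

    def test_low_adherence_rejected(self, default_participant):
        import dataclasses
        p = default_participant
        bpm = p.hr.bpm.copy()
        mask = p.hr.missing_mask.copy()
        cut = int(0.21 * bpm.size)
        mask[:cut] = True
        bpm[:cut] = np.nan
        bad = dataclasses.replace(
            p, hr=HeartRateSeries(bpm, mask, 5, p.hr.start))
        rec = pp.eligibility_filter([bad])[0]
        assert not rec.eligible and "adherence" in rec.reasons

    def test_clustered_seizures_give_one_lead(self):
        cluster = np.array([1000.0, 1010.0, 1020.0, 1030.0])
        assert pp.count_lead_seizures(cluster, 60.0) == 1
        assert pp.count_lead_seizures(cluster, float(MIN_PER_DAY)) == 1
        spread = np.array([0.0, 120.0, 300.0])
        assert pp.count_lead_seizures(spread, 60.0) == 3


def test_feature_causality_audit(default_participant):
    """Features at time t are invariant to perturbing data at t + 2 h onward.

    The two-hour guard covers the documented look-ahead of the short-gap
    linear interpolation rule; everything else is strictly causal.
    """
    import dataclasses
    p = default_participant
    tau = 60 * MIN_PER_DAY
    guard = tau - 120
    bpm = p.hr.bpm.copy()
    bpm[tau * 12:] = 40.0 + 10 * np.sin(np.arange(bpm.size - tau * 12))
    steps2 = p.steps.steps.copy()
    steps2[tau:] = 0
    q = dataclasses.replace(
        p, hr=HeartRateSeries(bpm, p.hr.missing_mask.copy(), 5, p.hr.start),
        steps=StepSeries(steps2, p.steps.start))

    hr_a = pp.resample_heart_rate(p.hr, causal=True)
    hr_b = pp.resample_heart_rate(q.hr, causal=True)

    rch_a = pp.compute_rch(hr_a, "hourly")
    rch_b = pp.compute_rch(hr_b, "hourly")
    sel = rch_a.index < guard
    assert np.allclose(rch_a[sel], rch_b[sel], equal_nan=True)

    rhr_a = pp.compute_daily_rhr(hr_a, p.steps)
    rhr_b = pp.compute_daily_rhr(hr_b, q.steps)
    sel = rhr_a.index < guard
    assert np.allclose(rhr_a[sel], rhr_b[sel], equal_nan=True)

    sa = pp.steps_previous_hour(p.steps, np.arange(0.0, guard, 60.0))
    sb = pp.steps_previous_hour(q.steps, np.arange(0.0, guard, 60.0))
    assert np.array_equal(sa, sb)
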