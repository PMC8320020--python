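"""Feature primitives from raw wearable streams.

Turns the raw 5 s heart-rate stream, per-minute step counts, sleep-stage
labels and the seizure diary into the forecaster's inputs:

* 1-min resampled heart rate with rule-based gap filling (linear for gaps
  shorter than 2 h, series mean otherwise; the missing mask is retained);
* RCH — the minute-to-minute change in mean BPM, a crude heart-rate
  variability proxy, aggregated to the forecast grid as the mean absolute
  change over the preceding hour or day;
* daily resting heart rate (RHR) — mean of the lowest quintile of BPM among
  zero-step minutes of each day;
* step counts over the previous hour and the previous calendar day;
* seven daily sleep features per wake event (three stage durations plus total
  sleep, overnight heart rate, and onset/wake deviations from rolling
  medians over up to 90 prior nights);
* cohort eligibility and train/test split dates.

Every feature value at time ``t`` depends only on data strictly before ``t``.
All times are minutes since the participant's recording start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import (
    HeartRateSeries, StepSeries, SleepNight, SeizureDiary, Participant,
    SAMPLES_PER_MIN, MIN_PER_DAY,
)

SLEEP_FEATURES = (
    "total_sleep", "rem", "deep", "light",
    "mean_overnight_hr", "sleep_onset_deviation", "wake_time_deviation",
)

GAP_LINEAR_MAX_MIN = 120       # gaps shorter than 2 h: linear interpolation
RHR_MIN_MINUTES = 30           # fewer zero-step minutes -> carry RHR forward
MEDIAN_WINDOW_NIGHTS = 90      # rolling-median history for sleep deviations
MEDIAN_MIN_NIGHTS = 14         # warm-up before deviations are emitted


def resample_heart_rate(raw: HeartRateSeries, causal: bool = False) -> HeartRateSeries:
    """Down-sample the 5 s stream to 1-min means and fill gaps.

    Per-minute value = mean of the available 5 s samples in that minute.
    Minutes with no samples are filled linearly between flanking values when
    the gap is shorter than 2 h, and with the mean of the non-missing series
    otherwise.  The returned mask marks filled minutes so downstream stages
    can exclude them.

    With ``causal=True`` long gaps are filled with the mean of the
    non-missing data strictly *before* the gap (the walk-forward engine uses
    this variant so that no filled value depends on later data); the default
    matches the retrospective convention of filling at the whole-series mean.
    """
    if raw.n == 0:
        raise ValueError("empty heart-rate series")
    if raw.step_seconds == 60:
        return raw
    n_min = raw.n // SAMPLES_PER_MIN
    bpm = raw.bpm[: n_min * SAMPLES_PER_MIN].reshape(n_min, SAMPLES_PER_MIN)
    miss = raw.missing_mask[: n_min * SAMPLES_PER_MIN].reshape(n_min, SAMPLES_PER_MIN)
    avail = (~miss).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(np.where(miss, np.nan, bpm), axis=1)
    mask = avail == 0
    if mask.all():
        raise ValueError("heart-rate series entirely missing")
    series_mean = float(np.mean(vals[~mask]))

    filled = vals.copy()
    idx = np.flatnonzero(mask)
    if idx.size:
        # contiguous runs of missing minutes
        starts = idx[np.r_[True, np.diff(idx) > 1]]
        ends = idx[np.r_[np.diff(idx) > 1, True]]
        csum = np.cumsum(np.where(mask, 0.0, vals))
        cnt = np.cumsum(~mask)
        for a, b in zip(starts, ends):
            length = b - a + 1
            left = a - 1 if a > 0 and not mask[a - 1] else None
            right = b + 1 if b + 1 < n_min and not mask[b + 1] else None
            if length < GAP_LINEAR_MAX_MIN and left is not None and right is not None:
                filled[a:b + 1] = np.interp(
                    np.arange(a, b + 1), [left, right], [vals[left], vals[right]])
            elif causal:
                # mean of observed data strictly before the gap; a leading
                # gap falls back to the first observed value
                filled[a:b + 1] = (csum[a - 1] / cnt[a - 1]) if (
                    a > 0 and cnt[a - 1] > 0) else vals[~mask][0]
            else:
                filled[a:b + 1] = series_mean
    return HeartRateSeries(filled, mask, step_seconds=60, start=raw.start)


def compute_rch(hr: HeartRateSeries, horizon: str) -> pd.Series:
    """Rate of change in heart rate, aggregated to the forecast grid.

    The per-minute RCH is the mean BPM of a minute minus the mean BPM of the
    previous minute.  Because RCH stands in for heart-rate variability, the
    hourly/daily value is the mean *absolute* per-minute RCH over the
    preceding hour or day (variability is a magnitude).  Indexed by the
    minute at which the value becomes available (causal).
    """
    if horizon not in ("hourly", "daily"):
        raise ValueError("horizon must be 'hourly' or 'daily'")
    if hr.step_seconds != 60:
        raise ValueError("compute_rch expects the 1-min resampled series")
    if hr.n < 2:
        return pd.Series(dtype=float, name="RCH")
    abs_rch = np.abs(per_minute_rch(hr))
    window = 60 if horizon == "hourly" else MIN_PER_DAY
    csum = np.concatenate([[0.0], np.cumsum(abs_rch)])
    grid = list(range(window, hr.n + 1, window))
    if not grid or grid[-1] != hr.n:
        grid.append(hr.n)                       # final partial window
    vals = []
    for t in grid:
        hi = min(t - 1, abs_rch.size)           # only diffs complete before t
        lo = max(0, hi - window)
        vals.append((csum[hi] - csum[lo]) / max(hi - lo, 1))
    return pd.Series(vals, index=np.asarray(grid, dtype=float), name="RCH")


def per_minute_rch(hr: HeartRateSeries) -> np.ndarray:
    """Per-minute RCH: mean BPM of each minute minus that of the previous one."""
    return np.diff(hr.bpm)


def compute_daily_rhr(hr: HeartRateSeries, steps: StepSeries) -> pd.Series:
    """Daily resting heart rate: mean of the bottom BPM quintile at rest.

    For each calendar day, minutes with zero steps and observed (unmasked)
    heart rate are pooled; RHR is the mean of the lowest 20% of those BPM
    values.  Days with fewer than 30 such minutes inherit the previous day's
    value (forecasts are issued regardless of adherence); leading absent days
    are NaN.  Indexed by the minute the value becomes available (midnight at
    the *end* of the day, causal).
    """
    if hr.step_seconds != 60:
        raise ValueError("compute_daily_rhr expects the 1-min resampled series")
    n = min(hr.n, steps.steps.size)
    n_days = n // MIN_PER_DAY
    out_idx, out_vals = [], []
    prev = np.nan
    for d in range(n_days):
        sl = slice(d * MIN_PER_DAY, (d + 1) * MIN_PER_DAY)
        ok = (steps.steps[sl] == 0) & (~hr.missing_mask[sl])
        vals = hr.bpm[sl][ok]
        if vals.size >= RHR_MIN_MINUTES:
            k = max(1, int(np.ceil(vals.size * 0.2)))
            prev = float(np.mean(np.sort(vals)[:k]))
        out_idx.append(float((d + 1) * MIN_PER_DAY))
        out_vals.append(prev)
    return pd.Series(out_vals, index=out_idx, name="RHR")


def bottom_quintile_mean(values) -> float:
    """Mean of the lowest 20% of values (at least one value)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    k = max(1, int(np.ceil(v.size * 0.2)))
    return float(np.mean(v[:k]))


def steps_previous_hour(steps: StepSeries, times_min) -> np.ndarray:
    """Steps in the 60 minutes strictly before each forecast time."""
    csum = np.concatenate([[0], np.cumsum(steps.steps)])
    t = np.clip(np.asarray(times_min, dtype=int), 0, steps.steps.size)
    lo = np.clip(t - 60, 0, None)
    return (csum[t] - csum[lo]).astype(float)


def steps_previous_day(steps: StepSeries, times_min) -> np.ndarray:
    """Steps over the previous calendar day relative to each forecast time."""
    daily = np.add.reduceat(
        steps.steps[: (steps.steps.size // MIN_PER_DAY) * MIN_PER_DAY],
        np.arange(0, (steps.steps.size // MIN_PER_DAY) * MIN_PER_DAY, MIN_PER_DAY))
    day = (np.asarray(times_min, dtype=int) // MIN_PER_DAY) - 1
    out = np.zeros(len(day), dtype=float)
    ok = (day >= 0) & (day < daily.size)
    out[ok] = daily[day[ok]]
    return out


def compute_sleep_features(nights, hr: HeartRateSeries) -> pd.DataFrame:
    """One seven-feature vector per wake from main sleep.

    Columns: total minutes asleep during main sleep (wake-within-sleep and
    naps excluded), REM / deep / light minutes, mean overnight heart rate,
    and signed deviations of sleep onset and wake clock-times from their
    rolling medians over up to 90 prior nights (zero, flagged, before 14
    nights of history).  Indexed by the wake minute; naps are skipped.
    """
    if hr.step_seconds != 60:
        raise ValueError("compute_sleep_features expects the 1-min resampled series")
    rows = []
    onset_hist, wake_hist = [], []
    for nt in sorted(nights, key=lambda x: x.onset_min):
        if not nt.is_main_sleep:
            continue
        rem = nt.stage_minutes("rem")
        deep = nt.stage_minutes("deep")
        light = nt.stage_minutes("light")
        total = rem + deep + light
        sl = slice(max(nt.onset_min, 0), min(nt.wake_min, hr.n))
        seg = hr.bpm[sl][~hr.missing_mask[sl]]
        overnight = float(np.mean(seg)) if seg.size else np.nan
        # clock-times measured from 18:00 of the evening the night began,
        # so onsets straddling midnight stay on one continuous axis
        night_anchor = (nt.onset_min - 18 * 60) // MIN_PER_DAY * MIN_PER_DAY + 18 * 60
        onset_clock = nt.onset_min - night_anchor
        wake_clock = nt.wake_min - night_anchor
        if len(onset_hist) >= MEDIAN_MIN_NIGHTS:
            onset_dev = onset_clock - float(np.median(onset_hist[-MEDIAN_WINDOW_NIGHTS:]))
            wake_dev = wake_clock - float(np.median(wake_hist[-MEDIAN_WINDOW_NIGHTS:]))
            warm = False
        else:
            onset_dev = wake_dev = 0.0
            warm = True
        onset_hist.append(onset_clock)
        wake_hist.append(wake_clock)
        rows.append({
            "wake_min": float(nt.wake_min), "total_sleep": float(total),
            "rem": float(rem), "deep": float(deep), "light": float(light),
            "mean_overnight_hr": overnight,
            "sleep_onset_deviation": float(onset_dev),
            "wake_time_deviation": float(wake_dev),
            "deviation_warmup": warm,
        })
    df = pd.DataFrame(rows)
    return df.set_index("wake_min") if len(df) else df


# ---------------------------------------------------------------------------
# eligibility and split dates
# ---------------------------------------------------------------------------

@dataclass
class EligibilityRecord:
    eligible: bool
    reasons: list
    span_days: float
    adherence: float
    n_seizures: int
    training_cutoff_min: float | None      # end of the training dataset
    lead_seizures_hourly: int              # lead events in the testing span
    lead_seizures_daily: int
    passes_testing_gate: bool = False


def count_lead_seizures(times_min, horizon_min: float) -> int:
    """Events separated from the previous event by at least the horizon."""
    t = np.sort(np.asarray(times_min, dtype=float))
    if t.size == 0:
        return 0
    return 1 + int(np.sum(np.diff(t) >= horizon_min))


def training_cutoff(diary: SeizureDiary, span_min: float,
                    min_days: float = 60.0, min_seizures: int = 15) -> float | None:
    """Earliest minute by which >= 2 months have elapsed and >= 15 seizures occurred."""
    t = np.sort(diary.times_min)
    if t.size < min_seizures:
        return None
    cutoff = max(min_days * MIN_PER_DAY, float(np.ceil(t[min_seizures - 1])))
    return cutoff if cutoff < span_min else None


def eligibility_filter(participants) -> list:
    """Apply the cohort filters and derive per-participant split dates.

    A participant is eligible when the recording spans at least two months,
    heart-rate adherence (fraction of non-missing 1-min samples over the
    span) is at least 80%, and at least 20 seizures were reported.  The
    training cut-off is the earliest date by which two months of recording
    and 15 seizures had accrued; the testing gate additionally requires at
    least five lead seizures after the cut-off (>= 1 h apart hourly,
    >= 1 day apart daily).
    """
    records = []
    for p in participants:
        hr1 = resample_heart_rate(p.hr) if p.hr.step_seconds != 60 else p.hr
        span_min = hr1.n
        span_days = span_min / MIN_PER_DAY
        adherence = 1.0 - float(hr1.missing_mask.mean())
        reasons = []
        if span_days < 60:
            reasons.append("recording span")
        if adherence < 0.8:
            reasons.append("adherence")
        if p.diary.n < 20:
            reasons.append("seizure count")
        cutoff = training_cutoff(p.diary, span_min)
        if cutoff is None:
            reasons.append("training cutoff")
        lead_h = lead_d = 0
        gate = False
        if cutoff is not None:
            test_t = p.diary.times_min[p.diary.times_min >= cutoff]
            lead_h = count_lead_seizures(test_t, 60.0)
            lead_d = count_lead_seizures(test_t, float(MIN_PER_DAY))
            gate = lead_h >= 5 and lead_d >= 5
            if not gate:
                reasons.append("lead seizures")
        records.append(EligibilityRecord(
            eligible=not reasons, reasons=reasons, span_days=span_days,
            adherence=adherence, n_seizures=p.diary.n,
            training_cutoff_min=cutoff, lead_seizures_hourly=lead_h,
            lead_seizures_daily=lead_d, passes_testing_gate=gate))
    return records
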