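"""Cycle detection, phase extraction, circular statistics, encodings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wearcast.synthetic import HeartRateSeries
from wearcast import cycles as cyc

TWO_PI = 2 * np.pi


def sinusoid_hr(period_hours, days, amp=5.0, noise=0.0, baseline=70.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(days * 1440), dtype=float)
    bpm = baseline + amp * np.cos(TWO_PI * t / (period_hours * 60.0))
    if noise:
        bpm = bpm + rng.normal(0, noise, t.size)
    return HeartRateSeries(bpm, np.zeros(t.size, bool), 60)


# ---------------------------------------------------------------------------
# Hodges-Ajne
# ---------------------------------------------------------------------------

def brute_force_m(theta):
    """Independent oracle: exact minimum half-circle count by direct
    counting at boundaries just past every data point and antipode."""
    theta = np.asarray(theta) % TWO_PI
    best = theta.size
    for anchor in np.concatenate([theta, theta - np.pi]):
        t = anchor + 1e-9
        count = int(np.sum((theta - t) % TWO_PI < np.pi))
        best = min(best, count)
    return best


class TestHodgesAjne:
    @given(st.integers(5, 30), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_statistic_matches_brute_force(self, n, seed):
        theta = np.random.default_rng(seed).uniform(0, TWO_PI, n)
        m, p = cyc.hodges_ajne_test(theta)
        assert m == brute_force_m(theta)
        assert 0.0 <= p <= 1.0

    def test_identical_phases_are_maximally_concentrated(self):
        previous = 1.0
        for n in (5, 8, 12, 20):
            m, p = cyc.hodges_ajne_test(np.full(n, 2.2))
            assert m == 0
            assert p == pytest.approx((n * 2.0 ** (1 - n)) if n <= 50 else p)
            assert p < previous          # monotone decreasing in n
            previous = p

    def test_equally_spaced_phases_look_uniform(self):
        for n in (8, 16, 30):
            theta = np.arange(n) * TWO_PI / n
            m, p = cyc.hodges_ajne_test(theta)
            assert m == brute_force_m(theta)
            assert m >= n // 2 - 1
            assert p > 0.5

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            cyc.hodges_ajne_test([0.1, 0.2, 0.3, 0.4])

    def test_type_one_error_is_controlled(self):
        # the exact test is conservative: size never exceeds the nominal
        # level and is far below it at small n (discrete statistic)
        rng = np.random.default_rng(0)
        for n, lo in ((10, 0.005), (100, 0.015)):
            rej = sum(cyc.hodges_ajne_test(rng.uniform(0, TWO_PI, n))[1] < 0.05
                      for _ in range(400)) / 400
            assert lo <= rej <= 0.08


# ---------------------------------------------------------------------------
# periodogram and peak detection
# ---------------------------------------------------------------------------

class TestPeriodogram:
    def test_circadian_peak_recovered(self):
        hr = sinusoid_hr(24.0, 60, amp=5, noise=2.0, seed=1)
        spec = cyc.wavelet_periodogram(hr)
        top = spec.periods_hours[np.argmax(spec.power)]
        assert abs(top - 24.0) / 24.0 < 0.05

    def test_two_component_recovery(self):
        hr = sinusoid_hr(24.0, 90, amp=5, noise=1.0, seed=2)
        hr = HeartRateSeries(
            hr.bpm + 4 * np.cos(TWO_PI * np.arange(hr.n) / (168.0 * 60)),
            hr.missing_mask, 60)
        spec = cyc.wavelet_periodogram(hr)
        cands = cyc.detect_peak_periods(spec)
        assert any(abs(c - 24.0) / 24.0 < 0.05 for c in cands)
        assert any(abs(c - 168.0) / 168.0 < 0.05 for c in cands)

    def test_white_noise_rarely_beats_envelope(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            hr = HeartRateSeries(rng.normal(70, 3, 60 * 1440),
                                 np.zeros(60 * 1440, bool), 60)
            spec = cyc.wavelet_periodogram(hr)
            cands = [c for c in cyc.detect_peak_periods(spec) if c != 24.0]
            hits += bool(cands)
        assert hits <= 3

    def test_flat_spectrum_keeps_standing_circadian(self):
        hr = sinusoid_hr(24.0, 30, amp=0.0, noise=1.0, seed=3)
        cands = cyc.detect_peak_periods(cyc.wavelet_periodogram(hr))
        assert 24.0 in cands

    def test_nearby_peaks_merge_within_bandwidth(self):
        spec = cyc.CycleSpectrum(
            periods_hours=np.geomspace(100, 300, 60),
            power=np.zeros(60), background=np.zeros(60),
            ar1=0.0, dt_hours=1.0, n_samples=1000)
        i166 = np.argmin(np.abs(spec.periods_hours - 166))
        i170 = np.argmin(np.abs(spec.periods_hours - 170))
        spec.power[i166] = 1.0
        spec.power[i170] = 0.9
        spec.background[:] = 0.1
        cands = [c for c in cyc.detect_peak_periods(spec) if c > 36]
        assert len(cands) == 1


# ---------------------------------------------------------------------------
# phase extraction
# ---------------------------------------------------------------------------

class TestPhase:
    def test_phase_zero_at_peaks(self):
        P = 24.0
        hr = sinusoid_hr(P, 30)
        model = cyc.extract_cycle_phase(hr, P)
        peaks = np.arange(3 * int(P * 60), hr.n - 3 * int(P * 60), int(P * 60))
        assert np.all(np.abs(np.angle(np.exp(1j * model.phase[peaks]))) < 0.05)

    def test_quarter_period_after_peak_is_half_pi(self):
        P = 24.0
        hr = sinusoid_hr(P, 30)
        model = cyc.extract_cycle_phase(hr, P)
        q = 10 * int(P * 60) + int(P * 15)       # quarter period past a peak
        assert model.phase[q] == pytest.approx(np.pi / 2, abs=0.05)

    def test_unwrapped_slope_is_two_pi_per_period(self):
        P = 24.0
        hr = sinusoid_hr(P, 40, noise=0.5, seed=4)
        model = cyc.extract_cycle_phase(hr, P)
        inner = slice(3 * int(P * 60), hr.n - 3 * int(P * 60))
        t = np.arange(hr.n, dtype=float)[inner]
        slope = np.polyfit(t, np.unwrap(model.phase[inner]), 1)[0]
        assert slope == pytest.approx(TWO_PI / (P * 60), rel=0.01)

    def test_filter_is_zero_lag(self):
        # time-flipped input yields the time-flipped phase up to sign
        P = 24.0
        hr = sinusoid_hr(P, 30, noise=1.0, seed=5)
        fwd = cyc.extract_cycle_phase(hr, P)
        rev = cyc.extract_cycle_phase(
            HeartRateSeries(hr.bpm[::-1].copy(), hr.missing_mask, 60), P)
        inner = slice(5 * int(P * 60), hr.n - 5 * int(P * 60))
        diff = np.angle(np.exp(1j * (fwd.phase + rev.phase[::-1])))[inner]
        assert np.abs(diff).mean() < 0.1

    def test_record_too_short_rejected(self):
        hr = sinusoid_hr(24.0, 10)
        with pytest.raises(ValueError, match="3 cycles"):
            cyc.extract_cycle_phase(hr, 168.0)


# ---------------------------------------------------------------------------
# gating and encoding
# ---------------------------------------------------------------------------

class TestGate:
    @staticmethod
    def _model(period_hours, days):
        hr = sinusoid_hr(period_hours, days)
        return cyc.extract_cycle_phase(hr, period_hours)

    def test_daily_horizon_drops_circadian(self):
        m24 = self._model(24.0, 30)
        # seizures all at the same circadian phase: strongly locked
        times = np.arange(10) * 1440.0 + 300.0
        hourly = cyc.select_significant_cycles([m24], times, "hourly")
        daily = cyc.select_significant_cycles([m24], times, "daily")
        assert [m.period_hours for m in hourly] == [24.0]
        assert daily == []
        assert m24.significant and m24.pvalue < 0.05

    def test_too_few_events_never_significant(self):
        m24 = self._model(24.0, 30)
        times = np.arange(4) * 1440.0 + 300.0
        assert cyc.select_significant_cycles([m24], times, "hourly") == []
        assert m24.pvalue is None

    def test_uniform_events_rarely_retained(self):
        # type-I of the gate: the exact test's size at n = 25 is ~0.048
        m24 = self._model(24.0, 40)
        rng = np.random.default_rng(0)
        kept = 0
        runs = 150
        for _ in range(runs):
            times = np.sort(rng.uniform(0, 39 * 1440.0, 25))
            kept += bool(cyc.select_significant_cycles([m24], times, "hourly"))
        assert kept / runs <= 0.10


class TestEncoding:
    def test_cardinal_points(self):
        enc = cyc.encode_cyclic([0.0], TWO_PI)
        assert enc[0] == pytest.approx([0.0, 1.0], abs=1e-12)
        enc = cyc.encode_cyclic([np.pi / 2], TWO_PI)
        assert enc[0] == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_periodicity_and_unit_norm(self):
        vals = np.linspace(0, 42, 17)
        a = cyc.encode_cyclic(vals, 7.0)
        b = cyc.encode_cyclic(vals + 7.0, 7.0)
        assert np.allclose(a, b)
        assert np.allclose((a ** 2).sum(axis=1), 1.0)

    def test_invalid_modulus(self):
        with pytest.raises(ValueError):
            cyc.encode_cyclic([1.0], 0.0)
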