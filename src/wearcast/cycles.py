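"""Circadian and multiday heart-rate cycles.

Periodicities of the 1-min heart-rate series are located with a complex
Morlet wavelet (time-averaged "global" wavelet spectrum on a logarithmic
period grid), screened against a lag-1 autoregressive red-noise background,
then each retained period is isolated with a zero-phase second-order
Butterworth band-pass (band edges at +/-33% of the period) and its
instantaneous phase taken from the analytic signal (Hilbert transform).

Phase convention: 0 at the cycle peak, increasing through the falling limb,
wrapped to [0, 2*pi).

A cycle becomes a forecasting feature only if training seizures are
significantly phase-locked to it — Hodges-Ajne omnibus test for circular
uniformity, p < 0.05, with at least five training events.  Cyclic quantities
enter linear models as (sin, cos) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, fftfreq, next_fast_len
from scipy.signal import butter, sosfiltfilt, hilbert, argrelmax
from scipy.special import comb

from .synthetic import HeartRateSeries, MIN_PER_DAY

TWO_PI = 2.0 * np.pi
BAND_FACTOR = 1.33            # band edges at period/1.33 .. period*1.33
MORLET_OMEGA0 = 6.0           # standard time-frequency trade-off
_MORLET_DECORR = 2.32         # decorrelation factor gamma (chi^2 dof)
# Fourier period of a Morlet wavelet at scale 1 (period = factor * scale)
_FOURIER_FACTOR = 4.0 * np.pi / (MORLET_OMEGA0 + np.sqrt(2 + MORLET_OMEGA0 ** 2))


@dataclass
class CycleSpectrum:
    periods_hours: np.ndarray
    power: np.ndarray            # time-averaged wavelet power per period
    background: np.ndarray       # 95th-percentile red-noise envelope
    ar1: float                   # fitted lag-1 autocorrelation of the series
    dt_hours: float
    n_samples: int


@dataclass
class CycleModel:
    """One detected periodicity of the heart-rate series."""

    period_hours: float
    band_edges_hours: tuple
    filtered: np.ndarray = field(repr=False)     # BPM on the 1-min grid
    phase: np.ndarray = field(repr=False)        # radians in [0, 2pi) per minute
    pvalue: float | None = None                  # phase-locking of training seizures
    significant: bool = False
    n_events: int = 0


def wavelet_periodogram(
    hr: HeartRateSeries,
    min_period_hours: float = 2.4,
    max_period_hours: float | None = None,
    periods_per_decade: int = 64,
    decimate_minutes: int = 10,
) -> CycleSpectrum:
    """Time-averaged Morlet wavelet power over a logarithmic period grid.

    The 1-min series is block-averaged to ``decimate_minutes`` (all periods
    of interest are hours to weeks, far above that Nyquist limit) before the
    transform.  The complex Morlet transform (omega0 = 6) is computed in the
    frequency domain with zero padding; at each scale the wavelet is
    spectrum-normalized so that a white-noise input yields unit expected
    power at every scale, which makes the AR(1) red-noise screen exact.
    Columns inside the cone of influence (within e-folding distance sqrt(2)
    times the scale of either record edge) or sitting on mostly-masked data
    are excluded from the time average; scales with no usable interior are
    dropped.  The longest candidate period is one third of the record.
    """
    if hr.step_seconds != 60:
        raise ValueError("wavelet_periodogram expects the 1-min resampled series")
    span_hours = hr.n / 60.0
    cap = span_hours / 3.0
    if max_period_hours is None:
        max_period_hours = cap
    max_period_hours = min(max_period_hours, cap)
    if max_period_hours <= min_period_hours:
        raise ValueError("record too short for the requested period range")

    d = decimate_minutes
    nb = hr.n // d
    x = hr.bpm[: nb * d].reshape(nb, d).mean(axis=1)
    frac_masked = hr.missing_mask[: nb * d].reshape(nb, d).mean(axis=1)
    keep = frac_masked < 0.5
    x = x - x[keep].mean()
    x[~keep] = 0.0
    dt = d / 60.0                                  # hours per sample
    variance = float(np.var(x[keep]))
    a = _lag1_autocorr(x[keep])

    n_grid = int(np.ceil(np.log10(max_period_hours / min_period_hours)
                         * periods_per_decade)) + 1
    periods = np.geomspace(min_period_hours, max_period_hours, n_grid)
    scales = periods / _FOURIER_FACTOR             # in hours

    npad = next_fast_len(2 * nb)
    omega = TWO_PI * fftfreq(npad, dt)
    xf = fft(x, npad)
    # AR(1) spectrum on the FFT grid, scaled to the series variance
    p_ar = (1 - a ** 2) / (1 + a ** 2 - 2 * a * np.cos(omega * dt))

    idx = np.arange(nb)
    power, backgr, kept_periods = [], [], []
    for s, per in zip(scales, periods):
        psi_hat = np.where(omega > 0,
                           np.exp(-0.5 * (s * omega - MORLET_OMEGA0) ** 2), 0.0)
        energy = float(np.sum(psi_hat ** 2))
        if energy == 0:
            continue
        w = ifft(xf * psi_hat)[:nb]
        coi = np.sqrt(2.0) * s / dt                # e-folding, in samples
        valid = keep & (idx >= coi) & (idx < nb - coi)
        if valid.sum() < max(8, 2 * per / dt):     # need ~2 interior periods
            continue
        # power in units of equivalent input variance: a white-noise input
        # has expectation == its variance at every scale (the npad/energy
        # factor undoes the zero-padded convolution's dilution)
        pw = float(np.mean(np.abs(w[valid]) ** 2)) * npad / energy
        null_mean = variance * float(np.sum(psi_hat ** 2 * p_ar)) / energy
        nu = 2.0 * np.sqrt(1.0 + (valid.sum() * dt / (_MORLET_DECORR * s)) ** 2)
        power.append(pw)
        backgr.append(null_mean * _chi2_factor(nu, periods))
        kept_periods.append(per)
    if not power:
        raise ValueError("record too short for the requested period range")
    return CycleSpectrum(np.asarray(kept_periods), np.asarray(power),
                         np.asarray(backgr), a, dt, int(keep.sum()))


def _chi2_factor(nu: float, periods: np.ndarray, alpha: float = 0.05) -> float:
    """Chi-square envelope factor with a Sidak family-wise correction.

    The screen tests every scale of the grid; adjacent scales are correlated
    over roughly one filter bandwidth, so the effective number of
    independent scales is log(Pmax/Pmin)/log(1.33).  The per-scale quantile
    is raised so the family-wise false-peak rate stays near ``alpha``.
    """
    from scipy.stats import chi2
    n_indep = max(1.0, np.log(periods[-1] / periods[0]) / np.log(BAND_FACTOR))
    a_scale = 1.0 - (1.0 - alpha) ** (1.0 / n_indep)
    return float(chi2.ppf(1.0 - a_scale, nu) / nu)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(x[:-1], x[1:]) / denom, 0.0, 0.999))


def detect_peak_periods(spectrum: CycleSpectrum) -> list:
    """Candidate cycle periods: significant spectral peaks plus circadian.

    Local maxima of the global spectrum exceeding the red-noise envelope,
    deduplicated so no two candidates lie within one filter bandwidth
    (period ratio < 1.33; the stronger peak wins).  The 24 h circadian
    period is always a candidate, whether or not it is a spectral peak.
    """
    p, w = spectrum.periods_hours, spectrum.power
    peaks = list(argrelmax(w, order=2)[0])
    peaks = [i for i in peaks if w[i] > spectrum.background[i]]
    peaks.sort(key=lambda i: -w[i])
    kept = []
    for i in peaks:
        per = _refine_peak(p, w, i)
        if all(max(per, q) / min(per, q) >= BAND_FACTOR for q in kept):
            kept.append(per)
    if not any(max(24.0, q) / min(24.0, q) < BAND_FACTOR for q in kept):
        kept.append(24.0)
    return sorted(kept)


def _refine_peak(periods, power, i: int) -> float:
    """Sub-grid peak location by a parabola through the three bins in log-period."""
    if i == 0 or i == periods.size - 1:
        return float(periods[i])
    y0, y1, y2 = power[i - 1], power[i], power[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(periods[i])
    shift = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
    logp = np.log(periods)
    return float(np.exp(logp[i] + shift * (logp[i + 1] - logp[i])))


def extract_cycle_phase(hr: HeartRateSeries, period_hours: float) -> CycleModel:
    """Band-pass the series around one period and take the analytic phase.

    Zero-phase (forward-backward) second-order Butterworth band-pass at
    [period/1.33, period*1.33], then the Hilbert transform; the phase of the
    analytic signal is 0 at each filtered-cycle peak.  If the filter is
    numerically unstable at the requested band it is widened once.
    """
    if hr.step_seconds != 60:
        raise ValueError("extract_cycle_phase expects the 1-min resampled series")
    if hr.n < 3 * period_hours * 60:
        raise ValueError("record must span at least 3 cycles of the requested period")
    x = hr.bpm - float(hr.bpm.mean())
    for widen in (1.0, 1.6):
        lo = 1.0 / (period_hours * 60.0 * BAND_FACTOR * widen)
        hi = BAND_FACTOR * widen / (period_hours * 60.0)
        sos = butter(2, [2 * lo, 2 * hi], btype="bandpass", output="sos")
        filt = sosfiltfilt(sos, x)
        if np.all(np.isfinite(filt)):
            break
    else:
        raise RuntimeError(f"band-pass unstable at period {period_hours} h")
    nfft = next_fast_len(filt.size)
    analytic = hilbert(filt, N=nfft)[: filt.size]
    phase = np.angle(analytic) % TWO_PI
    return CycleModel(
        period_hours, (period_hours / BAND_FACTOR, period_hours * BAND_FACTOR),
        filt, phase)


def phase_at(model: CycleModel, times_min) -> np.ndarray:
    """Phase of a cycle at arbitrary in-record minutes (nearest grid sample)."""
    idx = np.clip(np.round(np.asarray(times_min, float)).astype(int), 0, model.phase.size - 1)
    return model.phase[idx]


def extrapolate_phase(model: CycleModel, times_min) -> np.ndarray:
    """Project a cycle's phase beyond the end of its record.

    Used when forecasting ahead of the data the filter saw: a line is fitted
    to the unwrapped phase over the final stretch of the record (up to ten
    periods, excluding the last half period where the Hilbert edge artifact
    concentrates) and evaluated at the requested times.  The fitted slope
    absorbs small errors in the detected period; fitting over many periods
    damps local phase wander.  Keeps forecast features causal.
    """
    n = model.phase.size
    period_min = model.period_hours * 60.0
    a = int(max(0, n - 10 * period_min))
    b = int(max(a + 60, n - 0.5 * period_min))
    t_tail = np.arange(a, min(b, n), dtype=float)
    unwrapped = np.unwrap(model.phase[a:min(b, n)])
    if t_tail.size >= 2:
        slope, intercept = np.polyfit(t_tail, unwrapped, 1)
    else:
        slope = TWO_PI / period_min
        intercept = float(np.mean(unwrapped - slope * t_tail))
    t = np.asarray(times_min, dtype=float)
    return (slope * t + intercept) % TWO_PI


# ---------------------------------------------------------------------------
# circular uniformity: Hodges-Ajne omnibus test
# ---------------------------------------------------------------------------

def hodges_ajne_test(phases) -> tuple:
    """Hodges-Ajne (omnibus) test statistic and p-value.

    ``m`` is the minimum number of points contained in any half-circle,
    found by sweeping half-circle boundaries anchored just past each data
    point and each antipode.  The p-value uses the exact Hodges (1955)
    formula ``p = (n - 2m) * C(n, m) / 2^(n-1)`` for n <= 50 and the
    normal-theory approximation for larger n; both are clipped to [0, 1].
    """
    theta = np.sort(np.asarray(phases, dtype=float) % TWO_PI)
    n = theta.size
    if n < 5:
        raise ValueError("Hodges-Ajne test requires at least 5 phases")
    m = hodges_ajne_statistic(theta)
    return m, hodges_ajne_pvalue(m, n)


def hodges_ajne_statistic(theta_sorted: np.ndarray) -> int:
    """Minimum count over all half-circles [t, t+pi), boundaries swept past
    every data point and antipode."""
    n = theta_sorted.size
    eps = 1e-9
    anchors = np.concatenate([theta_sorted + eps, (theta_sorted - np.pi) + eps]) % TWO_PI
    # count points with (theta - t) mod 2pi < pi via a doubled sorted array
    doubled = np.concatenate([theta_sorted, theta_sorted + TWO_PI])
    lo = np.searchsorted(doubled, anchors, side="left")
    hi = np.searchsorted(doubled, anchors + np.pi, side="left")
    return int(np.min(hi - lo))


def hodges_ajne_pvalue(m: int, n: int) -> float:
    if n - 2 * m <= 0:
        return 1.0
    if n <= 50:
        p = (n - 2 * m) * comb(n, m, exact=True) / 2 ** (n - 1)
    else:
        A = np.pi * np.sqrt(n) / (2.0 * (n - 2 * m))
        p = np.sqrt(TWO_PI) / A * np.exp(-np.pi ** 2 / (8.0 * A ** 2))
    return float(min(max(p, 0.0), 1.0))


def select_significant_cycles(cycles, seizure_times_min, horizon: str,
                              alpha: float = 0.05, min_events: int = 5) -> list:
    """Gate cycles on seizure phase-locking; the daily horizon keeps multiday only.

    Phases are evaluated at *training* seizure times.  A cycle is retained
    when at least ``min_events`` training seizures fall in its record and the
    Hodges-Ajne p-value is below ``alpha``.  For the daily forecast the
    circadian class (periods below 36 h) is dropped even when significant.
    """
    if horizon not in ("hourly", "daily"):
        raise ValueError("horizon must be 'hourly' or 'daily'")
    times = np.asarray(seizure_times_min, dtype=float)
    retained = []
    for c in cycles:
        in_span = times[(times >= 0) & (times < c.phase.size)]
        c.n_events = in_span.size
        if in_span.size >= min_events:
            _, c.pvalue = hodges_ajne_test(phase_at(c, in_span))
            c.significant = c.pvalue < alpha
        else:
            c.pvalue, c.significant = None, False
        if not c.significant:
            continue
        if horizon == "daily" and c.period_hours < 36.0:
            continue
        retained.append(c)
    return retained


def encode_cyclic(values, modulus: float) -> np.ndarray:
    """Map a cyclic quantity to a (sin, cos) pair.

    theta = 2*pi * (value mod modulus) / modulus; returns an (n, 2) array of
    (sin theta, cos theta).  Used for cycle phases (modulus 2*pi) and for
    elapsed time since the last / second-last seizure (modulus = a retained
    cycle's period).
    """
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    theta = TWO_PI * (np.asarray(values, dtype=float) % modulus) / modulus
    return np.column_stack([np.sin(theta), np.cos(theta)])
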