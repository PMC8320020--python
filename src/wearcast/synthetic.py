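"""Synthetic wearable cohorts with known cycles and phase-locked seizures.

Real long-term wearable cohorts (smartwatch heart rate, sleep staging, step
counts, self-reported seizure diaries) are rarely shareable, so every stage of
the forecasting pipeline in this package is exercised against cohorts generated
here.  The generator produces, per participant:

* a photoplethysmography-like heart-rate stream at 5 s resolution composed of a
  baseline, a circadian (24 h) sinusoid, one or more multiday sinusoids, an
  AR(1) noise process and a smooth nocturnal dip during main sleep;
* per-minute step counts with a diurnal activity envelope, near-zero during
  sleep;
* nightly main-sleep intervals partitioned into contiguous runs of sleep
  stages (wake / REM / light / deep), with optional naps;
* a seizure diary drawn from an inhomogeneous Poisson process whose intensity
  is modulated by von Mises densities of the true cycle phases, so events are
  phase-locked to chosen cycles with configurable concentration;
* contiguous missing-data gaps in the heart-rate stream (device off-wrist).

Ground truth (true cycle phases and per-event phases) is retained so that the
cycle-detection and forecasting modules can be validated quantitatively.
Generation is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

T0 = pd.Timestamp("2020-01-06 00:00:00")  # cohort epoch (a Monday)

SAMPLES_PER_MIN = 12  # heart rate is sampled every 5 s
MIN_PER_DAY = 1440

STAGES = ("wake", "rem", "light", "deep")


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of one synthetic cohort.

    Cycle-indexed tuples (``locking_kappa``, ``preferred_phases``) align with
    ``cycle_periods_hours``: the circadian (24 h) cycle first, then each entry
    of ``multiday_periods`` in order.
    """

    n_participants: int = 1
    duration_days: float = 365.0
    hr_baseline: float = 70.0            # BPM
    circadian_amplitude: float = 5.0     # BPM
    multiday_periods: tuple = (7.0,)     # days, each > 1
    multiday_amplitudes: tuple = (3.0,)  # BPM
    noise_sd: float = 3.0                # BPM, stationary sd of AR(1) noise
    noise_autocorr: float = 0.9          # lag-1 autocorrelation at 1 min
    seizure_rate: float = 4.0 / 30.0     # events/day (~4 per month)
    locking_kappa: tuple = (0.0, 2.0)    # von Mises concentration per cycle
    preferred_phases: tuple = (0.0, 0.0)  # radians per cycle
    missing_fraction: float = 0.05
    missing_gap_hours_mean: float = 2.0
    missing_gap_hours_max: float = 12.0
    sleep_onset_mean: float = 23.0 * 60  # clock minutes
    sleep_onset_sd: float = 30.0
    sleep_duration_mean: float = 480.0   # minutes
    sleep_duration_sd: float = 45.0
    nocturnal_dip: float = 8.0           # BPM depression during main sleep
    nap_probability: float = 0.0
    diary_jitter_minutes: float = 0.0    # reporting noise, off by default
    seed: int = 0

    @property
    def cycle_periods_hours(self) -> tuple:
        return (24.0,) + tuple(24.0 * p for p in self.multiday_periods)

    @property
    def cycle_amplitudes(self) -> tuple:
        return (self.circadian_amplitude,) + tuple(self.multiday_amplitudes)

    def validate(self) -> None:
        n_cycles = 1 + len(self.multiday_periods)
        if len(self.multiday_amplitudes) != len(self.multiday_periods):
            raise ValueError("multiday_amplitudes must match multiday_periods")
        if len(self.locking_kappa) != n_cycles or len(self.preferred_phases) != n_cycles:
            raise ValueError(
                "locking_kappa and preferred_phases must have one entry per "
                "cycle (circadian first, then each multiday period)"
            )
        if any(a < 0 for a in self.cycle_amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if any(p <= 1.0 for p in self.multiday_periods):
            raise ValueError("multiday periods must exceed 1 day")
        if any(k < 0 for k in self.locking_kappa):
            raise ValueError("locking_kappa must be non-negative")
        if self.noise_sd < 0 or self.seizure_rate < 0:
            raise ValueError("noise_sd and seizure_rate must be non-negative")
        if not (0.0 <= self.noise_autocorr < 1.0):
            raise ValueError("noise_autocorr must lie in [0, 1)")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.sleep_duration_sd < 0 or self.sleep_onset_sd < 0:
            raise ValueError("sleep sd parameters must be non-negative")


@dataclass
class GroundTruth:
    """True cycle phases and seizure phases of one synthetic participant.

    Phases follow the package convention: phase 0 at the cycle peak.  The
    per-cycle phase series is an exact function of time,
    ``phi(t) = (2*pi*t/P + offset) mod 2*pi``, so it is stored as
    (period, offset) pairs and evaluated on demand at any sample.
    """

    cycle_periods_hours: tuple
    cycle_offsets: tuple                 # radians at t = 0
    duration_days: float
    seizure_times_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    seizure_phases: dict = field(default_factory=dict)  # period_hours -> radians

    def phase(self, period_hours: float, times_min) -> np.ndarray:
        """True phase of the given cycle at times (minutes since epoch)."""
        i = self.cycle_periods_hours.index(period_hours)
        t = np.asarray(times_min, dtype=float)
        return (2.0 * np.pi * t / (period_hours * 60.0) + self.cycle_offsets[i]) % (2 * np.pi)


@dataclass
class HeartRateSeries:
    """Uniformly gridded BPM stream with an explicit missing-data mask."""

    bpm: np.ndarray
    missing_mask: np.ndarray     # True where the device recorded nothing
    step_seconds: int            # 5 for raw, 60 after resampling
    start: pd.Timestamp = T0

    def __post_init__(self):
        self.bpm = np.asarray(self.bpm, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.bpm.shape != self.missing_mask.shape:
            raise ValueError("bpm and missing_mask must have equal length")

    @property
    def n(self) -> int:
        return self.bpm.size

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n) * (self.step_seconds / 60.0)


@dataclass
class StepSeries:
    steps: np.ndarray            # integer steps per minute
    start: pd.Timestamp = T0

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.steps.size, dtype=float)


@dataclass
class SleepNight:
    """One sleep interval: contiguous per-minute stage runs covering it."""

    onset_min: int               # absolute minute index of sleep onset
    wake_min: int                # absolute minute index of waking (exclusive)
    stages: np.ndarray           # one stage label per minute, len = wake-onset
    is_main_sleep: bool = True

    @property
    def duration_min(self) -> int:
        return self.wake_min - self.onset_min

    def stage_minutes(self, stage: str) -> int:
        return int(np.sum(self.stages == stage))


@dataclass
class SeizureDiary:
    times_min: np.ndarray        # minutes since epoch, sorted
    types: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.times_min.size


@dataclass
class Participant:
    """Bundle of all streams for one synthetic participant."""

    hr: HeartRateSeries
    steps: StepSeries
    nights: list
    diary: SeizureDiary
    truth: GroundTruth
    config: SyntheticCohortConfig
    index: int = 0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _participant_rng(config: SyntheticCohortConfig, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    return np.random.Generator(np.random.PCG64(ss.spawn(config.n_participants)[index]))


def generate_activity_sleep(config: SyntheticCohortConfig, rng=None):
    """Generate per-minute step counts and nightly main-sleep intervals.

    Sleep onset and duration are Gaussian around the configured clock time;
    each night is partitioned into contiguous stage runs emulating ~90 min
    sleep cycles (light -> deep -> light -> REM with brief awakenings).  Steps
    follow a diurnal Poisson envelope, zero during sleep, with sedentary
    (zero-step) minutes in the daytime so a resting heart rate is computable.
    """
    config.validate()
    if rng is None:
        rng = _participant_rng(config, 0)
    n_days = int(np.floor(config.duration_days))
    n_min = int(round(config.duration_days * MIN_PER_DAY))

    nights = []
    for day in range(n_days):
        onset = day * MIN_PER_DAY + config.sleep_onset_mean
        if config.sleep_onset_sd > 0:
            onset += rng.normal(0.0, config.sleep_onset_sd)
        dur = config.sleep_duration_mean
        if config.sleep_duration_sd > 0:
            dur += rng.normal(0.0, config.sleep_duration_sd)
        onset = int(round(onset))
        dur = int(round(max(120.0, dur)))
        wake = min(onset + dur, n_min)
        if wake - onset < 120 or onset >= n_min:
            continue
        nights.append(SleepNight(onset, wake, _stage_runs(wake - onset, rng)))

    # optional short afternoon naps
    if config.nap_probability > 0:
        for day in range(n_days):
            if rng.random() < config.nap_probability:
                start = day * MIN_PER_DAY + int(rng.uniform(13 * 60, 16 * 60))
                dur = int(rng.uniform(20, 60))
                end = min(start + dur, n_min)
                if end - start >= 10 and not _overlaps_any(start, end, nights):
                    stages = np.full(end - start, "light", dtype=object)
                    nights.append(SleepNight(start, end, stages, is_main_sleep=False))
    nights.sort(key=lambda nt: nt.onset_min)

    steps = _step_counts(config, nights, n_min, rng)
    return StepSeries(steps), nights


def _overlaps_any(start, end, nights):
    return any(start < nt.wake_min and end > nt.onset_min for nt in nights)


def _stage_runs(duration: int, rng) -> np.ndarray:
    """Partition a night into stage runs; run minutes sum exactly to duration."""
    stages = []
    remaining = duration
    pattern = (("light", 25.0), ("deep", 18.0), ("light", 14.0), ("rem", 13.0))
    while remaining > 0:
        for stage, mean in pattern:
            if remaining <= 0:
                break
            run = int(round(rng.gamma(4.0, mean / 4.0))) if mean > 0 else 0
            run = max(1, min(run, remaining))
            stages.extend([stage] * run)
            remaining -= run
            # brief awakening between sleep cycles
            if stage == "rem" and remaining > 0 and rng.random() < 0.4:
                w = min(int(rng.integers(1, 4)), remaining)
                stages.extend(["wake"] * w)
                remaining -= w
    return np.asarray(stages, dtype=object)


def _step_counts(config, nights, n_min, rng) -> np.ndarray:
    minute_of_day = np.arange(n_min) % MIN_PER_DAY
    # diurnal envelope peaking mid-afternoon, active window ~07:00-23:00
    env = np.clip(np.sin(np.pi * (minute_of_day - 7 * 60) / (16 * 60.0)), 0.0, None)
    lam = 14.0 * (0.25 + 0.75 * env)
    asleep = np.zeros(n_min, dtype=bool)
    for nt in nights:
        asleep[nt.onset_min:nt.wake_min] = True
    active = rng.random(n_min) < 0.45      # sedentary zero-inflation
    steps = rng.poisson(lam)
    steps[~active] = 0
    steps[asleep] = 0
    return steps.astype(np.int64)


def generate_heart_rate(config: SyntheticCohortConfig, nights=None, rng=None):
    """Generate the 5 s heart-rate stream and its ground truth.

    BPM(t) = baseline + sum of cycle sinusoids + AR(1) noise + nocturnal dip.
    Each sinusoid is ``A*cos(phase)`` with phase 0 at its peak; per-cycle phase
    offsets are drawn uniformly (each participant sits at a random point of
    every cycle when recording starts) and recorded in the ground truth.
    The AR(1) noise is generated on the 1-min grid (wearable-derived heart
    rate is strongly autocorrelated) and linearly interpolated to 5 s.
    """
    config.validate()
    if config.duration_days < 2:
        raise ValueError("duration must be at least 2 days to host a circadian cycle")
    if rng is None:
        rng = _participant_rng(config, 0)

    n_min = int(round(config.duration_days * MIN_PER_DAY))
    n5 = n_min * SAMPLES_PER_MIN
    t5_min = np.arange(n5) * (5.0 / 60.0)

    offsets = tuple(rng.uniform(0.0, 2 * np.pi) for _ in config.cycle_periods_hours)
    truth = GroundTruth(config.cycle_periods_hours, offsets, config.duration_days)

    bpm = np.full(n5, config.hr_baseline, dtype=float)
    for period_h, amp in zip(config.cycle_periods_hours, config.cycle_amplitudes):
        if amp > 0:
            bpm += amp * np.cos(truth.phase(period_h, t5_min))

    if config.noise_sd > 0:
        a = config.noise_autocorr
        eps = rng.normal(0.0, config.noise_sd * np.sqrt(1.0 - a * a), n_min)
        x0 = rng.normal(0.0, config.noise_sd)
        from scipy.signal import lfilter
        noise, _ = lfilter([1.0], [1.0, -a], eps, zi=np.array([a * x0]))
        bpm += np.interp(t5_min, np.arange(n_min, dtype=float), noise)

    if config.nocturnal_dip > 0 and nights:
        dip = _dip_profile(nights, n_min) * config.nocturnal_dip
        bpm -= np.interp(t5_min, np.arange(n_min, dtype=float), dip)

    hr = HeartRateSeries(bpm, np.zeros(n5, dtype=bool), step_seconds=5)
    return hr, truth


def _dip_profile(nights, n_min, ramp: int = 30) -> np.ndarray:
    """Unit-depth depression during main sleep with raised-cosine ramps."""
    prof = np.zeros(n_min)
    for nt in nights:
        if not nt.is_main_sleep:
            continue
        a, b = nt.onset_min, nt.wake_min
        prof[a:b] = 1.0
        r = min(ramp, (b - a) // 2)
        if r > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
            prof[a:a + r] = np.minimum(prof[a:a + r], edge)
            prof[b - r:b] = np.minimum(prof[b - r:b], edge[::-1])
    return prof


def generate_seizures(config: SyntheticCohortConfig, truth: GroundTruth, rng=None) -> SeizureDiary:
    """Draw seizure events phase-locked to the configured cycles.

    Events follow a discretized (1-min bins) inhomogeneous Poisson process
    with intensity ``base_rate * prod_c 2*pi*f_vM(phi_c(t); kappa_c, mu_c)``.
    Each von Mises factor averages to one over a full cycle, so the realized
    mean rate matches ``seizure_rate``; ``kappa = 0`` factors are flat and
    leave event times uniform.
    """
    config.validate()
    if rng is None:
        rng = _participant_rng(config, 0)
    n_min = int(round(truth.duration_days * MIN_PER_DAY))
    if config.seizure_rate <= 0:
        return SeizureDiary(np.empty(0), [])

    t = np.arange(n_min, dtype=float) + 0.5
    log_mod = np.zeros(n_min)
    from scipy.special import i0
    for period_h, kappa, mu in zip(
        truth.cycle_periods_hours, config.locking_kappa, config.preferred_phases
    ):
        if kappa > 0:
            phi = truth.phase(period_h, t)
            # 2*pi * vonmises.pdf = exp(kappa*cos(phi-mu)) / I0(kappa)
            log_mod += kappa * np.cos(phi - mu) - np.log(i0(kappa))
    p = (config.seizure_rate / MIN_PER_DAY) * np.exp(log_mod)
    if np.any(p > 1.0):
        warnings.warn("per-minute event probability clipped at 1; rate too high "
                      "for the requested locking concentration")
        p = np.clip(p, 0.0, 1.0)
    hits = rng.random(n_min) < p
    times = t[hits]

    phases = {ph: truth.phase(ph, times) for ph in truth.cycle_periods_hours}
    if config.diary_jitter_minutes > 0:
        times = times + rng.uniform(
            -config.diary_jitter_minutes, config.diary_jitter_minutes, times.size
        )
        times = np.sort(np.clip(times, 0.0, n_min - 1e-6))
    truth.seizure_times_min = times
    truth.seizure_phases = phases
    return SeizureDiary(times, ["unclassified"] * times.size)


def inject_missingness(hr: HeartRateSeries, config: SyntheticCohortConfig, rng=None) -> HeartRateSeries:
    """Mask contiguous off-wrist gaps until the target missing fraction.

    Gap lengths are exponential with mean ``missing_gap_hours_mean``, truncated
    to [5 min, ``missing_gap_hours_max``]; starts are uniform.  Values under
    the mask are set to NaN (absent, not zero).  A missing fraction of 0.2 or
    more is allowed but warned about: it breaches the 80% adherence floor the
    eligibility filter enforces.
    """
    config.validate()
    if hr.missing_mask.any():
        raise ValueError("input series already has missing samples")
    if config.missing_fraction >= 0.2:
        warnings.warn("missing_fraction >= 0.2 violates the 80% adherence floor")
    if rng is None:
        rng = _participant_rng(config, 0)
    if config.missing_fraction == 0:
        return hr

    n = hr.n
    per_hour = int(3600 / hr.step_seconds)
    lo = max(1, per_hour // 12)                      # >= 5 min
    hi = max(lo + 1, int(config.missing_gap_hours_max * per_hour))
    mask = np.zeros(n, dtype=bool)
    target = int(config.missing_fraction * n)
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        length = int(rng.exponential(config.missing_gap_hours_mean * per_hour))
        length = min(max(length, lo), hi, target)  # never a single over-long gap
        start = int(rng.integers(0, max(1, n - length)))
        mask[start:start + length] = True
    bpm = hr.bpm.copy()
    bpm[mask] = np.nan
    return HeartRateSeries(bpm, mask, hr.step_seconds, hr.start)


def generate_participant(config: SyntheticCohortConfig, index: int = 0) -> Participant:
    """Generate all streams for one participant, deterministically from (config, seed, index)."""
    rng = _participant_rng(config, index)
    steps, nights = generate_activity_sleep(config, rng)
    hr, truth = generate_heart_rate(config, nights, rng)
    diary = generate_seizures(config, truth, rng)
    hr = inject_missingness(hr, config, rng)
    return Participant(hr, steps, nights, diary, truth, config, index)


def generate_cohort(config: SyntheticCohortConfig) -> list:
    config.validate()
    return [generate_participant(config, i) for i in range(config.n_participants)]


# ---------------------------------------------------------------------------
# on-disk cohort layout (plain CSV/JSON, one directory per participant)
# ---------------------------------------------------------------------------

def write_participant(path, p: Participant) -> None:
    """Write heart_rate.csv, steps.csv, sleep.csv, seizures.csv, truth.json, config.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t0 = p.hr.start

    idx = t0 + pd.to_timedelta(np.arange(p.hr.n) * p.hr.step_seconds, unit="s")
    pd.DataFrame({"timestamp": idx, "bpm": p.hr.bpm}).to_csv(
        path / "heart_rate.csv", index=False)

    sidx = t0 + pd.to_timedelta(np.arange(p.steps.steps.size), unit="min")
    pd.DataFrame({"timestamp": sidx, "steps": p.steps.steps}).to_csv(
        path / "steps.csv", index=False)

    rows = []
    for nt in p.nights:
        ts = t0 + pd.to_timedelta(np.arange(nt.onset_min, nt.wake_min), unit="min")
        rows.append(pd.DataFrame({
            "timestamp": ts, "stage": nt.stages,
            "is_main_sleep": nt.is_main_sleep}))
    (pd.concat(rows) if rows else
     pd.DataFrame(columns=["timestamp", "stage", "is_main_sleep"])
     ).to_csv(path / "sleep.csv", index=False)

    sz = t0 + pd.to_timedelta(p.diary.times_min, unit="min")
    pd.DataFrame({"timestamp": sz, "type": p.diary.types}).to_csv(
        path / "seizures.csv", index=False)

    truth = {
        "cycle_periods_hours": list(p.truth.cycle_periods_hours),
        "cycle_offsets": list(p.truth.cycle_offsets),
        "duration_days": p.truth.duration_days,
        "seizure_times_min": p.truth.seizure_times_min.tolist(),
        "seizure_phases": {str(k): v.tolist() for k, v in p.truth.seizure_phases.items()},
    }
    (path / "truth.json").write_text(json.dumps(truth))
    (path / "config.json").write_text(json.dumps(asdict(p.config)))


def read_participant(path) -> Participant:
    """Read a participant directory written by :func:`write_participant`."""
    path = Path(path)
    cfg = SyntheticCohortConfig(**{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in json.loads((path / "config.json").read_text()).items()
    })
    hr_df = pd.read_csv(path / "heart_rate.csv", parse_dates=["timestamp"])
    bpm = hr_df["bpm"].to_numpy()
    hr = HeartRateSeries(bpm, np.isnan(bpm), step_seconds=5,
                         start=hr_df["timestamp"].iloc[0])
    steps = StepSeries(pd.read_csv(path / "steps.csv")["steps"].to_numpy(np.int64), hr.start)

    sleep_df = pd.read_csv(path / "sleep.csv", parse_dates=["timestamp"])
    nights = []
    if len(sleep_df):
        mins = ((sleep_df["timestamp"] - hr.start).dt.total_seconds() / 60).round().astype(int)
        brk = np.where((np.diff(mins) != 1)
                       | (sleep_df["is_main_sleep"].to_numpy()[:-1]
                          != sleep_df["is_main_sleep"].to_numpy()[1:]))[0] + 1
        for seg in np.split(np.arange(len(sleep_df)), brk):
            nights.append(SleepNight(
                int(mins.iloc[seg[0]]), int(mins.iloc[seg[-1]]) + 1,
                sleep_df["stage"].to_numpy(object)[seg],
                bool(sleep_df["is_main_sleep"].iloc[seg[0]])))
    sz_df = pd.read_csv(path / "seizures.csv", parse_dates=["timestamp"])
    diary = SeizureDiary(
        ((sz_df["timestamp"] - hr.start).dt.total_seconds() / 60).to_numpy(),
        sz_df["type"].tolist())

    tr = json.loads((path / "truth.json").read_text())
    truth = GroundTruth(
        tuple(tr["cycle_periods_hours"]), tuple(tr["cycle_offsets"]),
        tr["duration_days"], np.asarray(tr["seizure_times_min"]),
        {float(k): np.asarray(v) for k, v in tr["seizure_phases"].items()})
    return Participant(hr, steps, nights, diary, truth, cfg)
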