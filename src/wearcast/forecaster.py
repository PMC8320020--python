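"""Stacked ensemble seizure-likelihood forecaster with walk-forward retraining.

Architecture (per forecast horizon, hourly or daily):

* an LSTM over the previous seven nights of sleep features (7 x 7 history
  per forecast) emits a daily seizure likelihood;
* a bootstrap-aggregated random-forest regressor (1000 trees, minimum 120
  samples per leaf) consumes all other features — retained heart-rate cycle
  phases and elapsed-seizure encodings, RCH, daily resting heart rate, step
  counts — plus the LSTM output, after 1:1 oversampling of seizure steps;
* a logistic-regression stacker combines the two base outputs into the final
  likelihood, trained on out-of-fold base predictions (contiguous temporal
  folds) with the steps adjacent to each seizure removed.

Training is walk-forward: the initial fit uses data up to the participant's
training cut-off (two months and 15 seizures); thereafter the models, the
cycle set and the risk thresholds are refit on all accumulated data at a
weekly cadence, and each 7-day block is forecast by models that never saw
it.  Every feature value at step ``t`` is a function of data strictly
before ``t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from . import cycles as cyc
from . import preprocess as pp
from .nn import SleepLSTM
from .risk import ThresholdPair, classify_risk, optimize_thresholds
from .synthetic import HeartRateSeries, Participant, MIN_PER_DAY

SLEEP_HISTORY_DAYS = 7
N_SLEEP_FEATURES = 7
DEVIATION_FEATURES = (5, 6)     # indices of onset/wake deviations in the tensor


@dataclass(frozen=True)
class ForecastConfig:
    """Hyperparameters; the defaults are the full-scale deployment values."""

    n_trees: int = 1000
    n_trees_oof: int | None = None       # forest size for fold models (None: n_trees)
    min_samples_leaf: int = 120
    lstm_units: int = 64
    lstm_dense_units: int = 32
    lstm_epochs: int = 100
    lstm_batch_size: int = 32
    lstm_lr: float = 1e-3
    n_folds: int = 10
    retrain_days: float = 7.0
    rolling_window_days: float | None = None    # None: keep all past data
    min_training_seizures: int = 15
    min_training_days: float = 60.0
    periods_per_decade: int = 64
    decimate_minutes: int = 10
    max_period_hours: float | None = None
    rf_max_samples: float | None = None


def load_config(path) -> ForecastConfig:
    """Read a ForecastConfig from a plain key-value text file.

    One ``key = value`` pair per line; ``#`` starts a comment; unknown keys
    are rejected.  Values are coerced to the field's type; ``none`` clears
    an optional field.
    """
    import dataclasses
    from pathlib import Path

    fields = {f.name: f for f in dataclasses.fields(ForecastConfig)}
    kwargs = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"unknown config key: {key!r}")
        if value.lower() == "none":
            kwargs[key] = None
        elif key in ("n_trees", "n_trees_oof", "min_samples_leaf", "lstm_units",
                     "lstm_dense_units", "lstm_epochs", "lstm_batch_size",
                     "n_folds", "min_training_seizures", "periods_per_decade",
                     "decimate_minutes"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return ForecastConfig(**kwargs)


def scaled_config() -> ForecastConfig:
    """A reduced-scale profile for desk-size benchmark runs.

    Smaller forest (200 trees on 12% bootstrap draws; 40-tree fold models
    for the out-of-fold stacker inputs), 5 stacking folds, a shorter
    full-batch LSTM schedule, six-weekly retraining and a coarser
    periodogram grid capped at 400 h.  The scientific procedure is
    unchanged; only problem sizes shrink.
    """
    return ForecastConfig(
        n_trees=200, n_trees_oof=40, rf_max_samples=0.12, n_folds=5,
        lstm_epochs=12, lstm_batch_size=256, lstm_lr=5e-3, retrain_days=42.0,
        periods_per_decade=24, decimate_minutes=20, max_period_hours=400.0)


@dataclass
class ForecastTrace:
    """Concatenated out-of-training forecasts over the testing span."""

    horizon: str
    times_min: np.ndarray
    durations_min: np.ndarray
    likelihood: np.ndarray
    tier: np.ndarray
    theta_med: np.ndarray
    theta_high: np.ndarray
    epoch: np.ndarray
    labels: np.ndarray
    seizure_times_min: np.ndarray
    feature_groups_used: set = field(default_factory=set)
    threshold_reports: list = field(default_factory=list)
    retained_cycles: list = field(default_factory=list)   # per epoch: periods


# ---------------------------------------------------------------------------
# per-participant preparation (causal features, grids, cached cycle states)
# ---------------------------------------------------------------------------

class PreparedParticipant:
    """Causal feature primitives of one participant, shared across runs.

    All precomputed quantities are causal (each value depends only on
    strictly earlier data), so they can be computed once on the full record;
    cycle detection, which must only see data up to each retraining date, is
    redone per epoch and memoized on the cut-off minute.
    """

    def __init__(self, participant: Participant, config: ForecastConfig | None = None):
        self.participant = participant
        self.config = config or ForecastConfig()
        self.hr1 = pp.resample_heart_rate(participant.hr, causal=True)
        self.diary_min = np.sort(participant.diary.times_min)
        self.rch_hourly = pp.compute_rch(self.hr1, "hourly")
        self.rch_daily = pp.compute_rch(self.hr1, "daily")
        self.rhr = pp.compute_daily_rhr(self.hr1, participant.steps)
        self.sleep_df = pp.compute_sleep_features(participant.nights, self.hr1)
        self.wake_times = self.sleep_df.index.to_numpy(dtype=float)
        self.tensors = self._sleep_history_tensors()
        self._cycle_cache: dict = {}
        self._grids: dict = {}

    # -- sleep history ------------------------------------------------------

    def _sleep_history_tensors(self) -> np.ndarray:
        """One (7, 7) history per wake: the seven calendar days before it.

        Absent nights are forward-filled from the most recent earlier night
        with their deviation features zeroed (the deviation of a night that
        did not happen is not meaningful); days before any recorded night
        reuse the first night the same way.
        """
        feats = self.sleep_df[list(pp.SLEEP_FEATURES)].to_numpy(dtype=float)
        # forward-fill NaNs (e.g. fully masked overnight HR) from prior nights
        for j in range(feats.shape[1]):
            col = feats[:, j]
            nan = np.isnan(col)
            if nan.all():
                col[:] = 0.0
            elif nan.any():
                idx = np.where(~nan, np.arange(col.size), -1)
                np.maximum.accumulate(idx, out=idx)
                first = col[~nan][0]
                col[:] = np.where(idx >= 0, col[np.clip(idx, 0, None)], first)
        wake_day = (self.wake_times // MIN_PER_DAY).astype(int)
        by_day = {}
        out = np.zeros((len(self.wake_times), SLEEP_HISTORY_DAYS, N_SLEEP_FEATURES))
        for i, wd in enumerate(wake_day):
            for k, dd in enumerate(range(wd - SLEEP_HISTORY_DAYS, wd)):
                row = by_day.get(dd)
                if row is None:
                    # most recent earlier night, deviations zeroed
                    earlier = [d for d in by_day if d < dd]
                    src = by_day[max(earlier)] if earlier else feats[0]
                    row = src.copy()
                    row[list(DEVIATION_FEATURES)] = 0.0
                out[i, k] = row
            by_day[wd] = feats[i]
        return out

    # -- forecast grids ------------------------------------------------------

    def grid(self, horizon: str):
        """(times, durations, labels, day_index) for one horizon.

        Hourly steps start at each hour from the second recording day; daily
        steps are issued at each wake and span to the next wake.  The label
        of a step is 1 when at least one diary seizure falls in its window.
        ``day_index`` maps each step to the sleep-history row whose LSTM
        output applies (the latest wake at or before the step).
        """
        if horizon in self._grids:
            return self._grids[horizon]
        n_min = self.hr1.n
        if horizon == "hourly":
            times = np.arange(MIN_PER_DAY, (n_min // 60) * 60 - 59, 60, dtype=float)
            durations = np.full(times.size, 60.0)
        elif horizon == "daily":
            times = self.wake_times.copy()
            nxt = np.append(times[1:], min(times[-1] + MIN_PER_DAY, n_min))
            durations = nxt - times
            keep = durations > 0
            times, durations = times[keep], durations[keep]
        else:
            raise ValueError("horizon must be 'hourly' or 'daily'")
        ends = times + durations
        labels = np.zeros(times.size, dtype=int)
        if self.diary_min.size:
            lo = np.searchsorted(self.diary_min, times, side="left")
            hi = np.searchsorted(self.diary_min, ends, side="left")
            labels = (hi > lo).astype(int)
        day_index = np.searchsorted(self.wake_times, times, side="right") - 1
        self._grids[horizon] = (times, durations, labels, day_index)
        return self._grids[horizon]

    # -- static (epoch-independent) causal feature columns -------------------

    def static_features(self, horizon: str, times: np.ndarray) -> dict:
        """Causal per-step features by group, excluding cycles and sleep."""
        cols = {}
        if horizon == "hourly":
            cols["rch"] = ("heart_rate", _latest(self.rch_hourly, times))
            cols["steps_prev_hour"] = (
                "activity", pp.steps_previous_hour(self.participant.steps, times))
        else:
            cols["rch"] = ("heart_rate", _latest(self.rch_daily, times))
        cols["rhr"] = ("heart_rate", _latest(self.rhr, times))
        cols["steps_prev_day"] = (
            "activity", pp.steps_previous_day(self.participant.steps, times))
        return cols

    def elapsed_seizure_times(self, times: np.ndarray):
        """Minutes since the last and second-last seizure strictly before t
        (NaN where fewer than one/two prior events exist)."""
        pos = np.searchsorted(self.diary_min, times, side="left")
        last = np.full(times.size, np.nan)
        second = np.full(times.size, np.nan)
        ok1 = pos >= 1
        last[ok1] = times[ok1] - self.diary_min[pos[ok1] - 1]
        ok2 = pos >= 2
        second[ok2] = times[ok2] - self.diary_min[pos[ok2] - 2]
        return last, second

    # -- per-epoch cycle state (memoized on the cut-off) ----------------------

    def cycle_models(self, cutoff_min: float) -> list:
        """Candidate cycles detected on data strictly before the cut-off."""
        key = int(cutoff_min)
        if key in self._cycle_cache:
            return self._cycle_cache[key]
        cfg = self.config
        sl = HeartRateSeries(
            self.hr1.bpm[:key], self.hr1.missing_mask[:key], 60, self.hr1.start)
        try:
            spectrum = cyc.wavelet_periodogram(
                sl, periods_per_decade=cfg.periods_per_decade,
                decimate_minutes=cfg.decimate_minutes,
                max_period_hours=cfg.max_period_hours)
            candidates = cyc.detect_peak_periods(spectrum)
        except ValueError:
            candidates = [24.0]
        models = []
        for period in candidates:
            if sl.n < 3 * period * 60:
                continue
            try:
                models.append(cyc.extract_cycle_phase(sl, period))
            except RuntimeError:
                continue
        self._cycle_cache[key] = models
        return models


def _latest(series, times: np.ndarray) -> np.ndarray:
    """Most recent value of a causal feature series at or before each time."""
    idx = np.searchsorted(series.index.to_numpy(), times, side="right") - 1
    out = np.full(times.size, np.nan)
    ok = idx >= 0
    out[ok] = series.to_numpy()[idx[ok]]
    return out


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

def oversample_minority(X: np.ndarray, y: np.ndarray, rng) -> tuple:
    """Duplicate minority rows (with replacement) to a 1:1 class ratio.

    Rows are exact copies, no interpolation.  With one class absent the
    input is returned unchanged with a warning.
    """
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        warnings.warn("oversample_minority: one class absent, returning input")
        return X, y
    if pos.size == neg.size:
        return X, y
    minority, majority = (pos, neg) if pos.size < neg.size else (neg, pos)
    extra = rng.choice(minority, size=majority.size - minority.size, replace=True)
    idx = np.concatenate([np.arange(y.size), extra])
    return X[idx], y[idx]


def train_sleep_model(tensors: np.ndarray, labels: np.ndarray,
                      config: ForecastConfig, seed: int) -> SleepLSTM:
    """Fit the recurrent sleep model on (n, 7, 7) histories and 0/1 labels."""
    if tensors.shape[1:] != (SLEEP_HISTORY_DAYS, N_SLEEP_FEATURES):
        raise ValueError("sleep histories must be (n, 7, 7)")
    model = SleepLSTM(
        units=config.lstm_units, dense_units=config.lstm_dense_units,
        epochs=config.lstm_epochs, lr=config.lstm_lr,
        batch_size=config.lstm_batch_size, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(tensors, labels)
    return model


def train_tree_regressor(X: np.ndarray, y: np.ndarray,
                         config: ForecastConfig, seed: int,
                         rng=None) -> RandomForestRegressor:
    """Fit the 0/1-target regression forest after minority oversampling."""
    if rng is None:
        rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xb, yb = oversample_minority(X, y, rng)
    rf = RandomForestRegressor(
        n_estimators=config.n_trees, min_samples_leaf=config.min_samples_leaf,
        max_samples=config.rf_max_samples, random_state=seed, n_jobs=1)
    rf.fit(Xb, yb)
    return rf


def train_stacker(base_outputs: np.ndarray, labels: np.ndarray,
                  keep_mask: np.ndarray, min_positive: int = 10):
    """Logistic stacker on out-of-fold base outputs.

    ``keep_mask`` marks rows surviving adjacency removal.  With fewer than
    ``min_positive`` positive rows left (or a single class), falls back to a
    rank-average of the base outputs.  Returns a callable mapping base
    outputs to likelihoods in [0, 1].

    Base outputs are likelihood estimates, so their stacker weights are
    constrained to be non-negative: with few positive rows an unconstrained
    fit can assign a negative weight to a base model's own likelihood and
    invert otherwise-sound forecasts.  Inputs whose fitted weight comes out
    negative are dropped and the stacker refit on the rest.
    """

    # fallback outputs are rescaled to the training event rate: likelihood
    # traces are concatenated across retraining epochs, so an epoch whose
    # values sat on a unit-rank scale would dominate every other epoch
    rate = float(np.mean(labels)) if labels.size else 0.0

    def rank_average(B):
        r = np.column_stack([rankdata(B[:, j]) for j in range(B.shape[1])])
        unit = (r.mean(axis=1) - 0.5) / B.shape[0]
        return np.clip(unit * 2.0 * max(rate, 1e-6), 0.0, 1.0)
    rank_average.fallback = True

    Xk, yk = base_outputs[keep_mask], labels[keep_mask]
    if int(yk.sum()) < min_positive or len(np.unique(yk)) < 2:
        return rank_average
    active = list(range(base_outputs.shape[1]))
    while active:
        lr = LogisticRegression(max_iter=1000)
        lr.fit(Xk[:, active], yk)
        neg = [active[j] for j in range(len(active)) if lr.coef_[0][j] < 0]
        if not neg:
            break
        active = [a for a in active if a not in neg]
    if not active:
        return rank_average
    kept = list(active)

    def predict(B):
        return lr.predict_proba(B[:, kept])[:, 1]
    predict.fallback = False
    predict.model = lr
    predict.active_inputs = kept
    return predict


def adjacency_keep_mask(row_times: np.ndarray, labels: np.ndarray,
                        seizure_times: np.ndarray) -> np.ndarray:
    """Drop the step immediately before and after each seizure's step.

    The seizure step itself is kept; the flanking steps are removed from
    stacker training to blunt diary-timing imprecision."""
    keep = np.ones(row_times.size, dtype=bool)
    if row_times.size == 0:
        return keep
    idx = np.searchsorted(row_times, seizure_times, side="right") - 1
    idx = idx[(idx >= 0) & (idx < row_times.size)]
    for i in np.unique(idx):
        if i - 1 >= 0:
            keep[i - 1] = False
        if i + 1 < row_times.size:
            keep[i + 1] = False
    keep[np.unique(idx)] = True
    return keep


# ---------------------------------------------------------------------------
# feature assembly per retraining epoch
# ---------------------------------------------------------------------------

def _epoch_features(prep: PreparedParticipant, horizon: str, cutoff: float,
                    train_rows: np.ndarray, block_rows: np.ndarray,
                    exclude_groups: tuple, config: ForecastConfig):
    """Feature matrix (minus the sleep column) for training and block rows."""
    times, _, _, _ = prep.grid(horizon)
    t_train, t_block = times[train_rows], times[block_rows]
    names, groups, cols_tr, cols_bl = [], [], [], []

    retained = []
    if "cycles" not in exclude_groups:
        models = prep.cycle_models(cutoff)
        train_sz = prep.diary_min[prep.diary_min < cutoff]
        retained = cyc.select_significant_cycles(models, train_sz, horizon)
        for m in retained:
            ph_tr = cyc.phase_at(m, t_train)
            ph_bl = cyc.extrapolate_phase(m, t_block)
            for comp, fn in (("sin", np.sin), ("cos", np.cos)):
                names.append(f"cycle_{m.period_hours:.1f}h_{comp}")
                groups.append("cycles")
                cols_tr.append(fn(ph_tr))
                cols_bl.append(fn(ph_bl))
        # elapsed time since last / second-last seizure, cyclically encoded
        moduli = [m.period_hours * 60.0 for m in retained if m.period_hours >= 36.0]
        if not moduli:
            isi = np.diff(train_sz)
            moduli = [float(np.percentile(isi, 95)) if isi.size else 7 * MIN_PER_DAY]
        last_tr, second_tr = prep.elapsed_seizure_times(t_train)
        last_bl, second_bl = prep.elapsed_seizure_times(t_block)
        for mod in moduli:
            for tag, v_tr, v_bl in (("last", last_tr, last_bl),
                                    ("second", second_tr, second_bl)):
                enc_tr = cyc.encode_cyclic(np.nan_to_num(v_tr), mod)
                enc_bl = cyc.encode_cyclic(np.nan_to_num(v_bl), mod)
                enc_tr[np.isnan(v_tr)] = 0.0      # undefined before 1st/2nd event
                enc_bl[np.isnan(v_bl)] = 0.0
                for j, comp in enumerate(("sin", "cos")):
                    names.append(f"{tag}_sz_mod{mod / MIN_PER_DAY:.1f}d_{comp}")
                    groups.append("cycles")
                    cols_tr.append(enc_tr[:, j])
                    cols_bl.append(enc_bl[:, j])

    static_tr = prep.static_features(horizon, t_train)
    static_bl = prep.static_features(horizon, t_block)
    for name, (group, v_tr) in static_tr.items():
        if group in exclude_groups:
            continue
        names.append(name)
        groups.append(group)
        cols_tr.append(v_tr)
        cols_bl.append(static_bl[name][1])

    X_tr = np.column_stack(cols_tr) if cols_tr else np.empty((t_train.size, 0))
    X_bl = np.column_stack(cols_bl) if cols_bl else np.empty((t_block.size, 0))
    # causal imputation: column means over training rows
    for j in range(X_tr.shape[1]):
        col = X_tr[:, j]
        fill = float(np.nanmean(col)) if np.any(~np.isnan(col)) else 0.0
        X_tr[np.isnan(col), j] = fill
        X_bl[np.isnan(X_bl[:, j]), j] = fill
    return X_tr, X_bl, names, groups, retained


# ---------------------------------------------------------------------------
# walk-forward engine
# ---------------------------------------------------------------------------

def walk_forward_run(participant, horizon: str, config: ForecastConfig | None = None,
                     seed: int = 0, exclude_groups: tuple = (),
                     retrain: bool = True, cutoff_min: float | None = None) -> ForecastTrace:
    """Run the full pipeline for one participant and horizon.

    Initial training uses data up to the training cut-off; each subsequent
    ``retrain_days`` block is forecast by models frozen before it, then the
    whole ensemble (cycle set, base models, stacker, thresholds) is refit
    with the block appended.  ``exclude_groups`` withholds feature groups
    (for ablation); ``retrain=False`` freezes the initial fit.
    """
    config = config or ForecastConfig()
    prep = participant if isinstance(participant, PreparedParticipant) \
        else PreparedParticipant(participant, config)
    if prep.config.periods_per_decade != config.periods_per_decade or \
       prep.config.decimate_minutes != config.decimate_minutes or \
       prep.config.max_period_hours != config.max_period_hours:
        prep = PreparedParticipant(prep.participant, config)
    times, durations, labels, day_index = prep.grid(horizon)

    if cutoff_min is None:
        cutoff_min = pp.training_cutoff(
            prep.participant.diary, prep.hr1.n,
            config.min_training_days, config.min_training_seizures)
    if cutoff_min is None:
        raise ValueError("participant never satisfies the training criteria")

    retrain_min = config.retrain_days * MIN_PER_DAY
    end = times[-1] + durations[-1]
    epoch_starts = []
    c = float(cutoff_min)
    while c < end:
        epoch_starts.append(c)
        c += retrain_min
    ss = np.random.SeedSequence(seed)
    epoch_seeds = ss.spawn(len(epoch_starts))

    out = {k: [] for k in ("t", "d", "l", "tier", "tm", "th", "ep", "y")}
    groups_used: set = set()
    reports, retained_log = [], []
    frozen = None

    for k, c_k in enumerate(epoch_starts):
        block_rows = np.flatnonzero((times >= c_k) & (times < c_k + retrain_min))
        if block_rows.size == 0:
            continue
        if not retrain and frozen is not None:
            state = frozen
            train_cut = epoch_starts[0]
        else:
            train_cut = c_k
            state = _fit_epoch(prep, horizon, c_k, exclude_groups, config,
                               epoch_seeds[k])
            if state is None:
                continue
            if not retrain:
                frozen = state
        lik = _predict_block(prep, horizon, state, train_cut, block_rows,
                             exclude_groups, config)
        pair, report = state["thresholds"], state["threshold_report"]
        tiers = classify_risk(lik, pair)
        out["t"].append(times[block_rows])
        out["d"].append(durations[block_rows])
        out["l"].append(lik)
        out["tier"].append(tiers)
        out["tm"].append(np.full(block_rows.size, pair.theta_med))
        out["th"].append(np.full(block_rows.size, pair.theta_high))
        out["ep"].append(np.full(block_rows.size, k))
        out["y"].append(labels[block_rows])
        groups_used |= state["groups_used"]
        reports.append(report)
        retained_log.append([m.period_hours for m in state["retained"]])

    if not out["t"]:
        raise RuntimeError("no forecast blocks were produced")
    test_sz = prep.diary_min[prep.diary_min >= epoch_starts[0]]
    return ForecastTrace(
        horizon=horizon,
        times_min=np.concatenate(out["t"]),
        durations_min=np.concatenate(out["d"]),
        likelihood=np.concatenate(out["l"]),
        tier=np.concatenate(out["tier"]),
        theta_med=np.concatenate(out["tm"]),
        theta_high=np.concatenate(out["th"]),
        epoch=np.concatenate(out["ep"]),
        labels=np.concatenate(out["y"]),
        seizure_times_min=test_sz,
        feature_groups_used=groups_used,
        threshold_reports=reports,
        retained_cycles=retained_log)


def _fit_epoch(prep, horizon, cutoff, exclude_groups, config, seedseq):
    """Fit cycle set, base models, stacker and thresholds on data < cutoff."""
    times, durations, labels, day_index = prep.grid(horizon)
    ends = times + durations
    lo = 0.0
    if config.rolling_window_days is not None:
        lo = cutoff - config.rolling_window_days * MIN_PER_DAY
    train_rows = np.flatnonzero((ends <= cutoff) & (times >= lo))
    if train_rows.size < 2 * config.n_folds or labels[train_rows].sum() == 0:
        return None
    rng = np.random.default_rng(seedseq)
    int_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * config.n_folds + 2)

    X_tr, _, names, groups, retained = _epoch_features(
        prep, horizon, cutoff, train_rows, train_rows[:1], exclude_groups, config)
    y_tr = labels[train_rows]
    t_tr = times[train_rows]

    use_sleep = "sleep" not in exclude_groups
    day_labels, day_rows_map = _daily_training_labels(prep, horizon, cutoff)
    tensors_tr = prep.tensors[day_rows_map] if day_rows_map.size else None
    sleep_ok = use_sleep and day_rows_map.size >= 15

    # --- out-of-fold base outputs for the stacker ---
    n = train_rows.size
    folds = np.array_split(np.arange(n), config.n_folds)
    oof_sleep = np.zeros(n)
    oof_rf = np.zeros(n)
    day_of_row = day_index[train_rows]
    for f_i, fold in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        t_lo = t_tr[fold[0]]
        t_hi = t_tr[fold[-1]]
        sleep_col = np.full(n, float(y_tr[mask].mean()) if mask.any() else 0.0)
        if sleep_ok:
            wake_t = prep.wake_times[day_rows_map]
            d_mask = (wake_t < t_lo) | (wake_t > t_hi)
            if d_mask.sum() >= 15 and len(np.unique(day_labels[d_mask])) == 2:
                lstm_f = train_sleep_model(
                    tensors_tr[d_mask], day_labels[d_mask], config,
                    int(int_seeds[2 * f_i]))
                preds = lstm_f.predict(prep.tensors)
                sleep_col = _broadcast_sleep(preds, day_of_row, sleep_col)
        Xf = np.column_stack([X_tr, sleep_col]) if use_sleep else X_tr
        if Xf.shape[1] == 0:
            oof_rf[fold] = y_tr[mask].mean()
            oof_sleep[fold] = sleep_col[fold]
            continue
        fold_config = config if config.n_trees_oof is None else \
            replace(config, n_trees=config.n_trees_oof)
        rf = train_tree_regressor(Xf[mask], y_tr[mask], fold_config,
                                  int(int_seeds[2 * f_i + 1]), rng)
        oof_rf[fold] = np.clip(rf.predict(Xf[fold]), 0.0, 1.0)
        oof_sleep[fold] = sleep_col[fold]

    # --- final base models on all training rows ---
    # the final forest consumes the *out-of-fold* sleep likelihoods: feeding
    # it the full LSTM's in-sample predictions would let it overweight a
    # feature whose training-time accuracy is not available at forecast time
    lstm_full = None
    if sleep_ok:
        lstm_full = train_sleep_model(tensors_tr, day_labels, config,
                                      int(int_seeds[-2]))
    X_full = np.column_stack([X_tr, oof_sleep]) if use_sleep else X_tr
    rf_full = None
    if X_full.shape[1] > 0:
        rf_full = train_tree_regressor(X_full, y_tr, config,
                                       int(int_seeds[-1]), rng)

    base = np.column_stack([oof_sleep, oof_rf]) if use_sleep else oof_rf[:, None]
    train_sz = prep.diary_min[(prep.diary_min >= t_tr[0]) & (prep.diary_min < cutoff)]
    keep = adjacency_keep_mask(t_tr, y_tr, train_sz)
    stacker = train_stacker(base, y_tr, keep)
    train_lik = np.clip(stacker(base), 0.0, 1.0)

    sz_rows = np.clip(np.searchsorted(t_tr, train_sz, side="right") - 1, 0, n - 1)
    pair, report = optimize_thresholds(train_lik, train_lik[sz_rows])

    groups_used = set(groups)
    if use_sleep and sleep_ok:
        groups_used.add("sleep")
    return {
        "retained": retained, "names": names, "groups": groups,
        "lstm": lstm_full, "rf": rf_full, "stacker": stacker,
        "use_sleep": use_sleep, "sleep_ok": sleep_ok,
        "train_label_mean": float(y_tr.mean()),
        "thresholds": pair, "threshold_report": report,
        "groups_used": groups_used, "train_rows": train_rows,
        "train_likelihood": train_lik, "base_oof": base,
    }


def _daily_training_labels(prep, horizon, cutoff):
    """Daily 0/1 labels for sleep-model training (windows ending before cutoff)."""
    d_times, d_dur, d_labels, _ = prep.grid("daily")
    ok = np.flatnonzero(d_times + d_dur <= cutoff)
    # map daily grid rows back to sleep tensor rows (same wake ordering)
    keep_idx = np.searchsorted(prep.wake_times, d_times[ok])
    return d_labels[ok], keep_idx


def _broadcast_sleep(day_preds, day_of_row, default_col):
    """The day's sleep likelihood holds for every step after that waking."""
    col = default_col.copy()
    ok = day_of_row >= 0
    col[ok] = day_preds[day_of_row[ok]]
    return col


def _predict_block(prep, horizon, state, train_cut, block_rows,
                   exclude_groups, config):
    """Likelihoods for one forecast block from the frozen epoch state."""
    times, durations, labels, day_index = prep.grid(horizon)
    train_rows = state["train_rows"]
    _, X_bl, _, _, _ = _epoch_features(
        prep, horizon, train_cut, train_rows, block_rows, exclude_groups, config)

    sleep_col = np.full(block_rows.size, state["train_label_mean"])
    if state["use_sleep"] and state["sleep_ok"] and state["lstm"] is not None:
        preds = state["lstm"].predict(prep.tensors)
        sleep_col = _broadcast_sleep(preds, day_index[block_rows], sleep_col)
    Xb = np.column_stack([X_bl, sleep_col]) if state["use_sleep"] else X_bl

    if state["rf"] is not None:
        rf_out = np.clip(state["rf"].predict(Xb), 0.0, 1.0)
    else:
        rf_out = np.full(block_rows.size, state["train_label_mean"])
    base = np.column_stack([sleep_col, rf_out]) if state["use_sleep"] else rf_out[:, None]
    stacker = state["stacker"]
    if getattr(stacker, "fallback", False):
        # rank-average fallback: rank block rows jointly with the training rows
        joint = np.vstack([state["base_oof"], base])
        lik = stacker(joint)[-base.shape[0]:]
    else:
        lik = stacker(base)
    return np.clip(lik, 0.0, 1.0)
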