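"""Forecast scoring: chance-referenced AUC, calibration, tier metrics, ablation.

A forecast trace is scored by (i) the rank-based AUC of its likelihoods
against the binary seizure labels, referenced to the distribution of AUCs of
rate-matched random forecasts — binary forecasts that flag each step
independently with the training-set seizure rate; a trace is "above chance"
when its AUC exceeds the null's 95th percentile — (ii) the Brier score and a
10-bin reliability (calibration) table, and (iii) tier metrics: time and
seizure counts per risk tier and the mean time spent continuously in high
risk before each seizure ("prediction time").  A feature-group ablation
quantifies the contribution of the cycles / heart-rate / sleep / activity
feature groups to the AUC across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_1samp


def compute_auc(likelihoods, labels) -> float:
    """Rank-based AUC (Mann-Whitney with midrank tie handling)."""
    l = np.asarray(likelihoods, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = int(y.sum())
    neg = y.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    r = rankdata(l)
    return float((r[y == 1].sum() - pos * (pos + 1) / 2) / (pos * neg))


def rate_matched_null(labels, training_rate: float, n_draws: int = 1000,
                      seed: int = 0) -> np.ndarray:
    """AUC distribution of rate-matched random binary forecasts.

    Each draw flags every step independently as elevated risk (likelihood 1,
    else 0) with probability equal to the per-step training seizure rate, and
    is scored against the true labels with the same midrank AUC.  For a
    binary forecast the AUC has the closed form
    ``(tp*(N-fp) + (tp*fp + (P-tp)*(N-fp))/2) / (P*N)``.
    """
    y = np.asarray(labels).astype(int)
    pos = int(y.sum())
    neg = y.size - pos
    if pos == 0 or neg == 0 or not (0.0 < training_rate):
        raise ValueError("degenerate labels or non-positive training rate")
    p = min(training_rate, 1.0)
    rng = np.random.default_rng(seed)
    tp = rng.binomial(pos, p, n_draws).astype(float)
    fp = rng.binomial(neg, p, n_draws).astype(float)
    return (tp * (neg - fp) + 0.5 * (tp * fp + (pos - tp) * (neg - fp))) / (pos * neg)


def brier_score(likelihoods, labels) -> float:
    """Mean squared difference between forecast likelihood and outcome."""
    l = np.asarray(likelihoods, dtype=float)
    y = np.asarray(labels).astype(float)
    return float(np.mean((l - y) ** 2))


def calibration_curve(likelihoods, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table on equal-width likelihood bins over [0, 1].

    One row per bin: mean forecast, observed event rate and count; empty
    bins keep NaN means and a zero count (never interpolated).
    """
    l = np.asarray(likelihoods, dtype=float)
    y = np.asarray(labels).astype(float)
    if l.size == 0:
        raise ValueError("no scored steps")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(l, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean_forecast": float(l[sel].mean()) if n else np.nan,
            "observed_rate": float(y[sel].mean()) if n else np.nan,
            "count": n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tier occupancy and prediction time
# ---------------------------------------------------------------------------

def risk_time_summary(step_times_min, step_durations_min, tiers,
                      seizure_times_min) -> dict:
    """Tier occupancy, per-tier seizure counts and mean prediction time.

    Time fractions weight each step by its duration.  Each seizure event is
    assigned to the tier of its containing step.  The prediction time of a
    seizure is the duration of the unbroken run of high-tier steps strictly
    before its step (zero when its own step is not high tier); the summary
    reports the mean over seizures in minutes.
    """
    t = np.asarray(step_times_min, dtype=float)
    dur = np.asarray(step_durations_min, dtype=float)
    tiers = np.asarray(tiers, dtype=object)
    sz = np.asarray(seizure_times_min, dtype=float)
    sz = sz[(sz >= t[0]) & (sz < t[-1] + dur[-1])]

    total = dur.sum()
    fractions = {tier: float(dur[tiers == tier].sum() / total)
                 for tier in ("low", "medium", "high")}

    step_of = np.clip(np.searchsorted(t, sz, side="right") - 1, 0, t.size - 1)
    counts = {tier: int(np.sum(tiers[step_of] == tier))
              for tier in ("low", "medium", "high")}

    pred_times = []
    for s_idx in step_of:
        if tiers[s_idx] != "high":
            pred_times.append(0.0)
            continue
        j = s_idx
        while j > 0 and tiers[j - 1] == "high":
            j -= 1
        pred_times.append(float(dur[j:s_idx].sum()))
    mean_pred = float(np.mean(pred_times)) if pred_times else None
    return {
        "tier_time_fractions": fractions,
        "tier_seizure_counts": counts,
        "mean_prediction_time_min": mean_pred,
        "n_seizures": int(sz.size),
    }


def forecast_accuracy(tiers, labels) -> float:
    """Stand-in accuracy: agreement between (tier == high) and the label,
    medium collapsed to low.  Forecast "accuracy" has no standard
    definition for tiered seizure forecasts; this one is explicit."""
    tiers = np.asarray(tiers, dtype=object)
    y = np.asarray(labels).astype(bool)
    return float(np.mean((tiers == "high") == y))


# ---------------------------------------------------------------------------
# full per-trace report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    auc: float
    null_auc_q95: float
    null_auc_mean: float
    above_chance: bool
    brier: float
    calibration: pd.DataFrame = field(repr=False)
    tier_time_fractions: dict = field(default_factory=dict)
    tier_seizure_counts: dict = field(default_factory=dict)
    mean_prediction_time_min: float | None = None
    accuracy: float | None = None
    n_steps: int = 0
    n_positive: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "calibration"}
        d["calibration"] = self.calibration.to_dict(orient="records")
        return d


def evaluate_trace(trace, training_rate: float, n_draws: int = 1000,
                   seed: int = 0) -> EvaluationReport:
    """Score one ForecastTrace (see :mod:`wearcast.forecaster`)."""
    null = rate_matched_null(trace.labels, training_rate, n_draws, seed)
    auc = compute_auc(trace.likelihood, trace.labels)
    q95 = float(np.quantile(null, 0.95))
    summary = risk_time_summary(
        trace.times_min, trace.durations_min, trace.tier, trace.seizure_times_min)
    return EvaluationReport(
        auc=auc, null_auc_q95=q95, null_auc_mean=float(null.mean()),
        above_chance=auc > q95, brier=brier_score(trace.likelihood, trace.labels),
        calibration=calibration_curve(trace.likelihood, trace.labels),
        tier_time_fractions=summary["tier_time_fractions"],
        tier_seizure_counts=summary["tier_seizure_counts"],
        mean_prediction_time_min=summary["mean_prediction_time_min"],
        accuracy=forecast_accuracy(trace.tier, trace.labels),
        n_steps=int(trace.labels.size), n_positive=int(trace.labels.sum()))


# ---------------------------------------------------------------------------
# feature-group ablation
# ---------------------------------------------------------------------------

FEATURE_GROUPS = ("cycles", "heart_rate", "sleep", "activity")


def feature_group_ablation(participants, horizon: str, config=None,
                           n_runs: int = 10, seed: int = 0,
                           groups=FEATURE_GROUPS) -> dict:
    """Per-group AUC contribution across a cohort, with a one-sided t-test.

    For each participant and seeded run, the full pipeline AUC is compared
    with the AUC of the pipeline with one feature group withheld; the
    group's delta-AUC for a participant is the mean over runs.  The cohort
    test asks whether the mean delta-AUC exceeds zero (one-sided t-test).
    Participants for whom a group contributes no columns (e.g. no retained
    cycle) are excluded from that group's test.
    """
    from .forecaster import walk_forward_run

    deltas = {g: [] for g in groups}
    for pi, p in enumerate(participants):
        per_run = {g: [] for g in groups}
        for r in range(n_runs):
            run_seed = (seed + 7919 * pi + 104729 * r) % (2 ** 31)
            full = walk_forward_run(p, horizon, config=config, seed=run_seed)
            auc_full = compute_auc(full.likelihood, full.labels)
            for g in groups:
                reduced = walk_forward_run(
                    p, horizon, config=config, seed=run_seed, exclude_groups=(g,))
                if g not in full.feature_groups_used:
                    continue
                per_run[g].append(auc_full - compute_auc(reduced.likelihood,
                                                         reduced.labels))
        for g in groups:
            if per_run[g]:
                deltas[g].append(float(np.mean(per_run[g])))

    out = {}
    for g in groups:
        d = np.asarray(deltas[g])
        if d.size >= 2:
            res = ttest_1samp(d, 0.0, alternative="greater")
            out[g] = {"mean_delta_auc": float(d.mean()), "n": int(d.size),
                      "t": float(res.statistic), "p": float(res.pvalue),
                      "deltas": d.tolist()}
        else:
            out[g] = {"mean_delta_auc": float(d.mean()) if d.size else None,
                      "n": int(d.size), "t": None, "p": None,
                      "deltas": d.tolist()}
    return out


def render_summary_table(reports: dict) -> str:
    """Plain-text participant x horizon summary (AUC, chance flag, Brier)."""
    lines = [f"{'participant':<14}{'horizon':<9}{'AUC':>7}{'null95':>8}"
             f"{'above':>7}{'Brier':>8}"]
    for (name, horizon), rep in sorted(reports.items()):
        lines.append(f"{name:<14}{horizon:<9}{rep.auc:>7.3f}{rep.null_auc_q95:>8.3f}"
                     f"{'*' if rep.above_chance else '':>7}{rep.brier:>8.4f}")
    return "\n".join(lines)
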