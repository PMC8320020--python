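"""Plain-text outputs: feature matrices, cycle reports, forecasts, scores.

All artifacts are CSV or JSON so a cohort run can be inspected with nothing
but a text editor.  Participant input directories are read and written by
:mod:`wearcast.synthetic` (``write_participant`` / ``read_participant``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_forecast_csv(path, trace) -> None:
    """timestamp, likelihood, tier, theta_med, theta_high, epoch — one row per step."""
    from .synthetic import T0
    ts = T0 + pd.to_timedelta(trace.times_min, unit="min")
    pd.DataFrame({
        "timestamp": ts,
        "likelihood": trace.likelihood,
        "tier": trace.tier,
        "theta_med": trace.theta_med,
        "theta_high": trace.theta_high,
        "epoch": trace.epoch,
        "label": trace.labels,
    }).to_csv(path, index=False)


def write_cycles_json(path, cycle_models) -> None:
    """Period, band, phase-locking p-value and significance per cycle."""
    out = [{
        "period_hours": m.period_hours,
        "band_edges_hours": list(m.band_edges_hours),
        "pvalue": m.pvalue,
        "significant": bool(m.significant),
        "n_events": int(m.n_events),
    } for m in cycle_models]
    Path(path).write_text(json.dumps(out, indent=1))


def write_phases_csv(path, cycle_models) -> None:
    """Per-minute instantaneous phase of each cycle, one column per period."""
    cols = {f"phase_{m.period_hours:.1f}h": m.phase for m in cycle_models}
    pd.DataFrame(cols).to_csv(path, index_label="minute")


def write_features_csv(path, X: np.ndarray, names, times_min, labels) -> None:
    """One row per forecast step with named feature columns and the label."""
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "time_min", times_min)
    df["label"] = labels
    df.to_csv(path, index=False, na_rep="NA")


def write_report_json(path, report) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1, default=_np_default))


def write_eligibility_json(path, records) -> None:
    out = [{k: _np_default(v) if isinstance(v, (np.generic, np.ndarray)) else v
            for k, v in r.__dict__.items()} for r in records]
    Path(path).write_text(json.dumps(out, indent=1))


def _np_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
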