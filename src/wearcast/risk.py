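"""Three-tier risk stratification of likelihood traces.

Forecast likelihoods are mapped to low / medium / high risk by two
thresholds chosen on training data.  The optimizer searches percentile pairs
of the training likelihood distribution for thresholds satisfying

* C1 — time in low risk > time in medium risk > time in high risk, and
* C2 — seizures in high risk > seizures in medium risk > seizures in low risk

(strict inequalities), and among satisfying pairs maximizes the product of
time in low risk and the number of seizures in high risk (C3 x C4).  When no
pair satisfies C1 and C2 jointly, the global maximizer of that product is
returned and the report says so.  Thresholds are re-optimized at every
retraining epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ThresholdPair:
    theta_med: float
    theta_high: float

    def __post_init__(self):
        if not (0.0 <= self.theta_med <= self.theta_high <= 1.0):
            raise ValueError("need 0 <= theta_med <= theta_high <= 1")


def classify_risk(likelihoods, thresholds: ThresholdPair) -> np.ndarray:
    """Tier per step: 'low' below theta_med, 'high' at/above theta_high."""
    l = np.asarray(likelihoods, dtype=float)
    tiers = np.full(l.shape, "medium", dtype=object)
    tiers[l < thresholds.theta_med] = "low"
    tiers[l >= thresholds.theta_high] = "high"
    return tiers


def tier_stats(likelihoods, seizure_likelihoods, pair: ThresholdPair):
    """(time fractions, seizure-event counts) per (low, medium, high) tier."""
    l = np.asarray(likelihoods, dtype=float)
    s = np.asarray(seizure_likelihoods, dtype=float)
    tm, th = pair.theta_med, pair.theta_high
    fl = float(np.mean(l < tm))
    fh = float(np.mean(l >= th))
    sl = int(np.sum(s < tm))
    sh = int(np.sum(s >= th))
    return (fl, 1.0 - fl - fh, fh), (sl, len(s) - sl - sh, sh)


def optimize_thresholds(likelihoods, seizure_likelihoods,
                        percentile_step: float = 1.0):
    """Grid-search the C1-C4 threshold pair on training data.

    Parameters
    ----------
    likelihoods : training likelihood trace (one value per forecast step).
    seizure_likelihoods : the trace value at each training seizure's step
        (one entry per seizure *event*).
    percentile_step : grid spacing over the 1st-99th percentiles.

    Returns
    -------
    (ThresholdPair, report) — the report records which criteria were
    satisfied, whether the fallback was used, and the achieved objective.
    Ties are broken toward larger theta_high, then larger theta_med.
    """
    l = np.asarray(likelihoods, dtype=float)
    s = np.asarray(seizure_likelihoods, dtype=float)
    if l.size == 0:
        raise ValueError("empty likelihood trace")
    if np.ptp(l) == 0:
        pair = ThresholdPair(float(l[0]), float(l[0]))
        return pair, {"c1": False, "c2": False, "fallback": True,
                      "degenerate": True, "objective": 0.0}

    grid = np.unique(np.percentile(
        l, np.arange(1.0, 100.0, percentile_step)))
    n, ns = l.size, s.size
    ls = np.sort(l)
    ss = np.sort(s)
    below_l = np.searchsorted(ls, grid, side="left")   # steps with l < g
    below_s = np.searchsorted(ss, grid, side="left")   # events with value < g

    best = None            # (satisfies, objective, theta_high, theta_med, pair info)
    for j in range(grid.size):          # theta_high
        nh = n - below_l[j]
        sh = ns - below_s[j]
        for i in range(j + 1):          # theta_med <= theta_high
            nl = below_l[i]
            sl = below_s[i]
            nm = n - nl - nh
            sm = ns - sl - sh
            c1 = nl > nm > nh
            c2 = sh > sm > sl
            obj = (nl / n) * sh
            key = (c1 and c2, obj, grid[j], grid[i])
            if best is None or key > best[0]:
                best = (key, (c1, c2))
    (both, obj, th, tm), (c1, c2) = best
    pair = ThresholdPair(float(min(tm, th)), float(th))
    return pair, {"c1": bool(c1), "c2": bool(c2), "fallback": not both,
                  "degenerate": False, "objective": float(obj)}
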