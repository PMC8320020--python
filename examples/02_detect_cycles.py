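"""Detect heart-rate cycles and test seizure phase-locking.

Generates one participant, finds spectral peak periods with the Morlet
wavelet periodogram, extracts each cycle's instantaneous phase, and runs
the Hodges-Ajne gate on the training seizures.  The injected 7-day cycle
should be recovered and retained; incidental peaks should be rejected.
"""

import numpy as np

from wearcast.synthetic import SyntheticCohortConfig, generate_participant
from wearcast import preprocess as pp, cycles as cyc

p = generate_participant(SyntheticCohortConfig(
    duration_days=120.0, seizure_rate=6.0 / 30.0,
    locking_kappa=(0.0, 3.0), seed=11))
hr1 = pp.resample_heart_rate(p.hr)

spectrum = cyc.wavelet_periodogram(hr1)
candidates = cyc.detect_peak_periods(spectrum)
print("candidate periods (h):", [f"{c:.1f}" for c in candidates])

models = [cyc.extract_cycle_phase(hr1, c) for c in candidates]
retained = cyc.select_significant_cycles(models, p.diary.times_min, "hourly")

for m in models:
    flag = "retained" if m in retained else "rejected"
    pv = "n/a" if m.pvalue is None else f"{m.pvalue:.4f}"
    print(f"  {m.period_hours:7.1f} h cycle: phase-locking p = {pv} "
          f"({m.n_events} events) -> {flag}")

m7 = next(m for m in retained if m.period_hours > 36)
truth = p.truth.phase(168.0, np.arange(hr1.n, dtype=float))
err = np.abs(np.angle(np.exp(1j * (m7.phase - truth))))[10080:-10080]
print(f"mean absolute phase error vs ground truth (7-day cycle, "
      f"edges trimmed): {err.mean():.3f} rad")
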