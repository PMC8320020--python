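"""Quantify each feature group's contribution to forecast AUC.

Builds a small cohort whose seizures lock to a 7-day heart-rate cycle and
compares the full hourly pipeline against the pipeline with one feature
group withheld.  Expect a clearly positive delta for the cycles group and
near-zero deltas for the others.  Takes a few minutes at this size.
"""

from wearcast.synthetic import SyntheticCohortConfig, generate_participant
from wearcast.forecaster import PreparedParticipant, scaled_config
from wearcast.evaluation import feature_group_ablation

config = scaled_config()
cohort = []
for i in range(3):
    cfg = SyntheticCohortConfig(
        duration_days=180.0, seizure_rate=8.0 / 30.0,
        locking_kappa=(0.0, 4.0), seed=20 + i)
    cohort.append(PreparedParticipant(generate_participant(cfg), config))

result = feature_group_ablation(cohort, "hourly", config=config,
                                n_runs=2, seed=0)
print("AUC change when each feature group is added (mean over runs):")
for group, stats in result.items():
    print(f"  {group:<12} delta-AUC = {stats['mean_delta_auc']:+.3f} "
          f"(one-sided p = {stats['p']:.4f}, n = {stats['n']} participants)")
print("\nA positive delta means the group improves discrimination; the "
      "planted signal lives in the heart-rate cycle, so only the cycles "
      "group should matter.")
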