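"""Rank features by their Fisher criterion (F-score) over movement time.

The F-score of a feature at an epoch is the squared class-mean difference
over the summed class variances; the F-group score pools all twelve
standardized features.  Both grow as the hand progressively conforms to the
object, and the epoch-wise Bonferroni-corrected paired contrasts show when
each feature starts discriminating the object size.
"""
import numpy as np

from graspkin import SyntheticConfig, simulate_feature_dataset
from graspkin.discriminability import epochwise_contrasts, fscore_over_time

matrix = simulate_feature_dataset(SyntheticConfig(n_participants=8,
                                                  n_trials_per_size=15, seed=3))
table = fscore_over_time(matrix)

print("F-scores by epoch (rows = epochs 10%..100%):")
print(f"{'epoch':>6} {'grip_ap':>8} {'wrist_v':>8} {'wrist_h':>8} {'fgroup':>8}")
for i, e in enumerate(table.epochs):
    print(f"{e:>5}% {table.feature_scores('grip_aperture')[i]:8.2f} "
          f"{table.feature_scores('wrist_velocity')[i]:8.2f} "
          f"{table.feature_scores('wrist_height')[i]:8.2f} "
          f"{table.fgroup[i]:8.2f}")
print("grip aperture dominates throughout; the F-group score rises "
      "monotonically as information accumulates")

contrasts = epochwise_contrasts(matrix)
print("\nfirst epoch at which each feature discriminates object size "
      "(paired t, Bonferroni-corrected):")
for feature in matrix.feature_names:
    rows = contrasts[contrasts.feature == feature]
    sig = rows[rows.significant]
    first = f"{int(sig.epoch_pct.min())}%" if len(sig) else "never"
    print(f"  {feature:<16} {first}")
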