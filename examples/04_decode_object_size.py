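"""Decode the grasped object's size from kinematics, epoch by epoch.

At each epoch an RBF-kernel SVM is trained on the 12-feature slice with
grid-searched C and gamma and scored by stratified ten-fold cross-validation.
Accuracy starts near chance early in the reach and approaches 100% before
contact — the movement reveals its target progressively.
"""
import numpy as np

from graspkin import SyntheticConfig, simulate_feature_dataset
from graspkin.classify import SVMSettings, accuracy_over_time

matrix = simulate_feature_dataset(SyntheticConfig(n_participants=6,
                                                  n_trials_per_size=10, seed=5))
settings = SVMSettings(c_grid=(2.0**-3, 2.0**1, 2.0**5),
                       gamma_grid=(2.0**-7, 2.0**-3, 2.0**1),
                       n_folds=10, fold_seed=0)
curve = accuracy_over_time(matrix, settings)

print("epoch   accuracy   selected (C, gamma)")
for e, a, c, g in zip(curve.epochs, curve.accuracy_pct, curve.C, curve.gamma):
    bar = "#" * int(round((a - 50) / 2)) if a > 50 else ""
    print(f"{e:4d}%   {a:6.1f}%   (2^{int(np.log2(c)):+d}, 2^{int(np.log2(g)):+d})  {bar}")

print("\nchance level is 50%; accuracy above it means the kinematics already "
      "carry object-size information at that fraction of the movement")
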