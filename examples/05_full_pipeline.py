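"""Run the whole analysis in one reproducible call.

simulate -> extract -> outlier-replace -> F-scores & contrasts -> per-epoch
SVM, all seeded from one master seed.  The report collects dataset summary,
replacement fractions, the accuracy curve and the F-score table; with an
output directory every intermediate table is written as TSV plus a JSON
report.
"""
from graspkin.classify import SVMSettings
from graspkin.pipeline import RunConfig, run_full_analysis
from graspkin.synthetic import SyntheticConfig

config = RunConfig(
    synthetic=SyntheticConfig(n_participants=4, n_trials_per_size=6),
    synthetic_mode="features",
    svm=SVMSettings(c_grid=(0.5, 8.0), gamma_grid=(2.0**-7, 2.0**-3), n_folds=5),
    output_dir="run_output",
    seed=11,
)
report = run_full_analysis(config)

print(f"config hash {report.config_hash} (rerun with the same config reproduces this exactly)")
print(f"trials analysed: {report.n_trials}, dropped: {report.n_dropped}")
print(f"outlier cells replaced: participant-level "
      f"{report.outlier_fraction_participant:.2%}, group-level "
      f"{report.outlier_fraction_group:.2%}")
print("\nepoch   accuracy   F-group")
for e, a, f in zip(report.accuracy.epochs, report.accuracy.accuracy_pct,
                   report.fscores.fgroup):
    print(f"{e:4d}%   {a:6.1f}%   {f:7.3f}")
print("\ntables written to run_output/ (features, fscores, contrasts, accuracy, report.json)")
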