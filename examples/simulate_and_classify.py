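"""End-to-end classification of synthetic treatment-response EEG.

Simulates the default benchmark dataset (200 windows per class), turns
every window into a frequency-attention graph sample, and runs the
cross-validated classifier (hold-out split, stratified 5-fold CV, final
hold-out fit).  The dataset size matters: the fixed training protocol
(lr 0.01, batch 30, at most 100 epochs) only accumulates enough gradient
updates to calibrate the class scores from a few hundred windows upward.
Takes about half a minute on one CPU.
"""

from gfacnn import (
    SimConfig, TrainConfig, build_graph_samples, run_pipeline,
    simulate_dataset, stack_samples,
)

ds = simulate_dataset(200, 200, SimConfig(), seed=0)
samples = stack_samples(build_graph_samples(ds.segments))
result = run_pipeline(samples, TrainConfig(seed=0))

print(f"dataset: {len(ds)} windows "
      f"({ds.segments.window_len} samples at {ds.segments.fs:g} Hz)")
print("5-fold cross-validation (320 windows):")
for key in ("accuracy", "sensitivity", "specificity", "auc"):
    print(f"  {key:12s} {result.cv.mean[key]:.3f} "
          f"(+/- {result.cv.std[key]:.3f})")
print("hold-out test set (80 windows):")
print(f"  accuracy     {result.holdout.accuracy:.3f}")
print(f"  auc          {result.holdout.auc:.3f}")
print()
print("Sensitivity counts treatment-responsive windows recovered;"
      " specificity counts treatment-resistant ones.")
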