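"""Simulate an imbalanced 3-class cohort with label noise.

The generator mimics a small multi-site sample: 37 controls, 7 autism and
8 Asperger's subjects, each with a 150-volume scan over 12 ROIs, where the
diagnostic classes differ only in a block of ROI-ROI correlations.
"""

import numpy as np

from csldl import CohortConfig, generate_cohort

config = CohortConfig(
    class_sizes=(37, 7, 8),
    n_rois=12,
    n_timepoints=150,
    separation=0.5,   # strength of the class-specific connectivity block
    noise_rate=0.1,   # 10% of observed diagnoses are flipped
    seed=7,
)
records = generate_cohort(config)

truth = np.array([r.true_class for r in records])
observed = np.array([int(np.argmax(r.observed_logical_label)) for r in records])
print(f"subjects: {len(records)}, time series shape: {records[0].time_series.shape}")
print(f"true class counts:     {np.bincount(truth).tolist()}")
print(f"observed class counts: {np.bincount(observed, minlength=3).tolist()}")
print(f"label-noise flips: {(truth != observed).sum()} "
      f"(= floor(0.1 * {len(records)}), ground truth kept for scoring)")
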