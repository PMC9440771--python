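"""Turn ROI time series into functional-connectivity feature vectors.

Each subject's T x R series becomes an R x R Pearson correlation matrix;
the strictly-upper triangle, read row by row, is the feature vector of
length R(R-1)/2.
"""

import numpy as np

from csldl import (
    CohortConfig,
    build_feature_matrix,
    generate_cohort,
    pearson_fc_matrix,
    upper_triangle_vector,
)

records = generate_cohort(
    CohortConfig(class_sizes=(3, 2), n_rois=5, n_timepoints=200, separation=0.5, seed=0)
)

fc = pearson_fc_matrix(records[0].time_series)
print("FC matrix (5 ROIs), unit diagonal, symmetric:")
print(np.round(fc.values, 3))

vec = upper_triangle_vector(fc)
print(f"\nfeature vector (upper triangle, row-major), length {vec.size} = 5*4/2:")
print(np.round(vec, 3))

features = build_feature_matrix(records)
print(f"\nstacked cohort features: {features.values.shape} "
      "(one row per subject, same pair ordering everywhere)")
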