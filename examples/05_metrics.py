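"""The label-distribution and multiclass evaluation suite.

Four distances (Chebyshev, KL, Clark, Canberra: lower is better) and two
similarities (intersection, cosine: higher is better) compare distribution
pairs; precision and macro-average precision score the hard decisions.
"""

import numpy as np

from csldl import (
    canberra,
    chebyshev,
    clark,
    cosine,
    intersection,
    kl_divergence,
    macro_average_precision,
    precision_metric,
)

d = np.array([0.5, 0.3, 0.2])      # ground-truth distribution
dhat = np.array([0.4, 0.4, 0.2])   # a prediction

print(f"truth      {d}\nprediction {dhat}\n")
print(f"Chebyshev    {chebyshev(d, dhat):.6f}   (largest per-class gap)")
print(f"KL           {kl_divergence(d, dhat):.6f}   (truth || prediction)")
print(f"Clark        {clark(d, dhat):.6f}")
print(f"Canberra     {canberra(d, dhat):.6f}")
print(f"intersection {intersection(d, dhat):.6f}   (shared probability mass)")
print(f"cosine       {cosine(d, dhat):.6f}")

# the degenerate anchor: predicting every subject as the majority class of
# a 3-class cohort gives macro precision exactly 1/3
truth = np.repeat([0, 1, 2], (37, 7, 8))
pred = np.zeros(truth.size, dtype=int)
print(f"\nall-majority predictor on a 37/7/8 cohort:")
print(f"  precision (accuracy) = {precision_metric(truth, pred):.4f}")
print(f"  macro-average precision = {macro_average_precision(truth, pred, 3):.4f} "
      "(recalls 1, 0, 0 averaged)")
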