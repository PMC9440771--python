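# Methods

## Problem setting

A cohort of N subjects carries resting-state ROI time series (T volumes ×
R parcels), a one-hot diagnostic label over K classes (here typically
Normal / Autism / Asperger's syndrome), and — after enhancement — a label
distribution d_i on the K-simplex.  The package estimates a map from
connectivity features to label distributions that is robust to label
noise (through the distributional targets) and to class imbalance
(through cost weighting), and scores it with the standard
label-distribution metric suite.

## Synthetic cohort generator

Subjects are drawn from zero-mean multivariate normals.  The baseline ROI
correlation matrix is AR(1)-like, ρ_ab = 0.3^|a−b|.  Class c adds
`separation` to the off-diagonal entries of its own contiguous ROI block
(the R ROIs are split into K equal blocks), clips entries to ±0.99, and
projects back to a valid correlation matrix by eigenvalue clipping at
1e-6 followed by diagonal renormalization.  Classes therefore differ
*only* in connectivity, matching the premise that the FC upper triangle
carries the diagnostic signal.  Label noise reassigns a uniformly chosen
⌊rate·N⌋ subjects to a uniformly chosen other class (optionally only
between the two ASD subcategories, mimicking blurred subcategory
boundaries); the true class is always retained separately so noise
recovery can be scored.

What the generator deliberately does **not** model: haemodynamics,
scanner/site effects, motion artefacts, ROI-size heterogeneity, and any
non-Gaussian temporal structure.  Passing tests on these cohorts
demonstrate the algorithmic claims (stability, imbalance mechanics,
recovery of a known generating model), not clinical performance on real
multi-site data.

Separation is a geometric dial.  Pearson features have sampling noise
≈ O(1/√T) per entry, so "well separated" means the between-class centroid
distance is several times the within-class spread.  The test and
acceptance cohorts use R = 12, T = 1200, separation 0.6 for that regime
(between/within ≈ 9), and T = 100–600 with separation 0.2–0.3 for
overlapping regimes.  These sizes were chosen as the smallest cohorts in
which each effect is cleanly expressed.

## Connectivity features

Pairwise Pearson correlation over columns; strictly-upper-triangular
entries concatenated row-major: (r_{1,2}, …, r_{1,R}, r_{2,3}, …,
r_{R−1,R}), q = R(R−1)/2.  The constant diagonal is excluded; no Fisher
z-transform is applied.  A zero-variance ROI raises an error naming the
ROI rather than propagating NaNs — dead channels in real exports should
fail loudly.

## Label enhancement

Three steps: fuzzy C-means over the feature rows, a label–cluster
association matrix, and a fuzzy composition.

**Membership rule.**  m_i^k = 1 / Σ_j (Dist(x_i,μ_k)/Dist(x_i,μ_j))^{1/(β−1)}
with Dist the plain Euclidean distance.  Note the exponent acts on the
*distance* ratio: with β = 2 this is m ∝ 1/d, a softer rule than textbook
FCM's m ∝ 1/d² (the two families coincide under β ↦ 2β−1 when distances
are squared).  A point coinciding with one or more centers receives the
indicator of those centers, uniform over exact ties.

**Objective and center update.**  Both alternating steps descend the one
objective J = Σ_i Σ_k (m_i^k)^β ‖x_i − μ_k‖ — the membership-weighted sum
of distances.  The membership rule above is the exact row-constrained
minimizer of J for fixed centers; the center update is a
majorize–minimize (Weiszfeld) step toward the (m^β)-weighted geometric
median, i.e. a weighted mean with weights m^β/max(d, 1e-12).  This makes
the recorded objective trace non-increasing by construction.  (A plain
m^β-weighted mean — the minimizer of the *squared*-distance criterion —
is not a descent step for J; on this membership rule it can drift all
centers to the grand mean.)

**Initialization.**  Farthest-point seeding: a seeded random sample
first, then greedily the point maximizing the minimum distance to the
chosen set.  On blob-separated data every restart then reaches the same
optimum, which is what makes repeated enhancement runs agree to below
1e-6 in Chebyshev and KL — the stability property the enhancement is
supposed to have.  Purely random seeding can place two initial centers in
one blob, where they merge into a degenerate coincident-center fixed
point.

**Defaults.**  p = K clusters (one per diagnostic class — the minimal
assumption, and the one that makes the identity-composition sanity check
meaningful), β = 2, convergence when the objective changes by < 1e-9
(1e-12 in the stability experiments, where restart agreement must resolve
below the 1e-6 bound), max 300 sweeps.

**Association and composition.**  Row j of A accumulates the membership
vectors of class-j samples and is normalized to sum to one; an empty
class is an error, never a silent uniform row.  Composition is
sum-product (score = A m, a fuzzy-relation matrix–vector product) by
default; classical max–min composition is available.  Scores are
normalized onto the simplex; an all-zero score vector (impossible under
sum-product with valid inputs) raises.

The fitted enhancer is a reusable transform: held-out subjects get
distributions from the *training-fold* centers and association matrix,
which is how cross-validation stays leakage-free.

## CSLDSVR

Targets are the logits t_i = logit(clip(d_i, 0.001, 0.999)); the clip
keeps logits finite for near-degenerate distributions.  Scores are
f_j(x) = Σ_i α_{ij} κ(x_i, x) + b_j over the training points
(representer-style expansion), and the training problem is

  min_{α,b}  ½ Σ_j α_{·j}ᵀ K α_{·j} + C Σ_i w_i max(0, ‖t_i − f(x_i)‖₂ − ε)²

with K the kernel Gram matrix.  Design choices:

- the ε-tube is applied to the *joint* residual vector norm, not
  per output, so the insensitive zone is a ball in label space;
- the squared hinge keeps the problem C¹-smooth, so a deterministic
  quasi-Newton method (L-BFGS from a zero start) solves it; identical
  data and parameters give identical coefficients, with the objective
  recorded per accepted iterate;
- cost weights w_j = N/(K·N_j) (uniform when `cost_sensitive=False`),
  with N_j counted on the training fold.  The mean-1 scaling keeps C on
  the same scale across imbalance levels;
- kernels: linear a·b, polynomial (a·b + 1)³ (degree and offset
  configurable), Gaussian exp(−‖a−b‖²/2σ²).

Prediction renormalizes the per-class sigmoids, so outputs are strictly
positive simplex vectors; hard decisions take the argmax with ties to the
lowest class index.  Models serialize to JSON with exact float round-trip.

Non-convergence within `max_iter` (default 2000) warns with the final
objective rather than failing: on easy problems L-BFGS occasionally stops
on the iteration cap with a solution already far inside the tolerance
that matters downstream.

## Metrics

Chebyshev max_j |d_j−d̂_j|; KL Σ d_j ln(d_j/d̂_j) with the prediction
clipped below at 1e-12 (baselines can emit exact zeros; the truth side
uses 0·ln 0 = 0); Clark √Σ (d_j−d̂_j)²/(d_j+d̂_j)²; Canberra
Σ |d_j−d̂_j|/(d_j+d̂_j) (empty components contribute 0 in both);
intersection Σ min(d_j, d̂_j); cosine similarity.  KL is asymmetric and
fixed as KL(truth ‖ prediction); it is scored lower-is-better.  Precision
is exact-match accuracy.  mAP is the macro average over classes of the
per-class recall P_j = (#class-j predicted j)/(#class-j), classes absent
from the truth excluded — the reading under which an all-majority
predictor on a 3-class set scores exactly 1/3, the standard degeneracy
flag.  Each metric carries direction metadata used by the grid search.

## Cross-validation and grid search

Seeded random partition into 10 near-equal folds (sizes differ by ≤ 1);
optional stratified dealing, useful when a 7-subject class must survive
in every training set.  Per fold: enhancement fit on the nine training
parts (an `enhance_on_full_data` flag mirrors the transductive
alternative), model fit on training, held-out distributions and classes
evaluated with the full metric report; aggregation is mean and
*population* standard deviation over folds.  A fold whose training set
lost a class entirely is skipped with a warning and flagged.  Grid search
enumerates all valid combinations (bandwidth only under the Gaussian
kernel; the default grid has 7·4·(1+1+5) = 196 candidates), runs the same
CV per candidate, and selects by the chosen metric in its direction,
ties to the earlier candidate; selection is single-level (not nested CV).

## Known limitations

- The enhancement is only as good as the cluster geometry: when classes
  overlap heavily in feature space the fuzzy memberships flatten and the
  enhanced distributions approach uniform.  This is a property of the
  method, visible in the no-signal tests.
- The softer-than-textbook membership rule makes cluster structure harder
  to resolve at fixed β than classical FCM; β is configurable.
- Cost sensitivity reweights the regression loss; it does not resample,
  and with fully separable classes it changes nothing (both variants hit
  ceiling).
- Per-output ε-tubes, non-Euclidean enhancement distances, and the
  problem-transformation/neural LDL baselines are out of scope.
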