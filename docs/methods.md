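# Methods

This note documents the model, the conventions fixed where several readings
were possible, the synthetic-data generator, and the numerical choices. It is
the package's own account of its science; every number quoted here is
computed by the test-suite or by `scripts/acceptance.py`.

## Voxel descriptor

Each voxel of a normalized region of interest (ROI) is described by 315
values, ordered as: position (1), grey level (1), four Haralick groups of 66
(cubic masks m = 3, 5, 7, 9), and 49 Haar-like features.

**Normalization and quantization.** Intensities are min–max normalized to
[0, 1] over the whole ROI, then quantized once to G grey levels by
`level = floor(I·G)` clamped to G−1, so every window shares one level map.
G defaults to 8: with smaller G the cooccurrence matrices of 3×3 windows are
dominated by ties; with much larger G the 9 (to 81) pairs of a small window
cannot populate the G² cells. G is configurable everywhere.

**Cooccurrence statistics.** For each mask size m, each of the three m×m
plane projections through the voxel (slice normal to x, y, z; the in-plane
(row, col) axes are the remaining axes in increasing order) and each
orientation 0°, 45°, 90°, 135° (offsets (0,1), (−1,1), (−1,0), (−1,−1) in
(row, col); pair distance 1, the standard choice), ordered grey-level pairs
are counted in both directions (symmetrization) and normalized to a joint
probability p(k, l). Four statistics are taken per matrix: energy, contrast,
correlation and inverse difference moment; correlation is defined as 0 when
a marginal variance is degenerate (below 1e−12), which covers constant
windows.

**Gradients.** The 13 distinct directions of the 26-neighbourhood (3 axes, 6
face diagonals, 4 body diagonals) give signed differences
I(v + r·d) − I(v − r·d) with r = (m−1)/2, i.e. the probing distance grows
with the mask size. Signed rather than absolute values preserve edge
polarity. Directions carry canonical segment labels on the reference cube
(vertices A…H; body diagonals AG, CE, DF, BH; axes MN, OP, QR between face
midpoints; face diagonals IL, JK, ST, UV, WX, YZ between edge midpoints);
the letter assignment is a documented convention, as a geometric figure
alone cannot fix it.

**Moments.** The five principal statistical moments of the m³ cube: mean,
variance, skewness, excess kurtosis and the 5th standardized central moment
— the minimal consistent reading of "5 principal moments" given that
skewness is explicitly among the selected features in the motivating study
design. Standardized moments are 0 by convention at degenerate variance.

**Haar-like bank.** Exactly 49 block-mean differences, each
mean(positive block) − mean(negative block): 13-direction half-cube
contrasts (cube split by the plane through the center normal to d; voxels on
the plane excluded) at m ∈ {5, 7, 9} (39 features); axis-aligned half-cube
contrasts at m ∈ {3, 5} (6); and center–surround contrasts of a c³ cube
against its (c+2)³ shell for c ∈ {1, 3, 5, 7} (4). The bank composition is a
package convention — only the two template *types* (split cube, center–
surround) are externally prescribed — and is enumerated in
`features._haar_bank`. The three axis templates at m = 5 appear in both
half-cube sets; the duplication is accepted to keep both sub-banks complete.

**Position.** A single scalar — Euclidean distance from the ROI center
normalized by the half-diagonal — keeps the descriptor at 315 values; an
optional `coords` mode emits the three normalized coordinates (317 values)
but is non-default.

**Border policy.** All windows use nearest-voxel clamping (edge
replication), so every ROI voxel is featurizable; the vectorized path
implements the same policy via edge padding and is verified against the
per-voxel reference implementation to 1e−8.

## Classifier and evaluation

A two-class Gaussian naive Bayes: per class, per feature, maximum-likelihood
mean and variance; priors are training class frequencies; posteriors are
computed in log space. Variances are floored at 1e−9 times the feature's
variance over the whole training set, so a feature constant within one class
cannot produce infinite densities while the floor remains scale-equivariant.
The decision threshold is fixed at P(A|x) ≥ 0.5 (tie to the foreground —
classification tuning is deliberately out of scope); threshold 0/1 behaviour
is defined and validated.

Evaluation is k-fold cross-validation at the *subject* level: folds
partition subjects (sizes differing by at most one), each validation subject
gets its own confusion matrix and Dice, and the report is mean ± sample sd
across validation subjects (each subject is validated exactly once). The ±
is across subjects, not folds, and is labelled as such in the output.
Voxel-level folds would leak information between neighbouring voxels of one
subject and are not offered.

Metrics follow the standard confusion-matrix calculus: total efficiency,
purity (precision), completeness (recall), contamination = 1 − purity, and
Dice = 2·N_AA/(2·N_AA + N_BA + N_AB); the equality of the harmonic-mean and
count forms is asserted as a property test. A Dice with neither true nor
predicted foreground is reported as 0 with a warning (the conservative
choice when averaging over subjects).

## Selection strategies

* **K-S filter** — per feature, the two-sample Kolmogorov–Smirnov statistic
  between foreground and background voxel values with its asymptotic
  p-value; keep p < α, default α = 0.05 ("distributions differ at the 5%
  level"), ordered by ascending p. ECDF-based, hence invariant under
  strictly monotone feature transforms.
* **Sequential forward selection (SFS)** — at each step score every
  remaining candidate jointly with the current set by the CV-Dice evaluator
  and add the argmax. The returned subset is the prefix at the *peak* of the
  criterion trajectory (first occurrence, i.e. the smallest such subset).
* **Sequential backward elimination (SBE)** — mirror image, starting from
  the full pool; the trajectory includes the untouched pool as step 0 and
  the returned subset is the surviving set at the peak (first occurrence,
  i.e. the larger subset).
* **Random Forest importance thresholding** — a forest (100 trees, seeded)
  is fitted once; the acceptance threshold on mean-impurity-decrease
  importances is swept over importance quantiles (always including 0 = full
  set), each surviving subset is scored by CV Dice, and the best is kept,
  preferring the larger subset on ties.
* **PCA baseline** — the smallest number of leading components reaching a
  target explained-variance fraction (default 0.99); a feature-*extraction*
  control, expected to underperform selection for segmentation since
  high-variance directions need not be discriminative.
* **Random-subset null** — the CV-Dice distribution of uniform
  without-replacement subsets of a fixed size; the empirical p of a selected
  subset is the fraction of draws at or above its Dice.

Ties everywhere break towards the lowest feature index, making every run
deterministic given its seed.

**Desk-scale wrapper protocol.** A full greedy pass over all p = 315
features costs O(p²) cross-validated fits. The package's documented
desk-scale protocol restricts the wrapper search to the top-40 features of
the K-S ranking (a standard filter-then-wrap cascade) and runs SFS forward
over, and SBE backward from, that pool; the full-315 score is computed once
for comparison. `max_steps` / `min_features` / `candidate_pool` expose the
budget; unrestricted runs are supported and used on small instances in the
oracle tests, where each greedy step is checked against exhaustive per-step
search.

## Phantom generator

`generate_phantom` produces a box volume with an ellipsoidal foreground:
mask(v) = 1 iff Σ((v−c)/a)² ≤ 1, intensities = per-region mean + Gaussian
white noise convolved with a Gaussian kernel of the region's smoothing
length and rescaled to the requested marginal sd, clipped to the intensity
range. Identical configs are bit-identical; per-subject seeds derive from
the master seed via `SeedSequence` so cohorts are reproducible and
collision-free. Cohort jitter perturbs center (±1 voxel), semi-axes (±10%),
region means (±3) and noise sd (±10%) per subject.

Default study conditions (`PhantomConfig()`): shape 28×26×24, semi-axes
(7, 6, 5); foreground mean 130, background 110, both with noise sd 12;
smoothing 1.5 voxels inside vs 0.5 outside; range [0, 255]. The 20-unit mean
difference against 12 units of noise makes intensity informative but far
from sufficient, and the autocorrelation contrast puts real signal into the
cooccurrence and gradient features — an overlapping-class regime in which
selection genuinely matters. A 6-subject cohort at these settings yields
roughly 20–25 thousand voxels with ~20% foreground.

What the phantoms do *not* emulate: MRI physics (bias fields, Rician noise,
partial-volume effects), registration artifacts, anatomical shape variation,
or inter-subject intensity standardization error. Passing tests therefore
demonstrate correctness and the qualitative selection phenomenology
(small selected subsets matching or beating the full descriptor; random
subsets rarely matching an optimized one), not clinical segmentation
accuracy on real scans.

`make_planted_matrix` is a second, purely tabular generator for
feature-recovery studies: 3 informative columns (class mean shift 0.8 sd)
hidden among 17 standard-normal noise columns, 6 subjects × 120 voxels — a
moderate effect size at which recovery is reliable but not trivial.

## Numerical choices and degenerate inputs

* Variance degeneracy threshold 1e−12 (GLCM correlation, standardized
  moments); naive Bayes variance floor 1e−9 × overall feature variance.
* Constant ROI volumes are rejected at normalization (the map is undefined);
  constant features get K-S statistic 0 and are never selected.
* Empty masks, 4D images, shape mismatches, k < 2, k > n_subjects,
  out-of-range thresholds and empty feature subsets all raise distinct,
  named errors before any heavy compute.
* The vectorized extraction path uses cumulative-sum sliding windows and
  kernel correlation; its agreement with the per-voxel reference is part of
  the test-suite (atol 1e−8).

## Known limitations

* The K-S filter at α = 0.05 keeps nearly every feature at phantom sample
  sizes (tens of thousands of voxels make tiny distributional differences
  significant); its *ranking* is what the desk-scale cascade uses.
* SBE from the full 315 features is O(p²) in evaluator calls and is not run
  at full scale by default; the peak-selection semantics are unchanged by
  the pool restriction.
* The naive Bayes conditional-independence assumption is knowingly violated
  by overlapping windows; it is the evaluation yardstick here, not a claim
  of optimality.
* Dice of an always-foreground classifier is 2f/(1+f) for foreground
  fraction f, so chance levels depend on class balance; the test-suite pins
  this closed form.
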