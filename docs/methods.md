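# Methods

## Statistical model

Each analyte class k is modelled as a Gaussian in the plane of the first
two principal components of the mean-centered response matrix.  Since PCA
is a linear map, Gaussian sensor noise implies Gaussian class scores, so
the model is exact whenever per-sensor noise is Gaussian; skewed or
multimodal sensor marginals violate it.  Only mean-centering is applied —
no unit-variance scaling — so sensors with larger fractional responses
weigh more in the embedding, which is intentional: response magnitude is
signal in screening data.

### Predictive variance inflation

For a class with n_k replicates, the variance of a *new* draw along a
local principal axis, integrating over the uncertainty of the estimated
mean and variance, is

    σ̃²_pred = s² (1 + 1/n_k) (n_k − 1)/(n_k − 2),   n_k > 2,

with s² the unbiased sample variance along that axis.  The factor is
always > 1 and decreases monotonically to 1 as n_k grows (1.6 at n_k = 5).
For n_k = 2 the variance-uncertainty factor diverges; the implementation
then applies only the unknown-mean factor (1 + 1/n_k) and relies on the
shrinkage and eigenvalue floor to absorb the remaining uncertainty — a
conservative, finite choice continuous in spirit with the n_k > 2 branch.
The inflated per-axis variances form a diagonal covariance in the local
frame which is rotated back to global PC coordinates, enlarging each
class ellipse along its own principal directions without reorienting it.
`inflation: unadjusted` skips this step (raw scatter), which produces
optimistic error estimates and is useful only as a sanity check.

### Shrinkage and conditioning

Off-diagonal covariance entries are the least stable under small n_k, so
each inflated class covariance Σ_k is blended toward the pooled covariance
Σ_pool (classes weighted by n_k − 1 degrees of freedom):

    Σ_k ← (1 − λ_k) Σ_k + λ_k Σ_pool .

The intensity λ_k follows the Ledoit–Wolf construction — the estimated
sampling variance of the covariance entries over the squared Frobenius
distance to the target, clipped to [0, 1].  Lacking the class sample
fluctuations at this stage, the sampling variance uses the Gaussian
plug-in Var(S_ij) ≈ (S_ii S_jj + S_ij²)/n_k.  This estimator is a design
choice and is deliberately isolated in one function
(`covariance._lw_intensity`) so it can be swapped.  Finally eigenvalues
are clipped from below at max(10⁻⁶ · λ_max(Σ_pool), 10⁻¹²) — scale-aware,
so the floor adapts to the data's units.  In 1D mode the same pipeline
operates on scalar variances.

### Decision models and their properties

QDA uses the full discriminant g_k(x) = −½ log|Σ_k| − ½ d²_k(x) + log π_k
(d²_k the Mahalanobis distance), with uniform priors — replicate counts
are balanced by design in screening campaigns.  Voronoi assigns the
nearest centroid and is the equal-isotropic-covariance limit of QDA.
Ties break to the lowest class index for determinism.

A caveat worth stating precisely: scaling *all* class covariances by a
common factor c leaves QDA labels unchanged exactly when the class
covariance determinants are equal (the pairwise log-determinant
differences then vanish and the Mahalanobis terms scale uniformly).  When
determinants differ, the boundary shifts by an amount governed by
log(|Σ_a|/|Σ_b|); near-boundary points can then flip under extreme
scaling.  The inflation step multiplies every class by the same factor
(balanced n_k), so its direct geometric effect is confined to this
log-determinant imbalance — the motivation for pairing inflation with
shrinkage rather than relying on either alone.

### Error estimation

Without a hold-out set, the per-class error is estimated parametrically:
draw Monte-Carlo samples from the class's corrected Gaussian, classify
them by direct discriminant evaluation (not grid lookup, avoiding raster
error), and report the fraction assigned elsewhere.  Default 10⁵ draws
per class give a standard error below 0.16 percentage points at worst
(p = 0.5); the long-loop experiments below use 10³–2·10³ draws per class,
trading ~1-point MC noise for speed, which is immaterial when comparing
errors separated by tens of points.  The mean error e(l) is the
unweighted average over classes, in percent.  ARI is computed between the
true labels and the classifier's labels on the measured training samples
themselves.  The decision-region raster exists for visualisation and is
written for the first iteration and the selected working points only;
per-iteration ellipse parameters are always written.

### Sensor scoring and elimination

The ruler thresholds use the classifier family active in the run:
midpoints of consecutive class means under Voronoi, 1D QDA roots under
QDA (variances inflated analogously to the 2D case, then shrunk/floored
in their 1D form; when the quadratic has no real root between the two
means the midpoint is used).  Values exactly on a threshold bin left.
Coincident thresholds (identical class means) are deduplicated and the
degenerate classes share an interval.  Pairwise wFS statistics are
computed on the same bins restricted to the two classes; Δ(a,b) is the
distance between class *sample* centroids along the sensor axis (the
zone-geometry alternative gives the same ordering in the non-degenerate
case and sample centroids are well-defined even when a class zone is
empty), clipped below at 10⁻⁹ of the sensor's data range so confusable
pairs get large but finite weight.  Elimination removes the
lowest-scoring sensor (least stand-alone discriminative power); ties
break by column order.  Boundaries, bins, and the whole embedding are
recomputed every iteration.

### Working point

J(l) = e(l) + η·l with e in percent and η in percent per sensor; defaults
η = 3 (parsimony-leaning) and η = 0.5 (accuracy-leaning).  Ties in J go
to the smaller l.  l*(η) is a non-increasing step function of η; the
`--eta-sweep` output exposes the stable regions.

## Synthetic data

The generator draws class-by-class from specified Gaussians at the
screening conditions: K = 3–6 classes, p = 10–30 sensors, n_k = 3–5
replicates, partial class overlap.  Two standard fixtures:

- **Planted recovery** — two informative sensors carry class means placed
  on a circle with nearest-neighbour distance `separation` (default 5σ,
  phase-offset to keep 1D projections distinct); the remaining sensors
  are pure noise with identical means.  The acceptance experiment runs
  K = 5, p = 10, n_k = 5 over 100 seeds and measures how often the
  planted pair survives last.
- **Inflation stress** — resample a baseline with means unchanged and
  every class covariance multiplied by factor² (factors 2, 5, 10;
  50 replicates per class).  Because PCA is linear, inflating class
  variance in PC space is equivalent to resampling each sensor's
  Gaussian with enlarged variance, so the stress protocol operates in
  sensor space and reruns the full loop.  Working-point error should
  rise monotonically with the factor; the acceptance baseline uses
  separation 6σ so the factor-1 control is nearly separable and each
  inflation step visibly degrades it.

What the synthetic fixtures do *not* emulate: event-level cross-sensor
correlation (classes are sampled with diagonal covariance), sensor drift,
batch effects, and non-Gaussian noise.  Passing tests therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to real-world artifacts that violate
them.

## Numerical choices

- PCA via SVD with a deterministic sign convention (largest-magnitude
  loading entry of each component positive), so reruns are bit-identical.
- The 1D switch triggers on PC1 explained variance strictly greater than
  the 0.95 threshold; the flag is off by default to preserve the 2D
  decision maps.
- All randomness derives from the single config seed through
  per-(iteration, class) seed sequences, making every Monte-Carlo
  estimate reproducible independently of evaluation order.
- Degenerate classes (zero scatter) get identity local frames and are
  repaired by the eigenvalue floor; rank-0 *data* is rejected.
- Problem sizes in the test-suite experiments (p = 8–10 sensor loops,
  10³–2·10³ MC draws; one 30-sensor end-to-end run at 10⁴ draws) were
  chosen to keep the full suite fast while leaving each comparison's
  signal far above MC noise.

## Known limitations

- The embedding is restricted to PC1–PC2 (or PC1); separability living in
  higher components is invisible.  Under strong variance inflation the
  leading-component share drops and this truncation bites hardest.
- Backward elimination is greedy: synergistic sensor pairs whose value
  appears only jointly can be eliminated early.  wFS mitigates but does
  not remove this.
- The error estimate assumes the corrected class Gaussians are adequate —
  it is a model-based estimate for choosing a working point, not a
  cross-validated generalisation error.
- Concatenating sensors measured in separate runs treats them as jointly
  observed; real event-level covariance is then absent from the model.
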