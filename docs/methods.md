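# Methods

`metanorm` benchmarks data-driven normalization methods for LC/MS untargeted
metabolomics peak tables. This note documents the models and procedures the
package implements, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

Throughout, a peak table is a features x samples matrix of non-negative
intensities; per-feature statistics are row statistics, per-sample
corrections are column operations.

## Synthetic data generator

The generator produces two-class case/control studies with pooled QC samples
and known ground truth. Its signal model is

    x_ij = d_j * mu_i * f_ij * exp(b * eta_ij) + a * eps_ij,   clipped at 0,

with log-normal base abundances mu_i (right-skewed, log-mean 5.5, log-SD
1.2), per-sample log-normal dilution factors d_j (log-SD `dilution_sd`), a
multiplicative class effect f_ij = `effect_fold` on the spike-in features in
the case class, and the two-component additive + multiplicative error model
(additive SD `a` in intensity units, multiplicative SD `b` on the natural-log
scale). This error model is exactly the one variance-stabilizing transforms
are built for, which makes the VSN stabilization property directly testable.
QC samples are the pooled mean of the study design. Every sample is
attenuated by exp(`drift_slope` * injection position); study injection
positions are randomized with respect to class (as real designs randomize
run order) while QCs are interleaved evenly — without this randomization a
nonzero drift would masquerade as a class effect.

Missingness is a mixture: a fraction `mnar_weight` of the missing cells is
drawn with probability increasing steeply as intensity decreases (dropout
tracks abundance), the rest uniformly. Only the `affected_features_frac`
(default 0.8) lowest-intensity features can lose cells; the remainder stay
fully observed. This mirrors the reported structure of real tables — 10-40%
missing cells touching up to ~80% of features — and guarantees that a
"shared by all samples" feature set exists, without which MSTUS is
undefined. Defaults (500 features, 60+60 study samples, 12 QCs, 25 spike-ins
at 2-fold, dilution log-SD 0.3, a=5, b=0.15, 20% missing with 70% MNAR,
drift -0.002) are desk-scale but inside the ranges the generator is meant to
emulate.

What the generator does **not** emulate: chromatographic peak shapes,
adducts/isotopes, retention-time misalignment, batch-to-batch level jumps,
or correlated metabolite modules. Tests passing on this generator therefore
certify the algorithmic contracts (invariants, recovery of planted
structure) — not performance on any particular real cohort.

## Pre-processing chain

Order is fixed: QC filtering, then drift correction, then imputation.
Filtering first removes features that would corrupt neighbor distances
during imputation; drift is removed before imputation so it cannot leak into
imputed values.

* **QC filtering.** A feature is dropped when detected in < 20% of QC
  samples, or when its QC relative standard deviation exceeds 30%. The RSD
  cut operationalizes "large variation" with the community-standard
  threshold; both numbers are configurable.
* **Drift correction.** Per feature and batch, a degree-1 loess curve (span
  0.75, 3 robustness iterations) of QC intensity vs injection order is
  fitted; every sample in the batch is divided by the curve value at its own
  injection order and rescaled so the batch QC median is preserved exactly
  (the rescaling divisor is the median of the QC ratios, making the
  invariance hold by construction). Features with fewer than 4 QC
  observations in a batch pass through. If the robustness iterations zero
  out every local weight (possible at very small QC counts) the fit falls
  back to a non-robust pass, then to pass-through.
* **KNN imputation.** Neighbors are features (k = 10). Distances are RMS
  differences over co-observed samples, computed on log2(1+x) values
  centered by each feature's observed mean. A missing cell is imputed as the
  target's observed log-mean plus the inverse-distance-weighted mean of the
  neighbors' deviations from their own means over the target's observed
  columns (zero-distance ties share uniform weights; fewer than k available
  neighbors triggers a warning and uses all). The centered-log formulation
  matters: intensity levels span orders of magnitude, and imputing absolute
  neighbor values transfers the neighbors' level rather than their
  co-variation — on the generator's data that is *worse* than feature-mean
  imputation, while the centered form beats it clearly (the test suite
  measures both RMSEs in a masking experiment). Identical features still
  impute exactly (up to the log/exp round trip).

## The sixteen normalization methods

Eight sample-wise methods remove sample-to-sample variation; eight
feature-wise methods rescale or transform per metabolite to tame
heteroscedasticity. Every method returns both the normalized matrix and a
frozen reference model, so held-out samples can be normalized without
touching the training fit (see "Frozen references" below).

Sample-wise:

* **Linear baseline** — baseline b_i = median over samples; each sample is
  scaled by mean(b)/mean(x_.j).
* **PQN** — optional integral normalization to total 100 first (default on,
  as in the original description), reference r_i = median spectrum, dilution
  d_j = median of the quotients x_ij/r_i, sample divided by d_j. The model
  also records the effective per-sample divisor on the raw scale, which is
  the package's dilution estimate.
* **MSTUS** — total signal over the features shared by all samples
  (sharedness judged on the *pre-imputation* missing mask); output rescaled
  by the mean total so it stays on the intensity scale (pure division via
  flag).
* **Quantile** — classical rank/mean-reference normalization; ties receive
  the mean of the rank-means they span (tie-free cells take the rank-mean
  bitwise exactly).
* **Cyclic loess** — for every sample pair, loess of M = log2 ratio on
  A = mean log2 intensity (span 0.75, degree 1, 3 robustness iterations,
  with a 1% delta shortcut for speed), fit split evenly between the two
  samples; up to 3 cycles or until the largest adjustment falls below 1e-3.
* **Contrast** — log intensities rotated per feature by an orthonormal
  (Helmert) basis whose first axis is the overall level; each of the n-1
  contrast coordinates is loess-smoothed against the level and the fit
  removed; rotation inverted; exponentiated. Non-positive values are first
  replaced by half the smallest positive value (the classical epsilon
  policy; strict mode available).
* **Cubic splines** — baseline = geometric mean spectrum; per sample, 100
  evenly spaced quantile pairs on the log scale anchor a cubic smoothing
  spline (GCV-chosen penalty) mapping sample onto baseline, applied to all
  values, iterated 3 times with rotated quantile offsets; linear extension
  beyond the anchored range keeps tails monotone.
* **Li-Wong** — baseline sample = the one with the median total intensity;
  per sample, a rank-invariant feature set (proportional rank difference
  below 0.005, re-ranked within the set until stable) anchors a loess fit of
  baseline on sample in log space; the full sample is mapped through the
  curve with linear end extension. At desk-scale feature counts a 0.005
  threshold can leave fewer than 10 invariant features, so the threshold is
  doubled (with a warning) until 10 are reached; strict mode errors instead.

Feature-wise (per feature; mu and s are the mean and n-1 standard
deviation):

* auto (x-mu)/s; level (x-mu)/mu; pareto (x-mu)/sqrt(s);
  range (x-mu)/(max-min); vast ((x-mu)/s)(mu/s); power sqrt(x)-mean(sqrt(x))
  (centering after the square root). Degenerate denominators raise by
  default; a drop-with-warning policy exists.
* **Log transformation** — elementwise log (default base 2; base e and 10
  available). Non-positive values either raise (strict) or are replaced by
  half the smallest positive value; the epsilon is stored in the model so
  held-out samples reuse it.
* **VSN** — per-sample affine arsinh transforms h_j(x) = arsinh((x-a_j)/b_j)
  fitted so all samples match a common per-feature reference profile. The
  fit maximizes a trimmed Gaussian *profile likelihood*: for each sample,
  m/2 log RSS minus the log-Jacobian sum log h'(x) with
  h'(x) = 1/sqrt(b^2+(x-a)^2), where trimming (default keep fraction 0.9)
  retains the features with the smallest squared residuals. The Jacobian
  term is essential — a pure (trimmed) least-squares criterion is
  scale-degenerate, since compressing the transform shrinks every residual;
  during development the pure-LS alternation visibly drifted and never
  stabilized the variance. All samples' (a_j, log b_j) are optimized
  *jointly* by L-BFGS with analytic gradients (the per-sample alternation
  against the evolving mean reference has a continuum of near-fixed points
  and stalls); the trimmed sets are then refreshed and the fit repeated
  until they stabilize (at most `max_iter` rounds, parameter tolerance
  1e-6). Output is on the natural-log-like scale. On the generator's noise
  model (a=5, b=0.15) the fitted scale parameters land near the theoretical
  optimum a/b and the Spearman correlation between feature SD and mean drops
  from above 0.5 to below 0.1 in absolute value (measured by the test suite
  and the acceptance script).

### Frozen references

Held-out (validation) samples are always normalized with parameters frozen
on training data: stored baselines (linear baseline, cubic splines,
Li-Wong), the stored median reference and integral flag (PQN), the stored
shared-feature set and mean total (MSTUS), interpolation into the stored
reference distribution (quantile), stored per-feature scaler statistics and
log epsilon, and the stored VSN reference profile (each new sample gets its
own (a_j, b_j) fitted against that fixed profile). For methods whose
training fit is intrinsically joint — cyclic loess and contrast — exact
two-path identity is impossible; their frozen path adjusts each new sample
against the stored mean log2 reference spectrum by the same M-A loess, which
agrees closely with the joint fit on data with the dilution structure these
methods assume (median |delta log2| below 0.05 in tests). All other methods
reproduce their training output exactly (1e-9) when the frozen model is
re-applied to the training samples.

## Evaluation

Differential features are the intersection of PLS-DA VIP > 1 and two-sample
t-test p < 0.05. The t-test is Welch's by default (a pooled-variance flag
exists); no multiplicity correction is applied, mirroring the raw p < 0.05
rule (a BH flag exists but is off). PLS-DA uses a NIPALS fit with the class
as a 0/1 response, 2 components by default, with features auto-scaled
*inside* the fit only; VIP_i = sqrt(p * sum_a SS_a (w_ia/||w_a||)^2 /
sum_a SS_a) with SS_a the Y sum of squares explained by component a, so the
mean squared VIP is 1 identically. An empty intersection raises by default;
the benchmark uses a logged top-10-VIP fallback so a sweep never dies on one
degenerate cell.

The classifier is an RBF SVM tuned by stratified 10-fold cross-validated
accuracy over C in {0.1, 1, 10, 100} and gamma in {1e-3, 1e-2, 1e-1, 1}/p (a
reduced 2x2 grid is provided for sweeps), refitted on the full training
data. Features are standardized inside the classifier with training
statistics — the convention of the standard SVM implementations this
procedure follows; without it the RBF kernel saturates on intensity-scale
features. Folds are reduced with a warning when the smaller class cannot
fill ten.

Validation scoring uses decision threshold 0 for the confusion counts,
ACC = (TP+TN)/(TP+FP+TN+FN) (asserted against the counts on every result),
the full decision-value sweep for the ROC, and the trapezoid AUC (equal to
the Mann-Whitney statistic; verified against an O(n^2) concordance oracle).

## Benchmark and categorization

The study samples are split once into training and validation by stratified
random sampling (seeded). Sub-datasets at 10% ... 100% of the training set
(class ratio preserved) are drawn per class from k-means strata (k = 10 per
class by default — stable proportional strata at the smallest class counts):
each sub-dataset draws from every cluster proportionally to cluster size via
largest-remainder rounding. Sub-datasets are nested by default (each
fraction extends the previous; cluster members are randomly ordered once and
taken as prefixes, each next draw going to the cluster furthest below its
quota), which removes sampling noise from the size-trend curves; independent
draws are available.

Every (method, size) cell normalizes the sub-dataset, freezes the reference,
normalizes the fixed validation set with it, selects features, tunes the
SVM, and records ACC, the ROC and the AUC. Cell failures are logged and
skipped, and finished cells are cached on disk so interrupted sweeps resume.
One seed drives the split, the subsampling, and the CV folds; identical
seeds give identical AUC matrices. Methods that take logs internally receive
the half-minimum epsilon policy inside the benchmark because clipped
intensities legitimately contain zeros.

Each method's 10-dimensional AUC vector is compared by Manhattan and
Euclidean distance; missing cells are imputed by the method's row mean (with
a warning) for clustering only. Ward's minimum-variance linkage is computed
with the Lance-Williams recurrence on squared dissimilarities (the
"ward.D2"-equivalent variant, stated explicitly because the two common Ward
implementations differ). Cutting the dendrogram at k = 3 and ranking
clusters by mean AUC yields group A (superior), B (good) and C (poor);
within B, B1 contains methods whose AUC reaches the top tertile of all
methods on at least one size (tertile = best ceil(n/3) methods per column),
B2 the rest. Group names are tied to mean-AUC ranks, never to dendrogram
drawing order. The report (markdown, with optional PNG heatmap/ROC/boxplot
figures and the dendrogram embedded as Newick) lists the AUC table with the
per-column extremes highlighted.

## Numerical choices and degenerate inputs

* Standard deviations use the n-1 denominator throughout.
* Loess everywhere is degree 1, span 0.75 (Li-Wong uses 0.4 over its
  invariant set), 3 robustness iterations.
* Quantile ties: mean of the spanned rank-means; quantile frozen
  application interpolates at (r-1)/(p-1).
* Zero-distance KNN/loess ties: uniform weights.
* Newick leaf labels are quoted so method names with underscores survive
  the unquoted-underscore convention; branch lengths are merge-height
  differences.
* Non-positive input to log-based methods: strict error naming the cells,
  or half-minimum replacement where the classical method prescribes it.
* PeakTable requires >= 2 features and samples, unique IDs, no negative
  observed intensities, and keeps NaN exactly where the missing mask is set.

## Problem sizes used by the test suite and acceptance script

The shipped analyses run the default generator study (500 features, 132
samples) through the full 16 x 10 benchmark with the reduced SVM grid, plus
dedicated simulations for dilution recovery (500 x 120), variance
stabilization (500 x 60), null calibration (1000 features, 50 vs 50) and a
label-permutation control (300 x 300). These sizes were chosen so each
quantity is measured with adequate statistical resolution at desk scale.

## Known limitations

* The generator's simplifications listed above; in particular no
  batch-level jumps, so multi-batch drift correction is exercised only by
  synthetic within-batch drift.
* Cyclic loess cost grows with the square of the sample count (all pairs,
  every cycle); it dominates the benchmark wall time.
* The VSN trimmed profile likelihood is a self-contained variant of the
  classical variance-stabilization scheme, not a re-derivation of the
  original array-background likelihood.
* With very small validation sets the ROC is coarse; AUC granularity is
  1/(n1*n2).
* k-means subsampling uses Euclidean distance on standardized log
  intensities; other embeddings may stratify differently.
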