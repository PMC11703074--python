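# Methods

`geomstate` implements a state-space analysis of working-memory task
representations: it asks whether the *arrangement* of condition-mean neural
patterns mirrors the geometry of the task design, rather than merely whether
conditions are decodable. This note documents the models, the estimators,
the synthetic-data generator used to validate them, and the numerical and
design choices that were genuinely open.

## Task structure and condition geometries

The emulated task crosses two binary goal dimensions — size (bigger/smaller)
and color (redder/greener) — into four goals, applied to sample stimuli drawn
from a 3 × 3 grid of size and color bins. A counterbalanced session has
4 × 3 × 3 × 18 = 648 trials in 12 blocks. The color dimension of the stimulus
set is a morph ladder of 150 rendered variants with the 30 most extreme
discarded, leaving 120 usable steps.

Two reference geometries follow from the design:

* **Goal square** — four goals at the corners of a square, connected in the
  order bigger-redder → bigger-greener → smaller-greener → smaller-redder, so
  consecutive vertices differ on exactly one dimension (an edge walk, never a
  diagonal).
* **Stimulus hexagon** — the 3 × 3 stimulus grid loses its middle color bin
  (a 9-point grid has no closed non-crossing walk through interior points),
  leaving a 3-size × 2-color lattice walked along its perimeter:
  (small,green) → (mid,green) → (big,green) → (big,red) → (mid,red) →
  (small,red). This order is the only one in which grid-adjacent conditions
  are polygon-adjacent.

## The circularity index

For each analysis the condition-mean matrix (n_conditions × n_channels) is
column-standardized (each channel z-scored across conditions; zero-variance
channels are zeroed rather than dropped, keeping channel indexing stable) and
reduced to its top-2 principal components. Condition means are projected
into that plane, connected in the fixed design order, and scored by

    C = 4π · Area / Perimeter²

computed from the shoelace formula (|signed area| of the vertex cycle) and
the edge-length sum. C = 1 for a circle, π/4 ≈ 0.785 for a square — the
maximum over all quadrilaterals — and 0 for degenerate (zero-perimeter or
collinear) configurations. Self-intersecting walks are deliberately *not*
repaired: the signed lobes of a crossed quadrilateral cancel, so
task-incongruent orderings score near zero, which is precisely the design
signature the statistic must reward. PCA scores are not whitened; whitening
would push every geometry toward a circle and inflate C.

Numerical notes:

* The per-window/per-permutation hot path computes PCA scores from the
  eigendecomposition of the small n_cond × n_cond Gram matrix of the
  standardized data (identical to SVD scores, batched over windows); the
  public `fit_subspace`/`project` API uses an explicit SVD and is
  cross-checked against scikit-learn's PCA in the tests.
* Per-channel standardization is the analysis convention but it is *not*
  exactly invariant to orthogonal rotations of channel space (per-channel
  variance scaling breaks rotational symmetry). `fit_subspace(...,
  standardize=False)` provides the centered-only variant, for which the
  invariance is exact; the tests verify both the exact property there and
  approximate stability of the standardized default.
* C itself is exactly invariant to translation, rotation, reflection and
  uniform scaling of the projected vertices.

## Time courses and cluster permutation inference

Epochs run −500…+4300 ms around goal-cue onset at 250 Hz, with task epochs
Goal cue 0–400, Delay 1 400–1700, Sample 1700–2300, Delay 2 2300–3800,
Response 3800–4300 ms. The epoch is tiled with non-overlapping 80-ms windows
anchored at the epoch start (trailing partial windows dropped), giving 60
points per trial. Within a window, trials are resampled stratified by
condition (with replacement, preserving per-condition counts — resampling
without a replacement statement is read as the variance-valid choice at
small counts), the pipeline above runs per resample, and the resample mean
(default 10) is the window's value.

Significance uses a cluster-based permutation test: labels are shuffled
within participant, the identical resampling protocol re-runs (default 5,000
permutations), per-participant null curves are averaged across participants,
and the per-window (1−α) null quantile forms the pointwise threshold
(a pooled-quantile variant is available behind a flag). The cluster
statistic is the *run length* of contiguous supra-threshold windows; each
observed run receives p = (1 + #{null max-run ≥ size}) / (1 + n_perm), which
is the calibrated finite-sample version of thresholding at the null's 95th
percentile (also reported). Inference is one-sided (circularity has a
positive-signal alternative); the trial-split difference test is two-sided
by default.

The behavioral-relevance split contrasts the bottom vs top quartiles (or
halves) of the combined error — the sum of z-scored absolute size and color
errors (a constant error column is excluded with a warning). Both splits are
projected into the subspace fitted on *all* trials so the comparison is
fair; the permutation null reshuffles good/bad membership within condition,
which keeps every polygon vertex covered under the null. Resample draws are
keyed to the trial-index set rather than the split's role, so swapping the
definitions of good and bad negates the difference curve exactly.

Control analyses: motor relabeling takes the sign pair of (final − initial)
response-object values as a 4-level adjustment-direction label (zero
differences are excluded and logged); incorrect-memory relabeling keeps only
trials whose adjustment direction contradicts the cued goal and relabels them
by the actual direction. Both feed the standard pipeline unchanged.

## RSA

The 2D goal model RDM counts mismatching goal dimensions (0 / 0.5 / 1); the
conjunctive model sets all between-goal distances to 1. Because the two are
positively correlated once conditions are enriched (goal × stimulus bins),
model–data similarity is assessed both separately (Spearman, average-rank
ties) and competitively (partial Spearman, each model partialed on the
others; significance per time point without cluster correction).

Data RDMs are cross-validated correlation distances: channels are z-scored
across trials, trials are stratified into 4 folds, and for every condition
pair the correlation distance between condition means from *disjoint* folds
is averaged over all ordered fold pairs (which makes the matrix exactly
symmetric). Cross-validation makes the distance an unbiased but possibly
negative estimator; negative entries are retained. Two quirks worth knowing:
the diagonal is fixed at 0 by RDM convention (the cross-validated
within-condition distance is itself a useful noise diagnostic), and the
standardization centers the fold × condition cells, so pure-noise condition
pairs sit at an expected distance of 1 + 1/(K−1) (K = folds × conditions),
not exactly 1 — the tests assert the exact form.

## Coherence (frontomedial theta coupling)

Cross-spectra between the frontal midline seed (Fz) and every posterior
channel are estimated per epoch by complex Morlet convolution at 1–12 Hz in
1-Hz steps. The nominal 5-cycle wavelet is capped at freq/2 cycles below
10 Hz so the slowest wavelets fit within the epoch (the standard
low-frequency taper). The weighted phase lag index

    wPLI = |E[Im S]| / E[|Im S|]

is computed across epochs per seed–target pair and then averaged over
posterior targets; cells with no imaginary energy are set to 0. wPLI lives
in [0, 1], is insensitive to zero-lag (volume-conduction-like) coupling, and
is invariant to swapping seed and target. Maps are baseline-corrected per
frequency against the −500…0 ms pre-cue window (configurable; the window is
a package choice) and tested across subjects with a one-tailed sign-flip
cluster permutation test over the time–frequency plane. Significant
clusters restricted to 4–7 Hz become masks; each subject's mean
baseline-corrected coupling inside the mask is correlated (one-tailed
Spearman, BH-corrected) with per-epoch circularity, and the same path serves
the 1–3 Hz delta control.

## Volumetric searchlight and beta-series connectivity

Trial-wise beta volumes (synthetic here; user-supplied NIfTI in general) are
analyzed with a searchlight: for every in-mask voxel, the in-mask voxels
within 9 mm (center-to-center, inclusive; edge spheres keep their in-mask
members, spheres under 3 voxels are skipped) act as channels for the
standard condition-geometry pipeline. Group correction follows a
bootstrap-of-permutations scheme: each subject contributes label-shuffled
searchlight maps (100 per subject at full scale); a group-null draw averages
one random permuted map per subject; voxels where the true group mean
exceeds the per-voxel 99th null percentile are clustered by face adjacency;
and the max-cluster-size distribution over null draws calibrates cluster
p-values. ROI robustness repeats the circularity estimate as the mean of 20
stratified trial-bootstrap replicates over all ROI voxels against a
label-shuffled null built the same way. Beta-series functional connectivity
averages betas within each ROI per trial and Pearson-correlates ROI pairs
across trials; declared connection families (e.g., the 9 goal–goal or 12
goal–stimulus pairs) are tested against behavior with Spearman, BH
adjustment within family, and an optional JZS Bayes factor.

## The synthetic-data generator

Every inference stage is validated by parameter recovery, so the generator
is first-class tested code. Its signal model: a trial in condition c with
latent plane coordinates u_c contributes gain·a(t)·(M u_c) to the channels,
where M is a channels × 2 mixing with orthonormal columns and a(t) is a
piecewise-constant gain over the task epochs (separately configurable per
channel group, to emulate frontal-early/posterior-late activation). Noise is
i.i.d. Gaussian. Under this model PCA provably recovers the planted plane,
so the planted polygon's analytic circularity is the pipeline's ground
truth.

One generator detail is load-bearing: the default mixing is *equal-gain* —
loading angles equally spaced within each channel group, with a random
rotation and channel permutation. Because the analysis z-scores each channel
across conditions, only equal per-channel signal power passes through
standardization as a pure global scale; an unconstrained random mixing would
make even noise-free recovery land slightly below the analytic value.
Unconstrained QR mixing remains available (`equal_gain=False`) for
robustness checks.

Behavioral errors are drawn with a per-trial scale
noise_sd · exp(−coupling · z(strength)), so stronger planted geometry means
tighter errors: with coupling > 0 the bottom quartile of |error| carries the
strongest geometry, with coupling = 0 errors are independent of it. A
mean-shift coupling was rejected because any nonzero mean *inflates* the
expected absolute error, inverting the intended direction. Coupling acts on
the per-trial signal gain, never on label identity, so labels stay
exchangeable under the null. An optional lapse rate flips response
directions to create the incorrect-memory trials.

Trial-wise beta volumes plant the same latent geometry inside a 9-mm sphere
on a 3-mm isotropic grid (pure noise outside). The response object starts at
a random continuous value and moves to the goal-consistent target, providing
the initial/final values the motor relabeling consumes.

All randomness descends from one user seed via `numpy.random.SeedSequence`
splitting; identical seeds reproduce byte-identical tables, arrays and JSON
outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: oscillatory background and 1/f spectra,
channel covariance from volume conduction (except as explicit zero-lag
surrogates in the coherence tests), non-Gaussian artifacts, trial-order and
learning effects, hemodynamic spatial autocorrelation, and any anatomical
realism in the volumes. Recovery results certify the *estimators*, not the
neuroscience.

## Presets and problem sizes

Two presets separate inference scale: `paper_faithful` (5,000 permutations,
10 resamples, 10,000 bootstraps, 100 label shuffles per subject) and
`scaled_down` (500 / 5 / 500 / 20), which is the scale the package's own
test suite and calibration studies run at. The calibration study uses 200
simulated null sessions (108 trials, 8 channels, 20 windows) and bounds the
familywise error by the nominal level plus twice the Monte-Carlo standard
error; the recovery study uses 10 seeds at 216 trials and 16 channels; the
searchlight study uses 6 subjects on a 20³ grid. Every run records its
resolved configuration and output hashes in a manifest.

## Known limitations

* Group-concatenated PCA (`group_concatenate`) is a visualization helper
  only; it is not part of the validated inference path.
* The searchlight RSA variant is a composition of the neighborhood machinery
  with the RSA statistic, not a separately validated method.
* Cluster extents, real-data correlations and coordinate tables from any
  particular recording campaign are outside what synthetic validation can
  reproduce; the package certifies calibration and recovery, not empirical
  findings.
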