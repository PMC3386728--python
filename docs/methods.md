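# Methods

## Pipeline overview

`aromafuse` classifies fruit measurements into six (harvest week, storage
day) classes from two sensing modalities. The stages, in order:

1. **Sniff-cycle feature extraction.** A sniff cycle is a timed recording
   of 32 resistance channels: a 10 s baseline-purge window followed by a
   50 s sample-draw window. The baseline S₀ of a channel is the *mean*
   resistance over the baseline window (noise-robust, versus taking the
   last sample), S_max the maximum over the draw window, and the feature
   is the fractional response S_frac = (S_max − S₀)/S₀ — dimensionless
   and invariant to channel gain, which suppresses sensor-to-sensor level
   differences and slow drift. Each fruit is sniffed five times and the
   first sniff is discarded (residual volatiles from the previous sample);
   each retained sniff is one analysis row. A fruit contributing a single
   sniff is dropped with a warning.
2. **Acoustic features.** FI = M^(2/3) · f₀² / s from a tap's resonance
   frequency f₀ (Hz) and the fruit mass M (g); the scaling factor s is a
   config parameter (default 1.0 — every downstream use is scale-invariant
   after autoscaling). The impact-based AFI is accepted as an
   instrument-supplied input column. FI and AFI are averaged over the
   4 locations × 3 repeats of a fruit and the per-fruit averages attach to
   each of its sniff rows.
3. **Autoscaling.** Every column is scaled to zero mean, unit sd (n−1
   denominator, the convention of mainstream statistics packages). Scaling
   statistics are recorded so held-out rows are transformed with training
   statistics. Zero-variance columns are dropped with a warning.
4. **Fusion.** The two scaled blocks are concatenated column-wise
   (32 + 2 = 34 variables) and the combined matrix is autoscaled once
   more. The second pass is near-identity but guarantees an exactly
   standardized fused table whatever the provenance of the inputs; its
   statistics are kept so either block is recoverable to 1e−8.
5. **Screening.** Univariate Wilks' lambda per variable,
   Λ_j = SS_within,j / SS_total,j, with its exact one-way ANOVA
   equivalent F_j = ((1 − Λ_j)/Λ_j)·((n − g)/(g − 1)) on (g−1, n−g)
   degrees of freedom. Variables with F-test p > α (default α = 0.05) are
   dropped: with six balanced classes of 80 this keeps any variable
   carrying real class signal and removes only noise columns.
6. **PCA** (exploration): eigendecomposition of the sample covariance;
   the retained dimensionality is the smallest k whose cumulative
   explained-variance ratio reaches 80 %.
7. **LDA.** Discriminant directions solve S_b v = λ S_w v (between- versus
   pooled within-class scatter), sorted by decreasing λ and normalized to
   unit pooled within-class variance. Classification uses Fisher's linear
   discriminant functions with equal priors (the design is balanced);
   exact score ties go to the lowest class label. Leave-one-out CV refits
   the model for every held-out row. A singular S_w is ridge-regularized
   (1e−8 · trace/p on the diagonal) with a warning — relevant only when
   p approaches n, as in deliberately tiny test configurations.
8. **CLNN.** A competitive layer of S = 6 neurons clusters the first
   three LDA discriminant scores (three scores suffice here and keep the
   representation plottable; the count is configurable). Net input
   n_i = −‖p − w_i‖₂ + b_i — the unique form for which the maximum
   zero-bias net input is 0, attained when the input equals a weight.
   Winner-take-all with lowest-index tie-break; the winner moves by the
   Kohonen rule with constant α (default 0.1 for pipeline training; 0.5
   reproduces the textbook single-step example; an optional per-epoch
   multiplicative decay damps the constant-α limit cycle when exact
   centroid convergence is wanted). Conscience bias learning tracks
   running win frequencies c_i ← (1−λ)c_i + λ·[i won] (λ = 0.001) and
   sets b_i = e^(1 − ln c_i) − e, so persistently losing neurons gain
   bias and re-enter the competition. Training runs 200 epochs × 3
   repeats (shuffled presentation each epoch); the repeat with the lowest
   quantization error (mean distance of each row to its winning weight)
   is kept. Everything is deterministic under a fixed seed.
9. **Cluster detection and evaluation.** After training, rows are
   assigned to their winning neurons. Active neurons whose weights lie
   within 2× the quantization error of each other are merged into one
   *detected cluster* — two prototypes inside the same point cloud are
   one group, not two. Each detected cluster takes the majority class of
   the rows its neurons win (ties to the lowest label); the number of
   distinct classes over detected clusters is the reported
   `n_classes_detected`. Accuracy uses a stratified 25 %/75 % split: LDA
   and CLNN are fitted and mapped on the 120 training rows only, and
   accuracy is measured on the 360 held-out rows.

## Synthetic data: what it emulates, and what it does not

The generator draws 480 rows — six balanced classes of 80, organised as
20 virtual fruits × 4 retained sniffs per class — as class mean plus
isotropic Gaussian noise per block (e-nose sd 1.0 per channel). The class
means encode the study's structure:

* the three week-7 ("Green") e-nose means each activate a different
  block of channels, pairwise ≥ 6 noise sds apart and ≥ 6 sds from the
  common week-8 pattern;
* the three week-8 ("Mature") e-nose means differ by ≤ 0.5 sds — a ripe
  fruit's headspace barely changes over storage, so the e-nose alone can
  resolve at most four groups (verified by an exact nearest-class-mean
  oracle on the noiseless means);
* the acoustic (FI, AFI) means follow the measured per-class firmness
  averages of the motivating study: Green firmer than Mature on day 2,
  order reversed by days 4 and 7, with a steep day-2 → day-4 drop. The
  acoustic noise sd is 0.2 index units, placing the closest day-differing
  pair (week 8, day 4 vs day 7) at 6.6 sds — the minimal separation
  consistent with the generator's invariant that firmness resolves
  storage days. (A noise sd of 1.0 on those printed means would
  contradict that invariant, so 0.2 is the default.)

Raw sniff cycles are simulated as first-order rises
R(t) = S₀(1 + A(1 − e^{−(t−10)/τ})) with τ = 10 s, ≥ 99 % of plateau by
the end of the draw, and amplitudes calibrated so the extracted
fractional response equals the class mean in the noiseless limit.

The generator does **not** emulate humidity/temperature drift, purge
dynamics, headspace depletion over repeated sniffs, fruit-to-fruit random
effects (rows are iid within class), or non-Gaussian sensor noise.
Passing results therefore demonstrate that the pipeline recovers the
designed class geometry, not that it would meet the same accuracies on
instrument data.

## Design choices where the design was open

* **CLNN weight initialization: farthest-point (maxmin) from training
  rows**, random start per repeat. Discriminant-score clusters here
  differ in separation by two orders of magnitude (≈ 6 to ≈ 100 within-
  cluster sds). The conscience bias of a neuron that still wins a few
  rows saturates at e/c − e with c bounded below by its win rate, so
  bias learning alone cannot move a surplus prototype across the largest
  gaps: networks started with all weights coincident at the data
  midpoint were observed to converge with two prototypes in one cluster
  and none in another. Farthest-point seeding guarantees initial cluster
  coverage; midpoint and uniform-box initialization remain available.
* **Merged-cluster class mapping.** Counting distinct classes over
  per-neuron majority maps overstates the detected group count when
  several classes coincide in score space (each surplus prototype in the
  collapsed cloud picks an essentially random plurality class). Merging
  co-located prototypes first (threshold 2× quantization error, chosen
  from the geometry: intra-cloud prototype distances ≈ 1× QE,
  between-cluster distances ≥ 4× QE here) yields the honest count: four
  detected groups on the e-nose arm, six on the fused arm.
* **Repeat selection** by lowest quantization error among the three
  training repeats.
* **Equal LDA priors** (balanced design) and lowest-label tie-breaks
  everywhere, for deterministic reporting.
* **Problem sizes.** Tests and the acceptance script use the study-scale
  dataset (480 rows; leave-one-out refits all 480 folds) and five
  generator seeds for stochastic summaries; property tests use small
  synthetic instances sized for sub-second oracle comparisons.

## Numerical notes

* Autoscale: idempotent to 1e−10; commutes with row permutation.
* LDA is invariant in its assignments to any common invertible affine
  transform of the features; the generalized eigenproblem is solved with
  scipy's symmetric solver.
* Wilks Λ computed from scatter sums and from inverting the F identity
  agree to 1e−10; scipy's F distribution supplies p-values.
* Degenerate inputs: zero-variance columns (dropped in autoscale,
  error in Wilks), single-sniff fruits (dropped, warning), classes with
  < 2 rows (error), LOO folds that would empty a class (skipped,
  warning), non-positive baselines (error).

## Known limitations

* The conscience constants (λ = 0.001) and the merge factor (2.0) are
  tuned to well-separated cluster geometries; heavily overlapping
  clusters would need a merge criterion based on assignment densities
  rather than prototype distances.
* Constant-α Kohonen training converges to a limit cycle, not a point;
  quantization-error comparisons between repeats inherit that jitter.
* The stratified split uses 25 % for both LDA and CLNN fitting; with
  only 20 training rows per class the LDA within-class scatter of the
  34-variable table is near-singular and relies on the ridge guard.
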