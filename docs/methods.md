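# Methods

`kinescreen` re-implements, as a tested pipeline, a movement-biomarker
analysis that discriminates children with autism spectrum disorder (ASD)
from typically-developing (TD) children using depth-camera pose streams
recorded during a staged stimulation session. This note documents the
models, the parameters that matter, the synthetic-data design, and the
numerical and design choices that were genuinely open.

## Data model

The input is the output shape of a BODY_25-style pose estimator on RGB-D
video: per frame, 25 joints with image coordinates `(u, v)` in pixels, a
depth `z` in meters and a detection confidence `c ∈ [0, 1]`. A session
follows a fixed schedule of six segments — a 120 s baseline before each of
three 160 s stimulus conditions (visual `V`, visual-auditory `VA`,
visual-auditory-olfactory `VAO`; 840 s total). Joints are partitioned for
analysis into head {15, 16, 17, 18}, trunk {1, 8}, arms {2–7}, legs {9–14}
and feet {19–24}; the nose (joint 0) belongs to no analysis group by
default because the analysis partition excludes it (an `include_nose`
option restores it to the head set).

Back-projection to 3D uses the pinhole model `X = (u − cx) z / fx`,
`Y = (v − cy) z / fy`, `Z = z`. Intrinsics default to
`fx = fy = 600, cx = 424, cy = 240` (plausible for an 848×480 depth
sensor); they only need to be self-consistent between forward and backward
projection, so their exact values never affect the analysis of data
generated by this package. Frames are assigned to segments by the
half-open convention `[start, end)`, which makes every frame's assignment
unambiguous.

## Movement features

For each subject, joint and segment: samples with confidence strictly
below 0.5 are discarded (a sample at exactly 0.5 is kept); the joint's 3D
displacement is the Euclidean distance between consecutive frames; the
feature is the arithmetic mean of those displacements, in meters per
frame step.

Two details are deliberate:

* **Gap handling.** Displacements are computed only between retained
  samples at *adjacent original frames*. Pairing across a confidence gap
  would integrate motion over the gap and fabricate large displacements,
  so gap pairs contribute nothing. A cell with no surviving pair is
  missing, not zero.
* **Imputation.** Missing cells are filled with the column median (and
  counted). A column missing for every subject is a hard error. Frame-rate
  normalisation (meters per second instead of per frame step) exists as a
  flag and defaults to off.

## Joint-level statistics

Per (joint, segment) cell, a Shapiro–Wilk screen per group justifies the
nonparametric route, and the two groups are compared with the two-sample
Wilcoxon rank-sum (Mann–Whitney U) test, two-sided: exact null
distribution when both groups have ≤ 20 untied values, tie-corrected
normal approximation otherwise. Significance tiers use the conventional
stars (`*` p < 0.05, `**` p < 0.01, `***` p < 0.001). The groups are
independent samples of unequal size, so the unpaired rank-sum test is the
valid choice; a `paired` escape hatch runs the signed-rank test on
equal-length data. No multiple-testing correction is applied by default
(to mirror the analysis being reproduced across ~150 cells); a
Benjamini–Hochberg option exists.

## Classification stack

For each of the 24 models (6 joint sets × 4 stimulus sets):

1. **PCA** on the raw feature matrix keeps the smallest number of
   components whose cumulative explained-variance ratio reaches 0.95.
   By default the PCA is fit globally, before the cross-validation loop,
   reproducing the replicated pipeline's stated order despite its mild
   leakage; `pca_scope="per-fold"` provides the leakage-free variant.
   Component signs follow a deterministic convention (largest-magnitude
   loading positive).
2. **LOSO cross-validation**: each subject is held out once. The training
   block is normalised per dimension by `(x − median) / MAD`, where the
   MAD is the raw median absolute deviation *without* the 1.4826
   consistency factor (the factor is a monotone rescale absorbed by the
   kernel width anyway); zero-MAD columns pass through centered and
   flagged. The held-out row is transformed with the training statistics.
3. **Hyperparameters**: cost and gamma of the Gaussian C-SVM share one
   grid of 7 logarithmically spaced values on [0.1, 1000]. Each fold
   picks its pair by stratified 3-fold accuracy on its training block
   (ties prefer the smaller cost, then the smaller gamma).
4. **Feature ranking**: nonlinear SVM-RFE with correlation bias reduction
   (below) ranks the PCA features on each fold's training block; the
   median rank across folds orders the features.
5. **Model selection**: candidate subsets are nested top-k prefixes of the
   median-rank order. The reported configuration maximises the LOSO
   Cohen's kappa over k, each fold predicting with its own (cost, gamma);
   ties prefer fewer features, then higher accuracy. An alternative view
   that optimises a single global (cost, gamma) jointly with k over the
   full LOSO surface is recorded alongside (`grid_*` fields) but kept out
   of the headline metrics: selecting the maximum of ~k·49 correlated
   LOSO kappas inflates the reported kappa by ≈ 0.4 under a pure-noise
   cohort, whereas the nested view stays near zero (≈ 0.1–0.2 averaged
   over 20 null seeds, measured by the acceptance suite and script). The
   same caveat applies to any published number produced by the global
   search.

Reported metrics: accuracy, TPR (sensitivity toward ASD), TNR
(specificity toward TD), and Cohen's kappa
`(p_o − p_e)/(1 − p_e)` with `p_e` from the marginal products. With the
group sizes fixed, printed TPR/TNR identify the confusion counts uniquely
(`tp = round(TPR·n_ASD)`), which is what `metrics_from_rates` exploits to
rebuild accuracy and kappa from class-wise rates.

### Nonlinear SVM-RFE with correlation bias reduction

Feature `i` is scored by the dual-objective change at fixed dual
coefficients when the kernel is recomputed without it:

    DJ(i) = ½ aᵀK a − ½ aᵀK₍₋ᵢ₎ a,      K_st = exp(−γ‖x_s − x_t‖²)

over the support vectors, where `a` folds the labels into the dual
coefficients. For the Gaussian kernel, removing a feature subset S
factorises as `K₍₋S₎ = exp(−γ(D − Σ_{i∈S} d_i))` with `d_i` the
per-feature squared differences, so each elimination round costs one SVM
fit plus array work. The feature with the smallest DJ is eliminated;
rank 1 is eliminated last.

Correlated features mask each other under this criterion (removing one
leaves its partners' information in the kernel), so jointly informative
groups can be discarded. CBR groups features whose pairwise |Pearson r| on
the training block reaches 0.9 (connected components of that graph) and
scores every member by removing the whole group; ties within a group fall
back to the individual score, then the feature index, so the procedure is
fully deterministic. With a grouping threshold above 1 the procedure
reduces exactly to plain nonlinear SVM-RFE.

A caveat found while validating the bias demonstration: with exactly two
*identical* copies, each elimination refit restores the surviving copy's
importance, so the best copy ends near rank 1 with or without CBR. The
bias is demonstrated with three strongly correlated copies (r ≈ 0.94)
among four noise features in a high-cost regime (C ≈ 46.4, γ ≈ 0.46, both
grid values), where plain RFE demotes the best copy in about half the
replicates and CBR keeps one copy at rank 1 in ≥ 90%.

### Fast SVM path

The selection stage fits tens of thousands of SVMs on ≤ 46 samples, where
scikit-learn's per-call validation dominates. The hot loops therefore call
scikit-learn's low-level libsvm binding with precomputed Gram matrices; a
unit test asserts prediction equality with `sklearn.svm.SVC` on random
problems, and the code falls back to `SVC` if the binding is unavailable.

## Synthetic cohorts

No recording data accompany the analysis being reproduced, so a generator
supplies labelled two-group cohorts with exactly the statistical structure
the pipeline consumes. Each joint follows an anchored Gaussian random walk
in 3D: `position(t+1) = position(t) + ε`, `ε ~ N(0, σ² I₃)` with
`σ = base_step_sd · λ(group, joint, segment)`. Defaults are the study
conditions: 22 ASD / 25 TD subjects, 30 Hz, `base_step_sd = 3 mm`,
confidence drawn high (uniform around 0.9) with probability `1 − p_drop`
and uniform on [0, 0.5) otherwise (`p_drop = 0.05`), so the 0.5 filter
separates dropout from retention exactly. The depth coordinate is
reflected at a 0.2 m floor so the forward projection stays defined on long
sessions; reflection preserves step lengths except at (rare) boundary
crossings.

The random walk is chosen over oscillatory kinematics because the
analysis consumes only the mean inter-frame displacement, which the walk
controls in closed form: the step length is chi-distributed with 3
degrees of freedom, so the expected mean displacement is
`σ · 2√(2/π) ≈ 1.5958 σ`. Every downstream stage is therefore checkable
analytically. A `duration_factor` scales all segment lengths (tests and
the acceptance script use 0.1, an 84 s session, so cohorts build in
under a second); the type-I-error replicates use 0.025.

The `paper_like_effects` preset encodes the qualitative direction of the
group differences the joint-level analysis targets — elevated head
movement in all three stimulus conditions (λ = 3), elevated leg movement
mostly under `V` (λ = 1.5), a mild trunk elevation under `V` (λ = 1.3) and
one head joint moving less during two baselines (λ = 0.7). The magnitudes
are a design choice; no calibration target exists.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: between-subject heterogeneity (optional
`subject_sd` log-normal multiplier, default 0, so null cohorts are exactly
exchangeable and the closed form holds per recording), whole-body postural
sway shared across joints (optional `body_sway_sd`, default 0),
oscillatory or bout-structured stereotypies, joint-to-joint kinematic
coupling, and realistic confidence failure modes (occlusion runs rather
than independent per-frame dropout). With zero subject-level variability,
even modest λ effects make groups nearly separable, so recovery tests
certify the pipeline's mechanics, not clinical effect sizes.

## Numerical choices and degenerate inputs

* Exact rank-sum p-values only when both groups ≤ 20 and the pooled values
  are tie-free; otherwise the tie-corrected normal approximation.
* PCA on an all-constant matrix, a single-class training block, or a
  feature column missing for every subject: hard errors naming the cause.
* A fully confidence-filtered series yields an empty displacement series,
  which propagates as a missing cell.
* All stochastic stages (generator, inner CV splits) draw from seeds
  derived deterministically via `numpy.random.SeedSequence`; reruns with
  the same seed are byte-identical, which the test suite asserts at the
  report-file level.
* Tie-breaks everywhere (elimination order, grid choice, model selection)
  are fully specified so no run depends on dictionary or sort instability.

## Known limitations

* The headline kappa still conditions one choice (the feature count) on
  the LOSO surface; with 47 subjects this retains a small optimism
  (≈ 0.1–0.2 mean null kappa depending on the seed set), which users
  should keep in mind when reading absolute numbers.
* Global PCA sees the held-out subject's features (by design, for
  fidelity); `pca_scope="per-fold"` removes this.
* The published accuracies were computed on unreleased clinical
  recordings; nothing here can reproduce them from data. The package
  instead verifies the arithmetic consistency of the published
  class-rate/accuracy/kappa rows and the recoverability of planted
  effects under the synthetic conditions above.
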