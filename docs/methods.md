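# Methods

`perisurv` implements a survival-prediction pipeline for radiotherapy
planning CT of non-small cell lung cancer: radiomics from the gross tumor
volume (GTV) and from concentric peritumoral shells, deep features from a
3D squeeze-and-excitation residual network trained with the Cox partial
likelihood, sparse selection and PCA fusion into a combined
proportional-hazards risk model, and a censoring-aware evaluation suite.
This note records the model assumptions, the defaults and why they were
chosen, the numerical conventions, and what the synthetic phantoms do and
do not establish.

## The synthetic cohort and its generative model

Real planning-CT cohorts have no known generative model, so the package
ships a phantom generator whose statistical structure matches the
pipeline's assumptions while remaining fully known. Every distributional
choice below is a synthetic stand-in, not a claim about real anatomy.

**Phantom geometry and intensities.** Each subject is a 96³ voxel volume at
1 mm isotropic spacing (the desk pipeline preset uses 72³ with smaller
tumors to keep a 60-subject run on one CPU in minutes). The background is
i.i.d. Gaussian noise at lung-parenchyma intensity (mean −800, SD 50,
HU-like units, so that normalization code paths behave as on real CT). One
solid ellipsoidal tumor per subject has semi-axes drawn uniformly from
5–20 mm, mean intensity +40, and voxel-wise Gaussian texture whose
subject-level SD ("texture contrast") is drawn from 10–60. A peritumoral
shell of drawn width 2–6 mm interpolates linearly from the tumor intensity
to the noisy background, standing in for the intensity gradient at the
tumor–parenchyma interface. Placement guarantees a ≥10 mm clearance so the
9 mm ring never clips the volume edge.

**Survival.** Three image-derived covariates — log tumor volume, texture
contrast, rim width — are standardized over the cohort and enter a Weibull
proportional-hazards model: `T = λ (E · e^{−η})^{1/k}` with `E ~ Exp(1)`,
`η = z·β`. Defaults: shape `k = 1.2`, scale `λ = 700` days (baseline median
≈ 515 days, comparable to locally advanced NSCLC radiotherapy cohorts), and
`β = (0.8, 0.5, 0.3)` per SD — a dominant size effect with weaker texture
and rim effects, which is the qualitative structure radiomics models
exploit. Censoring is administrative and independent of covariates: uniform
on 60–1825 days (a 5-year follow-up window), yielding roughly one third
censoring. Because the model is exactly proportional hazards,
Schoenfeld-style checks on the planted covariates are clean at large n and
any systematic trend in a fit indicates an implementation defect.

**Seeding.** A master seed feeds `numpy.random.SeedSequence`; each subject
consumes one spawned child (the survival draw takes the last). Identical
`(spec, truth, n, seed)` reproduce a cohort bit-identically, including the
serialized NIfTI/CSV artifacts.

**What the phantoms do not emulate:** airway/vessel anatomy, multi-lesion
subjects, scanner-specific noise texture and reconstruction kernels,
breathing artifacts, inter-observer segmentation variability, and
covariate-dependent censoring. Passing recovery tests on phantoms
establishes that the estimators and the plumbing are correct — not that the
features are prognostic in real patients.

## Preprocessing

Volumes are resampled to 1 mm isotropic spacing with cubic B-spline
interpolation; masks with nearest-neighbour interpolation (preserving
binarity — the mask rule is our choice, as is common). The output grid is
centre-aligned inside the physical extent, which keeps the identity
resample exact and round-trips unbiased. Network inputs crop the tight GTV
bounding box (non-tumor voxels inside the box retained; a `mask_background`
switch zeroes them — the box-versus-masked question is genuinely open, and
the raw box is the default), resize it to a fixed cube by trilinear
interpolation, and z-normalize. The resize maps output index `j` to input
coordinate `j·n_in/n_out` (integer zoom factors reproduce source voxels
exactly; edge samples clamp). A zero-SD block z-normalizes to all zeros
rather than failing.

## Peritumoral geometry

Expansion by `d` mm is defined through the exact Euclidean distance
transform with the voxel spacing as sampling: a voxel joins the expansion
iff its centre lies within `d` of the nearest GTV voxel centre (boundary
included). Rings exclude the GTV and may optionally be intersected with a
body mask; by default no parenchyma clipping is applied. Rings are clipped
at image bounds, and an empty ring is an error with a diagnostic rather
than a silent empty row.

## Radiomics

Per region the extractor emits 1316 features: 18 first-order, 14 shape,
75 texture (24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM), and the same
18 + 75 recomputed on 8 one-level wavelet sub-bands (744) and 5 LoG scales
(465). IBSI definitions are the contract; the conventions where IBSI
admits choices:

- **Normalization and binning.** Whole-image z-score scaled by 100, then
  fixed-bin-width binning at width 25 (`level = floor((x − min_roi)/25) + 1`;
  the ROI maximum lands in the top bin). Filtered images are binned at the
  same width without re-normalization.
- **GLCM**: distance 1, the 13 unique 3D directions, symmetric
  accumulation, features computed per direction and averaged.
- **GLRLM**: 13 directions, feature-then-average; runs are counted through
  the segment identity `N_l = S_l − 2S_{l+1} + S_{l+2}` where `S_l` counts
  length-≥l same-level segments (equivalent to maximal-run enumeration and
  vectorizable).
- **GLSZM/GLDM/NGTDM**: 26-connectivity; GLDM with dependence tolerance
  α = 0.
- **Wavelet**: one-level stationary (undecimated) coif1 decomposition —
  sub-bands stay voxel-aligned with the image, so one ROI mask serves all
  bands; odd axes are edge-padded and cropped back.
- **LoG**: scale-normalized (σ²-weighted) Gaussian-Laplace with σ in mm;
  the image mean is subtracted before filtering so a constant image maps to
  exactly zero despite kernel truncation.
- **Shape**: marching-cubes mesh of the mask after a light Gaussian
  smoothing (σ = 0.7 × min spacing, in physical space) — raw binary meshes
  overestimate surface area by the staircase factor, which biases
  sphericity low; smoothing recovers analytic sphere values within a few
  percent. Maximum diameters come from the convex hull of mesh vertices
  (hulls beyond 3000 points are subsampled; the error is negligible at that
  density). Axis lengths are `4√λ` from the voxel-centre covariance
  eigenvalues.
- **Zero-variance guards** (constant ROI): skewness/kurtosis → 0, GLCM
  correlation and MCC → 1 (a constant image is perfectly autocorrelated),
  IMC1/IMC2 → 0, NGTDM contrast/busyness/complexity/strength → 0,
  coarseness capped at 10⁶. Guards return these documented constants, never
  NaN; the extractor refuses to emit non-finite values.

## The deep survival network

The architecture is a 3D ResNet-18-style backbone adapted to survival
analysis: stem 3×3×3 convolution (stride 2) → 3×3×3 max-pool (stride 2) →
four residual blocks of two units with filters (64, 128, 256, 512), an SE
channel-attention module (compression ratio 64, bottleneck `max(C/64, 1)`)
after every block, global average pooling (the 512-wide exported feature
vector), and a fully connected head 512→512→256→128 with dropout 0.4 and
L2 1e-4, ending in one tanh-bounded output. The first block's first
convolution acts directly on the pooled stem output; every other unit is
pre-activation (BN+ReLU+conv); down-sampling blocks use a 1×1×1 stride-2
projection shortcut (our choice; any shape-matching shortcut would do); a
final BN+ReLU precedes the GAP, as usual for pre-activation networks. SE
is applied to the block output after the residual addition.

Training minimizes the negative log Cox partial likelihood (below) plus the
L2 penalty with Adam at learning rate 1e-4, decayed ×0.96 every 1000 steps,
batch size 32, up to 100 epochs with early stopping after 15 non-improving
validation epochs; the best-validation state is kept. The validation split
is event-stratified (20 % by default); batches are event-stratified so no
batch is event-free. Augmentation (each transform independent): contrast
1.0–1.75 @15 %, brightness 0.7–1.5 @15 %, gamma 0.5–2.0 @15 % (on the
min–max-rescaled block), Gaussian noise variance 0–0.05 @15 %, Gaussian
blur σ 0.5–1.5 @15 %, mirroring @30 % (each axis flipped with probability
½ when triggered), z-axis rotation 0–360° @30 % with linear interpolation.

**Cox loss.** With risk scores `h`, Breslow handling of ties, risk set
`{j: T_j ≥ T_i}` (ties at-risk), normalized by the batch event count `D`:

    L = −(1/D) Σ_{i: δ_i=1} [ h_i − log Σ_{j: T_j ≥ T_i} exp(h_j) ]

log-sum-exp stabilized; an event-free batch contributes loss 0 with a
warning. Event-count normalization makes the gradient scale independent of
batch size; Breslow is the standard convention for batched deep Cox losses.
The analytic gradient is verified against finite differences of an
independently coded brute-force likelihood.

**Engine.** The network is implemented directly in numpy (im2col 3D
convolutions, hand-derived backward passes, float32) with TF-style SAME
padding, so spatial sizes follow `ceil(n/stride)`. Determinism is by
construction: all randomness (init, dropout, batch order, augmentation)
derives from the training seed, and two runs with the same seed produce
bit-identical histories and weights.

**Desk preset.** Filters (8, 16, 32, 64) on 32³ blocks, SE ratio 8, head
64→32→16, learning rate 1e-3, batch 16, 20 epochs. This preset exists so a
120-subject training run takes tens of seconds on one CPU; the full-scale
preset matches the architecture above. At desk scale the SE module's
*benefit* is not reproducible (over fixed seeds 1–3 on the planted-volume
cohort it improved validation loss in 1 of 3 runs); the ablation switch is
provided, but no direction claim is asserted at this scale.

**What the network can learn from phantoms.** Input blocks are
tight-bbox-resized, which removes absolute size. Size reaches the network
through resize side-channels — interpolation smoothing of the texture and
the apparent (rescaled) rim width — and the planted-volume recovery test
(validation C-index > 0.65 at n = 120, 20 epochs) passes through exactly
those cues. This is a correctness check of the training loop, not evidence
about real CT.

## Selection and fusion

Per feature block (intratumoral radiomics, peritumoral radiomics at the
chosen distance, deep features), on training rows only:

1. **Z-score** with training mean/SD (population SD); zero-SD columns are
   dropped with a warning.
2. **Univariate Cox screen** at Wald p < 0.05. Each fit is Newton–Raphson
   on the Breslow partial likelihood, vectorized across all columns
   (steps clipped at ±2; monotone-likelihood features — |β| > 15 per SD or
   collapsed information — are flagged and excluded).
3. **Lasso-Cox**: coxnet path of 100 penalties down 4 decades from the
   all-zero solution; 10-fold CV scored by Verweij–van Houwelingen deviance
   `−2[pl_full(β_fold) − pl_train−fold(β_fold)]`. The default penalty is
   the **one-standard-error rule** (largest penalty within one SE of the
   minimum): the deviance minimizer systematically over-selects in
   planted-signal simulations (≈10–16 false positives against 3 true
   features among 50), while λ.1se recovers the planted support with ≤1
   false positive; `penalty_rule="min"` restores the minimizer. Nonzero
   coefficients form the signature; its score is reproducible from the
   stored standardization statistics alone.

**Fusion.** The selected raw (standardized) features of all blocks are
concatenated and PCA-fitted on training rows; the smallest component count
reaching 95 % cumulative explained variance is retained; a multivariable
Cox model on the components gives the combined risk score (its linear
predictor), and the training median risk is stored as the stratification
cutoff. Fusing per-block signature *scores* instead is a config switch
(`fuse_on="signature_scores"`); raw selected features are the default
because component loadings over individual features are what a loading
heatmap displays. No test-row information enters standardization,
screening, selection, PCA, the Cox fit, or the cutoff; a dedicated test
recomputes the chain with corrupted held-out rows and asserts bit-equality.

## Evaluation

- **Harrell's C**: comparable pairs are `(i, j)` with `T_i < T_j`,
  `δ_i = 1`; score ties credit 0.5; pairs tied on time with both events are
  excluded. Exact pair enumeration is the test oracle; scikit-survival is
  an independent cross-check. CIs by subject-level percentile bootstrap
  (1000 draws, seeded).
- **Time-dependent AUC**: cumulative-cases/dynamic-controls with IPCW from
  the KM censoring estimator (scikit-survival), at 1/2/3-year horizons.
  Without censoring before the horizon it reduces exactly to the binary
  Mann–Whitney AUC of the dichotomized outcome.
- **DeLong**: placement-value paired variance, two-sided normal p, applied
  to horizon-dichotomized status; subjects censored at or before the
  horizon have unknown status and are excluded (DeLong is defined for
  binary outcomes; this adaptation is ours and is stated as such).
  Zero variance yields p = 1 with a warning.
- **KM / log-rank / HR**: product-limit estimator, two-group log-rank with
  hypergeometric variance, single-binary-covariate Cox HR with Wald CI
  (all via lifelines). An event-free group is reported as a monotone
  likelihood with an unbounded HR, not a crash.
- **Calibration**: quantile bins of predicted survival at a horizon
  (quintiles; degenerate bins merged), observed = per-bin KM at the
  horizon, 1000-draw bootstrap percentile bands; the predicted survival
  comes from the Cox model's Breslow baseline.
- **Subgroups**: KM + log-rank + HR of the risk grouping within each
  clinical stratum; strata lacking both risk groups or any event are
  reported not-evaluable.

## Pipeline, presets, problem sizes

`run_pipeline` chains simulate → preprocess → rings → radiomics → deep
survival → selection/fusion → evaluation → expansion-distance comparison
from one schema-validated YAML config; unknown keys are rejected before any
compute. Heavy stages cache by config hash and are skipped on rerun; the
cheap modelling stages are recomputed (they are deterministic given their
inputs — all randomness is seeded, and every table crosses a serialization
round-trip so cached and fresh runs are bit-identical). The manifest
records package version, config hash, seed, and the content hash of every
artifact; it contains no timestamps, so two runs of one config agree
byte-for-byte. Train and test cohorts are generated from disjoint derived
seeds, standing in for the two-centre design.

The desk preset (72³ phantoms, tumors 5–14 mm, 32³ network blocks, the
short training schedule) targets a complete 60-subject run in minutes on
one CPU; these sizes were chosen as the smallest at which every stage has
non-trivial work (multiple gray levels per ROI, several events per fold,
both risk groups populated). The full-scale preset (96³ phantoms, 64³
blocks, full architecture and schedule) is the default for the library
objects themselves.

## Known limitations

- The phantom generator's realism limits (listed above) bound what any
  green test shows about clinical data.
- Harrell's C is computed by O(n²) pair enumeration — fine for cohort
  sizes here, not for biobank scale.
- The numpy network engine is single-threaded per matmul call and intended
  for desk-scale inputs; the full 64³ architecture builds and runs
  forward/backward but trains slowly on CPU.
- GLCM distance is fixed at 1 voxel and features are 3D-only (no per-slice
  variants); no resegmentation window is applied.
- DeLong on censored horizons discards unknown-status subjects rather than
  using IPCW weighting.
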