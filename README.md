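# perisurv

Survival prediction from radiotherapy planning CT by fusing intratumoral
and **peritumoral** radiomics with 3D deep-learning features.

Prognosis in non-small cell lung cancer (NSCLC) is usually staged from the
tumor itself, yet the lung parenchyma just outside the gross tumor volume
(GTV) — the tumor–host interface — carries information about invasion and
microenvironmental change. `perisurv` implements the full modelling chain
for testing that idea on CT:

1. **Preprocessing** — isotropic 1 mm resampling (cubic B-spline for
   intensities, nearest-neighbour for masks) and fixed-size z-normalized
   tumor blocks for the network.
2. **Peritumoral geometry** — concentric rings at millimetre-calibrated
   distances (3/6/9 mm by default) from the GTV, via the exact Euclidean
   distance transform.
3. **Radiomics** — 1316 IBSI-consistent features per region: 18
   first-order, 14 shape, 75 texture (GLCM/GLRLM/GLSZM/NGTDM/GLDM), plus
   the 93 intensity/texture features recomputed on 8 wavelet sub-bands
   (744) and 5 Laplacian-of-Gaussian scales (465).
4. **Deep survival network** — a 3D squeeze-and-excitation ResNet trained
   with the Cox partial-likelihood loss

       L(h) = −(1/D) Σ_{i: δᵢ=1} [ hᵢ − log Σ_{j: Tⱼ ≥ Tᵢ} exp(hⱼ) ]

   (Breslow ties, Adam, exponential LR decay, early stopping); the
   512-dimensional global-average-pooling activations are the exported
   deep features. The network engine is a self-contained numpy
   implementation with hand-derived backpropagation.
5. **Selection and fusion** — per feature block: z-score → univariate Cox
   screen (Wald p < 0.05) → Lasso-Cox with 10-fold cross-validated
   partial-likelihood deviance; the selected features of all blocks are
   fused by PCA (components kept to ≥95 % cumulative variance) and a
   multivariable Cox model on the components yields the combined risk
   score, with the training median as the stratification cutoff.
6. **Evaluation** — Harrell's C with bootstrap CIs, time-dependent
   (cumulative/dynamic, IPCW) AUC at 1/2/3 years, DeLong comparisons,
   Kaplan–Meier curves, log-rank tests, hazard ratios, bootstrap
   calibration curves and clinical subgroup reports.

Because real multicenter cohorts cannot ship with a package, `perisurv`
includes a **synthetic CT-phantom cohort generator** with planted
prognostic signal (log tumor volume, texture contrast, peritumoral rim
width under a Weibull proportional-hazards model) and recorded ground
truth, so every stage is testable end to end. See `docs/methods.md` for
the model details and for what phantom-based tests do and do not show.

## Worked example

A complete desk-scale run (synthetic two-cohort design, 24 training + 10
test subjects, scaled-down network) from Python:

```python
from perisurv.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="run", seed=5, n_train=24, n_test=10,
                     truth={"beta": (2.0, 0.8, 0.3),
                            "censoring_window_days": (365.0, 2500.0)})
state = run_pipeline(cfg)
print(state["model"].summary())
```

prints:

```
Combined peritumoral/deep-feature risk model
==============================================
  block rad_intra                screened  266  selected   4
  block rad_peri6                screened  529  selected   2
  block deep                     screened   24  selected   4
  PCA: 6 components (97.3% of variance, threshold 95%)
  stratification cutoff (training median risk): -0.4715

               coef  se(coef)         p
covariate
PC1        1.177245  0.285027  0.000036
PC2       -0.096994  0.240323  0.686507
PC3        0.381421  0.271307  0.159765
PC4        0.324592  0.400610  0.417799
PC5        0.485878  0.421192  0.248674
PC6        1.672285  0.797749  0.036059
```

Each block's 1316 features (64 deep features at desk scale) are screened
to the hundreds by the univariate Cox filter and Lasso-selected down to a
handful; six principal components carry 97 % of their variance, and the
dominant component — loaded on the planted size/texture/rim directions —
is strongly prognostic (PC1, p ≈ 4e-5). On this run the combined risk
score reaches a training C-index of 0.888 and a held-out test C-index of
0.698 (`state["reports"]` holds these together with AUCs, the hazard
ratio between median-split risk groups and the log-rank p). `run/`
contains every table, figure and model file plus a content-hashed
manifest: two runs of one config are byte-identical.

The same run from the shell:

```bash
perisurv run-all --out-dir run --seed 5 --n-train 24 --n-test 10
perisurv compare-distances --out-dir run --seed 5   # 7-scheme C-index table
periring --gtv gtv.nii.gz --distances 3,6,9 --out-prefix sub01  # rings only
```

Reproducibility note: per-subject seeds derive from the master seed by
`numpy.random.SeedSequence(master).spawn(n)` — subject *i* uses child *i*,
the survival draw uses the last child; the train and test cohorts use two
disjoint children of the master seed.

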