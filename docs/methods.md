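# Methods

## Problem and overall design

Glaucoma thins the neuroretinal rim — the tissue between the optic cup
and optic disc boundaries in a fundus photograph. The package implements
a two-stage detector built around that geometry:

1. **Segmentation / geometry stage.** Starting from cup/disc label masks
   (either supplied directly or predicted by the bundled segmentation
   network), each eye is reduced to a 24-direction cup-to-disc ratio
   (CDR) profile, the vertical CDR, and the cup-to-disc area ratio
   (CDAR).
2. **Generative classification stage.** A hierarchical Gaussian model of
   the profile vector is fitted by maximum likelihood to labeled eyes,
   and new eyes are scored with the Bayes posterior probability of
   glaucoma or the equivalent Rim Deformation Score (RDS).

## CDR profile geometry

For direction `d = 1..24` at angle `15°·(d−1)` (0° at 3 o'clock,
counter-clockwise on screen), `CDR_d = r_cup / r_disc`, where the radii
are measured from the disc-region centroid by a fixed-step (0.25 px) ray
march and clipped to `[0, 1]`. Decisions that the data formats do not
force, made once and kept:

* **Ray origin**: the disc-region centroid. It is stable under boundary
  noise and coincides with the center for elliptical discs.
* **Anchor**: no left/right-eye anatomical re-anchoring; direction 1 is
  always the image's 3-o'clock ray. The generative model's Fourier mean
  absorbs any consistent angular offset in training data.
* **Boundaries**: raw raster contours by default; an `ellipse_fit`
  option measures radii on least-squares-fitted ellipses instead, for
  pipelines whose reference annotations are themselves best-fitting
  ellipses.
* A cup pixel outside the disc is anatomically impossible; such pixels
  are relabeled as disc and counted in a logged warning.
* The returned radius is the distance to the center of the outermost
  in-region pixel along the ray, so a single-pixel region has radius 0
  and rasterized shapes are recovered within about half a pixel.

Accuracy against closed-form ray/ellipse oracles is within 0.02 per
direction and 0.01 in CDAR for semi-axes ≥ 20 px; below that,
pixelation noise grows and no guarantee is made.

## The generative model

With `Y_{i,d}` the CDR of eye `i` in direction `d`:

```
Y_{i,d} = β0 + β_{G,0}·I_G + β_CDAR·CDAR_i
          + Σ_{k=1,2} [ β_{G,2k-1} sin(2πkd/24) + β_{G,2k} cos(2πkd/24) ]·I_G
          + Σ_{k=1,2} [ β_{H,2k-1} sin(2πkd/24) + β_{H,2k} cos(2πkd/24) ]·I_H
          + z_i + e_{i,d}
```

`z_i ~ N(0, σ_z²)` is a per-eye random effect shared across directions;
`e_{i,d}` is i.i.d. noise with group-specific variance (σ_G² for
glaucoma, σ_H² for healthy — glaucomatous rims are more irregular, so
the model allows them more noise). Marginally each profile is
`N(μ_g(CDAR), V_g)` with compound-symmetric `V_g = σ_z²·J + σ_g²·I`,
whose two eigenvalues (`σ_g²` with multiplicity 23, `σ_g² + 24·σ_z²`
with multiplicity 1) give exact `log|V|` and quadratic forms without any
dense solve.

Parameter accounting for the full configuration: 1 prior probability +
11 fixed effects (β0, β_{G,0}, β_CDAR, 8 Fourier coefficients) + 3
variance components = **15 free parameters**; dropping CDAR and/or
sharing one noise variance gives 14/14/13. The two group-specific
Fourier sums use distinct sine and cosine coefficients (β_{·,1..4} per
group); this is the only reading under which those counts are attainable.

### Fitting

Maximum likelihood with the fixed effects profiled out: given the
variance components, the GLS estimate
`β̂ = (Σ XᵀV⁻¹X)⁻¹ Σ XᵀV⁻¹y` is closed-form (V⁻¹ via
Sherman–Morrison), and the profiled log-likelihood is maximized over
`log σ_z², log σ_G², log σ_H²` by L-BFGS-B from a moment-based start
(between-eye vs within-eye residual variance). The normal error model
makes the likelihood unimodal, so a single start is used. `log σ_z²` is
bounded below at −30, which lets σ_z² collapse to an effective zero at
the boundary. Standard errors of the fixed effects come from
`(Σ XᵀV⁻¹X)⁻¹` at the optimum. The prior glaucoma probability defaults
to the training prevalence and can be overridden.

### Classification

The posterior is computed in log space from the structured densities;
the RDS is `½[d²_M(y, μ_H) − d²_M(y, μ_G)]` with **squared** Mahalanobis
distances, each under its own group covariance. Under a shared
covariance (one noise variance) the identity
`log[p/(1−p) · (1−p_G)/p_G] = RDS` holds exactly, so posterior and RDS
thresholding give the same decisions; with two variances the posterior
additionally carries the `½·log(|V_H|/|V_G|)` term, so the posterior —
never the RDS — is the primary score. The decision rule is
`glaucoma iff score ≥ threshold`; the default threshold is the ROC point
closest to the top-left corner on the training scores (ties resolved
towards sensitivity).

The CDAR-only baseline is a two-parameter logistic discriminant
(intercept + slope on CDAR) scored by the same ROC machinery.

## Synthetic data

`sample_profiles` is the forward model above plus truncation of profiles
to `[0, 1]` (a CDR is a ratio); the truncation rate is reported so
simulations can be kept honest (< 1% under the defaults). The default
generating truth is chosen once as a realistic regime: healthy mean
CDR ≈ 0.45 and glaucomatous ≈ 0.70 (β0 = 0.35, β_{G,0} = 0.18,
β_CDAR = 0.35), small Fourier asymmetries (0.01–0.05), σ_z² = 0.004,
σ_G² = 0.006 > σ_H² = 0.003, glaucoma fraction 0.3, and group CDAR laws
N(0.5, 0.1²) vs N(0.3, 0.1²) truncated to [0, 1]. Under these values the
CDAR-only baseline lands strictly between chance and the full model, the
expected qualitative ordering.

`render_masks` rasterizes a disc/cup ellipse pair by evaluating the
implicit equation on the pixel grid (optionally warped by a smooth
random angular perturbation) and returns the closed-form ray/ellipse
profile, area ratio and vertical-extent ratio of the noiseless ellipses.
`render_pseudo_fundus` colors the three regions with well-separated
intensities, adds mild Gaussian noise and a black circular field border.
It makes no attempt to imitate vessels, texture or camera effects —
passing segmentation tests on it demonstrates the training/prediction
machinery, not clinical-grade segmentation.

## Segmentation network

A U-shaped fully convolutional network: a stride-2 stem, seven encoder
stages of mobile inverted-bottleneck (MBConv) blocks with
squeeze-and-excitation gating (kernel sizes 3/5, expansion 4, overall
downsampling ×32), and five decoder blocks of 2×2 stride-2 transposed
convolution, skip concatenation with the matching encoder resolution,
and two batch-normalized ReLU convolutions, ending in a 1×1 convolution
with a per-pixel softmax over background/rim/cup. The layers and
backpropagation are implemented directly on numpy arrays (im2col
convolutions, closed-form batch-norm and SE gradients), so everything
runs single-threaded on a CPU and is bit-reproducible under a seed.

Choices left open by the architecture sketch: per-pixel cross-entropy
loss by default (soft-Dice as an option), Adam with learning rate 1e−3,
decoder widths (32, 24, 16, 12, 8), and random (never pretrained)
encoder initialization. The default widths are deliberately slim
(~116k parameters) so that the bundled capacity check — overfitting one
96×96 pseudo-fundus image to cup and disc Dice > 0.9 in under 200
steps — runs in well under a minute; widths scale through
`NetworkConfig` for real data. Preprocessing crops the bounding box of
pixels whose maximum channel reaches 10 (of 255) — removing black
camera borders — and resizes to the working resolution (bilinear for
images, nearest-neighbor for masks). Training retains the checkpoint
with the best held-out pixel accuracy (training pairs double as the
held-out set when none is given).

## Evaluation metrics

Dice, Jaccard and accuracy are computed from pixel-pooled confusion
counts (per-image averaging available via the per-class summary on
individual images); zero denominators raise rather than return 0.
AUROC uses the rank (Mann–Whitney) formulation with midranks for ties,
which equals the trapezoidal area under the empirical ROC. Candidate
thresholds are midpoints between consecutive distinct scores plus ±∞.
Predictive values with an empty predicted class are NaN, not 0.
Bland–Altman agreement reports the mean difference and bias ± 1.96
sample SD limits.

## Numerical notes and limitations

* Structured log-densities agree with dense multivariate-normal solves
  to better than 1e−8; the dense path remains available for generic
  covariances.
* Zero noise variance is allowed in parameter objects for noiseless
  forward simulation, but density evaluation requires it positive.
* Problem sizes used by the test suite — 500 training eyes for
  parameter recovery, 4000 held-out eyes for the Bayes-optimality
  check, 10 000 for moment checks, one 96×96 image for the segmentation
  capacity check — were chosen as the smallest sizes at which the
  statistical tolerances (3 SE, 20% relative error on variances, 0.02
  AUROC) are meaningful.
* The synthetic cohort is exactly the model's own distribution; passing
  recovery and Bayes-consistency tests shows correctness of the
  machinery, not robustness to model misspecification, segmentation
  error or annotation noise in real fundus data.
* No confidence intervals are attached to AUROC, and the classifier
  offers no covariates beyond CDAR or correlation structure beyond
  compound symmetry.
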