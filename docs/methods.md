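# Methods

This note documents the models, parameter choices, and numerical decisions
behind `latentmorph`, and what the synthetic-phantom experiments do and do not
demonstrate.

## Synthetic phantoms

A phantom is an elliptical head on a dark background: paired para-central
ellipses of CSF (lateral ventricles), a cortical gray-matter ribbon following
the head boundary, white matter filling the interior, and optional
periventricular lesion blobs. The controllable attributes are

| attribute | unit / range | default | role |
|---|---|---|---|
| `ventricle_scale` | area multiple, ≥ 0 | 1.0 | ventricular CSF area (atrophy surrogate) |
| `cortical_thinning` | fraction [0, 1] | 0.0 | shrinks the GM ribbon |
| `lesion_count` | count ≥ 0 | 0 | periventricular blobs |
| `slice_position` | index 0–5 | 2 | head size modulation across slices |
| `age_proxy` | years | 37 | head size covariate |

Cohort-conditional distributions: `ventricle_scale` is log-normal with the
diseased cohort shifted +0.25 on the log scale (σ = 0.15 HC / 0.20 MS);
`lesion_count` is Poisson (ADC: 0.3 HC / 4.0 MS; T1w: 0.1 / 1.5 — lesions are
mainly an ADC-contrast feature); `cortical_thinning` is Beta(2, 20) HC /
Beta(4, 12) MS; ages follow the cohort demographics (36.9 ± 12.6 / 38.8 ± 10.1
years). Effect sizes are free parameters of the generator, chosen to give
segmentation-detectable but not caricatured differences; they are
config-exposed (`CohortModel`) and are not calibrated against any clinical
table.

T1w multi-echo intensities follow a mono-exponential T2* decay
`S0(τ)·exp(−TE_c/T2*(τ))` at TE = 8.12, 13.19, 19.26 ms with amplitudes
ordered WM > GM > CSF > background, so per-tissue intensity is non-increasing
across the three channels. ADC phantoms have one physical channel (CSF ≈
lesion > GM > WM) duplicated to three. Additive Gaussian acquisition noise
(σ = 0.02 intensity units) is applied before clipping to [0, 1]; for ADC it is
added before duplication so the three channels stay identical.

What the phantoms do **not** emulate: gyral/sulcal geometry, bias fields,
partial-volume effects, registration error, or any 3D structure. Results on
phantoms therefore validate the pipeline's mechanics (inversion accuracy,
direction recovery, segmentation-based morphometry), not its performance on
clinical data.

## Generative model

The generator is a style-based GAN reduced to desk scale: latent dimension 64,
4-layer mapping network (lr-multiplier 0.01, pixel-normalized input), and a
synthesis network growing from a learned 4×4 constant by nearest-neighbour
upsampling with binomial blur (≈ bilinear), two style-modulated 3×3
convolutions per resolution, per-layer scalar-gained noise injection, and a
final 1×1 toRGB without demodulation. The number of style inputs is
`L = 2·log₂(res) − 2` (8 at 32 px), with toRGB consuming the last slot.
Equalized learning rate and weight demodulation follow the usual conventions;
channel widths default to {4: 64, 8: 48, 16: 32, 32: 24}.

The discriminator mirrors the generator with residual downsampling blocks, a
minibatch-standard-deviation channel, and a dense head. Training uses the
non-saturating logistic loss, R1 regularization (γ = 1, applied lazily every
16 steps and scaled by the interval), Adam(0, 0.99, 1e−8) at learning rate
0.0025 for both networks, and adaptive discriminator augmentation with
horizontal mirroring as the only augmentation: the mirroring probability p
moves by ±0.01 per step according to whether the sign-mean of the
discriminator's real-batch outputs exceeds the target 0.6, clamped to [0, 1].
γ, the laziness interval, and the ADA constants are package defaults
(config-exposed); they follow common practice for this model family.

Image quality is tracked with the Fréchet distance between Gaussian fits of
feature embeddings of real and generated sets. The default embedder is a
fixed-seed random convolutional stack — reproducible everywhere without
downloads — and any pretrained backbone exposing the same two-method contract
(`feature_maps`, `embed`) can be plugged in; numbers from different embedders
are never compared.

### Autodiff

No deep-learning framework is used; `latentmorph.tensor` is a small
reverse-mode autodiff engine over NumPy whose vector-Jacobian products are
themselves graph operations, so `grad(..., create_graph=True)` supports the
double backward needed by R1. Linear resampling/convolution plumbing is
implemented as mutually adjoint primitive pairs (`im2col`/`col2im`,
`upsample2x`/`sumpool2x`, circular `blur3` which is self-adjoint), each
verified against finite differences in the test suite. Piecewise-linear
activations treat their masks as locally constant, which is exact almost
everywhere.

## Projection (GAN inversion)

Inversion optimizes an extended code w⁺ (one 64-vector per style layer) and
all noise maps. Decisions where the method description admitted latitude:

- **Initialization**: of N = 10,000 sampled codes (drawn in Z, mapped to W),
  the mean of the 100 whose zero-noise renderings score highest on SSIM
  against the target is used; `top_k = 1` recovers "single best", and
  `top_k = N` recovers the classical mean-of-all initializer. σ_w is the
  scalar root-mean per-component variance of all N sampled w (a scalar, not a
  per-component vector).
- **Exploration noise** added to w⁺ has standard deviation `0.05·σ_w·t²`,
  with t falling linearly 1 → 0 over the first 750 iterations.
- **Learning rate**: cosine half-wave 0 → 0.1 over the first 50 iterations,
  plateau, cosine to exactly 0 at the last of the 250 final iterations; the
  two ramps are composed with a min so degenerate short runs stay valid.
- **Noise regularizer**: for each noise map, a pyramid is built by 2×2
  average pooling with ×2 amplitude compensation (unit-variance noise stays
  unit-variance) down to 8×8; at each level the penalty is
  `(1/r²)(Σ p·p_x)² + (1/r²)(Σ p·p_y)²` with circular single-pixel shifts.
  The total over layers and levels enters the loss with weight c = 1e5.
  The 4×4 base-layer map is below the pyramid floor and is therefore
  normalized but not regularized.
- **Normalization** of every noise map to zero mean/unit variance happens
  after each optimizer step, per layer (not per pyramid level).
- Adam betas for projection reuse the training values (0, 0.99).

The perceptual distance is the sum of squared differences of multi-scale
embedder feature maps, with the same pluggable-embedder contract as the
Fréchet metric: tests and defaults use the fixed-seed random embedder, so no
pretrained weights are required.

## Semantic directions and editing

The cohort direction is the unit normal of a linear SVM (hinge loss, C = 1,
no feature standardization — the hyperplane lives in raw latent coordinates)
fit on flattened W⁺ codes, oriented from the healthy toward the diseased
cohort; per-layer restriction of an edit is available via a layer-range mask.
The released direction is the full-data fit; 10-fold refits report hold-out
accuracy and pairwise fold-direction cosines as a stability diagnostic.
Conditionalization removes the component along a confounder direction and
**renormalizes** to unit length (a documented divergence from the raw
projection formula) so that α keeps a consistent scale; one extra
re-orthogonalization pass keeps the residual inner product at the 1e−16
level. Editing synthesizes `G_syn(w⁺ + α·n)` with the projection's fixed
noise maps, so the α = 0 entry is bit-identical to the reconstruction.

The editing range in the pipeline defaults to `alpha_max = "auto"`: twice the
inter-cohort mean separation along **n** in latent units. Unlike a
photographic face model with a fixed latent geometry, the scale of a freshly
trained toy model's W⁺ varies run to run, so the separation itself is the
natural unit; a fixed numeric grid remains available in the config.

## Morphometry

Tissue volumes come from per-image k-means (k = 4, k-means++ with 10
restarts, fixed seed) on channel-0 intensities. The background cluster is the
one dominating the image border — a rule that works for both contrasts — and
the remaining clusters map to tissues by ascending centroid intensity
(T1w: CSF < GM < WM; ADC: WM < GM < CSF). BPF is computed from a single 2D
slice. Paired t-tests against the α = 0 column are two-sided with threshold
0.001; zero-variance differences return NaN ("undefined") and are never
flagged significant. Clustering is per image rather than pooled across the
cohort, keeping subjects independent.

## Reference study conditions

The validation experiments (`latentmorph.experiments`, also driven by
`scripts/acceptance.py`) run at the package's desk-scale defaults: 32×32
phantoms, 1,000 per cohort (2,000 training images), 9.6 kimg of adversarial
training at batch 16, inversion of 30 + 30 subjects at 120 iterations with a
256-sample SSIM initialization, a 10-fold SVM direction, and a 5-point α grid
from 0 to twice the cohort separation. At these sizes the full pipeline runs
in roughly ten minutes on one CPU. The isolated projection-recovery
experiment uses the fuller setting (300 iterations, 1,024 init samples) on a
generator-produced target.

## Known limitations

- Phantom anatomy is deliberately schematic; no claim is made about clinical
  MRI beyond the mechanics being exercised.
- The random-feature perceptual embedder and Fréchet embedder are not
  perceptually calibrated; they order distortions correctly on average but
  their absolute values are not comparable to published FID/LPIPS numbers.
- The GAN, at desk scale and short schedules, can drift or mode-collapse for
  unlucky seeds; the end-to-end trend test is stochastic by nature.
- Editing very far along a direction leaves the data manifold; the auto α
  range keeps edits within twice the observed cohort separation.
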