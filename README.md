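# latentmorph

Latent-space analysis of neurodegenerative disease patterns in brain MRI,
exercised end to end on synthetic brain phantoms.

Multiple sclerosis (MS) produces diffuse imaging changes — ventricular
enlargement, cortical atrophy, white-matter lesions — that are hard to
summarize with hand-crafted markers. One way to study them is to let a
generative image model learn the anatomy distribution of patients and
controls, embed individual scans into the model's latent space, and then move
each scan's latent code along the direction that separates the two cohorts:
the resulting image sequence is a per-subject simulation of disease
progression, and downstream morphometry quantifies what changed.

`latentmorph` implements that whole pipeline as a reusable, CPU-friendly
package:

1. **`phantom`** — synthetic 2D brain slices (3-channel multi-echo T1w-like or
   ADC-like contrast) with exact ground-truth tissue masks and controllable
   ventricle size, cortical thickness, and lesion load for two cohorts
   (HC/MS).
2. **`stylegan`** — a scaled-down style-based GAN: a 4-layer mapping network
   `G_map: Z → W`, a style-modulated synthesis network `G_syn: W → X` with
   per-layer noise injection, non-saturating logistic loss with R1
   regularization, Adam(β₁=0, β₂=0.99, ε=1e−8), adaptive discriminator
   augmentation restricted to horizontal mirroring, and a Fréchet-distance
   quality metric with a pluggable feature embedder.
3. **`projection`** — GAN inversion into the extended latent space W⁺:
   SSIM-ranked initialization (mean of the top-100 of 10,000 samples),
   perceptual loss plus a noise-map autocorrelation regularizer with weight
   c = 1e5, a 3,000-iteration Adam loop with a 50-up/250-down cosine
   learning-rate schedule, latent exploration noise `N(0, (0.05·σ_w·t²)²)`
   decaying over the first 750 iterations, and per-iteration renormalization
   of every noise map to zero mean and unit variance.
4. **`semantics`** — the cohort direction as the unit normal **n** of a linear
   SVM hyperplane separating the flattened projected codes (10-fold
   cross-validated), conditional manipulation
   `n₁ ← normalize(n₁ − (n₁ᵀn₂)n₂)` against confounder directions, and image
   editing `x(α) = G_syn(w⁺ + α·n)`.
5. **`morphometry`** — k-means (k = 4) tissue segmentation into
   background/CSF/GM/WM, the single-slice brain parenchymal fraction
   `BPF = (V_GM + V_WM) / (V_GM + V_WM + V_CSF)`, BPF-vs-α curves with paired
   t-tests (significance threshold 0.001), intensity profiles, and signed
   difference maps.
6. **`workbench`** — YAML configuration, seed management, stage caching, a
   JSON-lines log, and the `latentmorph` CLI
   (`simulate / train / project / direction / edit / analyze / run`).

The package contains its own reverse-mode autodiff engine over NumPy
(`latentmorph.tensor`), including the double-backward support needed by the
R1 gradient penalty — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from latentmorph import experiments as ex

run = ex.end_to_end(seed=1)
print("alpha grid:", np.round(run["alpha_grid"], 2))
print("mean BPF per alpha:", np.round(run["mean_bpf"], 4))
print("fraction of subjects with negative BPF-alpha correlation:",
      run["fraction_negative_correlation"])
```

This trains the toy GAN on 2,000 phantoms (1,000 per cohort, 32×32), inverts
30 healthy and 30 diseased subjects, fits the cohort SVM direction, and pushes
each healthy subject toward the diseased side of the hyperplane over a grid of
scaling factors α. A run with seed 1 prints:

```
alpha grid: [0.   1.11 2.23 3.34 4.46]
mean BPF per alpha: [0.815 0.812 0.8101 0.8057 0.8015]
fraction of subjects with negative BPF-alpha correlation: 0.8
```

Mean segmented BPF falls monotonically with manipulation strength — the
simulated progression shows the expected brain-volume loss — and 80% of
subjects' individual BPF-vs-α trajectories are decreasing.

The same experiment is available from the shell:

```bash
latentmorph run --seed 1 --out pipeline_out
```

which writes per-stage artifacts, `bpf_analysis.csv`, and `summary.json`
under `pipeline_out/`.

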