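"""Canned validation experiments exercising the pipeline end to end.

These drivers define the package's reference study conditions: desk-scale
cohorts of 32x32 phantoms, a 64-dimensional latent space, and short training
and inversion schedules. Each returns plain dictionaries of measured
quantities so they can back both the test suite and reproduction scripts.
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.stats import spearmanr

from . import morphometry as mm
from . import phantom as ph
from . import projection as pj
from . import semantics as sem
from . import stylegan as sg


def subseed(seed: int, tag: str) -> int:
    """Stable derived seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def bpf_oracle_errors(seed: int, n: int = 50, size: int = 64) -> np.ndarray:
    """|segmented BPF - analytic BPF| over clean phantoms of both cohorts."""
    half = n // 2
    cohort = (ph.sample_cohort(half, "HC", seed=subseed(seed, "bpf-hc"),
                               size=size, noise_std=0.0)
              + ph.sample_cohort(n - half, "MS", seed=subseed(seed, "bpf-ms"),
                                 size=size, noise_std=0.0))
    errors = []
    for p in cohort:
        seg = mm.segment_tissues(p.channels[0], seed=0, contrast="t1w")
        errors.append(abs(mm.bpf_from_labels(seg) - ph.analytic_bpf(p)))
    return np.asarray(errors)


def orthogonality_worst_case(seed: int, n_pairs: int = 10_000, dim: int = 512) -> float:
    """Max |<conditionalize(n1, n2), n2>| over random unit-vector pairs."""
    rng = np.random.default_rng(subseed(seed, "ortho"))
    worst = 0.0
    for _ in range(n_pairs):
        v1 = rng.standard_normal(dim)
        v2 = rng.standard_normal(dim)
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        worst = max(worst, abs(sem.conditionalize(v1, v2) @ v2))
    return worst


def direction_recovery(seed: int, n: int = 100, dim: int = 64, margin: float = 2.0,
                       noise: float = 0.3, folds: int = 10) -> dict:
    """Planted-direction simulation: SVM must recover e1 and be fold-stable."""
    rng = np.random.default_rng(subseed(seed, "direction"))
    a = rng.normal(0, noise, (n, dim))
    b = rng.normal(0, noise, (n, dim))
    a[:, 0] = -margin / 2
    b[:, 0] = margin / 2
    d = sem.fit_direction(a, b, folds=folds, seed=subseed(seed, "direction-cv"))
    e1 = np.zeros(dim)
    e1[0] = 1.0
    return {
        "cosine_with_planted_axis": abs(float(d.n @ e1)),
        "min_fold_cosine": float(min(d.cv_report["fold_cosines"])),
        "fold_accuracy": d.cv_report["fold_accuracy"],
    }


def projection_recovery(seed: int, iterations: int = 300, resolution: int = 32,
                        latent_dim: int = 64) -> dict:
    """Invert a generator-produced target and measure reconstruction quality."""
    model = sg.GeneratorModel(sg.GeneratorConfig(
        resolution=resolution, latent_dim=latent_dim, seed=subseed(seed, "proj-model")))
    rng = np.random.default_rng(subseed(seed, "proj-target"))
    w_true = sg.map_latent(model, rng.standard_normal(latent_dim))
    target = sg.synthesize(model, w_true, noise="zero")
    cfg = pj.ProjectionConfig(
        iterations=iterations, init_samples=1024, init_top_k=100,
        lr_rampup_iters=max(1, iterations // 20),
        lr_rampdown_iters=max(1, iterations // 4),
        noise_ramp_iters=max(1, iterations // 4),
        seed=subseed(seed, "proj-opt"))
    res = pj.project(model, target, cfg)
    recon = sg.synthesize(model, res.wplus,
                          noise=[m[None, None] for m in res.noise_maps])
    rel_mse = float(((recon - target) ** 2).mean() / (target ** 2).mean())
    return {
        "perceptual_ratio": float(res.loss_trace[-1, 1] / res.loss_trace[0, 1]),
        "relative_mse": rel_mse,
        "iterations": iterations,
    }


def end_to_end(seed: int, n_train_per_cohort: int = 1000, resolution: int = 32,
               kimg: float = 9.6, n_proj: int = 30, proj_iterations: int = 120,
               n_alphas: int = 5) -> dict:
    """Scaled-down full pipeline: cohort phantoms -> GAN -> inversion -> SVM
    direction -> manipulation of HC subjects toward the diseased cohort -> BPF.

    Returns the mean BPF trajectory over the alpha grid, the BPF drop between
    baseline and the strongest edit, and the fraction of subjects whose
    BPF-vs-alpha Spearman correlation is negative.
    """
    hc = ph.sample_cohort(n_train_per_cohort, "HC", seed=subseed(seed, "e2e-hc"),
                          size=resolution)
    ms = ph.sample_cohort(n_train_per_cohort, "MS", seed=subseed(seed, "e2e-ms"),
                          size=resolution)
    data = np.stack([p.channels for p in hc + ms])
    tcfg = sg.TrainConfig(kimg_budget=kimg, batch_size=16, metric_interval=200,
                          seed=subseed(seed, "e2e-train"))
    result = sg.train(data, tcfg, sg.GeneratorConfig(
        resolution=resolution, latent_dim=64, seed=subseed(seed, "e2e-train")))
    model = result.model

    def invert(cohort, tag):
        lats, noises = [], []
        for i, p in enumerate(cohort[:n_proj]):
            cfg = pj.ProjectionConfig(
                iterations=proj_iterations, init_samples=256, init_top_k=32,
                lr_rampup_iters=10, lr_rampdown_iters=30, noise_ramp_iters=30,
                seed=subseed(seed, f"e2e-proj-{tag}-{i}"))
            r = pj.project(model, p.channels, cfg)
            lats.append(r.wplus)
            noises.append(r.noise_maps)
        return np.stack(lats), noises

    hc_lat, hc_noise = invert(hc, "hc")
    ms_lat, _ = invert(ms, "ms")
    flat_hc = hc_lat.reshape(n_proj, -1)
    flat_ms = ms_lat.reshape(n_proj, -1)
    direction = sem.fit_direction(flat_hc, flat_ms, folds=min(10, n_proj),
                                  attribute="MS", seed=subseed(seed, "e2e-svm"))

    separation = float((flat_ms.mean(0) - flat_hc.mean(0)) @ direction.n)
    alpha_max = 2.0 * abs(separation)
    grid = np.linspace(0.0, alpha_max, n_alphas)

    bpf = np.full((n_proj, n_alphas), np.nan)
    for i in range(n_proj):
        series = sem.manipulate(model, hc_lat[i], direction.n, grid,
                                noise_maps=hc_noise[i])
        for j, img in enumerate(series.images):
            try:
                seg = mm.segment_tissues(img[0], seed=0, contrast="t1w")
                bpf[i, j] = mm.bpf_from_labels(seg)
            except ValueError:
                pass  # degenerate edit; stays NaN
    rho = np.array([spearmanr(grid, row).statistic for row in bpf])
    valid = np.isfinite(rho)
    return {
        "alpha_grid": grid.tolist(),
        "mean_bpf": np.nanmean(bpf, axis=0).tolist(),
        "bpf_drop": float(np.nanmean(bpf[:, 0]) - np.nanmean(bpf[:, -1])),
        "fraction_negative_correlation": float((rho[valid] < 0).mean()),
        "latent_separation": separation,
        "final_frechet": float(result.history["frechet"][-1]),
        "initial_frechet": float(result.history["frechet"][0]),
        "n_subjects": int(n_proj),
        "n_train_images": int(2 * n_train_per_cohort),
    }
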