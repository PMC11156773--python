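"""Synthetic 2D brain-slice phantoms with known tissue masks.

A phantom is an elliptical "head" containing ventricular CSF, a cortical
gray-matter ribbon, white matter, and optional periventricular lesions. The
geometry is controlled by a small attribute record so that morphometric
summary statistics — ventricular area, cortical thickness, brain parenchymal
fraction (BPF), lesion load — are known exactly and can serve as ground truth
for segmentation and latent-manipulation experiments.

Two contrasts are emulated. ``t1w_multiecho`` stacks three gradient-echo
channels at echo times TE = 8.12, 13.19 and 19.26 ms; the intensity of tissue
``tau`` in channel ``c`` follows a mono-exponential T2* decay
``S0(tau) * exp(-TE_c / T2*(tau))``, so per-tissue intensity is non-increasing
across channels. ``adc`` maps have one physical channel duplicated three
times, with CSF and lesions bright and white matter dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_TE_MS = (8.12, 13.19, 19.26)

# t1w: proton-density-like amplitude and T2* (ms) per tissue; ordering WM > GM > CSF > bg
_T1W_S0 = {"background": 0.02, "csf": 0.25, "gm": 0.70, "wm": 0.92, "lesion": 0.55}
_T1W_T2S = {"background": 1e9, "csf": 200.0, "gm": 65.0, "wm": 50.0, "lesion": 90.0}

# adc: single intensity per tissue; CSF ~ lesion bright, WM dark
_ADC_LEVEL = {"background": 0.02, "csf": 0.95, "gm": 0.55, "wm": 0.40, "lesion": 0.90}

TISSUES = ("background", "csf", "gm", "wm")


@dataclass(frozen=True)
class AttributeRecord:
    """Generating attributes of one phantom."""

    cohort_label: str = "HC"
    ventricle_scale: float = 1.0
    cortical_thinning: float = 0.0
    lesion_count: int = 0
    slice_position: int = 2
    age_proxy: float = 37.0
    contrast: str = "t1w_multiecho"
    seed: int = 0

    def __post_init__(self):
        if self.ventricle_scale < 0:
            raise ValueError("ventricle_scale must be >= 0")
        if not 0.0 <= self.cortical_thinning <= 1.0:
            raise ValueError("cortical_thinning must be in [0, 1]")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if self.cohort_label not in ("HC", "MS"):
            raise ValueError(f"unknown cohort label: {self.cohort_label!r}")
        if self.contrast not in ("t1w_multiecho", "adc"):
            raise ValueError(f"unknown contrast: {self.contrast!r}")


@dataclass
class Phantom:
    """Rendered phantom: 3-channel raster plus ground-truth masks."""

    channels: np.ndarray  # (3, H, W) in [0, 1]
    tissue_masks: dict[str, np.ndarray]  # four mutually exclusive boolean masks
    lesion_mask: np.ndarray
    attrs: AttributeRecord
    te_values: tuple[float, ...] = field(default=DEFAULT_TE_MS)

    @property
    def image(self) -> np.ndarray:
        return self.channels


@dataclass
class CohortModel:
    """Cohort-conditional attribute distributions.

    Ventricle size is log-normal with the MS location shifted +0.25 on the log
    scale; lesion counts are Poisson; ages follow the per-cohort demographics
    (HC 36.9 +/- 12.6 yrs, MS 38.8 +/- 10.1 yrs); six slice positions.
    """

    vent_logmu: dict[str, float] = field(default_factory=lambda: {"HC": 0.0, "MS": 0.25})
    vent_logsigma: dict[str, float] = field(default_factory=lambda: {"HC": 0.15, "MS": 0.20})
    lesion_rate_adc: dict[str, float] = field(default_factory=lambda: {"HC": 0.3, "MS": 4.0})
    lesion_rate_t1w: dict[str, float] = field(default_factory=lambda: {"HC": 0.1, "MS": 1.5})
    thinning_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (2.0, 20.0), "MS": (4.0, 12.0)})
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (36.94, 12.55), "MS": (38.75, 10.08)})
    n_slice_positions: int = 6


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / max(ry, 1e-9)) ** 2 + ((xx - cx) / max(rx, 1e-9)) ** 2 <= 1.0


def make_phantom(attrs: AttributeRecord, size: int = 64, noise_std: float = 0.02) -> Phantom:
    """Render one phantom at ``size`` x ``size`` pixels (power of two, >= 32).

    Deterministic given ``(attrs, size, noise_std)``; the only randomness is
    the additive acquisition noise and lesion placement, both driven by
    ``attrs.seed``.
    """
    if size < 32 or (size & (size - 1)) != 0:
        raise ValueError(f"size must be a power of two >= 32, got {size}")
    rng = np.random.default_rng(np.uint32(attrs.seed * 2654435761 % (2**31)))
    h = w = size
    cy = cx = (size - 1) / 2.0

    # head ellipse: axes scale with age and slice position (superior slices smaller)
    age_factor = 1.0 + 0.04 * np.tanh((attrs.age_proxy - 37.0) / 25.0)
    slice_factor = 1.0 - 0.025 * abs(attrs.slice_position - 2)
    ry_head = 0.44 * size * age_factor * slice_factor
    rx_head = 0.36 * size * age_factor * slice_factor
    head = _ellipse(h, w, cy, cx, ry_head, rx_head)

    # lateral ventricles: two para-central ellipses, area proportional to ventricle_scale
    s = np.sqrt(attrs.ventricle_scale)
    ry_v, rx_v = 0.16 * size * s, 0.07 * size * s
    if ry_v > 0.85 * ry_head or rx_v > 0.40 * rx_head:
        raise ValueError(
            f"ventricle_scale={attrs.ventricle_scale} yields ventricles larger than the head")
    dx = 0.085 * size
    vent = (_ellipse(h, w, cy - 0.02 * size, cx - dx, ry_v, rx_v)
            | _ellipse(h, w, cy - 0.02 * size, cx + dx, ry_v, rx_v))
    vent &= head

    # cortical gray-matter ribbon: between the head boundary and an inner ellipse
    thickness = 0.09 * (1.0 - attrs.cortical_thinning) + 0.015
    inner = _ellipse(h, w, cy, cx, ry_head * (1 - thickness), rx_head * (1 - thickness))
    gm = head & ~inner
    wm = inner & ~vent
    gm &= ~vent
    csf = vent
    background = ~head

    # periventricular lesion blobs inside WM
    lesion = np.zeros((h, w), dtype=bool)
    for _ in range(attrs.lesion_count):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(1.12, 1.6)
        ly = cy - 0.02 * size + rad * ry_v * np.sin(ang)
        lx = cx + np.sign(np.cos(ang)) * dx + rad * rx_v * np.cos(ang)
        r_l = rng.uniform(0.015, 0.035) * size
        lesion |= _ellipse(h, w, ly, lx, r_l, r_l)
    lesion &= (wm | gm)

    masks = {"background": background, "csf": csf, "gm": gm, "wm": wm}

    channels = np.zeros((3, h, w), dtype=np.float64)
    if attrs.contrast == "t1w_multiecho":
        for c, te in enumerate(DEFAULT_TE_MS):
            img = np.zeros((h, w))
            for t in TISSUES:
                img[masks[t]] = _T1W_S0[t] * np.exp(-te / _T1W_T2S[t])
            img[lesion] = _T1W_S0["lesion"] * np.exp(-te / _T1W_T2S["lesion"])
            channels[c] = img
        if noise_std > 0:
            channels = channels + rng.normal(0.0, noise_std, channels.shape)
    else:  # adc: one physical channel (incl. its noise) duplicated
        img = np.zeros((h, w))
        for t in TISSUES:
            img[masks[t]] = _ADC_LEVEL[t]
        img[lesion] = _ADC_LEVEL["lesion"]
        if noise_std > 0:
            img = img + rng.normal(0.0, noise_std, img.shape)
        channels[:] = img[None]

    channels = np.clip(channels, 0.0, 1.0).astype(np.float32)

    return Phantom(channels=channels, tissue_masks=masks, lesion_mask=lesion, attrs=attrs)


def sample_attributes(n: int, label: str, contrast: str = "t1w_multiecho",
                      seed: int = 0, model: CohortModel | None = None) -> list[AttributeRecord]:
    """Draw ``n`` attribute records from the cohort-conditional distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if label not in ("HC", "MS"):
        raise ValueError(f"unknown cohort label: {label!r}")
    if model is None:
        model = CohortModel()
    rng = np.random.default_rng(seed)
    rate = (model.lesion_rate_adc if contrast == "adc" else model.lesion_rate_t1w)[label]
    a, b = model.thinning_beta[label]
    mu_age, sd_age = model.age_mean_sd[label]
    out = []
    for i in range(n):
        out.append(AttributeRecord(
            cohort_label=label,
            ventricle_scale=float(rng.lognormal(model.vent_logmu[label],
                                                model.vent_logsigma[label])),
            cortical_thinning=float(rng.beta(a, b)),
            lesion_count=int(rng.poisson(rate)),
            slice_position=int(rng.integers(0, model.n_slice_positions)),
            age_proxy=float(np.clip(rng.normal(mu_age, sd_age), 18.0, 75.0)),
            contrast=contrast,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


def sample_cohort(n: int, label: str, contrast: str = "t1w_multiecho", seed: int = 0,
                  size: int = 64, noise_std: float = 0.02,
                  model: CohortModel | None = None) -> list[Phantom]:
    """Render a cohort of ``n`` phantoms with attributes from :func:`sample_attributes`."""
    attrs = sample_attributes(n, label, contrast=contrast, seed=seed, model=model)
    return [make_phantom(a, size=size, noise_std=noise_std) for a in attrs]


def analytic_bpf(p: Phantom) -> float:
    """Ground-truth brain parenchymal fraction (GM+WM)/(GM+WM+CSF) by pixel count."""
    gm = int(p.tissue_masks["gm"].sum())
    wm = int(p.tissue_masks["wm"].sum())
    csf = int(p.tissue_masks["csf"].sum())
    intracranial = gm + wm + csf
    if intracranial == 0:
        raise ValueError("phantom has an empty intracranial region")
    return (gm + wm) / intracranial


def rescale(attrs: AttributeRecord, **changes) -> AttributeRecord:
    """Convenience copy-with-changes for attribute records."""
    return replace(attrs, **changes)
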