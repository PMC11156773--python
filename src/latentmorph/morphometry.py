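"""Morphometric analysis of (manipulated) brain slices.

Tissue volumes come from k-means intensity clustering with k = 4 clusters
(background, CSF, gray matter, white matter) on a single channel of a single
2D slice. The background cluster is identified as the one dominating the
image border; the remaining clusters are mapped to tissues by centroid
intensity, in the order appropriate for the contrast (T1w: CSF < GM < WM;
ADC: WM < GM < CSF). The brain parenchymal fraction

    BPF = (V_GM + V_WM) / (V_GM + V_WM + V_CSF)

is the atrophy surrogate tracked across latent-manipulation strength alpha;
per-alpha changes against baseline are tested with a two-sided paired t-test
at a 0.001 significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .semantics import ManipulationSeries

SIGNIFICANCE_THRESHOLD = 0.001

_TISSUE_ORDER = {
    "t1w": ("csf", "gm", "wm"),   # ascending intensity
    "adc": ("wm", "gm", "csf"),
}


@dataclass
class TissueSegmentation:
    labels: np.ndarray               # str-labeled per-pixel map
    centroids: dict[str, float]
    assignment_rule: dict

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == tissue

    def counts(self) -> dict[str, int]:
        return {t: int((self.labels == t).sum()) for t in ("background", "csf", "gm", "wm")}


@dataclass
class BPFCurve:
    alpha_grid: np.ndarray
    bpf: np.ndarray                  # (subjects, alphas)
    volumes: list[dict]              # per-alpha mean V_GM/V_WM/V_CSF
    t_values: np.ndarray
    p_values: np.ndarray             # NaN where the paired test is degenerate/undefined
    significant: np.ndarray
    significance_threshold: float = SIGNIFICANCE_THRESHOLD
    baseline_index: int = 0


def segment_tissues(image: np.ndarray, seed: int = 0, contrast: str = "t1w",
                    n_init: int = 10) -> TissueSegmentation:
    """k-means (k = 4) tissue segmentation of a single-channel raster."""
    img = np.asarray(image, np.float64)
    if img.ndim == 3:
        img = img[0]
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D raster")
    if contrast not in _TISSUE_ORDER:
        raise ValueError(f"unknown contrast: {contrast!r}")
    if np.ptp(img) == 0:
        raise ValueError("constant image cannot be segmented")
    km = KMeans(n_clusters=4, n_init=n_init, random_state=seed)
    flat_labels = km.fit_predict(img.reshape(-1, 1))
    labels = flat_labels.reshape(img.shape)
    centers = km.cluster_centers_.ravel()

    border = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    bg_cluster = int(np.bincount(border, minlength=4).argmax())
    rest = [c for c in range(4) if c != bg_cluster]
    rest_sorted = sorted(rest, key=lambda c: centers[c])
    mapping = {bg_cluster: "background"}
    for cluster, tissue in zip(rest_sorted, _TISSUE_ORDER[contrast]):
        mapping[cluster] = tissue

    named = np.empty(img.shape, dtype=object)
    for cluster, tissue in mapping.items():
        named[labels == cluster] = tissue
    named = named.astype(str)
    if not np.isin(named, ("csf", "gm", "wm")).any():
        raise ValueError("segmentation found no non-background tissue")
    return TissueSegmentation(
        labels=named,
        centroids={t: float(centers[c]) for c, t in mapping.items()},
        assignment_rule={"background": "border-dominant cluster",
                         "order": _TISSUE_ORDER[contrast], "contrast": contrast,
                         "cluster_to_tissue": {int(c): t for c, t in mapping.items()}},
    )


def bpf_from_labels(seg: TissueSegmentation) -> float:
    """(V_GM + V_WM) / (V_GM + V_WM + V_CSF) from a label map (single 2D slice)."""
    c = seg.counts()
    intracranial = c["gm"] + c["wm"] + c["csf"]
    if intracranial == 0:
        raise ValueError("empty intracranial region")
    return (c["gm"] + c["wm"]) / intracranial


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p), with p = NaN when degenerate."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(x - y) == 0:
        return (np.nan, np.nan)
    t, p = stats.ttest_rel(x, y)
    return (float(t), float(p))


def bpf_curve(series_per_subject: list[ManipulationSeries], contrast: str = "t1w",
              seed: int = 0) -> BPFCurve:
    """Segment every image of every subject's manipulation series and track BPF.

    Each per-alpha BPF column is compared against the alpha = 0 column with a
    paired t-test; entries with p below the 0.001 threshold are flagged. With a
    single subject (or zero-variance differences) p is NaN and nothing is
    flagged.
    """
    if not series_per_subject:
        raise ValueError("no subjects given")
    grid = series_per_subject[0].alpha_grid
    for s in series_per_subject[1:]:
        if not np.array_equal(s.alpha_grid, grid):
            raise ValueError("all subjects must share one alpha grid")
    n_sub, n_alpha = len(series_per_subject), len(grid)
    bpf = np.zeros((n_sub, n_alpha))
    vols = [dict(gm=0.0, wm=0.0, csf=0.0) for _ in range(n_alpha)]
    for i, series in enumerate(series_per_subject):
        for j, img in enumerate(series.images):
            seg = segment_tissues(img, seed=seed, contrast=contrast)
            bpf[i, j] = bpf_from_labels(seg)
            c = seg.counts()
            for t in ("gm", "wm", "csf"):
                vols[j][t] += c[t] / n_sub
    baseline = series_per_subject[0].baseline_index
    t_vals = np.full(n_alpha, np.nan)
    p_vals = np.full(n_alpha, np.nan)
    for j in range(n_alpha):
        if j == baseline or n_sub < 2:
            continue
        t_vals[j], p_vals[j] = paired_ttest(bpf[:, j], bpf[:, baseline])
    significant = np.zeros(n_alpha, dtype=bool)
    finite = np.isfinite(p_vals)
    significant[finite] = p_vals[finite] < SIGNIFICANCE_THRESHOLD
    return BPFCurve(alpha_grid=grid, bpf=bpf, volumes=vols, t_values=t_vals,
                    p_values=p_vals, significant=significant, baseline_index=baseline)


def intensity_profile(image: np.ndarray, row_index: int,
                      col_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw intensity of one row and one column (channel 0) through the image."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[0]
    h, w = img.shape
    if not (0 <= row_index < h and 0 <= col_index < w):
        raise IndexError(f"profile indices ({row_index}, {col_index}) out of bounds "
                         f"for {h}x{w} image")
    return img[row_index, :].copy(), img[:, col_index].copy()


def difference_map(image: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Signed change from baseline (positive = intensity increase)."""
    a = np.asarray(image, np.float64)
    b = np.asarray(baseline, np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b
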