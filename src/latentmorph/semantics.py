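"""Semantic directions in latent space and image editing along them.

A binary attribute (e.g. healthy-control vs MS cohort) is located in the
extended latent space by fitting a linear SVM to the flattened projected
codes of the two groups; the unit normal of the separating hyperplane is the
attribute's latent direction. Editing moves a code along the direction,
``image = G_syn(w+ + alpha * n)``, optionally after conditionalizing the
direction against a confounder's direction (removing its parallel component)
so the edit leaves the confounding attribute's latent coordinate unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import svm

from .stylegan import GeneratorModel, synthesize


@dataclass
class SemanticDirection:
    """Unit normal of an SVM hyperplane in flattened W+."""

    n: np.ndarray
    attribute: str = ""
    hyperplane_offset: float = 0.0
    cv_report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n = np.asarray(self.n, np.float64)
        norm = np.linalg.norm(self.n)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, got |n| = {norm}")


@dataclass
class ManipulationSeries:
    alpha_grid: np.ndarray
    images: list[np.ndarray]
    wplus_series: list[np.ndarray]
    baseline_index: int


def _svm_normal(x: np.ndarray, y: np.ndarray, C: float,
                random_state: int = 0) -> tuple[np.ndarray, float]:
    clf = svm.LinearSVC(C=C, loss="hinge", max_iter=100_000, tol=1e-6,
                        random_state=random_state)
    clf.fit(x, y)
    if getattr(clf, "n_iter_", 0) >= 100_000:
        raise RuntimeError("SVM solver did not converge")
    w = clf.coef_.ravel().astype(np.float64)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise RuntimeError("degenerate SVM solution (zero weight vector)")
    return w / norm, float(clf.intercept_[0] / norm)


def fit_direction(latents_a: np.ndarray, latents_b: np.ndarray, folds: int = 10,
                  attribute: str = "", C: float = 1.0, seed: int = 0) -> SemanticDirection:
    """Linear-SVM hyperplane normal pointing from group A toward group B.

    The released direction comes from a full-data fit; ``folds``-fold
    cross-validation reports per-fold hold-out accuracy and the pairwise
    cosines between fold directions (a stability check).
    """
    a = np.asarray(latents_a, np.float64).reshape(len(latents_a), -1)
    b = np.asarray(latents_b, np.float64).reshape(len(latents_b), -1)
    if a.shape[1] != b.shape[1]:
        raise ValueError("latent sets must share vector length")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per class")
    x = np.concatenate([a, b])
    y = np.concatenate([np.zeros(len(a)), np.ones(len(b))])

    n_full, offset = _svm_normal(x, y, C)

    cv: dict = {"fold_accuracy": [], "fold_cosines": []}
    fold_dirs = []
    if folds >= 2 and len(x) >= folds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(x))
        splits = np.array_split(order, folds)
        for k in range(folds):
            test_idx = splits[k]
            train_idx = np.concatenate([splits[j] for j in range(folds) if j != k])
            if len(np.unique(y[train_idx])) < 2:
                continue
            nk, off_k = _svm_normal(x[train_idx], y[train_idx], C)
            fold_dirs.append(nk)
            pred = (x[test_idx] @ nk + off_k) > 0
            cv["fold_accuracy"].append(float((pred == y[test_idx]).mean()))
        for i in range(len(fold_dirs)):
            for j in range(i + 1, len(fold_dirs)):
                cv["fold_cosines"].append(float(fold_dirs[i] @ fold_dirs[j]))
    return SemanticDirection(n=n_full, attribute=attribute,
                             hyperplane_offset=offset, cv_report=cv)


def conditionalize(n1: SemanticDirection | np.ndarray,
                   n2: SemanticDirection | np.ndarray) -> np.ndarray:
    """Remove from n1 its component along n2: normalize(n1 - (n1.n2) n2).

    The result is exactly orthogonal to n2, so moving along it changes
    attribute 1 while leaving attribute 2's latent coordinate fixed. The
    output is renormalized to unit length so the editing scale of alpha is
    preserved.
    """
    v1 = np.asarray(n1.n if isinstance(n1, SemanticDirection) else n1, np.float64)
    v2 = np.asarray(n2.n if isinstance(n2, SemanticDirection) else n2, np.float64)
    resid = v1 - (v1 @ v2) * v2
    norm = np.linalg.norm(resid)
    if norm < 1e-8:
        raise ValueError("directions are (anti)parallel; conditionalization is degenerate")
    resid /= norm
    # one re-orthogonalization pass absorbs the floating-point residual
    resid -= (resid @ v2) * v2
    return resid / np.linalg.norm(resid)


def direction_similarity(d1, d2) -> float:
    """Inner product of two unit directions (cosine, in [-1, 1])."""
    v1 = np.asarray(d1.n if isinstance(d1, SemanticDirection) else d1, np.float64)
    v2 = np.asarray(d2.n if isinstance(d2, SemanticDirection) else d2, np.float64)
    if v1.shape != v2.shape:
        raise ValueError("direction length mismatch")
    return float(v1 @ v2)


def manipulate(model: GeneratorModel, wplus: np.ndarray,
               direction: SemanticDirection | np.ndarray, alpha_grid,
               noise_maps=None, layer_range: tuple[int, int] | None = None) -> ManipulationSeries:
    """Edit an inverted code along a direction over a grid of scaling factors.

    For each alpha the flattened direction is reshaped to (L, d) and the image
    ``G_syn(w+ + alpha * n)`` is synthesized with the (fixed) noise maps of the
    projection. ``layer_range`` optionally restricts the edit to a span of
    style layers.
    """
    alpha_grid = np.asarray(alpha_grid, np.float64)
    if not np.any(alpha_grid == 0.0):
        raise ValueError("alpha grid must contain the baseline alpha = 0")
    if np.any(np.diff(alpha_grid) <= 0):
        raise ValueError("alpha grid must be strictly increasing")
    wplus = np.asarray(wplus, np.float32)
    L, d = model.num_style_layers, model.cfg.latent_dim
    if wplus.shape != (L, d):
        raise ValueError(f"wplus must be ({L}, {d})")
    v = np.asarray(direction.n if isinstance(direction, SemanticDirection) else direction,
                   np.float64)
    if v.size != L * d:
        raise ValueError(f"direction length {v.size} does not match L*d = {L * d}")
    step = v.reshape(L, d).astype(np.float32)
    if layer_range is not None:
        lo, hi = layer_range
        mask = np.zeros((L, 1), np.float32)
        mask[lo:hi] = 1.0
        step = step * mask
    if noise_maps is None:
        noise = "zero"
    else:
        noise = [np.asarray(m, np.float32).reshape(1, 1, *np.asarray(m).shape[-2:])
                 for m in noise_maps]
    images, codes = [], []
    for alpha in alpha_grid:
        w_edit = wplus + np.float32(alpha) * step
        images.append(synthesize(model, w_edit, noise=noise))
        codes.append(w_edit)
    baseline = int(np.nonzero(alpha_grid == 0.0)[0][0])
    return ManipulationSeries(alpha_grid=alpha_grid, images=images,
                              wplus_series=codes, baseline_index=baseline)
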