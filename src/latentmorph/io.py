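"""Image and table I/O: 16-bit PNG per channel, NIfTI for multi-channel stacks."""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image


def write_image(path, image: np.ndarray) -> None:
    """Write an image in [0, 1].

    ``.png``: single channel only, stored as 16-bit grayscale. ``.nii`` /
    ``.nii.gz``: (C, H, W) stored as an (H, W, 1, C) volume so the channel axis
    rides in the 4th (echo/time) dimension.
    """
    path = Path(path)
    img = np.asarray(image, np.float64)
    if path.suffix == ".png":
        if img.ndim == 3:
            if img.shape[0] != 1:
                raise ValueError("PNG export is per channel; write channels separately "
                                 "or use NIfTI for multi-channel images")
            img = img[0]
        arr = np.clip(img * 65535.0 + 0.5, 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        if img.ndim == 2:
            img = img[None]
        vol = np.transpose(img, (1, 2, 0))[:, :, None, :].astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown image format: {path.suffix!r}")


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a PNG or NIfTI image; returns ((C, H, W) in [0, 1], metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix == ".png":
        with Image.open(path) as im:
            arr = np.asarray(im)
        if arr.dtype == np.uint8:
            scale = 255.0
        else:
            arr = arr.astype(np.uint16)
            scale = 65535.0
        img = (arr / scale)[None].astype(np.float32)
        return img, {"format": "png", "original_range": (0, int(scale)), "path": str(path)}
    if path.name.endswith((".nii", ".nii.gz")):
        try:
            vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        except Exception as e:
            raise ValueError(f"corrupt NIfTI file {path}: {e}") from e
        if vol.ndim == 4:
            img = np.transpose(vol[:, :, 0, :], (2, 0, 1))
        elif vol.ndim == 3:
            img = np.transpose(vol, (2, 0, 1))
        elif vol.ndim == 2:
            img = vol[None]
        else:
            raise ValueError(f"unsupported NIfTI dimensionality: {vol.ndim}")
        lo, hi = float(img.min()), float(img.max())
        if hi > 1.0 or lo < 0.0:
            img = (img - lo) / max(hi - lo, 1e-12)
        return img.astype(np.float32), {"format": "nifti", "original_range": (lo, hi),
                                        "path": str(path)}
    raise ValueError(f"unknown image format: {path.suffix!r}")


def export_cohort(out_dir, phantoms, fmt: str = "nifti") -> pd.DataFrame:
    """Write a cohort to disk plus its metadata table (CSV); returns the table."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, p in enumerate(phantoms):
        stem = f"{p.attrs.cohort_label.lower()}_{i:04d}"
        if fmt == "nifti":
            write_image(out_dir / f"{stem}.nii.gz", p.channels)
        elif fmt == "png":
            for c in range(p.channels.shape[0]):
                write_image(out_dir / f"{stem}_ch{c}.png", p.channels[c:c + 1])
        else:
            raise ValueError(f"unknown export format: {fmt!r}")
        rows.append({"subject_id": stem, "cohort": p.attrs.cohort_label,
                     "age_proxy": p.attrs.age_proxy,
                     "slice_position": p.attrs.slice_position,
                     "ventricle_scale": p.attrs.ventricle_scale,
                     "lesion_count": p.attrs.lesion_count,
                     "seed": p.attrs.seed})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "metadata.csv", index=False)
    return table
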