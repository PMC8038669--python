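"""Reading and writing angiograms, masks, cohort tables and sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .density import EnFaceAngiogram, SkeletonMask, VesselMask

__all__ = [
    "read_angiogram",
    "write_angiogram",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "write_sidecar",
    "sha256_file",
]

COHORT_COLUMNS = [
    "eye_id",
    "group",
    "timepoint",
    "age",
    "sex",
    "disease_duration",
    "ivi_before",
    "ivi_between",
    "atrophy",
    "fibrosis",
    "mnv_subtype",
    "anti_vegf",
    "regimen",
    "scp_mpd",
    "scp_mvd",
    "dcp_mpd",
    "dcp_mvd",
]


def read_angiogram(
    path,
    fov_mm: float = 6.0,
    plexus: str = "SCP",
    signal_strength: Optional[int] = None,
) -> EnFaceAngiogram:
    """Read an 8/16-bit grayscale PNG or TIFF as an angiogram in [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse an RGB(A) export to luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return EnFaceAngiogram(
        pixels=np.clip(arr, 0.0, 1.0),
        fov_mm=fov_mm,
        plexus=plexus,
        signal_strength=signal_strength,
    )


def write_angiogram(path, img: EnFaceAngiogram | np.ndarray, bitdepth: int = 8) -> Path:
    """Write an intensity grid in [0, 1] as grayscale PNG (8-bit) or TIFF (16-bit)."""
    path = Path(path)
    pixels = img.pixels if isinstance(img, EnFaceAngiogram) else np.asarray(img, float)
    if bitdepth == 8:
        data = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    elif bitdepth == 16:
        data = np.round(np.clip(pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    return path


def write_mask(path, mask: VesselMask | SkeletonMask | np.ndarray) -> Path:
    """Write a binary mask or skeleton as a 0/255 PNG."""
    path = Path(path)
    if isinstance(mask, VesselMask):
        arr = mask.mask
    elif isinstance(mask, SkeletonMask):
        arr = mask.skeleton
    else:
        arr = np.asarray(mask).astype(bool)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))
    return path


def write_cohort(path, cohort: pd.DataFrame) -> Path:
    path = Path(path)
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in cols]
    cohort[cols + extra].to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"eye_id", "group", "timepoint"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    for col in ("atrophy", "fibrosis"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_sidecar(path, payload: dict) -> Path:
    """Record the seed and parameters of a generated artifact as JSON."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
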