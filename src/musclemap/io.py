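"""Reading and writing slices, masks, labels and cohort manifests.

HU arrays travel as NPZ (lossless float) or 16-bit PNG with a +1024 offset
(the usual trick for nonnegative integer storage of CT data); label maps as
paletted PNG (black/red/green for Background/Muscle/Inside); masks as 8-bit
binary PNG.  DICOM input is read with pydicom, applying RescaleSlope and
RescaleIntercept to recover HU.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .phantom import HUImage, LabelMap, PhantomSample

__all__ = [
    "save_hu",
    "load_hu",
    "save_labels",
    "load_labels",
    "save_mask",
    "load_mask",
    "read_dicom_hu",
    "write_manifest",
]

HU_PNG_OFFSET = 1024
LABEL_COLORS = np.array(
    [[0, 0, 0], [255, 0, 0], [0, 255, 0]], dtype=np.uint8
)  # black / red / green


def save_hu(path: str | Path, img: HUImage) -> None:
    """NPZ (``.npz``) keeps floats exactly; PNG (``.png``) stores
    round(HU) + 1024 as uint16, clipped to [0, 65535]."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, hu=img.values, pixel_spacing=img.pixel_spacing)
    elif path.suffix == ".png":
        enc = np.clip(np.round(img.values) + HU_PNG_OFFSET, 0, 65535).astype(np.uint16)
        iio.imwrite(path, enc)
    else:
        raise ValueError(f"unsupported HU format {path.suffix!r} (use .npz or .png)")


def load_hu(path: str | Path, pixel_spacing: float = 1.0) -> HUImage:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return HUImage(z["hu"], float(z["pixel_spacing"]))
    if path.suffix == ".png":
        enc = iio.imread(path).astype(np.float64)
        return HUImage(enc - HU_PNG_OFFSET, pixel_spacing)
    if path.suffix == ".dcm":
        return read_dicom_hu(path)
    raise ValueError(f"unsupported HU format {path.suffix!r}")


def save_labels(path: str | Path, labels: LabelMap) -> None:
    """Label maps as RGB PNG using the fixed black/red/green legend."""
    iio.imwrite(Path(path), LABEL_COLORS[labels.classes])


def load_labels(path: str | Path) -> LabelMap:
    rgb = iio.imread(Path(path))
    if rgb.ndim == 2:  # already an index image
        return LabelMap(rgb)
    classes = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for idx, color in enumerate(LABEL_COLORS):
        classes[(rgb[..., :3] == color).all(axis=-1)] = idx
    return LabelMap(classes)


def save_mask(path: str | Path, mask) -> None:
    values = mask.values if hasattr(mask, "values") else np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (values.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def read_dicom_hu(path: str | Path) -> HUImage:
    """One axial slice from DICOM, rescaled to HU."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
    return HUImage(hu, spacing)


def write_manifest(path: str | Path, samples: Sequence[PhantomSample], paths: Sequence[dict] | None = None) -> None:
    """Cohort manifest CSV: id, stratum, habitus, seed and optional paths."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["id", "stratum", "habitus", "seed", "hu_path", "label_path"])
        for i, s in enumerate(samples):
            extra = paths[i] if paths else {}
            w.writerow(
                [
                    s.info.get("index", i),
                    s.info.get("stratum", ""),
                    f"{s.info.get('habitus', float('nan')):.4f}",
                    s.info.get("seed", ""),
                    extra.get("hu_path", ""),
                    extra.get("label_path", ""),
                ]
            )
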