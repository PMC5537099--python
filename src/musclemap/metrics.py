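"""Segmentation agreement metrics and error-overlay rendering.

Two published comparison measures:

    DSC        = 2 |GT ∩ P| / (|GT| + |P|)
    CSA error  = | |GT| - |P| | / |GT| x 100  (percent)

with areas counted in pixels (pixel spacing cancels in both).  Physical
cross-sectional area is |mask| x spacing^2 / 100 in cm^2.  Overlays follow
the standard tricolor convention: correctly segmented pixels red,
oversampled (predicted but not true) blue, undersampled (true but missed)
yellow, everything else black.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .threshold import BinaryMask

__all__ = [
    "MetricsReport",
    "dsc",
    "csa_error",
    "csa_cm2",
    "overlay",
    "evaluate_masks",
    "summarize",
]

OVERLAY_COLORS = {
    "correct": (255, 0, 0),  # red: GT ∩ P
    "over": (0, 0, 255),  # blue: P \ GT
    "under": (255, 255, 0),  # yellow: GT \ P
    "none": (0, 0, 0),
}


class EmptyMaskError(ValueError):
    """A metric is undefined because the relevant mask(s) are empty."""


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.values
    return np.asarray(mask, dtype=bool)


@dataclass(frozen=True)
class MetricsReport:
    """Per-image agreement summary between ground truth and prediction."""

    dsc: float
    csa_error_pct: float
    gt_area_px: int
    pred_area_px: int
    gt_area_cm2: float | None
    pred_area_cm2: float | None
    n_over: int  # predicted but not true
    n_under: int  # true but missed


def dsc(gt, pred) -> float:
    """Dice similarity coefficient; symmetric, in [0, 1]."""
    g, p = _as_bool(gt), _as_bool(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    denom = int(g.sum()) + int(p.sum())
    if denom == 0:
        raise EmptyMaskError("DSC undefined: both masks are empty")
    return 2.0 * int((g & p).sum()) / denom


def csa_error(gt, pred) -> float:
    """Absolute percent difference in area relative to ground truth."""
    g, p = _as_bool(gt), _as_bool(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    ga = int(g.sum())
    if ga == 0:
        raise EmptyMaskError("CSA error undefined: ground truth mask is empty")
    return abs(ga - int(p.sum())) / ga * 100.0


def csa_cm2(mask: BinaryMask) -> float:
    """Physical cross-sectional area: pixels x spacing^2, mm^2 -> cm^2."""
    if not isinstance(mask, BinaryMask) or mask.pixel_spacing is None:
        raise ValueError("csa_cm2 requires a BinaryMask with pixel spacing")
    if mask.pixel_spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    return mask.area_px * mask.pixel_spacing**2 / 100.0


def overlay(gt, pred) -> np.ndarray:
    """(h, w, 3) uint8 tricolor error overlay (red/blue/yellow/black)."""
    g, p = _as_bool(gt), _as_bool(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    img = np.zeros(g.shape + (3,), dtype=np.uint8)
    img[g & p] = OVERLAY_COLORS["correct"]
    img[p & ~g] = OVERLAY_COLORS["over"]
    img[g & ~p] = OVERLAY_COLORS["under"]
    return img


def evaluate_masks(gt, pred, pixel_spacing: float | None = None) -> MetricsReport:
    """Full per-image report: DSC, CSA error, areas, error decomposition."""
    g, p = _as_bool(gt), _as_bool(pred)
    if pixel_spacing is None and isinstance(gt, BinaryMask):
        pixel_spacing = gt.pixel_spacing
    to_cm2 = (
        (lambda n: n * pixel_spacing**2 / 100.0) if pixel_spacing else (lambda n: None)
    )
    return MetricsReport(
        dsc=dsc(g, p),
        csa_error_pct=csa_error(g, p),
        gt_area_px=int(g.sum()),
        pred_area_px=int(p.sum()),
        gt_area_cm2=to_cm2(int(g.sum())),
        pred_area_cm2=to_cm2(int(p.sum())),
        n_over=int((p & ~g).sum()),
        n_under=int((g & ~p).sum()),
    )


def summarize(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) per metric over a set of reports.

    With a single report the SD is undefined and reported as NaN.
    """
    if len(reports) == 0:
        raise ValueError("summarize requires at least one report")
    df = pd.DataFrame(
        {
            "dsc": [r.dsc for r in reports],
            "csa_error_pct": [r.csa_error_pct for r in reports],
            "gt_area_px": [r.gt_area_px for r in reports],
            "pred_area_px": [r.pred_area_px for r in reports],
        }
    )
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    return out
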