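"""HU-range thresholding: baseline segmentation and fat post-processing.

Lean muscle occupies a consistent Hounsfield interval ([-29, 150] under
intravenous contrast), and adipose tissue a disjoint one ([-190, -30]).
Two consequences drive this module: thresholding the muscle interval is the
classical semi-automated baseline (inaccurate wherever organs share the
lean-tissue range), and thresholding the fat interval yields a binary fat
map that removes intramuscular fat mistakenly segmented as muscle.

Intervals are closed on both ends.  The published fat/muscle ranges are
adjacent at -30/-29, so integer HU is partitioned unambiguously; real-valued
HU strictly inside (-30, -29) belongs to neither interval.  Post-processing
always consumes the original HU image, never the windowed grayscale, since
a narrow window may clip the fat range entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .phantom import HUImage

__all__ = [
    "ThresholdRanges",
    "BinaryMask",
    "threshold_segment",
    "fat_mask",
    "remove_intramuscular_fat",
    "HUThresholdSegmenter",
]


@dataclass(frozen=True)
class ThresholdRanges:
    """Disjoint closed HU intervals for muscle and fat."""

    muscle: tuple[float, float] = (-29.0, 150.0)
    fat: tuple[float, float] = (-190.0, -30.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("muscle", self.muscle), ("fat", self.fat)):
            if lo > hi:
                raise ValueError(f"{name} interval is empty: ({lo}, {hi})")
        if self.fat[0] <= self.muscle[1] and self.muscle[0] <= self.fat[1]:
            raise ValueError(
                f"muscle {self.muscle} and fat {self.fat} intervals overlap"
            )


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} pixel mask with the source image's pixel spacing (mm)."""

    values: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("BinaryMask requires a 2D array")
        if v.dtype != bool and not np.isin(v, (0, 1)).all():
            raise ValueError("BinaryMask values must be 0/1")
        object.__setattr__(self, "values", v.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_px(self) -> int:
        return int(self.values.sum())


def _as_hu_array(img: HUImage | np.ndarray) -> tuple[np.ndarray, float | None]:
    if isinstance(img, HUImage):
        return img.values, img.pixel_spacing
    return np.asarray(img, dtype=np.float64), None


def threshold_segment(img: HUImage | np.ndarray, lo: float, hi: float) -> BinaryMask:
    """Mask of pixels with lo <= HU <= hi (closed interval)."""
    if lo > hi:
        raise ValueError(f"lo must be <= hi, got ({lo}, {hi})")
    hu, spacing = _as_hu_array(img)
    return BinaryMask((hu >= lo) & (hu <= hi), spacing)


def fat_mask(img: HUImage | np.ndarray, ranges: ThresholdRanges | None = None) -> BinaryMask:
    """Binary fat map via HU thresholding of the fat interval."""
    ranges = ranges if ranges is not None else ThresholdRanges()
    return threshold_segment(img, *ranges.fat)


def remove_intramuscular_fat(
    pred_muscle: BinaryMask | np.ndarray,
    img: HUImage | np.ndarray,
    ranges: ThresholdRanges | None = None,
) -> BinaryMask:
    """Delete fat-HU pixels from a predicted muscle mask.

    Anti-extensive by construction: the result is a subset of the input
    mask, equal to it exactly when no predicted pixel carries fat-range HU.
    """
    pm = pred_muscle.values if isinstance(pred_muscle, BinaryMask) else np.asarray(pred_muscle, dtype=bool)
    spacing = pred_muscle.pixel_spacing if isinstance(pred_muscle, BinaryMask) else None
    hu, img_spacing = _as_hu_array(img)
    if pm.shape != hu.shape:
        raise ValueError(f"shape mismatch: mask {pm.shape} vs image {hu.shape}")
    fm = fat_mask(hu, ranges)
    return BinaryMask(pm & ~fm.values, spacing if spacing is not None else img_spacing)


class HUThresholdSegmenter(BaseEstimator):
    """Sklearn-style wrapper for the HU-interval baseline.

    ``predict`` maps an (n, h, w) stack of HU slices (or a list of
    :class:`HUImage`) to an (n, h, w) boolean muscle-mask stack.  There is
    nothing to learn; ``fit`` only validates the interval.
    """

    def __init__(self, lo: float = -29.0, hi: float = 150.0):
        self.lo = lo
        self.hi = hi

    def fit(self, X=None, y=None):
        if self.lo > self.hi:
            raise ValueError(f"lo must be <= hi, got ({self.lo}, {self.hi})")
        self.interval_ = (self.lo, self.hi)
        return self

    def predict(self, X) -> np.ndarray:
        self.fit()
        return np.stack(
            [threshold_segment(x, self.lo, self.hi).values for x in X]
        )
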