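"""Hounsfield-unit to bounded-bit-depth grayscale conversion.

CT pixels carry ~12 bits of dynamic range; display (and here, network
input) uses a linear window parameterized by window level WL (center, HU),
window width WW (span, HU) and bit depth BIT.  HU below the window floor
maps to gray 0, HU at or above the ceiling saturates to 2^BIT - 1, and the
interior is binned linearly:

    g = clip( floor((HU - (WL - WW/2)) / WW * 2^BIT), 0, 2^BIT - 1 )

The window is treated as the half-open interval [low, high): equal-width
bins, the window center maps to gray 2^(BIT-1), and for a fixed window the
6-bit image equals the 8-bit image right-shifted by two bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .phantom import HUImage

__all__ = [
    "WindowConfig",
    "GrayImage",
    "window_bounds",
    "hu_to_gray",
    "gray_levels",
    "sweep_grid",
    "SWEEP_WINDOW_SETTINGS",
    "HUWindower",
]

#: The seven (WL, WW) settings of the standard window sweep.
SWEEP_WINDOW_SETTINGS: tuple[tuple[float, float], ...] = (
    (40, 400),
    (40, 240),
    (40, 800),
    (40, 1200),
    (-40, 400),
    (100, 400),
    (160, 400),
)

_ALLOWED_BITS = (4, 6, 8, 10, 12)


@dataclass(frozen=True)
class WindowConfig:
    """(WL, WW, BIT): window level and width in HU, bits per pixel."""

    wl: float
    ww: float
    bit: int = 8

    def __post_init__(self) -> None:
        if self.ww <= 0:
            raise ValueError(f"window width must be positive, got {self.ww}")
        if self.bit not in _ALLOWED_BITS:
            raise ValueError(f"bit depth must be one of {_ALLOWED_BITS}, got {self.bit}")

    @property
    def bounds(self) -> tuple[float, float]:
        return window_bounds(self.wl, self.ww)

    @property
    def levels(self) -> int:
        return gray_levels(self.bit)


@dataclass(frozen=True)
class GrayImage:
    """Windowed grayscale image; integer values in [0, 2^BIT - 1]."""

    values: np.ndarray
    window: WindowConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("GrayImage requires a 2D array")
        if v.min() < 0 or v.max() > self.window.levels - 1:
            raise ValueError("GrayImage values exceed [0, 2^BIT - 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def normalized(self) -> np.ndarray:
        """Gray values rescaled to [0, 1] floats (network input scale)."""
        return self.values.astype(np.float64) / (self.window.levels - 1)


def window_bounds(wl: float, ww: float) -> tuple[float, float]:
    """HU interval displayed by a window: (WL - WW/2, WL + WW/2)."""
    if ww <= 0:
        raise ValueError(f"window width must be positive, got {ww}")
    return wl - ww / 2.0, wl + ww / 2.0


def gray_levels(bit: int) -> int:
    """Number of gray shades at a bit depth: 2^BIT."""
    if bit < 1:
        raise ValueError(f"bit depth must be >= 1, got {bit}")
    return 2**bit


def _smallest_uint(bit: int):
    return np.uint8 if bit <= 8 else np.uint16


def hu_to_gray(img: HUImage | np.ndarray, cfg: WindowConfig) -> GrayImage:
    """Apply the linear window transform with floor binning and clipping."""
    hu = img.values if isinstance(img, HUImage) else np.asarray(img, dtype=np.float64)
    low, _ = cfg.bounds
    n = cfg.levels
    g = np.floor((hu - low) / cfg.ww * n)
    g = np.clip(g, 0, n - 1).astype(_smallest_uint(cfg.bit))
    return GrayImage(g, cfg)


def sweep_grid(
    window_settings: Sequence[tuple[float, float]] | None = None,
    bits: Iterable[int] = (8, 6, 4),
) -> list[WindowConfig]:
    """Cartesian grid of window configs, bits outer / settings inner.

    Defaults reproduce the published 7-setting x 3-bit-depth sweep (21
    cells).
    """
    settings = list(SWEEP_WINDOW_SETTINGS if window_settings is None else window_settings)
    bits = list(bits)
    if not settings or not bits:
        raise ValueError("window_settings and bits must be non-empty")
    return [WindowConfig(wl, ww, b) for b, (wl, ww) in product(bits, settings)]


class HUWindower(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: stacks of HU slices -> normalized gray.

    ``transform`` accepts an (n, h, w) array of HU values (or a list of
    :class:`HUImage`) and returns (n, h, w) floats in [0, 1], i.e. the
    windowed gray values divided by 2^BIT - 1.
    """

    def __init__(self, wl: float = 40.0, ww: float = 400.0, bit: int = 8):
        self.wl = wl
        self.ww = ww
        self.bit = bit

    def fit(self, X, y=None):  # stateless; validates parameters
        self.window_ = WindowConfig(self.wl, self.ww, self.bit)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "window_"):
            self.fit(X)
        imgs = [x.values if isinstance(x, HUImage) else np.asarray(x) for x in X]
        return np.stack([hu_to_gray(v, self.window_).normalized() for v in imgs])
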