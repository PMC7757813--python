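"""Staining-contrast mapping for quality control.

The contrast ratio is the leveled intensity of the boundary stain relative
to the non-specific interior stain (interiors level to ~1.0, so the leveled
value *at* a boundary centerline is itself the ratio). The map samples the
leveled image at ridge-skeleton pixels only and averages those samples in a
local square window (default 27 µm side): averaging over sampled pixels
keeps the value a pure stain ratio, independent of fiber size. Regions
with a ratio above ~2.25 segment reliably; lower ratios flag weak staining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import RasterImage, ValidationError, odd_kernel_px
from .ridges import RidgeMap

__all__ = ["ContrastMap", "contrast_map", "contrast_ok_mask"]


@dataclass(frozen=True)
class ContrastMap:
    """Local boundary/interior stain-ratio map; 0 where no boundary sampled."""

    values: np.ndarray
    resolution: float

    def covered(self) -> np.ndarray:
        return self.values > 0


def contrast_map(leveled: RasterImage, ridges: RidgeMap,
                 kernel_um: float = 27.0) -> ContrastMap:
    """Windowed mean of leveled values sampled at skeleton pixels.

    The window is a square of side ``round(kernel_um/res)`` px, forced odd.
    Windows containing no skeleton pixel map to 0.
    """
    if leveled.pixels.shape != ridges.skeleton.shape:
        raise ValidationError("leveled image and ridge map shapes differ")
    if not (kernel_um > 0):
        raise ValidationError("kernel_um must be > 0")
    side = odd_kernel_px(kernel_um, leveled.resolution)
    skel = ridges.skeleton.astype(np.float64)
    if not ridges.skeleton.any():
        warnings.warn("empty ridge skeleton: contrast map is all zero")
        return ContrastMap(values=np.zeros_like(skel), resolution=leveled.resolution)
    sampled = leveled.pixels.astype(np.float64) * skel
    win_sum = ndi.uniform_filter(sampled, size=side, mode="constant", cval=0.0)
    win_cnt = ndi.uniform_filter(skel, size=side, mode="constant", cval=0.0)
    # uniform_filter returns means; a window holding one sample has weight
    # 1/side² — counts below half that are float rounding noise, not samples
    has_sample = win_cnt > 0.5 / (side * side)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(has_sample, win_sum / np.maximum(win_cnt, 1e-300), 0.0)
    return ContrastMap(values=vals, resolution=leveled.resolution)


def contrast_ok_mask(cmap: ContrastMap, ratio_threshold: float = 2.25) -> np.ndarray:
    """Binary mask of regions whose contrast ratio meets the threshold."""
    if not (ratio_threshold > 0):
        raise ValidationError("ratio_threshold must be > 0")
    return cmap.values >= ratio_threshold
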