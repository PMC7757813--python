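"""Stage 4 — seed (marker) generation from the ridge skeleton.

The skeleton is thickened with a disk-shaped dilation (default radius 6 µm)
to bridge small discontinuities, blurred with a Gaussian, and thresholded:
connected regions that stay strictly below the threshold (default 70 on the
0–255 scale of the blurred binary image) become watershed markers, and the
blurred image itself becomes the flooding topography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import RasterImage, ValidationError, um_to_px
from .ridges import RidgeMap

__all__ = ["MarkerImage", "NoSeedsError", "dilate_ridges", "blur_ridges",
           "make_markers", "default_min_seed_px"]


class NoSeedsError(ValidationError):
    """No connected region fell below the seed threshold."""


@dataclass(frozen=True)
class MarkerImage:
    """Integer-labelled seed regions plus the topography they sit in."""

    markers: np.ndarray       # 0 = unassigned, 1..M = seeds
    topography: np.ndarray    # the blurred ridge image (0-255)
    resolution: float

    @property
    def count(self) -> int:
        return int(self.markers.max())


def dilate_ridges(ridges: RidgeMap, radius_um: float = 6.0) -> np.ndarray:
    """Dilate the binary skeleton with a Euclidean disk of the given radius.

    Implemented via the exact Euclidean distance transform (equivalent to
    dilation with the discrete disk of radius ``round(radius_um/res)`` px).
    """
    if not (radius_um > 0):
        raise ValidationError("radius_um must be > 0")
    r = int(round(um_to_px(radius_um, ridges.resolution)))
    if not ridges.skeleton.any():
        return np.zeros_like(ridges.skeleton, dtype=bool)
    if r == 0:
        return ridges.skeleton.astype(bool)
    dist = ndi.distance_transform_edt(~ridges.skeleton)
    return dist <= r


def blur_ridges(dilated: np.ndarray, blur_sigma_um: float,
                resolution: float) -> np.ndarray:
    """Gaussian-blur the binary {0, 255} image; output is real in [0, 255]."""
    if not (blur_sigma_um > 0):
        raise ValidationError("blur_sigma_um must be > 0")
    sigma = um_to_px(blur_sigma_um, resolution)
    field = np.where(dilated, 255.0, 0.0)
    out = ndi.gaussian_filter(field, sigma, mode="reflect")
    return np.clip(out, 0.0, 255.0)


def default_min_seed_px(resolution: float, csa_min_um2: float = 200.0) -> int:
    """Quarter of the pixel area of the smallest admissible fiber."""
    return max(1, int(round(csa_min_um2 / resolution ** 2 / 4.0)))


def make_markers(blurred: np.ndarray, resolution: float,
                 threshold: float = 70.0,
                 min_seed_px: int = 1) -> MarkerImage:
    """Connected components of the strict sublevel set {blurred < threshold}.

    Components (8-connectivity) smaller than ``min_seed_px`` are discarded
    as noise seeds. Raises :class:`NoSeedsError` when nothing survives —
    the remedy is a higher threshold.
    """
    if not (0 < threshold < 255):
        raise ValidationError("threshold must lie in (0, 255)")
    support = blurred < threshold
    labels, n = ndi.label(support, structure=np.ones((3, 3), dtype=int))
    if n and min_seed_px > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_seed_px)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            # renumber to 1..M
            labels, n = ndi.label(labels > 0, structure=np.ones((3, 3), dtype=int))
        else:
            n = int(labels.max())
    if n == 0:
        raise NoSeedsError(
            "no seed regions below the threshold; increase seed_threshold")
    return MarkerImage(markers=labels.astype(np.int32), topography=blurred,
                       resolution=resolution)
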