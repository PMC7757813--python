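"""Domain types, image I/O and configuration shared by all pipeline stages.

All physical parameters are denominated in micrometres and converted to
pixels through the image resolution (µm/pixel), so the same configuration
applies to images acquired at different magnifications.

Conventions: 0-based, row-major, pixel-centred coordinates; areas are
``pixel_count * resolution**2`` (µm²); lengths are µm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("myoseg")

__all__ = [
    "RasterImage",
    "LabelImage",
    "PipelineConfig",
    "ValidationError",
    "read_image",
    "um_to_px",
    "odd_kernel_px",
    "write_results",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class RasterImage:
    """A single-channel grayscale image with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities. Integer 8/16-bit on input;
        real-valued after intensity leveling.
    resolution
        Pixel size in µm/pixel (> 0).
    """

    pixels: np.ndarray
    resolution: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D single-channel image, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have at least one pixel")
        if not (self.resolution > 0):
            raise ValidationError(f"resolution must be > 0 µm/px, got {self.resolution}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        """Same geometry, new pixel values."""
        return RasterImage(pixels=pixels, resolution=self.resolution)


@dataclass(frozen=True)
class LabelImage:
    """Integer label map: 0 = background/boundary, 1..N = fibers."""

    labels: np.ndarray
    resolution: float

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError("label image must be 2-D")
        if lab.size and lab.min() < 0:
            raise ValidationError("labels must be non-negative")
        if not (self.resolution > 0):
            raise ValidationError("resolution must be > 0")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the image."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class PipelineConfig:
    """Tunable parameters of the segmentation pipeline.

    µm-denominated fields are converted to pixels at run time from the image
    resolution. Defaults correspond to collagen/laminin-stained muscle
    cross-sections at ~0.4-0.5 µm/px.
    """

    median_kernel_um: float = 45.0      # background median kernel side
    pm_sigma_um: float = 3.0            # diffusion filter width σ (sets k)
    pm_iterations: int = 15
    pm_timestep: float = 0.2
    pm_conductance_fn: str = "exponential"   # or "rational"
    boost_exponent: float = 4.0
    line_width_um: float = 6.0          # target boundary line width w
    ridge_low_contrast: float | None = None   # hysteresis thresholds on salience;
    ridge_high_contrast: float | None = None  # None = per-image percentiles
    dilate_radius_um: float = 6.0
    blur_sigma_um: float = 3.0
    seed_threshold: float = 70.0        # on the 0-255 post-blur scale
    min_seed_px: int | None = None      # None = area of a 200 µm² disk / 4
    csa_min_um2: float = 200.0
    csa_max_um2: float = 10000.0
    exclude_edge_fibers: bool = True
    membrane_halfwidth_um: float | None = None  # None = line_width_um / 2
    contrast_kernel_um: float = 27.0
    contrast_ok_ratio: float = 2.25
    histogram_bin_um: float = 5.0

    def __post_init__(self):
        for name in ("median_kernel_um", "pm_sigma_um", "line_width_um",
                     "dilate_radius_um", "blur_sigma_um", "contrast_kernel_um",
                     "csa_min_um2", "csa_max_um2", "histogram_bin_um"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be > 0")
        if not (self.csa_min_um2 < self.csa_max_um2):
            raise ValidationError("csa_min_um2 must be < csa_max_um2")
        if not (0 < self.seed_threshold < 255):
            raise ValidationError("seed_threshold must lie in (0, 255)")
        if self.boost_exponent < 1:
            raise ValidationError("boost_exponent must be >= 1")
        if not (0 < self.pm_timestep <= 0.25):
            raise ValidationError("pm_timestep must lie in (0, 0.25]")
        if self.pm_conductance_fn not in ("exponential", "rational"):
            raise ValidationError("pm_conductance_fn must be 'exponential' or 'rational'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def um_to_px(value_um: float, resolution: float) -> float:
    """Convert a physical length (µm) to pixels; callers round per contract."""
    if not (resolution > 0):
        raise ValidationError(f"resolution must be > 0, got {resolution}")
    if value_um < 0:
        raise ValidationError(f"length must be >= 0 µm, got {value_um}")
    return value_um / resolution


def odd_kernel_px(value_um: float, resolution: float) -> int:
    """Kernel side in pixels: round(µm/res), forced odd (+1 if even), >= 1."""
    side = int(round(um_to_px(value_um, resolution)))
    if side % 2 == 0:
        side += 1
    return max(side, 1)


def read_image(path, resolution: float, channel: int | None = None) -> RasterImage:
    """Read a TIFF/PNG micrograph as a single-channel :class:`RasterImage`.

    Multi-channel files require an explicit ``channel`` index; there is no
    automatic RGB→gray conversion (the stain of interest is single-channel).
    """
    if not (resolution > 0):
        raise ValidationError(f"resolution must be > 0, got {resolution}")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # channel axis is whichever axis is small (planar or interleaved)
        ch_axis = 0 if arr.shape[0] <= 4 < arr.shape[-1] else -1
        n_ch = arr.shape[ch_axis]
        if channel is None:
            raise ValidationError(
                f"image has {n_ch} channels; pass an explicit channel index")
        if not (0 <= channel < n_ch):
            raise ValidationError(f"channel {channel} out of range [0, {n_ch})")
        arr = np.take(arr, channel, axis=ch_axis)
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality: {arr.ndim}")
    return RasterImage(pixels=arr, resolution=resolution)


def write_results(labels: LabelImage, table, summary: dict, outdir) -> dict:
    """Write label TIFF, overlay PNG, per-fiber CSV, summary JSON, histogram CSV.

    ``table`` is a :class:`myoseg.morphometry.FiberTable`. Returns the mapping
    of artifact name → path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    lab = labels.labels
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValidationError("more than 65535 labels; cannot write 16-bit TIFF")
    paths["labels"] = outdir / "labels.tif"
    tifffile.imwrite(paths["labels"], lab.astype(np.uint16))

    paths["fibers"] = outdir / "fibers.csv"
    table.to_dataframe().to_csv(paths["fibers"], index=False)

    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)

    hist = summary.get("histogram")
    if hist is not None:
        import pandas as pd
        paths["histogram"] = outdir / "min_feret_histogram.csv"
        pd.DataFrame(hist).to_csv(paths["histogram"], index=False)

    logger.info("wrote %d result files to %s", len(paths), outdir)
    return paths


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
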