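"""Synthetic muscle-section phantoms with exact ground truth.

A phantom is a mosaic of convex cells (regular hexagons, or Voronoi cells
of a Poisson-disk point process) separated by bright boundary stripes of
fixed physical width, mimicking membrane/matrix staining: interiors at a
base intensity, boundaries at ``contrast_ratio`` times that, an optional
multiplicative linear illumination gradient, and additive Gaussian pixel
noise. Ground-truth labels are the generating cells eroded by half the
boundary width, so true fiber size excludes the shared membrane — the same
convention the segmentation reports.

The hexagonal layout gives analytic truth (every fiber's minimum Feret
diameter equals pitch − boundary width); the Voronoi layout gives
realistic size dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .core import LabelImage, RasterImage, ValidationError
from .morphometry import FiberTable, measure_fibers

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "truth_table"]

INTERIOR_BASE = 1000.0   # counts; phantoms are written as 16-bit


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters.

    ``contrast_ratio`` may be a scalar or a (low, high) pair, in which case
    the ratio ramps linearly left→right across the image. ``illumination``
    is the peak-to-peak amplitude of a multiplicative linear gradient along
    x (0.3 = ±15% about unity). ``noise_sd`` is the additive Gaussian SD as
    a fraction of the interior base intensity.
    """

    width_px: int = 1000
    height_px: int = 1000
    resolution: float = 0.462
    layout: str = "hexagonal"            # or "voronoi"
    hex_pitch_um: float = 51.0           # seed spacing = cell flat-to-flat
    mean_fiber_diameter_um: float = 50.0  # voronoi layout
    diameter_cv: float = 0.2              # voronoi layout
    boundary_width_um: float = 6.0
    contrast_ratio: float | tuple[float, float] = 2.5
    illumination: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.layout not in ("hexagonal", "voronoi"):
            raise ValidationError("layout must be 'hexagonal' or 'voronoi'")
        if not (self.boundary_width_um > 0):
            raise ValidationError("boundary_width_um must be > 0")
        ratios = np.atleast_1d(np.asarray(self.contrast_ratio, dtype=float))
        if np.any(ratios < 1.0):
            raise ValidationError("contrast_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.illumination < 1):
            raise ValidationError("illumination amplitude must lie in [0, 1)")
        diam = (self.hex_pitch_um if self.layout == "hexagonal"
                else self.mean_fiber_diameter_um)
        if diam <= self.boundary_width_um:
            raise ValidationError(
                "fiber diameter must exceed the boundary width")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if isinstance(d.get("contrast_ratio"), list):
            d["contrast_ratio"] = tuple(d["contrast_ratio"])
        return cls(**d)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth labels plus the morphometrics measured from them."""

    labels: LabelImage
    records: FiberTable


def _hex_seeds(spec: PhantomSpec) -> np.ndarray:
    # origin offset (p/3, dy/3) keeps cell walls off the image frame, so no
    # membrane stripe runs along the frame (which would be a degenerate
    # alignment never seen in real crops)
    p = spec.hex_pitch_um / spec.resolution
    dy = p * np.sqrt(3.0) / 2.0
    rows = int(np.ceil(spec.height_px / dy)) + 3
    cols = int(np.ceil(spec.width_px / p)) + 3
    pts = []
    for i in range(-2, rows):
        y = i * dy + dy / 3.0
        x_off = p / 3.0 if i % 2 == 0 else p / 3.0 + p / 2.0
        for j in range(-2, cols):
            pts.append((j * p + x_off, y))
    return np.array(pts)


def _poisson_disk_seeds(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing Poisson-disk sampling.

    The rejection radius shrinks with ``diameter_cv``: tightly packed
    points (cv→0) approach a regular packing with uniform cells, while a
    smaller radius leaves room for irregular, variable cells.
    ``mean_fiber_diameter_um`` refers to the fiber proper (the cell minus
    the shared membrane), so the cell pitch adds the boundary width.
    """
    d = (spec.mean_fiber_diameter_um
         + spec.boundary_width_um) / spec.resolution
    r_min = d * max(0.05, 1.0 - spec.diameter_cv)
    area = spec.width_px * spec.height_px
    n_target = max(1, int(round(area / (0.866 * d * d))))
    margin = d
    buf = np.empty((n_target, 2))
    n_acc = 0
    attempts = 0
    max_attempts = 200 * n_target
    while n_acc < n_target and attempts < max_attempts:
        attempts += 1
        cx = rng.uniform(-margin, spec.width_px + margin)
        cy = rng.uniform(-margin, spec.height_px + margin)
        if n_acc:
            d2 = (buf[:n_acc, 0] - cx) ** 2 + (buf[:n_acc, 1] - cy) ** 2
            if d2.min() < r_min ** 2:
                continue
        buf[n_acc] = (cx, cy)
        n_acc += 1
    return buf[:n_acc].copy()


def generate_phantom(spec: PhantomSpec) -> tuple[RasterImage, PhantomTruth]:
    """Render the phantom image and its ground truth. Deterministic per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    if spec.layout == "hexagonal":
        seeds = _hex_seeds(spec)
    else:
        seeds = _poisson_disk_seeds(spec, rng)
    if len(seeds) < 1:
        raise ValidationError("degenerate phantom: no seed points")

    yy, xx = np.mgrid[0:spec.height_px, 0:spec.width_px]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    tree = cKDTree(seeds)
    dist, idx = tree.query(pix, k=2)
    d1 = dist[:, 0].reshape(yy.shape)
    d2 = dist[:, 1].reshape(yy.shape) if len(seeds) > 1 else np.full(yy.shape, np.inf)
    nearest = idx[:, 0].reshape(yy.shape)

    # distance from the pixel to the bisector between its two nearest cells
    half_gap = (d2 - d1) / 2.0
    w_half_px = (spec.boundary_width_um / 2.0) / spec.resolution
    boundary = half_gap < w_half_px

    labels = np.where(boundary, 0, nearest + 1).astype(np.int32)
    labels = _compress_labels(labels)

    ratio = np.atleast_1d(np.asarray(spec.contrast_ratio, dtype=float))
    if ratio.size == 2:
        ramp = xx / max(spec.width_px - 1, 1)
        ratio_field = ratio[0] + (ratio[1] - ratio[0]) * ramp
    else:
        ratio_field = np.full(yy.shape, float(ratio[0]))

    illum = 1.0 + spec.illumination * (xx / max(spec.width_px - 1, 1) - 0.5)
    signal = INTERIOR_BASE * illum * np.where(boundary, ratio_field, 1.0)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd * INTERIOR_BASE,
                                     size=signal.shape)
    img16 = np.clip(np.round(signal), 0, 65535).astype(np.uint16)

    label_img = LabelImage(labels=labels, resolution=spec.resolution)
    truth = PhantomTruth(labels=label_img, records=truth_table_from_labels(label_img))
    return RasterImage(pixels=img16, resolution=spec.resolution), truth


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to contiguous 1..N."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def truth_table_from_labels(labels: LabelImage) -> FiberTable:
    return measure_fibers(labels)


def truth_table(truth: PhantomTruth) -> FiberTable:
    """Morphometrics of the ground-truth labels (same measurement code path
    as the pipeline output, so truth and prediction are directly comparable)."""
    return truth_table_from_labels(truth.labels)
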