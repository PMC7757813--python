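"""Accuracy metrics against ground truth.

Comparison is at the image level (mean minimum Feret diameter and kept
fiber count per image), the granularity at which segmentation methods are
usually validated against manual tracing; fiber-to-fiber matching is out
of scope.
"""

from __future__ import annotations

import numpy as np

from .core import ValidationError
from .morphometry import FiberTable

__all__ = ["mean_feret_error", "signed_feret_error", "bland_altman",
           "count_error"]


def _mean_kept(table: FiberTable) -> float:
    vals = table.kept_min_feret()
    if vals.size == 0:
        raise ValidationError("table has no kept fibers")
    return float(vals.mean())


def signed_feret_error(pred: FiberTable, truth: FiberTable) -> float:
    """Signed percent difference of mean minimum Feret vs ground truth."""
    m_truth = _mean_kept(truth)
    return 100.0 * (_mean_kept(pred) - m_truth) / m_truth


def mean_feret_error(pred: FiberTable, truth: FiberTable) -> float:
    """Absolute percent difference of mean minimum Feret vs ground truth."""
    return abs(signed_feret_error(pred, truth))


def count_error(pred: FiberTable, truth: FiberTable) -> float:
    """Signed percent difference in kept fiber count (positive = over-segmentation)."""
    n_truth = truth.n_kept
    if n_truth < 1:
        raise ValidationError("truth table has no kept fibers")
    return 100.0 * (pred.n_kept - n_truth) / n_truth


def bland_altman(pairs) -> dict:
    """Bland–Altman agreement of two methods over paired per-image values.

    For each pair (A, B) compute the mean m = (A+B)/2 and difference
    d = A−B; ordinary least squares of d on m quantifies proportional bias
    (slope), with the mean difference as the overall bias.

    Returns ``{"slope", "intercept", "bias", "loa_low", "loa_high"}`` where
    the limits of agreement are bias ± 1.96·SD(d).
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need >= 3 (A, B) pairs")
    a, b = arr[:, 0], arr[:, 1]
    m = (a + b) / 2.0
    d = a - b
    if np.ptp(m) == 0:
        raise ValidationError("all pair means identical; slope undefined")
    slope, intercept = np.polyfit(m, d, 1)
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return {"slope": float(slope), "intercept": float(intercept),
            "bias": bias, "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd}
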