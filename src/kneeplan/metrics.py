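"""Evaluation metrics for detection outputs and plan targets.

* Dice coefficient averaged over foreground and background,
* Average Symmetric Surface Distance (ASSD) between densely resampled
  contours,
* Euclidean keypoint distance (px and, when calibrated, mm),
* moment-based line centroid and orientation (raw image moments after
  truncating the heatmap at the two-sigma likelihood exp(-2)),
* test-set aggregation as median with a seeded percentile-bootstrap 95% CI,
  counting cancelled plans separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .decoding import NotDetected, TWO_SIGMA_THRESHOLD
from .encoding import Heatmap
from .geometry import Calibration, Keypoint, normalize_orientation_deg, resample_polyline


def dice_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice coefficient averaged over foreground and background.

    Foreground Dice is ``2|A n B| / (|A| + |B|)``; background Dice is the
    same on the complements. A channel empty in both prediction and ground
    truth scores 1 by convention.
    """
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")

    def _dice(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = int(a.sum()), int(b.sum())
        if sa + sb == 0:
            return 1.0
        return 2.0 * int((a & b).sum()) / (sa + sb)

    return 0.5 * (_dice(p, g) + _dice(~p, ~g))


def assd(contour_a: np.ndarray, contour_b: np.ndarray, spacing: float = 0.5) -> float:
    """Average Symmetric Surface Distance between two contours.

    ``ASSD = (sum_{x in C} d(x, C') + sum_{x' in C'} d(x', C)) / (|C| + |C'|)``
    with ``d`` the Euclidean nearest-point distance. Both contours are
    densely resampled (default <= 0.5 px spacing) before evaluation, which
    makes the value robust to the original vertex density.
    """
    a = resample_polyline(np.asarray(contour_a, dtype=float), spacing)
    b = resample_polyline(np.asarray(contour_b, dtype=float), spacing)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("contours must be non-empty")
    da = cKDTree(b).query(a)[0]
    db = cKDTree(a).query(b)[0]
    return float((da.sum() + db.sum()) / (len(a) + len(b)))


def keypoint_ed(
    pred: Keypoint, gt: Keypoint, cal: Optional[Calibration] = None
) -> tuple[float, Optional[float]]:
    """Euclidean distance between predicted and true keypoint, in px (and mm)."""
    d = float(math.hypot(pred.x - gt.x, pred.y - gt.y))
    mm = d * cal.mm_per_px if cal is not None and cal.is_calibrated else None
    return d, mm


def line_moments(
    hm: Heatmap, threshold: float = TWO_SIGMA_THRESHOLD
) -> Union[tuple[tuple[float, float], float], NotDetected]:
    """Centroid and orientation of a line heatmap via raw image moments.

    The heatmap is first truncated at the two-sigma likelihood to suppress
    outliers; the centroid is ``(M10/M00, M01/M00)`` and the orientation
    ``gamma = 1/2 atan2(2 mu'11, mu'20 - mu'02)`` in degrees, folded into
    ``(-90, 90]``. Zero mass after truncation signals a missed detection.
    """
    g = np.where(hm.grid >= threshold, hm.grid, 0.0)
    m00 = g.sum()
    if m00 <= 0:
        return NotDetected(label=hm.label, reason="zero-mass")
    ys, xs = np.mgrid[0 : g.shape[0], 0 : g.shape[1]].astype(float)
    xbar = float((g * xs).sum() / m00)
    ybar = float((g * ys).sum() / m00)
    mu20 = float((g * xs * xs).sum() / m00) - xbar * xbar
    mu02 = float((g * ys * ys).sum() / m00) - ybar * ybar
    mu11 = float((g * xs * ys).sum() / m00) - xbar * ybar
    gamma = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    return (xbar, ybar), normalize_orientation_deg(gamma)


def angle_error_deg(a: float, b: float) -> float:
    """Smallest angle between two undirected line orientations, in [0, 90]."""
    d = abs(normalize_orientation_deg(a) - normalize_orientation_deg(b))
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------------
# Test-set aggregation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-sample metric table plus median / bootstrap-CI aggregates."""

    per_sample: pd.DataFrame
    aggregates: dict[str, dict[str, float]]
    cancelled: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"aggregates": self.aggregates, "cancelled": self.cancelled}, indent=1, sort_keys=True
        )


def bootstrap_median_ci(
    values: Sequence[float], n_boot: int = 10_000, seed: int = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """Median and percentile-bootstrap confidence interval for the median."""
    vals = np.asarray(list(values), dtype=float)
    if len(vals) == 0:
        raise ValueError("no values to aggregate")
    med = float(np.median(vals))
    if len(vals) == 1:
        return med, med, med
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    meds = np.median(vals[idx], axis=1)
    lo, hi = np.percentile(meds, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return med, float(lo), float(hi)


def evaluate_testset(
    per_sample_metrics: Sequence[dict[str, float]],
    cancelled: Optional[dict[str, int]] = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MetricsReport:
    """Aggregate per-sample metric dictionaries to medians with 95% CIs.

    ``per_sample_metrics`` is one dict per test sample mapping metric names
    to values (missing keys allowed, e.g. for cancelled plans); cancelled
    plan counts are carried through separately.
    """
    df = pd.DataFrame(list(per_sample_metrics))
    if df.empty:
        raise ValueError("no samples to evaluate")
    aggregates: dict[str, dict[str, float]] = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        med, lo, hi = bootstrap_median_ci(vals, n_boot=n_boot, seed=seed)
        aggregates[col] = {"median": med, "ci_lo": lo, "ci_hi": hi, "n": int(len(vals))}
    return MetricsReport(per_sample=df, aggregates=aggregates, cancelled=dict(cancelled or {}))
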