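"""Stage B: transform inferred spatial encodings into geometric objects.

Decoders convert the network's raw output grids back into keypoints,
polylines and polygons. A landmark whose evidence is too weak yields a
typed :class:`NotDetected` result rather than an exception, so downstream
plan construction can cancel gracefully instead of crashing.

Threshold conventions (unit-peak Gaussian heatmaps): "1 sigma" selects
values >= exp(-1/2) ~= 0.6065 and "2 sigma" values >= exp(-2) ~= 0.1353.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import interpolate, ndimage, optimize
from skimage import measure

from .encoding import Heatmap, MultiLabelMask
from .geometry import Keypoint, PolygonRegion, Polyline, resample_polyline

ONE_SIGMA_THRESHOLD = math.exp(-0.5)
TWO_SIGMA_THRESHOLD = math.exp(-2.0)
DETECTION_FLOOR = 0.05


@dataclass(frozen=True)
class NotDetected:
    """Typed failure signal for a feature that could not be recovered."""

    label: str = ""
    reason: str = "not-detected"

    def __bool__(self) -> bool:
        return False


DecodeResult = Union[Keypoint, Polyline, PolygonRegion, NotDetected]


@dataclass
class FeatureSet:
    """Named geometric features (ground truth or decoded predictions).

    Features are keyed by their registry label (``K*``, ``L*``, ``S*``).
    ``provenance`` records whether a feature was produced automatically or
    edited by the user.
    """

    keypoints: dict[str, Keypoint] = field(default_factory=dict)
    lines: dict[str, Polyline] = field(default_factory=dict)
    regions: dict[str, PolygonRegion] = field(default_factory=dict)
    missing: dict[str, NotDetected] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def get(self, label: str) -> DecodeResult:
        for pool in (self.keypoints, self.lines, self.regions):
            if label in pool:
                return pool[label]
        return self.missing.get(label, NotDetected(label=label, reason="unknown-label"))

    def add(self, feature: DecodeResult, provenance: str = "automatic") -> None:
        if isinstance(feature, Keypoint):
            self.keypoints[feature.label] = feature
        elif isinstance(feature, Polyline):
            self.lines[feature.label] = feature
        elif isinstance(feature, PolygonRegion):
            self.regions[feature.label] = feature
        elif isinstance(feature, NotDetected):
            self.missing[feature.label] = feature
        else:
            raise TypeError(f"cannot add {type(feature).__name__}")
        self.provenance[feature.label] = provenance

    def labels(self) -> list[str]:
        return sorted({*self.keypoints, *self.lines, *self.regions, *self.missing})


# DecodedFeatureSet is the historical name for decoded predictions; ground
# truth uses the identical container so downstream handling is source-agnostic.
DecodedFeatureSet = FeatureSet


# ---------------------------------------------------------------------------
# Keypoint decoding
# ---------------------------------------------------------------------------


def decode_keypoint_argmax(hm: Heatmap, floor: float = DETECTION_FLOOR) -> Union[Keypoint, NotDetected]:
    """Spatial argmax: the coordinate of the maximal grid cell.

    Ties break deterministically to the lowest ``y`` then lowest ``x`` (the
    first maximal cell in row-major scan order). A peak below ``floor``
    signals a missed detection.
    """
    grid = hm.grid
    if grid.size == 0:
        return NotDetected(label=hm.label, reason="empty-heatmap")
    idx = int(np.argmax(grid))  # row-major: first occurrence = lowest y, then x
    y, x = divmod(idx, grid.shape[1])
    peak = float(grid[y, x])
    if peak < floor:
        return NotDetected(label=hm.label, reason="peak-below-floor")
    return Keypoint(x=float(x), y=float(y), label=hm.label, confidence=min(max(peak, 0.0), 1.0))


def decode_keypoint_fit(
    hm: Heatmap, window: Optional[float] = None, floor: float = DETECTION_FLOOR
) -> Union[Keypoint, NotDetected]:
    """Sub-pixel keypoint decoding by least-squares fit of an isotropic
    Gaussian ``A * exp(-r^2 / (2 s^2))`` in a window around the argmax.

    Falls back to the argmax coordinate when the fit diverges or wanders
    further than the window radius from its initialization.
    """
    seed = decode_keypoint_argmax(hm, floor=floor)
    if isinstance(seed, NotDetected):
        return seed
    if window is None:
        window = 3.0 * hm.sigma
    h, w = hm.grid.shape
    r = int(np.ceil(window))
    x0, x1 = max(0, int(seed.x) - r), min(w - 1, int(seed.x) + r)
    y0, y1 = max(0, int(seed.y) - r), min(h - 1, int(seed.y) + r)
    patch = hm.grid[y0 : y1 + 1, x0 : x1 + 1]
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float))
    if np.ptp(patch) <= 1e-12:  # flat window: nothing to fit
        return seed

    def residual(p):
        amp, cx, cy, s = p
        model = amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * s * s))
        return (model - patch).ravel()

    p0 = np.array([max(seed.confidence or 1.0, 1e-3), seed.x, seed.y, max(hm.sigma, 1.0)])
    try:
        sol = optimize.least_squares(residual, p0, method="lm", max_nfev=200)
    except Exception:
        return seed
    amp, cx, cy, s = sol.x
    if (
        not sol.success
        or not np.all(np.isfinite(sol.x))
        or abs(cx - seed.x) > window
        or abs(cy - seed.y) > window
        or s <= 0
    ):
        return seed
    conf = min(max(float(amp), 0.0), 1.0)
    return Keypoint(x=float(cx), y=float(cy), label=hm.label, confidence=conf)


# ---------------------------------------------------------------------------
# Line decoding
# ---------------------------------------------------------------------------


def decode_line(
    hm: Heatmap,
    n_samples: int = 50,
    threshold: float = ONE_SIGMA_THRESHOLD,
    smoothing: Optional[float] = None,
) -> Union[Polyline, NotDetected]:
    """Convert a line heatmap back to a polyline.

    Pixels with likelihood >= ``threshold`` form a weighted point cloud. The
    points are ordered by their projection onto the cloud's principal axis,
    aggregated into per-bin weighted means, interpolated with a smoothing
    parametric cubic B-spline and finally resampled at ``n_samples``
    equidistant arc-length positions. Fully parametric, so vertical lines
    pose no singularity.
    """
    ys, xs = np.nonzero(hm.grid >= threshold)
    if len(xs) < 4:
        return NotDetected(label=hm.label, reason="too-few-points")
    wts = hm.grid[ys, xs].astype(float)
    pts = np.column_stack([xs, ys]).astype(float)
    mean = np.average(pts, axis=0, weights=wts)
    centered = pts - mean
    cov = (centered * wts[:, None]).T @ centered / wts.sum()
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    proj = centered @ axis
    order = np.argsort(proj, kind="stable")
    proj_sorted = proj[order]
    pts_sorted = pts[order]
    wts_sorted = wts[order]
    # aggregate into ~1 px bins along the principal axis (weighted means)
    bins = np.floor(proj_sorted - proj_sorted[0]).astype(int)
    agg_pts = []
    for b in np.unique(bins):
        sel = bins == b
        wsum = wts_sorted[sel].sum()
        agg_pts.append((pts_sorted[sel] * wts_sorted[sel, None]).sum(axis=0) / wsum)
    agg = np.asarray(agg_pts)
    if len(agg) < 4:
        return NotDetected(label=hm.label, reason="too-few-points")
    s = len(agg) if smoothing is None else smoothing
    try:
        tck, _ = interpolate.splprep([agg[:, 0], agg[:, 1]], s=s, k=min(3, len(agg) - 1))
    except Exception:
        return NotDetected(label=hm.label, reason="spline-failure")
    dense_u = np.linspace(0.0, 1.0, 20 * n_samples)
    dense = np.column_stack(interpolate.splev(dense_u, tck))
    seg = np.diff(dense, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if arc[-1] == 0:
        return NotDetected(label=hm.label, reason="degenerate-spline")
    targets = np.linspace(0.0, arc[-1], n_samples)
    u_eq = np.interp(targets, arc, dense_u)
    out = np.column_stack(interpolate.splev(u_eq, tck))
    return Polyline(points=out, label=hm.label, closed=False)


# ---------------------------------------------------------------------------
# Mask -> polygon decoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionDecodeResult:
    region: Union[PolygonRegion, NotDetected]
    fragmented: bool = False
    label: str = ""


def mask_to_polygons(mask: MultiLabelMask, min_area_frac: float = 0.01) -> list[RegionDecodeResult]:
    """Trace each mask channel's largest connected component to a closed
    polygon. Components below ``min_area_frac`` of the largest are dropped;
    if two or more components survive the threshold the channel is flagged
    as fragmented (the largest is still returned)."""
    results: list[RegionDecodeResult] = []
    for label, channel in zip(mask.labels, mask.data):
        lab, n = ndimage.label(channel)
        if n == 0:
            results.append(
                RegionDecodeResult(region=NotDetected(label=label, reason="empty-mask"), label=label)
            )
            continue
        areas = ndimage.sum_labels(np.ones_like(channel), lab, index=np.arange(1, n + 1))
        largest = int(np.argmax(areas)) + 1
        surviving = int(np.sum(areas >= min_area_frac * areas.max()))
        comp = (lab == largest).astype(float)
        # pad so contours around border-touching components close properly
        padded = np.pad(comp, 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            results.append(
                RegionDecodeResult(region=NotDetected(label=label, reason="contour-failure"), label=label)
            )
            continue
        contour = max(contours, key=len)
        ring = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])  # (row, col) -> (x, y)
        if np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        try:
            region = PolygonRegion(shell=ring, label=label)
        except Exception:
            results.append(
                RegionDecodeResult(region=NotDetected(label=label, reason="degenerate-contour"), label=label)
            )
            continue
        results.append(RegionDecodeResult(region=region, fragmented=surviving >= 2, label=label))
    return results


# ---------------------------------------------------------------------------
# Contour subsection
# ---------------------------------------------------------------------------


def _bilinear_sample(grid: np.ndarray, pts: np.ndarray) -> np.ndarray:
    h, w = grid.shape
    x = np.clip(pts[:, 0], 0, w - 1)
    y = np.clip(pts[:, 1], 0, h - 1)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2) if w > 1 else np.zeros(len(x), int)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2) if h > 1 else np.zeros(len(y), int)
    fx, fy = x - x0, y - y0
    return (
        grid[y0, x0] * (1 - fx) * (1 - fy)
        + grid[y0, x0 + 1] * fx * (1 - fy)
        + grid[y0 + 1, x0] * (1 - fx) * fy
        + grid[y0 + 1, x0 + 1] * fx * fy
    )


def contour_subsection(
    region: PolygonRegion,
    weight_hm: Heatmap,
    threshold: float = ONE_SIGMA_THRESHOLD,
    spacing: float = 1.0,
) -> Union[Polyline, NotDetected]:
    """Reduce a structure's contour to the subsection supported by a heatmap.

    The closed contour is densely resampled; points whose (bilinearly
    interpolated) heatmap value is >= ``threshold`` survive, and the longest
    contiguous run along the contour (circular) is returned as an open
    polyline. Used e.g. to extract the posterior cortex of the femoral shaft
    from the femur outline.
    """
    ring = np.vstack([region.shell, region.shell[:1]])
    dense = resample_polyline(ring, spacing)
    if np.allclose(dense[0], dense[-1]):
        dense = dense[:-1]
    n = len(dense)
    if n < 2:
        return NotDetected(label=region.label, reason="degenerate-contour")
    keep = _bilinear_sample(weight_hm.grid, dense) >= threshold
    if not np.any(keep):
        return NotDetected(label=region.label, reason="empty-subsection")
    if np.all(keep):
        # whole contour survives: open the ring at the deterministic start
        return Polyline(points=dense, label=region.label, closed=False)
    # longest circular run of surviving points
    k2 = np.concatenate([keep, keep])
    best_start, best_len, cur_start, cur_len = 0, 0, None, 0
    for i, flag in enumerate(k2):
        if flag:
            if cur_start is None:
                cur_start = i
            cur_len += 1
            if cur_len > best_len and cur_start < n:
                best_len, best_start = cur_len, cur_start
        else:
            cur_start, cur_len = None, 0
    best_len = min(best_len, n)
    idx = [(best_start + i) % n for i in range(best_len)]
    pts = dense[idx]
    if len(pts) < 2:
        return NotDetected(label=region.label, reason="subsection-too-short")
    return Polyline(points=pts, label=region.label, closed=False)


# ---------------------------------------------------------------------------
# Full decode of a model output
# ---------------------------------------------------------------------------


def decode_outputs(
    outputs: dict[str, np.ndarray],
    tasks,
    sigma: float,
    keypoint_decoder: str = "argmax",
) -> FeatureSet:
    """Decode a Stage A output dictionary into a :class:`FeatureSet`.

    ``tasks`` is the sequence of :class:`~kneeplan.model.TaskSpec` the model
    was built with; heatmap channels are clamped to [0, 1] before decoding.
    """
    from .model import TaskKind  # local import to avoid a hard dependency cycle

    fs = FeatureSet()
    for task in tasks:
        out = outputs[task.name]
        labels = task.channel_labels or tuple(f"{task.name}_{i}" for i in range(task.n_channels))
        if task.kind == TaskKind.segmentation:
            binary = (out >= 0.5).astype(np.uint8)
            mm = MultiLabelMask(labels=labels, data=binary)
            for res in mask_to_polygons(mm):
                fs.add(res.region if not isinstance(res.region, NotDetected) else res.region)
        else:
            clamped = np.clip(out, 0.0, 1.0)
            for label, channel in zip(labels, clamped):
                hm = Heatmap(grid=channel, sigma=sigma, kind=task.kind.value, label=label)  # type: ignore[arg-type]
                if task.kind == TaskKind.keypoint:
                    if keypoint_decoder == "fit":
                        fs.add(decode_keypoint_fit(hm))
                    else:
                        fs.add(decode_keypoint_argmax(hm))
                else:
                    fs.add(decode_line(hm))
    return fs
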