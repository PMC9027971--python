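"""Spatial ground-truth encodings learned by the network.

Numeric geometry (keypoints, polylines, bone polygons) is converted into the
dense spatial targets the detection network regresses:

* keypoint -> truncated, unnormalized Gaussian heatmap with peak value 1 at
  the landmark and standard deviation ``sigma`` (default 6 px),
* polyline -> line-symmetric heatmap obtained from the Gaussian of the
  point-to-segment distance inside a hull of orthogonal half-width 3 sigma,
* polygon set -> a multi-label binary mask stack in which channels may
  overlap (transmissive imaging superimposes structures additively, so bone
  regions are not required to be disjoint).

All heatmaps are truncated at +-3 sigma: values at distance > 3 sigma are
exactly zero, the value at exactly 3 sigma is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import shapely

from .geometry import GeometryError, Keypoint, PolygonRegion, Polyline

DEFAULT_SIGMA = 6.0


class HeatmapKind(str, Enum):
    keypoint = "keypoint"
    line = "line"


@dataclass(frozen=True)
class Heatmap:
    """A dense per-pixel likelihood grid in [0, 1]."""

    grid: np.ndarray  # (H, W) float
    sigma: float = DEFAULT_SIGMA
    kind: HeatmapKind = HeatmapKind.keypoint
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("heatmap grid must be 2D")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MultiLabelMask:
    """Per-structure binary channels; overlap between channels is permitted."""

    labels: tuple[str, ...]
    data: np.ndarray  # (C, H, W) uint8 in {0, 1}

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[0] != len(self.labels):
            raise ValueError("mask data must be (C, H, W) with one channel per label")
        object.__setattr__(self, "data", d.astype(np.uint8))

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


def _pixel_center_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.astype(float), ys.astype(float)


def encode_keypoint(kp: Keypoint, shape: tuple[int, int], sigma: float = DEFAULT_SIGMA) -> Heatmap:
    """Encode a keypoint as an unnormalized Gaussian peak.

    ``grid(p) = exp(-|p - kp|^2 / (2 sigma^2))`` for ``|p - kp| <= 3 sigma``
    and exactly 0 beyond the truncation radius. The peak value is 1 *at the
    continuous keypoint coordinate*; the maximal stored pixel is the one
    whose center is nearest the keypoint.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not kp.in_domain(shape):
        raise GeometryError(
            f"keypoint ({kp.x}, {kp.y}) outside image domain [0,{shape[1]})x[0,{shape[0]})"
        )
    h, w = shape
    grid = np.zeros((h, w), dtype=float)
    r = 3.0 * sigma
    x0, x1 = max(0, int(np.floor(kp.x - r))), min(w - 1, int(np.ceil(kp.x + r)))
    y0, y1 = max(0, int(np.floor(kp.y - r))), min(h - 1, int(np.ceil(kp.y + r)))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float))
    d2 = (xs - kp.x) ** 2 + (ys - kp.y) ** 2
    vals = np.exp(-d2 / (2.0 * sigma * sigma))
    vals[d2 > r * r] = 0.0
    grid[y0 : y1 + 1, x0 : x1 + 1] = vals
    return Heatmap(grid=grid, sigma=sigma, kind=HeatmapKind.keypoint, label=kp.label)


def _dist_to_segments(xs: np.ndarray, ys: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Euclidean distance from each (x, y) to the nearest point of a polyline."""
    p = np.stack([xs, ys], axis=-1)  # (..., 2)
    best = np.full(xs.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        ap = p - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(xs.shape)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(p - closest, axis=-1)
        best = np.minimum(best, d)
    return best


def encode_line(line: Polyline, shape: tuple[int, int], sigma: float = DEFAULT_SIGMA) -> Heatmap:
    """Encode an elongated structure as a line-symmetric heatmap.

    Each pixel within the hull (distance to the bounded polyline <= 3 sigma;
    segment endpoints are capped with half-disks of radius 3 sigma) takes the
    value ``exp(-d^2 / (2 sigma^2))`` of its distance ``d`` to the nearest
    point on the polyline; pixels outside the hull are zero. The hull's
    line-orthogonal width is therefore ``w = 6 sigma``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if line.length() == 0:
        raise GeometryError("cannot encode a zero-length line")
    h, w = shape
    pts = line.points
    if line.closed:
        pts = np.vstack([pts, pts[:1]])
    r = 3.0 * sigma
    x0 = max(0, int(np.floor(pts[:, 0].min() - r)))
    x1 = min(w - 1, int(np.ceil(pts[:, 0].max() + r)))
    y0 = max(0, int(np.floor(pts[:, 1].min() - r)))
    y1 = min(h - 1, int(np.ceil(pts[:, 1].max() + r)))
    grid = np.zeros((h, w), dtype=float)
    if x1 < x0 or y1 < y0:
        return Heatmap(grid=grid, sigma=sigma, kind=HeatmapKind.line, label=line.label)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float))
    d = _dist_to_segments(xs, ys, pts)
    vals = np.exp(-(d * d) / (2.0 * sigma * sigma))
    vals[d > r] = 0.0
    grid[y0 : y1 + 1, x0 : x1 + 1] = vals
    return Heatmap(grid=grid, sigma=sigma, kind=HeatmapKind.line, label=line.label)


def rasterize_mask(regions: Sequence[PolygonRegion], shape: tuple[int, int]) -> MultiLabelMask:
    """Rasterize outline polygons into a multi-label binary mask stack.

    A pixel is set iff its center lies inside the polygon (holes subtracted).
    Overlapping polygons set the bit in every covering channel.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"invalid mask shape {shape}")
    channels = []
    labels = []
    xs, ys = _pixel_center_grids(shape)
    for region in regions:
        poly = region.to_shapely()
        if poly.area <= 0:
            raise GeometryError(f"degenerate polygon for label {region.label!r}")
        minx, miny, maxx, maxy = poly.bounds
        x0, x1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
        y0, y1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
        grid = np.zeros((h, w), dtype=np.uint8)
        if x1 >= x0 and y1 >= y0:
            sub_x = xs[y0 : y1 + 1, x0 : x1 + 1]
            sub_y = ys[y0 : y1 + 1, x0 : x1 + 1]
            inside = shapely.contains_xy(poly, sub_x.ravel(), sub_y.ravel())
            grid[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(sub_x.shape).astype(np.uint8)
        channels.append(grid)
        labels.append(region.label)
    data = np.stack(channels, axis=0) if channels else np.zeros((0, h, w), dtype=np.uint8)
    return MultiLabelMask(labels=tuple(labels), data=data)
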