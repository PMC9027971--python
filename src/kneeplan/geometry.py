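"""Geometric primitives and coordinate conventions.

Conventions used throughout the package:

* Coordinates are 0-based and continuous (sub-pixel). ``x`` increases to the
  right, ``y`` increases downwards, and the origin is the *center* of the
  top-left pixel. An image of shape ``(H, W)`` covers the half-open domain
  ``[0, W) x [0, H)``.
* Angles are in degrees, measured from the +x axis. Undirected line
  orientations are reported in ``(-90, +90]``.
* A positive rotation angle maps the point ``(1, 0)`` towards ``(0, 1)``,
  i.e. it uses the matrix ``[[cos, -sin], [sin, cos]]`` applied to raw
  ``(x, y)`` pixel coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry.polygon import orient as _orient


class GeometryError(ValueError):
    """Raised for invalid geometric inputs (degenerate shapes, bad scales)."""


class CalibrationError(ValueError):
    """Raised for invalid pixel-to-mm calibration inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Keypoint:
    """A single anatomical landmark at continuous pixel coordinates."""

    x: float
    y: float
    label: str = ""
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite keypoint coordinates: {self.x}, {self.y}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise GeometryError(f"confidence outside [0, 1]: {self.confidence}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def in_domain(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return 0.0 <= self.x < w and 0.0 <= self.y < h


@dataclass(frozen=True)
class Polyline:
    """An ordered open (or closed) chain of >= 2 points."""

    points: np.ndarray  # (N, 2) float array of (x, y)
    label: str = ""
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise GeometryError("polyline needs an (N>=2, 2) point array")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("non-finite polyline coordinates")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise GeometryError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)

    def length(self) -> float:
        seg = np.diff(self.points, axis=0)
        total = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        if self.closed:
            total += float(np.hypot(*(self.points[0] - self.points[-1])))
        return total


@dataclass(frozen=True)
class PolygonRegion:
    """A closed region: one simple outer ring plus optional holes."""

    shell: np.ndarray  # (N>=3, 2)
    holes: tuple[np.ndarray, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        shell = np.asarray(self.shell, dtype=float)
        if shell.ndim != 2 or shell.shape[1] != 2 or shell.shape[0] < 3:
            raise GeometryError("polygon shell needs >= 3 points")
        if not np.all(np.isfinite(shell)):
            raise GeometryError("non-finite polygon coordinates")
        holes = tuple(np.asarray(h, dtype=float) for h in self.holes)
        poly = _ShapelyPolygon(shell, [h for h in holes])
        if not poly.is_valid:
            raise GeometryError(f"invalid polygon ({poly.is_valid and '' or 'self-intersection or bad ring'})")
        if poly.area <= 0.0:
            raise GeometryError("polygon area must be > 0")
        object.__setattr__(self, "shell", shell)
        object.__setattr__(self, "holes", holes)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.shell, [h for h in self.holes])

    @property
    def area(self) -> float:
        return float(self.to_shapely().area)


class CalibrationSource(str, Enum):
    sphere = "sphere"
    manual = "manual"
    none = "none"


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale of a radiograph."""

    mm_per_px: float = float("nan")
    source: CalibrationSource = CalibrationSource.none

    def __post_init__(self) -> None:
        if self.source != CalibrationSource.none:
            if not (math.isfinite(self.mm_per_px) and self.mm_per_px > 0):
                raise CalibrationError(f"mm_per_px must be positive, got {self.mm_per_px}")

    @property
    def is_calibrated(self) -> bool:
        return self.source != CalibrationSource.none

    def px_to_mm(self, px: float) -> float:
        if not self.is_calibrated:
            raise CalibrationError("no pixel-to-mm scale available")
        return px * self.mm_per_px

    def mm_to_px(self, mm: float) -> float:
        if not self.is_calibrated:
            raise CalibrationError("no pixel-to-mm scale available")
        return mm / self.mm_per_px


UNCALIBRATED = Calibration()


def calibrate_from_sphere(sphere_diameter_px: float, sphere_diameter_mm: float = 30.0) -> Calibration:
    """Derive the image scale from a reference sphere of known diameter.

    A steel sphere of known physical diameter (30 mm by default) imaged
    alongside the anatomy yields ``mm_per_px = diameter_mm / diameter_px``.
    """
    if not (sphere_diameter_px > 0 and sphere_diameter_mm > 0):
        raise CalibrationError(
            f"sphere diameters must be positive (got {sphere_diameter_px} px, {sphere_diameter_mm} mm)"
        )
    return Calibration(mm_per_px=sphere_diameter_mm / sphere_diameter_px, source=CalibrationSource.sphere)


# ---------------------------------------------------------------------------
# Similarity transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityTransform:
    """2D similarity: optional mirror, then rotation and isotropic scale, then translation.

    ``p' = s * R(angle) * M * p + t`` where ``M = diag(-1, 1)`` when
    ``mirror_x`` is set (reflection about the y axis through the origin).
    """

    angle_deg: float = 0.0
    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0
    mirror_x: bool = False

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise GeometryError(f"similarity scale must be > 0, got {self.scale}")

    @property
    def linear(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        c, s = math.cos(a), math.sin(a)
        rot = np.array([[c, -s], [s, c]])
        if self.mirror_x:
            rot = rot @ np.diag([-1.0, 1.0])
        return self.scale * rot

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        # (s R M)^-1 = M^-1 R^-1 / s ; expressed again as mirror-then-rotate
        inv_lin = np.linalg.inv(self.linear)
        inv_t = -inv_lin @ self.translation
        return _from_matrix(inv_lin, inv_t)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        lin = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return _from_matrix(lin, t)


def _from_matrix(lin: np.ndarray, t: np.ndarray) -> SimilarityTransform:
    det = float(np.linalg.det(lin))
    mirror = det < 0
    scale = math.sqrt(abs(det))
    base = lin @ np.diag([-1.0, 1.0]) if mirror else lin
    angle = math.degrees(math.atan2(base[1, 0], base[0, 0]))
    return SimilarityTransform(angle_deg=angle, scale=scale, tx=float(t[0]), ty=float(t[1]), mirror_x=mirror)


def apply_similarity(feature, transform: SimilarityTransform):
    """Map a :class:`Keypoint`, :class:`Polyline` or :class:`PolygonRegion`
    through a similarity transform, preserving type, label and point order.

    Polygon ring orientation is re-normalized (outer ring counter-clockwise in
    the raster frame) after mirroring so downstream area signs stay positive.
    """
    if isinstance(feature, Keypoint):
        (x, y), = transform.apply(feature.xy)
        return replace(feature, x=float(x), y=float(y))
    if isinstance(feature, Polyline):
        return replace(feature, points=transform.apply(feature.points))
    if isinstance(feature, PolygonRegion):
        shell = transform.apply(feature.shell)
        holes = tuple(transform.apply(h) for h in feature.holes)
        if transform.mirror_x:
            poly = _orient(_ShapelyPolygon(shell, [h for h in holes]))
            shell = np.asarray(poly.exterior.coords)[:-1]
            holes = tuple(np.asarray(r.coords)[:-1] for r in poly.interiors)
        return PolygonRegion(shell=shell, holes=holes, label=feature.label)
    raise TypeError(f"cannot transform object of type {type(feature).__name__}")


# ---------------------------------------------------------------------------
# Small helpers shared by planning / metrics
# ---------------------------------------------------------------------------


def normalize_orientation_deg(angle_deg: float) -> float:
    """Fold an undirected line angle into ``(-90, 90]`` degrees."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def unit_vector(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at approximately uniform arc-length ``spacing``."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total == 0:
        return pts[:1].copy()
    n = max(2, int(np.ceil(total / spacing)) + 1)
    t = np.linspace(0.0, total, n)
    x = np.interp(t, arclen, pts[:, 0])
    y = np.interp(t, arclen, pts[:, 1])
    return np.column_stack([x, y])
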