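"""Exact 2-D primitives underlying the ocular-motility rule engine.

Everything here works in image coordinates: ``x`` runs along columns
(rightward), ``y`` along rows (downward), both 0-based.  A mask pixel at
``(row r, col c)`` covers the half-open cell ``[c, c+1) x [r, r+1)`` and has
its center at the continuous point ``(c + 0.5, r + 0.5)``.

The module provides an algebraic (Kasa) least-squares circle fit for the
corneal boundary, canthus landmark extraction from a palpebral-fissure mask,
and the circle-line relation (separated / tangent / intersecting, with an
explicit tangency tolerance) that the gaze rules are built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage import measure

SEPARATED = "separated"
TANGENT = "tangent"
INTERSECTING = "intersecting"
RELATIONS = (SEPARATED, TANGENT, INTERSECTING)


class DegenerateGeometryError(ValueError):
    """Raised when an input is too degenerate to define the primitive."""


class EmptyFissureError(DegenerateGeometryError):
    """Raised when the palpebral-fissure region is empty."""


class MultipleComponentsError(DegenerateGeometryError):
    """Raised when the fissure mask is not a single 4-connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"fissure mask has {n_components} connected components, expected 1"
        )


@dataclass(frozen=True)
class Point2D:
    """A point in image-plane coordinates (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DegenerateGeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass(frozen=True)
class LineSegment2D:
    """Two distinct points defining a line.

    For clearance purposes all rule lines are treated as infinite: the
    clinical constructions (the intercanthal line, the vertical line through
    a canthus) concern which side of the line the cornea sits on, not the
    drawn extent.
    """

    a: Point2D
    b: Point2D

    def __post_init__(self):
        if self.a.x == self.b.x and self.a.y == self.b.y:
            raise DegenerateGeometryError("degenerate line: a == b")

    @property
    def length(self) -> float:
        return math.hypot(self.b.x - self.a.x, self.b.y - self.a.y)

    def distance_to(self, p: Point2D) -> float:
        """Perpendicular distance from ``p`` to the infinite line."""
        dx, dy = self.b.x - self.a.x, self.b.y - self.a.y
        return abs(dx * (p.y - self.a.y) - dy * (p.x - self.a.x)) / math.hypot(dx, dy)

    def signed_side(self, p: Point2D) -> float:
        """Signed perpendicular distance (sign = side of the line)."""
        dx, dy = self.b.x - self.a.x, self.b.y - self.a.y
        return (dx * (p.y - self.a.y) - dy * (p.x - self.a.x)) / math.hypot(dx, dy)


@dataclass(frozen=True)
class CornealCircle:
    """A fitted corneal circle: center, radius and RMS boundary-fit error."""

    center: Point2D
    radius: float
    rms_residual: float = 0.0

    def __post_init__(self):
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise DegenerateGeometryError(f"invalid radius {self.radius}")
        if self.rms_residual < 0:
            raise DegenerateGeometryError("negative rms_residual")


@dataclass(frozen=True)
class CircleLineRelation:
    """Trichotomy of a circle against an (infinite) line.

    ``signed_clearance`` is ``distance(center, line) - radius``: positive when
    the circle is clear of the line, negative when it overlaps it.  The
    relation is ``tangent`` whenever ``|signed_clearance| <= tolerance``.
    """

    relation: str
    signed_clearance: float
    tolerance: float

    @classmethod
    def from_clearance(cls, clearance: float, tolerance: float) -> "CircleLineRelation":
        if tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {tolerance}")
        if abs(clearance) <= tolerance:
            rel = TANGENT
        elif clearance > tolerance:
            rel = SEPARATED
        else:
            rel = INTERSECTING
        return cls(rel, clearance, tolerance)


@dataclass(frozen=True)
class CanthusLandmarks:
    """Inner/outer canthus pixel coordinates of one eye.

    ``left``/``right`` are the raw horizontal extremes of the fissure mask
    (integer pixel coordinates); ``inner``/``outer`` resolve them to the
    nasal/temporal corner through the eye side: on a frontal photograph the
    anatomical right eye has its nasal corner toward the image right, the
    left eye toward the image left.
    """

    left: Point2D
    right: Point2D
    inner: Point2D
    outer: Point2D
    eye_side: str

    def intercanthal_line(self) -> LineSegment2D:
        """Line through the two canthus pixel centers."""
        return LineSegment2D(
            Point2D(self.left.x + 0.5, self.left.y + 0.5),
            Point2D(self.right.x + 0.5, self.right.y + 0.5),
        )

    def lateral_line(self, horizontal: int) -> LineSegment2D:
        """Vertical rule line through the gaze-side canthus.

        The line sits on the outer edge of the canthus pixel (``x = c + 1``
        for the right canthus, ``x = c`` for the left), matching the
        half-open pixel convention so that a cornea rendered exactly tangent
        to the true canthus vertex is read as tangent after rasterization.
        """
        if horizontal > 0:
            x = self.right.x + 1.0
            y = self.right.y
        elif horizontal < 0:
            x = self.left.x
            y = self.left.y
        else:
            raise ValueError("lateral line requires a nonzero horizontal component")
        return LineSegment2D(Point2D(x, y - 1.0), Point2D(x, y + 1.0))


def default_tolerance(radius: float) -> float:
    """Tangency tolerance: max(1 px, 2% of the corneal radius).

    Absorbs rasterization error on small corneas while scaling with corneal
    size on large ones.
    """
    return max(1.0, 0.02 * radius)


def _as_point_array(points: Union[np.ndarray, Iterable]) -> np.ndarray:
    if isinstance(points, np.ndarray):
        pts = np.asarray(points, dtype=float)
    else:
        rows = []
        for p in points:
            if isinstance(p, Point2D):
                rows.append((p.x, p.y))
            else:
                rows.append((float(p[0]), float(p[1])))
        pts = np.asarray(rows, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (N, 2) points, got shape {pts.shape}")
    return pts


def fit_corneal_circle(points: Union[np.ndarray, Sequence[Point2D]]) -> CornealCircle:
    """Algebraic (Kasa) least-squares circle through boundary points.

    Solves the linear system ``2*cx*x + 2*cy*y + (r^2 - cx^2 - cy^2) =
    x^2 + y^2`` in the least-squares sense; closed form, deterministic, and
    accurate for the near-complete circular arcs the renderer and segmenter
    produce.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or (numerically) collinear points.
    """
    pts = _as_point_array(points)
    if len(pts) < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    # center the data for conditioning
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    A = np.column_stack([u, v, np.ones_like(u)])
    b = u * u + v * v
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("collinear points: circle is undefined")
    cu, cv = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cu * cu + cv * cv
    if not (r2 > 0 and math.isfinite(r2)):
        raise DegenerateGeometryError("degenerate circle fit (non-positive radius)")
    # guard against near-collinear inputs that slip past the rank test
    radius = math.sqrt(r2)
    d = np.hypot(u - cu, v - cv) - radius
    rms = float(np.sqrt(np.mean(d * d)))
    if not math.isfinite(radius) or radius > 1e8:
        raise DegenerateGeometryError("collinear points: circle is undefined")
    return CornealCircle(Point2D(cu + mx, cv + my), radius, rms)


def fit_circle_center_fixed_radius(
    points: Union[np.ndarray, Sequence[Point2D]],
    radius: float,
    init: Point2D | None = None,
) -> CornealCircle:
    """Least-squares circle center for a *known* radius.

    When the visible corneal boundary is a short trailing arc (extreme
    lateral gaze clips the leading edge under the canthus), the free
    circle fit trades radius against center along the arc axis and the
    extrapolated clearance degrades.  The corneal radius is a per-eye
    constant, so fixing it from better-conditioned gazes and refitting
    only the center restores the clearance accuracy.
    """
    from scipy.optimize import least_squares

    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    pts = _as_point_array(points)
    if len(pts) < 2:
        raise DegenerateGeometryError(f"need >= 2 points, got {len(pts)}")
    if init is None:
        init = Point2D(float(pts[:, 0].mean()), float(pts[:, 1].mean()))

    def _resid(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - radius

    sol = least_squares(_resid, [init.x, init.y], method="lm")
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CornealCircle(Point2D(float(sol.x[0]), float(sol.x[1])), radius, rms)


def circle_line_relation(
    circle: CornealCircle, line: LineSegment2D, tolerance: float | None = None
) -> CircleLineRelation:
    """Relation of a circle to an infinite line with a tangency band.

    ``signed_clearance = distance(center, line) - radius``; the relation is
    tangent within ``tolerance`` of zero, separated above, intersecting below.
    """
    if tolerance is None:
        tolerance = default_tolerance(circle.radius)
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    clearance = line.distance_to(circle.center) - circle.radius
    return CircleLineRelation.from_clearance(clearance, tolerance)


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _fissure_mask(fissure) -> np.ndarray:
    labels = getattr(fissure, "labels", fissure)
    mask = np.asarray(labels)
    if mask.ndim != 2:
        raise ValueError("fissure mask must be 2-D")
    return mask > 0


def extract_canthi(fissure, eye_side: str = "right", min_span: int = 3) -> CanthusLandmarks:
    """Locate the inner and outer canthus on a fissure mask.

    The canthi are taken as the leftmost and rightmost fissure pixels (raw
    horizontal extremes, no rotational normalization); ties within the
    extreme column are broken by the vertically median pixel.  The fissure
    must be a single 4-connected component spanning at least ``min_span``
    columns.

    Parameters
    ----------
    fissure : EyeSegmentation or ndarray
        Segmentation (any nonzero label counts as fissure) or boolean mask.
    eye_side : {"right", "left"}
        Anatomical eye side, used to resolve left/right into nasal (inner)
        and temporal (outer) canthus.
    """
    if eye_side not in ("left", "right"):
        raise ValueError(f"eye_side must be 'left' or 'right', got {eye_side!r}")
    mask = _fissure_mask(fissure)
    if not mask.any():
        raise EmptyFissureError("empty fissure region")
    _, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
    if n > 1:
        raise MultipleComponentsError(n)
    ys, xs = np.nonzero(mask)
    x_left, x_right = int(xs.min()), int(xs.max())
    if x_right - x_left + 1 < min_span:
        raise DegenerateGeometryError(
            f"degenerate fissure: width {x_right - x_left + 1} px < minimum span {min_span}"
        )

    def _median_row(col: int) -> int:
        rows = np.sort(ys[xs == col])
        return int(rows[(len(rows) - 1) // 2])

    left = Point2D(float(x_left), float(_median_row(x_left)))
    right = Point2D(float(x_right), float(_median_row(x_right)))
    if eye_side == "right":
        inner, outer = right, left
    else:
        inner, outer = left, right
    return CanthusLandmarks(left=left, right=right, inner=inner, outer=outer, eye_side=eye_side)


def corneal_boundary_points(
    labels: np.ndarray,
    cornea_label: int = 2,
    lid_exclusion: float = 1.5,
    min_points: int = 8,
) -> np.ndarray:
    """Sub-pixel corneal boundary points from a segmentation label grid.

    Extracts the 0.5-level contour of the cornea region and drops contour
    points that lie on the fissure outline (within ``lid_exclusion`` px of
    the background), because there the visible cornea is clipped by the
    eyelids and the boundary no longer follows the corneal circle.  Falls
    back to the full contour when too few free-arc points remain.

    Returns points as ``(x, y)`` in continuous image coordinates.
    """
    labels = np.asarray(labels)
    cornea = labels == cornea_label
    if not cornea.any():
        raise EmptyFissureError("no cornea pixels in segmentation")
    contours = measure.find_contours(cornea.astype(float), 0.5)
    if not contours:
        raise DegenerateGeometryError("cornea region has no extractable contour")
    contour = max(contours, key=len)  # (row, col) in index coordinates
    fissure = labels > 0
    edt = ndimage.distance_transform_edt(fissure)
    free = ndimage.map_coordinates(edt, contour.T, order=1) > lid_exclusion
    pts = contour[free] if free.sum() >= min_points else contour
    # index coordinates -> continuous coordinates (pixel centers at +0.5)
    return np.column_stack([pts[:, 1] + 0.5, pts[:, 0] + 0.5])


def fit_cornea_from_mask(labels: np.ndarray, cornea_label: int = 2) -> CornealCircle:
    """Fit the corneal circle to the free (non-lid) boundary arc of a mask."""
    return fit_corneal_circle(corneal_boundary_points(labels, cornea_label=cornea_label))
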