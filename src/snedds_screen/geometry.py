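"""Exact geometry of the three-component mixture simplex.

A ternary mixture design lives on the 2-simplex {(a, b, c) : a + b + c = 1,
a, b, c >= 0}.  This module provides the barycentric/Cartesian coordinate
plumbing, the design figures used by the adaptive screening strategy
(hexagon around a center point, parallelogram and trapezoid refinements),
and the classical full lattice against which the adaptive design's
experiment count is compared.

Cartesian embedding convention: the simplex is drawn as the equilateral
triangle with vertices

    component 1 -> (0, 0)
    component 2 -> (1, 0)
    component 3 -> (1/2, sqrt(3)/2)

so all figure sizes (hexagon radius, edge lengths) are expressed in units
of the unit-edge triangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TernaryPoint",
    "PlanarPoint",
    "DesignFigure",
    "SimplexError",
    "validate_point",
    "to_cartesian",
    "from_cartesian",
    "hexagon_vertices",
    "parallelogram_points",
    "trapezoid_points",
    "lattice",
]

SQRT3 = math.sqrt(3.0)
#: Cartesian vertices of the unit-edge equilateral triangle.
TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, SQRT3 / 2.0]])


class SimplexError(ValueError):
    """Raised when a point or figure violates the simplex constraints."""


@dataclass(frozen=True)
class TernaryPoint:
    """A three-component composition: fractions summing to one.

    The constructor normalizes the (already nearly unit-sum) fractions so
    that ``a + b + c == 1`` to machine precision; tolerance-based validation
    of raw user input belongs to :func:`validate_point`.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c)
        if not all(math.isfinite(v) for v in vals):
            raise SimplexError(f"non-finite composition {vals}")
        if min(vals) < -1e-9:
            raise SimplexError(f"negative component in composition {vals}")
        total = sum(vals)
        if abs(total - 1.0) > 1e-6:
            raise SimplexError(
                f"composition {vals} sums to {total:.6g}, expected 1"
            )
        a, b, c = (max(v, 0.0) / total for v in vals)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def as_percent(self) -> tuple[float, float, float]:
        return (100.0 * self.a, 100.0 * self.b, 100.0 * self.c)


@dataclass(frozen=True)
class PlanarPoint:
    """Cartesian coordinates in the equilateral-triangle embedding."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


#: Cartesian coordinates of the simplex centroid (1/3, 1/3, 1/3).
CENTROID = TernaryPoint(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


def validate_point(
    raw: Sequence[float],
    scale: str = "unit",
    tol: float = 0.005,
) -> TernaryPoint:
    """Validate and normalize a raw composition triple.

    Parameters
    ----------
    raw
        Three finite numbers, fractions (``scale="unit"``) or percentages
        (``scale="percent"``).
    tol
        Maximum allowed relative deviation of the sum from 1 (or 100).
        Default 0.5%, the usual gravimetric bookkeeping slack.
    """
    if len(raw) != 3:
        raise SimplexError(f"expected 3 components, got {len(raw)}")
    vals = [float(v) for v in raw]
    if not all(math.isfinite(v) for v in vals):
        raise SimplexError(f"non-finite composition {vals}")
    if scale == "percent":
        vals = [v / 100.0 for v in vals]
    elif scale != "unit":
        raise SimplexError(f"unknown scale {scale!r}")
    if min(vals) < 0:
        raise SimplexError(f"negative component in composition {vals}")
    total = sum(vals)
    if abs(total - 1.0) > tol:
        reported = total * (100.0 if scale == "percent" else 1.0)
        raise SimplexError(
            f"composition sums to {reported:.6g}, outside tolerance {tol:g}"
        )
    return TernaryPoint(*(v / total for v in vals))


def to_cartesian(p: TernaryPoint) -> PlanarPoint:
    """Project barycentric fractions onto the triangle embedding."""
    xy = p.as_array() @ TRIANGLE_VERTICES
    return PlanarPoint(float(xy[0]), float(xy[1]))


def from_cartesian(q: PlanarPoint | Sequence[float], tol: float = 1e-9) -> TernaryPoint:
    """Invert the triangle embedding; errors outside the simplex.

    ``tol`` is the Cartesian slack allowed before a point is declared
    outside the triangle (tiny negatives from round-off are clamped).
    """
    x, y = (q.x, q.y) if isinstance(q, PlanarPoint) else (float(q[0]), float(q[1]))
    c = y / (SQRT3 / 2.0)
    b = x - 0.5 * c
    a = 1.0 - b - c
    if min(a, b, c) < -tol:
        raise SimplexError(
            f"Cartesian point ({x:.6g}, {y:.6g}) lies outside the simplex "
            f"(barycentric {a:.3g}, {b:.3g}, {c:.3g})"
        )
    a, b, c = (max(v, 0.0) for v in (a, b, c))
    return TernaryPoint(*(v / (a + b + c) for v in (a, b, c)))


def _points_from_cartesian(
    coords: Iterable[np.ndarray], what: str
) -> list[TernaryPoint]:
    points, bad = [], []
    coords = list(coords)
    for i, xy in enumerate(coords):
        try:
            points.append(from_cartesian(PlanarPoint(float(xy[0]), float(xy[1]))))
        except SimplexError:
            bad.append(i)
    if bad:
        raise SimplexError(
            f"{what}: vertices {bad} fall outside the simplex "
            "(shrink the figure or move its anchor)"
        )
    return points


def hexagon_vertices(
    center: TernaryPoint, radius: float, rotation: float = 0.0
) -> list[TernaryPoint]:
    """Six points at Cartesian distance ``radius`` from ``center``.

    Vertex k sits at angle ``rotation + k*60°`` (radians, k = 0..5).
    """
    if radius <= 0:
        raise SimplexError(f"hexagon radius must be positive, got {radius}")
    c = to_cartesian(center).as_array()
    angles = rotation + np.arange(6) * (math.pi / 3.0)
    coords = c + radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return _points_from_cartesian(coords, "hexagon")


def parallelogram_points(
    anchor: TernaryPoint,
    edge1: Sequence[float],
    edge2: Sequence[float],
) -> list[TernaryPoint]:
    """Anchor plus the three other vertices spanned by two edge vectors."""
    e1 = np.asarray(edge1, dtype=float)
    e2 = np.asarray(edge2, dtype=float)
    cross = e1[0] * e2[1] - e1[1] * e2[0]
    scale = np.linalg.norm(e1) * np.linalg.norm(e2)
    if scale == 0 or abs(cross) < 1e-12 * max(scale, 1e-12):
        raise SimplexError("parallelogram edges are degenerate or collinear")
    a = to_cartesian(anchor).as_array()
    coords = [a, a + e1, a + e2, a + e1 + e2]
    return _points_from_cartesian(coords, "parallelogram")


def trapezoid_points(
    anchor: TernaryPoint,
    parallel_edge1: Sequence[float],
    parallel_edge2: Sequence[float],
    offset: Sequence[float],
    extras: tuple[int, int] = (0, 0),
) -> list[TernaryPoint]:
    """Trapezoid vertices plus evenly spaced points on the parallel sides.

    Side 1 runs from the anchor along ``parallel_edge1``; side 2 from
    ``anchor + offset`` along ``parallel_edge2``.  The two sides must be
    parallel; ``extras[i]`` (0-2) interior points are inserted on side i,
    evenly spaced between its endpoints.
    """
    e1 = np.asarray(parallel_edge1, dtype=float)
    e2 = np.asarray(parallel_edge2, dtype=float)
    off = np.asarray(offset, dtype=float)
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if n1 == 0 or n2 == 0 or np.linalg.norm(off) == 0:
        raise SimplexError("trapezoid edges/offset must be nonzero")
    cross = e1[0] * e2[1] - e1[1] * e2[0]
    if abs(cross) > 1e-9 * n1 * n2:
        raise SimplexError("designated trapezoid sides are not parallel")
    for n in extras:
        if n not in (0, 1, 2):
            raise SimplexError(f"extras per side must be 0-2, got {extras}")
    a = to_cartesian(anchor).as_array()
    side1 = (a, a + e1)
    side2 = (a + off, a + off + e2)
    coords = [side1[0], side1[1], side2[0], side2[1]]
    for (p, q), n in zip((side1, side2), extras):
        for i in range(1, n + 1):
            coords.append(p + (q - p) * i / (n + 1))
    return _points_from_cartesian(coords, "trapezoid")


def lattice(step: float, minimum: float = 0.0) -> list[TernaryPoint]:
    """The classical full grid: all compositions in multiples of ``step``.

    With m = 1/step the count is (m+1)(m+2)/2; ``minimum`` restricts every
    coordinate to at least that fraction (e.g. the 10%-increment screen with
    no vertex-pure mixtures).
    """
    m = 1.0 / step
    if abs(m - round(m)) > 1e-9:
        raise SimplexError(f"step {step} does not divide 1")
    m = round(m)
    pts = []
    for i in range(m + 1):
        for j in range(m + 1 - i):
            k = m - i - j
            p = TernaryPoint(i / m, j / m, k / m)
            if min(p.a, p.b, p.c) >= minimum - 1e-12:
                pts.append(p)
    return pts


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    ca, sa = math.cos(angle), math.sin(angle)
    return np.array([ca * v[0] - sa * v[1], sa * v[0] + ca * v[1]])


@dataclass(frozen=True)
class DesignFigure:
    """A refinement figure placed on the simplex.

    ``size`` is the characteristic Cartesian length: hexagon radius, or the
    edge length of the parallelogram/trapezoid.  ``rotation`` orients the
    figure (radians); for the trapezoid it is the advance direction from the
    wide parallel side toward the narrow one.  ``extras`` applies to the
    trapezoid only: interior points per parallel side (wide, narrow).
    """

    kind: str
    anchor: TernaryPoint
    size: float
    rotation: float = 0.0
    extras: tuple[int, int] = (0, 0)
    #: trapezoid side widths relative to ``size`` (wide, narrow).
    widths: tuple[float, float] = field(default=(1.5, 0.75))

    def __post_init__(self) -> None:
        if self.kind not in ("hexagon", "parallelogram", "trapezoid"):
            raise SimplexError(f"unknown figure kind {self.kind!r}")
        if self.size <= 0:
            raise SimplexError(f"figure size must be positive, got {self.size}")

    def _points_at_scale(self, s: float) -> list[TernaryPoint]:
        size = self.size * s
        if self.kind == "hexagon":
            return hexagon_vertices(self.anchor, size, self.rotation)
        d = np.array([math.cos(self.rotation), math.sin(self.rotation)])
        if self.kind == "parallelogram":
            return parallelogram_points(
                self.anchor, size * d, size * _rotate(d, math.pi / 3.0)
            )
        perp = _rotate(d, math.pi / 2.0)
        w1, w2 = (w * size for w in self.widths)
        a = to_cartesian(self.anchor).as_array()
        # re-anchor so the wide side is centered on the anchor point
        start = a - 0.5 * w1 * perp
        base = from_cartesian(PlanarPoint(*start))
        return trapezoid_points(
            base,
            w1 * perp,
            w2 * perp,
            size * d + 0.5 * (w1 - w2) * perp,
            self.extras,
        )

    def points(self, shrink_to_fit: bool = False) -> list[TernaryPoint]:
        """Generate the figure's sample points.

        By default a figure with any vertex outside the simplex fails
        loudly (silent clipping would change experiment counts).  With
        ``shrink_to_fit`` the figure is scaled toward its anchor, in 5%
        steps, until all points are valid.
        """
        if not shrink_to_fit:
            return self._points_at_scale(1.0)
        scale = 1.0
        while scale > 1e-3:
            try:
                return self._points_at_scale(scale)
            except SimplexError:
                scale *= 0.95
        raise SimplexError(
            f"{self.kind} cannot be shrunk to fit the simplex at anchor "
            f"({self.anchor.a:.3f}, {self.anchor.b:.3f}, {self.anchor.c:.3f})"
        )

    @property
    def n_points(self) -> int:
        return {"hexagon": 6, "parallelogram": 4, "trapezoid": 4 + sum(self.extras)}[
            self.kind
        ]
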