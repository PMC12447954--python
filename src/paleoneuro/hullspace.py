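"""Minimum convex polygons in brain-body log-log space.

Class-level grades of encephalization are classically delimited by the
convex hull of a group's specimens in (log10 body mass, log10 brain mass)
space: living mammals, birds and reptiles each occupy a polygon, with the
reptile polygon lying well below the other two. A fossil can then be
*classified* against a polygon — inside it, above it (more brain than the
group's envelope allows at that body mass), or below it.

Because dinosaurs extend to body masses far beyond any living reptile, the
reptile polygon must be *extended* rightward before classifying very large
or very archaic specimens against it: the upper boundary is continued from
the rightmost vertex (by default at the slope of the last upper-hull edge,
optionally at the theoretical 2/3), with a parallel lower boundary through
the smallest-brain vertex. The extension assumes dinosaur brains followed
living-reptile size rules.

Vertices are stored counter-clockwise starting from the lexicographically
smallest vertex so polygons compare deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, DomainError

_EPS = 1e-9


class PointClass(str, Enum):
    ABOVE = "above"
    INSIDE = "inside"
    ON_BOUNDARY = "on_boundary"
    BELOW = "below"
    OUTSIDE_RANGE = "outside_range"


@dataclass(frozen=True)
class ConvexPolygon:
    """Ordered (log10 P, log10 E) vertices, counter-clockwise, >= 3 of them."""

    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise DegenerateGeometryError(
                f"a polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    @property
    def xs(self) -> np.ndarray:
        return np.asarray([v[0] for v in self.vertices])

    @property
    def ys(self) -> np.ndarray:
        return np.asarray([v[1] for v in self.vertices])

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.xs.min()), float(self.xs.max())

    def area(self) -> float:
        x, y = self.xs, self.ys
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def upper_chain(self) -> list[tuple[float, float]]:
        """Vertices along the upper boundary, left to right."""
        return _chain(self.vertices, upper=True)

    def lower_chain(self) -> list[tuple[float, float]]:
        """Vertices along the lower boundary, left to right."""
        return _chain(self.vertices, upper=False)


def _canonical(vertices: np.ndarray, label: str) -> ConvexPolygon:
    """CCW-orient, drop collinear interior vertices, start at lexicographic min."""
    pts = [tuple(map(float, v)) for v in vertices]
    # signed area; reverse if clockwise
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        pts = pts[::-1]
    # drop duplicate and collinear vertices
    cleaned: list[tuple[float, float]] = []
    m = len(pts)
    for i in range(m):
        prev, cur, nxt = pts[i - 1], pts[i], pts[(i + 1) % m]
        if abs(cur[0] - prev[0]) < _EPS and abs(cur[1] - prev[1]) < _EPS:
            continue
        cross = (cur[0] - prev[0]) * (nxt[1] - cur[1]) - (cur[1] - prev[1]) * (
            nxt[0] - cur[0]
        )
        if abs(cross) < _EPS:
            continue
        cleaned.append(cur)
    if len(cleaned) < 3:
        raise DegenerateGeometryError("points are collinear: no polygon")
    start = min(range(len(cleaned)), key=lambda i: cleaned[i])
    return ConvexPolygon(tuple(cleaned[start:] + cleaned[:start]), label=label)


def minimum_convex_polygon(
    points: Sequence[tuple[float, float]], label: str = ""
) -> ConvexPolygon:
    """Convex hull of (P, E) pairs after log10 transform.

    Every input point ends up inside or on the returned polygon; every
    vertex is (the log10 of) an input point.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 (P, E) points")
    if np.any(arr <= 0):
        raise DomainError("all masses and volumes must be positive")
    logged = np.log10(arr)
    try:
        hull = ConvexHull(logged)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    return _canonical(logged[hull.vertices], label)


def polygon_from_log_vertices(
    vertices: Sequence[tuple[float, float]], label: str = ""
) -> ConvexPolygon:
    """Build a canonical polygon from points already in log10 space."""
    arr = np.asarray(vertices, dtype=float)
    if arr.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 vertices")
    try:
        hull = ConvexHull(arr)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    return _canonical(arr[hull.vertices], label)


def _chain(
    vertices: Sequence[tuple[float, float]], upper: bool
) -> list[tuple[float, float]]:
    pts = sorted(set(vertices))
    chain: list[tuple[float, float]] = []
    src = pts if not upper else list(reversed(pts))
    for p in src:
        while len(chain) >= 2:
            ox, oy = chain[-2]
            ax, ay = chain[-1]
            if (ax - ox) * (p[1] - oy) - (ay - oy) * (p[0] - ox) <= _EPS:
                chain.pop()
            else:
                break
        chain.append(p)
    return chain if not upper else chain[::-1]


def _chain_y_at(chain: Sequence[tuple[float, float]], x: float) -> float:
    for (x0, y0), (x1, y1) in zip(chain, chain[1:]):
        if x0 - _EPS <= x <= x1 + _EPS:
            if abs(x1 - x0) < _EPS:
                return max(y0, y1)
            t = (x - x0) / (x1 - x0)
            return y0 + t * (y1 - y0)
    # single-vertex chain or x at an extreme
    return chain[0][1] if x <= chain[0][0] else chain[-1][1]


def classify_point(
    point: tuple[float, float], polygon: ConvexPolygon
) -> PointClass:
    """Locate a (P, E) point relative to a polygon, in log10 space.

    Returns ``inside``/``on_boundary`` by convex containment; otherwise
    ``above`` or ``below`` according to the polygon's upper/lower boundary
    chains evaluated at the point's log10 P — defined only when log10 P is
    within the polygon's horizontal extent, else ``outside_range``.
    """
    P, E = point
    if not P > 0 or not E > 0:
        raise DomainError("mass and volume must be positive")
    x, y = float(np.log10(P)), float(np.log10(E))

    xmin, xmax = polygon.x_range
    if x < xmin - _EPS or x > xmax + _EPS:
        return PointClass.OUTSIDE_RANGE

    verts = polygon.vertices
    on_boundary = False
    inside = True
    for (x0, y0), (x1, y1) in zip(verts, verts[1:] + verts[:1]):
        cross = (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)
        seg_len = np.hypot(x1 - x0, y1 - y0)
        if abs(cross) <= _EPS * max(1.0, seg_len):
            within = (
                min(x0, x1) - _EPS <= x <= max(x0, x1) + _EPS
                and min(y0, y1) - _EPS <= y <= max(y0, y1) + _EPS
            )
            if within:
                on_boundary = True
                continue
        if cross < 0:  # right of a CCW edge -> outside
            inside = False
    if on_boundary:
        return PointClass.ON_BOUNDARY
    if inside:
        return PointClass.INSIDE
    upper_y = _chain_y_at(polygon.upper_chain(), x)
    return PointClass.ABOVE if y > upper_y else PointClass.BELOW


def extend_polygon(
    polygon: ConvexPolygon,
    new_max_log10P: float,
    slope: float | None = None,
) -> ConvexPolygon:
    """Extend a polygon rightward to a larger body-mass limit.

    The upper boundary is continued from the rightmost upper vertex at
    ``slope`` (default: the slope of the last upper-hull edge); the lower
    boundary is the parallel line through the vertex of minimum log10 E.
    The result is re-convexified and always contains the original.
    """
    xmin, xmax = polygon.x_range
    if new_max_log10P < xmax - _EPS:
        raise DomainError(
            f"new maximum {new_max_log10P} does not extend beyond {xmax}"
        )
    if abs(new_max_log10P - xmax) <= _EPS:
        return _canonical(
            np.asarray(polygon.vertices), polygon.label or "extended"
        )

    upper = polygon.upper_chain()
    if slope is None:
        (x0, y0), (x1, y1) = upper[-2], upper[-1]
        if abs(x1 - x0) < _EPS:
            raise DomainError("last upper edge is vertical: pass a slope")
        slope = (y1 - y0) / (x1 - x0)

    xr, yr = upper[-1]  # rightmost upper vertex
    new_upper = (new_max_log10P, yr + slope * (new_max_log10P - xr))
    k = int(np.argmin(polygon.ys))
    xb, yb = polygon.vertices[k]  # vertex of minimum brain size
    new_lower = (new_max_log10P, yb + slope * (new_max_log10P - xb))

    allpts = np.asarray(list(polygon.vertices) + [new_upper, new_lower])
    label = f"{polygon.label}-extended" if polygon.label else "extended"
    return polygon_from_log_vertices(allpts, label=label)
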