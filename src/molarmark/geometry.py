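"""Planar geometry for occlusal crown outlines.

The crown perimeter is an ordered, simple, closed polygon in millimetres.
Internally every outline is stored counterclockwise in mathematical (y-up)
axes with the mesial side at negative x and the lingual side at positive y.
Five labelled groove points (the Type I inter-cusp landmarks g6..g10) sit on
polygon vertices; anatomically they run mesial -> lingual -> distolingual ->
distobuccal -> buccal, which in these axes is a *clockwise* tour of the
perimeter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import GeometryError, UsageError

GROOVE_LABELS = ("g6", "g7", "g8", "g9", "g10")

#: on-outline / vertex-coincidence tolerance, mm
ON_OUTLINE_TOL = 1e-9


class StarShapeWarning(UserWarning):
    """Outline is not star-shaped from the queried origin; nearest crossing used."""


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Outline:
    """Simple closed polygon (counterclockwise, implicit closing edge).

    Parameters
    ----------
    vertices : (n, 2) array
        Ordered perimeter vertices in mm.  A duplicated closing vertex is
        dropped; clockwise input is reversed so the stored orientation is
        always counterclockwise.
    """

    vertices: np.ndarray

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError(f"outline vertices must be (n, 2), got {v.shape}")
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise GeometryError("outline needs at least 3 distinct vertices")
        if not shapely.Polygon(v).is_valid:
            raise GeometryError("outline polygon is self-intersecting or degenerate")
        if _signed_area(v) < 0:
            v = v[::-1]
        object.__setattr__(self, "vertices", np.ascontiguousarray(v))

    # -- basic measures ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def closed(self) -> np.ndarray:
        """Vertices with the first point appended again (n+1, 2)."""
        return np.vstack([self.vertices, self.vertices[:1]])

    @property
    def edge_lengths(self) -> np.ndarray:
        c = self.closed
        return np.linalg.norm(np.diff(c, axis=0), axis=1)

    @property
    def perimeter(self) -> float:
        return float(self.edge_lengths.sum())

    @property
    def cumulative_lengths(self) -> np.ndarray:
        """Arc length at each vertex, starting at 0 for vertex 0 (n,)."""
        return np.concatenate([[0.0], np.cumsum(self.edge_lengths)[:-1]])

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax); raises on zero width or height."""
        xmin, ymin = self.vertices.min(axis=0)
        xmax, ymax = self.vertices.max(axis=0)
        if xmax - xmin <= 0 or ymax - ymin <= 0:
            raise GeometryError("degenerate bounding box (zero width or height)")
        return float(xmin), float(ymin), float(xmax), float(ymax)

    def box_center(self) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounding_box()
        return np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])

    # -- point queries -----------------------------------------------------
    def contains(self, point) -> bool:
        return bool(shapely.Polygon(self.vertices).covers(shapely.Point(point)))

    def is_star_shaped_from(self, point, tol: float = 1e-12) -> bool:
        """Kernel membership test: the point sees the whole boundary iff it
        lies on the interior side of every edge's supporting line."""
        p = np.asarray(point, dtype=float)
        a = self.vertices
        b = np.roll(a, -1, axis=0)
        e = b - a
        cross = e[:, 0] * (p[1] - a[:, 1]) - e[:, 1] * (p[0] - a[:, 0])
        scale = np.linalg.norm(e, axis=1)
        return bool(np.all(cross >= -tol * np.maximum(scale, 1.0)))

    def distance_to_boundary(self, point) -> float:
        ring = shapely.LinearRing(self.vertices)
        return float(ring.distance(shapely.Point(point)))

    # -- arc-length parameterization ----------------------------------------
    def point_at_arclength(self, s: float) -> np.ndarray:
        s = float(s) % self.perimeter
        ring = shapely.LinearRing(self.closed)
        p = ring.interpolate(s)
        return np.array([p.x, p.y])

    def arclength_of_point(self, point, tol: float = 1e-6) -> float:
        """Arc length of a point lying on the boundary (within tol)."""
        ring = shapely.LinearRing(self.closed)
        pt = shapely.Point(point)
        if ring.distance(pt) > tol:
            raise GeometryError(
                f"point {tuple(np.asarray(point))} is {ring.distance(pt):.3g} mm "
                "from the outline, beyond tolerance"
            )
        return float(ring.project(pt)) % self.perimeter

    def nearest_vertex(self, point) -> tuple[int, float]:
        """(index, distance) of the closest polygon vertex."""
        d = np.linalg.norm(self.vertices - np.asarray(point, dtype=float), axis=1)
        i = int(np.argmin(d))
        return i, float(d[i])

    def insert_vertex_at_arclength(self, s: float) -> tuple["Outline", int]:
        """Return a new outline with a vertex at arc length ``s`` and its index.

        If ``s`` falls on an existing vertex (within ON_OUTLINE_TOL) the
        outline is returned unchanged with that vertex's index.
        """
        p = self.point_at_arclength(s)
        i, d = self.nearest_vertex(p)
        if d <= ON_OUTLINE_TOL:
            return self, i
        cum = self.cumulative_lengths
        s = float(s) % self.perimeter
        # edge k spans [cum[k], cum[k] + edge_lengths[k])
        k = int(np.searchsorted(cum, s, side="right") - 1)
        new = np.insert(self.vertices, k + 1, p, axis=0)
        return Outline(new), k + 1

    # -- transforms ----------------------------------------------------------
    def translated(self, offset) -> "Outline":
        return Outline(self.vertices + np.asarray(offset, dtype=float))

    def scaled(self, factor: float, center=(0.0, 0.0)) -> "Outline":
        c = np.asarray(center, dtype=float)
        return Outline(c + factor * (self.vertices - c))

    def mirrored_x(self) -> "Outline":
        """Reflect about the vertical axis (x -> -x); re-normalized to CCW."""
        return Outline(self.vertices * np.array([-1.0, 1.0]))


@dataclass(frozen=True)
class GroovePoints:
    """The five Type I inter-cusp groove landmarks on the outline.

    g6 sits in the mesial edge groove (metaconid|protoconid), g7 lingual
    (metaconid|entoconid), g8 distolingual (entoconid|hypoconulid), g9
    distobuccal (hypoconulid|hypoconid), g10 buccal (hypoconid|protoconid).
    In the internal y-up axes this labelled order is a clockwise tour, i.e.
    arc length measured clockwise from g6 is strictly increasing g7 < g8 <
    g9 < g10.
    """

    points: np.ndarray  # (5, 2) in label order g6..g10
    vertex_indices: tuple[int, int, int, int, int] = field(default=None)

    def __init__(self, points, outline: Outline | None = None) -> None:
        p = np.asarray(points, dtype=float)
        if p.shape != (5, 2):
            raise UsageError(f"groove points must be (5, 2), got {p.shape}")
        object.__setattr__(self, "points", np.ascontiguousarray(p))
        idx = None
        if outline is not None:
            idx = tuple(self._validate(outline))
        object.__setattr__(self, "vertex_indices", idx)

    def _validate(self, outline: Outline) -> list[int]:
        indices = []
        for label, pt in zip(GROOVE_LABELS, self.points):
            i, d = outline.nearest_vertex(pt)
            if d > ON_OUTLINE_TOL:
                raise GeometryError(
                    f"groove point {label} is {d:.3g} mm from the nearest outline "
                    "vertex; groove points must coincide with polygon vertices"
                )
            indices.append(i)
        if len(set(indices)) != 5:
            raise GeometryError("groove points must be five distinct outline vertices")
        # clockwise arc-length from g6 must be strictly increasing g7..g10
        cum = outline.cumulative_lengths
        per = outline.perimeter
        s = cum[np.array(indices)]
        cw = (s[0] - s) % per  # clockwise offset from g6
        if not np.all(np.diff(cw[1:]) > 0) or np.any(cw[1:] <= 0):
            raise GeometryError(
                "groove points out of cyclic order: expected g6->g7->g8->g9->g10 "
                "to run mesial->lingual->distal->buccal (clockwise in y-up axes)"
            )
        return indices

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[GROOVE_LABELS.index(label)]

    def translated(self, offset) -> "GroovePoints":
        return GroovePoints(self.points + np.asarray(offset, dtype=float))

    def scaled(self, factor: float, center=(0.0, 0.0)) -> "GroovePoints":
        c = np.asarray(center, dtype=float)
        return GroovePoints(c + factor * (self.points - c))

    def mirrored_x(self) -> "GroovePoints":
        return GroovePoints(self.points * np.array([-1.0, 1.0]))


def ray_outline_intersection(origin, through, outline: Outline) -> np.ndarray:
    """Intersect the ray from ``origin`` through ``through`` with the outline.

    The ray is parameterized as origin + t*(through - origin), t > 0, so
    ``through`` sits at t = 1.  When ``through`` is inside the polygon the
    crossing with the smallest t >= 1 is returned (the perimeter point "beyond"
    ``through``); otherwise the first crossing t > 0.  Each polygon edge is
    solved exactly as a 2x2 linear system.  If the outline is not star-shaped
    along this ray (several crossings beyond ``through``) a StarShapeWarning
    is emitted and the nearest crossing is returned.
    """
    o = np.asarray(origin, dtype=float)
    q = np.asarray(through, dtype=float)
    d = q - o
    if np.linalg.norm(d) == 0:
        raise UsageError("ray direction is undefined: origin == through")

    a = outline.vertices
    b = np.roll(a, -1, axis=0)
    e = b - a
    # solve o + t d = a + u e  for each edge: [d, -e] [t, u]^T = a - o
    denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])  # det per edge
    rhs = a - o
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / denom
        u = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / denom
    ok = np.isfinite(t) & np.isfinite(u) & (u >= 0.0) & (u < 1.0) & (t > 1e-12)
    ts = np.sort(np.unique(np.round(t[ok], 12)))
    if ts.size == 0:
        raise GeometryError("ray does not cross the outline (origin outside?)")

    if outline.contains(q):
        beyond = ts[ts >= 1.0 - 1e-9]
        if beyond.size == 0:
            raise GeometryError("no outline crossing beyond the through point")
        if beyond.size > 1:
            warnings.warn(
                "outline is not star-shaped along this ray; using nearest crossing",
                StarShapeWarning,
                stacklevel=2,
            )
        t_hit = float(beyond[0])
    else:
        t_hit = float(ts[0])
    return o + t_hit * d


def arc_midpoint(outline: Outline, start, end) -> np.ndarray:
    """Point halfway (in arc length) along the counterclockwise arc start->end."""
    s0 = outline.arclength_of_point(start)
    s1 = outline.arclength_of_point(end)
    span = (s1 - s0) % outline.perimeter
    if span == 0:
        raise UsageError("arc endpoints coincide")
    return outline.point_at_arclength(s0 + span / 2.0)
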