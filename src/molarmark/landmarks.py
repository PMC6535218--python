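"""Derivation of the 29-landmark configuration from a crown outline.

The method starts from five anatomical (Type I) groove points on the occlusal
perimeter — the only features that survive heavy wear — and constructs the
remaining 24 landmarks mathematically (Type III):

====== =======================================================================
1      center of the axis-aligned bounding box of the outline
2-5    midpoints of the mesial, lingual, distal and buccal box sides
       (proxies for the corrected MD and maximum BL diameters)
6-10   the groove points g6..g10 (copied verbatim)
11-15  midpoints of the chords g6-g7, g7-g8, g8-g9, g9-g10, g10-g6
16-20  perimeter points on the rays from landmark 1 through 11..15
       (mid-arc point of each cusp: metaconid, entoconid, hypoconulid,
       hypoconid, protoconid)
21-25  midpoints of the segments 1->16 .. 1->20 (cusp-center proxies)
26-29  crossings of the mesial cusp line (21-25) and distal cusp line (22-24)
       with the lingual and buccal crown edge
====== =======================================================================

Inputs are assumed pre-oriented: mesial to the left (-x), lingual up (+y),
MD axis horizontal.  Right-side teeth are mirrored on ingest so all analyses
run in left-side configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, UsageError
from .geometry import (
    GROOVE_LABELS,
    GroovePoints,
    Outline,
    ray_outline_intersection,
)

N_LANDMARKS = 29

#: 1-based labels of landmarks constrained to lie on the outline
ON_OUTLINE_LANDMARKS = (6, 7, 8, 9, 10, 16, 17, 18, 19, 20, 26, 27, 28, 29)

CUSP_NAMES = ("metaconid", "entoconid", "hypoconulid", "hypoconid", "protoconid")


class OrientationWarning(UserWarning):
    """A cusp line exits through the mesial/distal rather than lingual/buccal wall."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """29 labelled 2D landmarks (mm) plus provenance flags.

    ``points`` is a (29, 2) array indexed 0..28 for landmarks 1..29; use
    :meth:`landmark` for 1-based access.
    """

    points: np.ndarray
    hypoconulid_inferred: bool = False
    c6_bisected: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.shape != (N_LANDMARKS, 2):
            raise UsageError(f"expected ({N_LANDMARKS}, 2) landmarks, got {p.shape}")
        object.__setattr__(self, "points", np.ascontiguousarray(p))

    def landmark(self, i: int) -> np.ndarray:
        """1-based landmark accessor (landmarks are numbered 1..29)."""
        if not 1 <= i <= N_LANDMARKS:
            raise UsageError(f"landmark index {i} out of range 1..{N_LANDMARKS}")
        return self.points[i - 1]

    def transformed(self, scale: float = 1.0, offset=(0.0, 0.0)) -> "LandmarkConfiguration":
        return replace(self, points=self.points * scale + np.asarray(offset, dtype=float))


def normalize_orientation(
    outline: Outline, groove: GroovePoints, side: str
) -> tuple[Outline, GroovePoints]:
    """Mirror right-side teeth about the vertical axis into left configuration.

    Mirroring x -> -x maps a right molar onto left-side anatomy with groove
    labels unchanged; left-side inputs pass through untouched.
    """
    if side == "left":
        return outline, groove
    if side == "right":
        return outline.mirrored_x(), groove.mirrored_x()
    raise UsageError(f"unknown side {side!r}: expected 'left' or 'right'")


def bounding_box_landmarks(outline: Outline) -> np.ndarray:
    """Landmarks 1-5: box center plus the four box-side midpoints.

    Landmark 2 is the mesial-most (x = xmin), 3 lingual-most (y = ymax),
    4 distal-most (x = xmax) and 5 buccal-most (y = ymin) point, each placed
    midway along its side of the axis-aligned bounding box.
    """
    xmin, ymin, xmax, ymax = outline.bounding_box()
    xc, yc = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    return np.array(
        [[xc, yc], [xmin, yc], [xc, ymax], [xmax, yc], [xc, ymin]], dtype=float
    )


def chord_midpoints(groove: GroovePoints) -> np.ndarray:
    """Landmarks 11-15: midpoints of the groove chords, in cusp order.

    11 = (g6+g7)/2 orients the metaconid, 12 = (g7+g8)/2 the entoconid,
    13 = (g8+g9)/2 the hypoconulid, 14 = (g9+g10)/2 the hypoconid and
    15 = (g10+g6)/2 the protoconid.
    """
    g = groove.points
    return (g + np.roll(g, -1, axis=0)) / 2.0


def cusp_arc_midpoints(point1, mids: np.ndarray, outline: Outline) -> np.ndarray:
    """Landmarks 16-20: perimeter points on the rays 1->11 .. 1->15."""
    return np.array(
        [ray_outline_intersection(point1, m, outline) for m in mids], dtype=float
    )


def cusp_center_proxies(point1, arc_mids: np.ndarray) -> np.ndarray:
    """Landmarks 21-25: midpoints of the segments from landmark 1 to 16-20."""
    return (np.asarray(point1, dtype=float) + arc_mids) / 2.0


def _line_edge_pair(inner_a, inner_b, outline: Outline) -> tuple[np.ndarray, np.ndarray]:
    """Extend the line a-b to the outline on both sides; return (lingual, buccal).

    The crossing beyond ``inner_a`` comes from the ray b->a and vice versa;
    lingual vs buccal is decided by the sign of the y-displacement from the
    segment midpoint (+y = lingual in the internal convention).
    """
    beyond_a = ray_outline_intersection(inner_b, inner_a, outline)
    beyond_b = ray_outline_intersection(inner_a, inner_b, outline)
    mid_y = (np.asarray(inner_a)[1] + np.asarray(inner_b)[1]) / 2.0
    da, db = beyond_a[1] - mid_y, beyond_b[1] - mid_y
    if da * db >= 0:
        warnings.warn(
            "cusp line exits through the mesial/distal wall; labelling crossings "
            "by y-displacement",
            OrientationWarning,
            stacklevel=3,
        )
    if da >= db:
        return beyond_a, beyond_b
    return beyond_b, beyond_a


def cusp_line_edge_points(
    p21, p25, p22, p24, outline: Outline
) -> np.ndarray:
    """Landmarks 26-29: cusp-line crossings with the lingual/buccal crown edge.

    The mesial cusp line through 21 (metaconid center) and 25 (protoconid
    center) gives 26 (lingual) and 29 (buccal); the distal cusp line through
    22 (entoconid) and 24 (hypoconid) gives 27 (lingual) and 28 (buccal).
    """
    p26, p29 = _line_edge_pair(p21, p25, outline)
    p27, p28 = _line_edge_pair(p22, p24, outline)
    return np.array([p26, p27, p28, p29], dtype=float)


def derive_landmarks(
    outline: Outline,
    groove: GroovePoints,
    *,
    side: str = "left",
    hypoconulid_inferred: bool = False,
    c6_bisected: bool = False,
    specimen_id: str | None = None,
) -> LandmarkConfiguration:
    """Run the full 29-landmark construction on one specimen.

    The groove points are re-validated against the outline; any geometric
    failure is re-raised with the specimen id prefixed.
    """
    try:
        outline, groove = normalize_orientation(outline, groove, side)
        groove = GroovePoints(groove.points, outline)  # re-validate on this outline
        box = bounding_box_landmarks(outline)
        p1 = box[0]
        if not outline.contains(p1):
            raise GeometryError("bounding-box center lies outside the outline")
        mids = chord_midpoints(groove)
        arc_mids = cusp_arc_midpoints(p1, mids, outline)
        centers = cusp_center_proxies(p1, arc_mids)
        edges = cusp_line_edge_points(centers[0], centers[4], centers[1], centers[3], outline)
    except Exception as exc:
        if specimen_id is not None:
            raise type(exc)(f"specimen {specimen_id!r}: {exc}") from exc
        raise
    points = np.vstack([box, groove.points, mids, arc_mids, centers, edges])
    return LandmarkConfiguration(
        points,
        hypoconulid_inferred=hypoconulid_inferred,
        c6_bisected=c6_bisected,
    )


def infer_hypoconulid_groove(
    outline: Outline, distal_groove, half_width: float
) -> tuple[Outline, np.ndarray, np.ndarray]:
    """Place g8/g9 around an inferred hypoconulid on a 4-cusp crown.

    On molars lacking a hypoconulid a single distal groove separates the
    entoconid from the hypoconid.  The missing cusp is inferred by siting g8
    and g9 at ±``half_width`` arc length (mm) around that groove, so the small
    inter-cusp area is landmarked as though it were a normal hypoconulid.
    g8 lies counterclockwise (lingual side) of the groove and g9 clockwise.

    Returns the outline with the two points inserted as vertices, plus the
    points themselves.
    """
    if half_width < 0:
        raise UsageError("half_width must be non-negative")
    if half_width >= outline.perimeter / 4.0:
        raise UsageError(
            f"half_width {half_width} mm is >= a quarter of the perimeter "
            f"({outline.perimeter / 4.0:.3g} mm)"
        )
    s0 = outline.arclength_of_point(distal_groove)
    out2, _ = outline.insert_vertex_at_arclength(s0 + half_width)
    out2, _ = out2.insert_vertex_at_arclength(s0 - half_width)
    g8 = out2.point_at_arclength(s0 + half_width)
    g9 = out2.point_at_arclength(s0 - half_width)
    return out2, g8, g9


def bisect_c6(outline: Outline, c6_start, c6_end) -> tuple[Outline, np.ndarray]:
    """Bisect a tuberculum sextum (C6) arc to mark the entoconid|hypoconulid groove.

    ``c6_start`` and ``c6_end`` delimit the sixth cusp on the outline, given
    counterclockwise (start -> end); the point halfway along that arc serves
    as g8.  The bisected arc must not exceed half the perimeter — a longer
    arc almost certainly means the endpoints were swapped.
    """
    s0 = outline.arclength_of_point(c6_start)
    s1 = outline.arclength_of_point(c6_end)
    span = (s1 - s0) % outline.perimeter
    if span == 0:
        raise UsageError("C6 endpoints coincide")
    if span > outline.perimeter / 2.0:
        raise UsageError(
            "C6 arc exceeds half the perimeter; endpoints are probably swapped "
            "(expected counterclockwise start -> end)"
        )
    out2, idx = outline.insert_vertex_at_arclength(s0 + span / 2.0)
    return out2, out2.vertices[idx].copy()
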