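"""The nine mathematically-derived diagnostic measurements.

Each variable is a distance, angle or ratio between named landmarks of the
29-point configuration:

===========================  ==================================================
md_diameter                  dist(2, 4) — mesiodistal diameter (mm)
bl_mesial_cusps              dist(26, 29) — buccolingual breadth across the
                             mesial cusps (mm)
bl_distal_cusps              dist(27, 28) — breadth across the distal cusps (mm)
bl_groove                    dist(7, 10) — breadth across the buccolingual
                             groove (mm)
buccal_groove_mesial_edge    dist(29, 10) — mesial edge of the buccal
                             development groove (mm)
buccal_groove_distal_edge    dist(10, 28) — distal edge of the buccal
                             development groove (mm)
angle_mesial_cusps           angle between the mesial cusp line (21-25) and
                             the MD diameter (2-4), radians in [0, pi)
angle_distal_cusps           angle between the distal cusp line (22-24) and
                             the MD diameter, radians in [0, pi)
hypoconulid_curvature_ratio  dist(13, 18) / dist(1, 18) — outward projection
                             of the hypoconulid arc, dimensionless in [0, 1)
===========================  ==================================================

Angles are undirected (lines, not rays), reported modulo pi so lingual and
buccal tilts of the same magnitude are treated symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import UsageError
from .landmarks import LandmarkConfiguration

MEASUREMENT_NAMES = (
    "md_diameter",
    "bl_mesial_cusps",
    "bl_distal_cusps",
    "bl_groove",
    "buccal_groove_mesial_edge",
    "buccal_groove_distal_edge",
    "angle_mesial_cusps",
    "angle_distal_cusps",
    "hypoconulid_curvature_ratio",
)


@dataclass(frozen=True)
class MeasurementVector:
    md_diameter: float
    bl_mesial_cusps: float
    bl_distal_cusps: float
    bl_groove: float
    buccal_groove_mesial_edge: float
    buccal_groove_distal_edge: float
    angle_mesial_cusps: float
    angle_distal_cusps: float
    hypoconulid_curvature_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def _dist(config: LandmarkConfiguration, i: int, j: int) -> float:
    return float(np.linalg.norm(config.landmark(i) - config.landmark(j)))


def angle_to_md_axis(p, q, config: LandmarkConfiguration) -> float:
    """Undirected angle in [0, pi) between line pq and the MD diameter (2-4)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    if np.linalg.norm(d) == 0:
        raise UsageError("cannot measure the angle of a zero-length line")
    md = config.landmark(4) - config.landmark(2)
    if np.linalg.norm(md) == 0:
        raise UsageError("degenerate MD axis: landmarks 2 and 4 coincide")
    theta = np.arctan2(d[1], d[0]) - np.arctan2(md[1], md[0])
    return float(np.mod(theta, np.pi))


def compute_measurements(config: LandmarkConfiguration) -> MeasurementVector:
    """Compute the nine diagnostic variables from one landmark configuration."""
    d_1_18 = _dist(config, 1, 18)
    if d_1_18 == 0:
        raise UsageError(
            "degenerate configuration: landmark 18 coincides with the box center"
        )
    return MeasurementVector(
        md_diameter=_dist(config, 2, 4),
        bl_mesial_cusps=_dist(config, 26, 29),
        bl_distal_cusps=_dist(config, 27, 28),
        bl_groove=_dist(config, 7, 10),
        buccal_groove_mesial_edge=_dist(config, 29, 10),
        buccal_groove_distal_edge=_dist(config, 10, 28),
        angle_mesial_cusps=angle_to_md_axis(
            config.landmark(21), config.landmark(25), config
        ),
        angle_distal_cusps=angle_to_md_axis(
            config.landmark(22), config.landmark(24), config
        ),
        hypoconulid_curvature_ratio=_dist(config, 13, 18) / d_1_18,
    )


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid (mm)."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, dtype=float)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


#: landmarks entering the extended pairwise catalog: everything named by the
#: nine diagnostic variables, plus 3 and 5 for the maximum BL diameter
_CATALOG_LANDMARKS = (1, 2, 3, 4, 5, 7, 10, 13, 18, 21, 22, 24, 25, 26, 27, 28, 29)


def extended_measurements(config: LandmarkConfiguration) -> dict[str, float]:
    """Superset catalog: all pairwise distances among the named landmarks,
    the maximum BL diameter dist(3, 5), centroid size, and the cusp-line
    angles.  Keys are ``d_i_j`` for distances."""
    out: dict[str, float] = {}
    for i, j in combinations(_CATALOG_LANDMARKS, 2):
        out[f"d_{i}_{j}"] = _dist(config, i, j)
    out["bl_max"] = _dist(config, 3, 5)
    out["centroid_size"] = centroid_size(config)
    out["angle_mesial_cusps"] = angle_to_md_axis(
        config.landmark(21), config.landmark(25), config
    )
    out["angle_distal_cusps"] = angle_to_md_axis(
        config.landmark(22), config.landmark(24), config
    )
    return out


def measurement_table(
    configs, ids=None, include_ln_centroid_size: bool = False
) -> pd.DataFrame:
    """Tabulate the nine variables (optionally plus ln centroid size) per specimen."""
    rows = []
    for c in configs:
        row = compute_measurements(c).as_dict()
        if include_ln_centroid_size:
            row["ln_centroid_size"] = float(np.log(centroid_size(c)))
        rows.append(row)
    df = pd.DataFrame(rows)
    if ids is not None:
        df.index = pd.Index(ids, name="specimen_id")
    return df
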