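"""Parametric 5-cusp molar crown generator.

Crowns are built as radial-bump curves around the origin,

    r(theta) = 1 + sum_i  a_i * exp(kappa * (cos(theta - theta_i) - 1)),

one von-Mises-shaped lobe per cusp, sampled on a fixed angular grid and then
anisotropically rescaled so the bounding box measures exactly the drawn
mesiodistal length by ``bl_md_ratio`` times that length, with the MD axis
horizontal (mesial at -x, lingual at +y).  Groove points are the radial
minima of the noiseless lobe function between adjacent cusps, kept as exact
polygon vertices.  Each template parameter maps to a named crown concept:
breadth ratio, per-cusp lobe prominence (a vanishing hypoconulid lobe gives
a 4-cusp crown), cusp-line orientations and a male size offset for sexual
dimorphism.

The five default templates (A-E) caricature the kinds of contrasts seen
among great-ape and human second molars — small narrow crowns, small broad
crowns with a reduced hypoconulid, medium and large narrow crowns with
strong size dimorphism — without claiming biological realism for any taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .errors import GeometryError, UsageError
from .geometry import GroovePoints, Outline
from .io_formats import LandmarkTable, SpecimenRecord
from .landmarks import LandmarkConfiguration, derive_landmarks
from .measurements import measurement_table

N_VERTICES = 512
_KAPPA = 12.0  # lobe concentration; width ~ 1/sqrt(kappa) rad

# cusp order used throughout: metaconid, entoconid, hypoconulid, hypoconid,
# protoconid (matching the chord-midpoint order of landmarks 11-15)
CUSP_ORDER = ("metaconid", "entoconid", "hypoconulid", "hypoconid", "protoconid")

#: nominal cusp azimuths (rad) before cusp-line adjustment: mesial = pi,
#: lingual = +pi/2 (metaconid mesiolingual, hypoconulid distal & slightly buccal)
_BASE_ANGLES = {
    "metaconid": np.deg2rad(135.0),
    "entoconid": np.deg2rad(48.0),
    "hypoconulid": np.deg2rad(-8.0),
    "hypoconid": np.deg2rad(-50.0),
    "protoconid": np.deg2rad(-135.0),
}

#: groove label sitting between each CCW-adjacent cusp pair
_GROOVE_OF_PAIR = {
    ("protoconid", "hypoconid"): "g10",
    ("hypoconid", "hypoconulid"): "g9",
    ("hypoconulid", "entoconid"): "g8",
    ("entoconid", "metaconid"): "g7",
    ("metaconid", "protoconid"): "g6",
}


@dataclass(frozen=True)
class CrownTemplate:
    name: str
    md_length_mean: float           # mm
    md_length_sd: float             # mm
    bl_md_ratio: float              # BL breadth / MD length
    cusp_lobe_amplitudes: tuple[float, float, float, float, float]
    cusp_angular_positions: tuple[float, float, float, float, float] = field(
        default=tuple(_BASE_ANGLES[c] for c in CUSP_ORDER)
    )
    mesial_cusp_angle: float = np.pi / 2   # target angle of the 21-25 line, rad
    distal_cusp_angle: float = np.pi / 2   # target angle of the 22-24 line, rad
    sex_size_offset: float = 0.0           # mm added to male MD length
    hypoconulid_present: bool = True
    noise_sd: float = 0.0                  # relative radial noise SD

    def __post_init__(self) -> None:
        if self.md_length_mean <= 0:
            raise UsageError("md_length_mean must be positive")
        amps = np.asarray(self.cusp_lobe_amplitudes, dtype=float)
        if amps.shape != (5,) or np.any(amps < 0) or np.any(amps >= 0.5):
            raise UsageError("cusp lobe amplitudes must be 5 values in [0, 0.5)")


@dataclass(frozen=True)
class SyntheticSpecimen:
    outline: Outline
    groove: GroovePoints
    record: SpecimenRecord
    ground_truth: dict


def default_templates() -> list[CrownTemplate]:
    """Five well-separated crown templates (A-E) spanning the size and shape
    contrasts of the hominoid study design: see the methods note for the
    rationale behind each value."""
    return [
        CrownTemplate(  # small, narrow, prominent hypoconulid
            name="A",
            md_length_mean=9.8, md_length_sd=0.45, bl_md_ratio=0.90,
            cusp_lobe_amplitudes=(0.16, 0.15, 0.13, 0.16, 0.17),
            sex_size_offset=0.15,
            noise_sd=0.012,
        ),
        CrownTemplate(  # small, broad, reduced/absent hypoconulid
            name="B",
            md_length_mean=10.8, md_length_sd=0.55, bl_md_ratio=1.02,
            cusp_lobe_amplitudes=(0.17, 0.16, 0.0, 0.17, 0.18),
            sex_size_offset=0.2,
            hypoconulid_present=False,
            noise_sd=0.012,
        ),
        CrownTemplate(  # medium, narrow, distally swung hypoconulid
            name="C",
            md_length_mean=11.6, md_length_sd=0.5, bl_md_ratio=0.92,
            cusp_lobe_amplitudes=(0.15, 0.16, 0.15, 0.17, 0.16),
            mesial_cusp_angle=np.deg2rad(97.0),
            sex_size_offset=0.2,
            noise_sd=0.012,
        ),
        CrownTemplate(  # large, narrow, strongly dimorphic
            name="D",
            md_length_mean=15.8, md_length_sd=0.8, bl_md_ratio=0.94,
            cusp_lobe_amplitudes=(0.16, 0.15, 0.14, 0.16, 0.17),
            distal_cusp_angle=np.deg2rad(84.0),
            sex_size_offset=1.0,
            noise_sd=0.012,
        ),
        CrownTemplate(  # largest, near-square, strongly dimorphic
            name="E",
            md_length_mean=17.6, md_length_sd=0.8, bl_md_ratio=0.98,
            cusp_lobe_amplitudes=(0.17, 0.16, 0.12, 0.15, 0.16),
            sex_size_offset=1.2,
            noise_sd=0.012,
        ),
    ]


# ---------------------------------------------------------------------------
# construction internals


def _adjusted_angles(template: CrownTemplate) -> np.ndarray:
    """Cusp azimuths after rotating the mesial and distal pairs so the chords
    between their lobe apices make the requested angles with the MD axis.

    For two points at equal radius the chord direction is perpendicular to
    the bisector of their azimuths, so a joint rotation of each pair sets the
    (pre-rescaling) cusp-line angle exactly.
    """
    ang = {c: a for c, a in zip(CUSP_ORDER, template.cusp_angular_positions)}
    # mesial pair: metaconid & protoconid, bisector near pi (mesial)
    target_bis = template.mesial_cusp_angle + np.pi / 2.0
    current_bis = (ang["metaconid"] + (ang["protoconid"] + 2 * np.pi)) / 2.0
    delta = np.mod(target_bis - current_bis + np.pi, 2 * np.pi) - np.pi
    ang["metaconid"] += delta
    ang["protoconid"] += delta
    # distal pair: entoconid & hypoconid, bisector near 0 (distal)
    target_bis = template.distal_cusp_angle - np.pi / 2.0
    current_bis = (ang["entoconid"] + ang["hypoconid"]) / 2.0
    delta = np.mod(target_bis - current_bis + np.pi, 2 * np.pi) - np.pi
    ang["entoconid"] += delta
    ang["hypoconid"] += delta
    return np.array([ang[c] for c in CUSP_ORDER])


def _smooth_radial_noise(rng, sd: float, n: int, sigma_vertices: float = 4.0) -> np.ndarray:
    """Stationary radial noise, correlated along the perimeter.

    White per-vertex noise would roughen the outline into something no
    digitized crown looks like (and destroy star-shapedness at realistic
    amplitudes); circularly smoothing with a Gaussian kernel and rescaling to
    the requested SD keeps perturbations wavelike, as digitization and
    orientation error actually are.
    """
    from scipy.ndimage import gaussian_filter1d

    white = rng.normal(0.0, 1.0, n)
    smooth = gaussian_filter1d(white, sigma_vertices, mode="wrap")
    # variance reduction of the kernel, restored deterministically
    kernel = gaussian_filter1d(np.eye(1, n, 0).ravel(), sigma_vertices, mode="wrap")
    return smooth * (sd / np.sqrt(np.sum(kernel**2)))


def _radial(theta: np.ndarray, angles: np.ndarray, amps: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    for a, th in zip(amps, angles):
        if a > 0:
            r += a * np.exp(_KAPPA * (np.cos(theta - th) - 1.0))
    return r


def _groove_indices(theta: np.ndarray, angles: np.ndarray, amps: np.ndarray) -> dict[str, int]:
    """Vertex index of the noiseless radial minimum between each adjacent cusp
    pair (CCW), keyed by groove label."""
    names = list(CUSP_ORDER)
    order = np.argsort(np.mod(angles, 2 * np.pi))
    r = _radial(theta, angles, amps)
    n = len(theta)
    out: dict[str, int] = {}
    for k in range(5):
        i_a, i_b = order[k], order[(k + 1) % 5]
        pair = (names[i_a], names[i_b])
        th_a = np.mod(angles[i_a], 2 * np.pi)
        th_b = np.mod(angles[i_b], 2 * np.pi)
        span = np.mod(th_b - th_a, 2 * np.pi)
        rel = np.mod(theta - th_a, 2 * np.pi)
        mask = (rel > 1e-9) & (rel < span - 1e-9)
        if not np.any(mask):
            raise GeometryError(f"no grid vertex between cusps {pair}")
        candidates = np.where(mask)[0]
        out[_GROOVE_OF_PAIR[pair]] = int(candidates[np.argmin(r[candidates])])
    return out


@lru_cache(maxsize=64)
def _template_ground_truth(template: CrownTemplate) -> dict[str, float]:
    """Analytic (grid-free) cusp-line angles implied by a template.

    Cusp-center proxies are midpoints of center->perimeter segments, so the
    line between two proxies is parallel to the line between the perimeter
    points; those are located on the continuous (noiseless) radial curve by
    bisecting the groove chords and intersecting center rays with a densely
    sampled curve.  Angles depend only on the template's shape parameters and
    its anisotropy — not on the drawn size — so the result is cached.
    """
    angles = _adjusted_angles(template)
    amps = np.asarray(template.cusp_lobe_amplitudes, dtype=float).copy()
    if not template.hypoconulid_present:
        amps[CUSP_ORDER.index("hypoconulid")] = 0.0
    theta = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
    r = _radial(theta, angles, amps)
    x, y = r * np.cos(theta), r * np.sin(theta)
    # anisotropy of the final crown: BL/MD ratio relative to the raw extents
    sx, sy = 1.0, template.bl_md_ratio * (x.max() - x.min()) / (y.max() - y.min())
    pts = np.column_stack([sx * x, sy * y])
    groove_idx = _groove_indices(theta, angles, amps)
    g = {lbl: pts[i] for lbl, i in groove_idx.items()}
    chords = {
        "metaconid": (g["g6"] + g["g7"]) / 2.0,
        "entoconid": (g["g7"] + g["g8"]) / 2.0,
        "hypoconid": (g["g9"] + g["g10"]) / 2.0,
        "protoconid": (g["g10"] + g["g6"]) / 2.0,
    }
    azimuth = np.arctan2(pts[:, 1], pts[:, 0])

    def on_curve(direction):
        phi = np.arctan2(direction[1], direction[0])
        i = int(np.argmin(np.abs(np.mod(azimuth - phi + np.pi, 2 * np.pi) - np.pi)))
        return pts[i]

    p16 = on_curve(chords["metaconid"])
    p20 = on_curve(chords["protoconid"])
    p17 = on_curve(chords["entoconid"])
    p19 = on_curve(chords["hypoconid"])
    mesial = np.mod(np.arctan2(*(p16 - p20)[::-1]), np.pi)
    distal = np.mod(np.arctan2(*(p17 - p19)[::-1]), np.pi)
    return {"mesial_cusp_angle": float(mesial), "distal_cusp_angle": float(distal)}


def generate_crown(
    template: CrownTemplate,
    rng_seed,
    *,
    sex: str = "F",
    specimen_id: str | None = None,
) -> SyntheticSpecimen:
    """Draw one crown from a template.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``; a
    fixed seed reproduces the specimen bitwise.  Males receive the template's
    MD size offset.  The generated outline is validated star-shaped from its
    bounding-box center.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    amps = np.asarray(template.cusp_lobe_amplitudes, dtype=float).copy()
    hypo_inferred = False
    if not template.hypoconulid_present:
        amps[CUSP_ORDER.index("hypoconulid")] = 0.0
        hypo_inferred = True

    angles = _adjusted_angles(template)
    theta = np.linspace(0, 2 * np.pi, N_VERTICES, endpoint=False)
    r = _radial(theta, angles, amps)
    groove_idx = _groove_indices(theta, angles, amps)
    if template.noise_sd > 0:
        r = r * (1.0 + _smooth_radial_noise(rng, template.noise_sd, N_VERTICES))

    md = template.md_length_mean + rng.normal(0.0, template.md_length_sd)
    if sex == "M":
        md += template.sex_size_offset
    if md <= 0:
        raise UsageError("drawn MD length is non-positive; shrink md_length_sd")
    bl = template.bl_md_ratio * md

    x = r * np.cos(theta)
    y = r * np.sin(theta)
    sx = md / (x.max() - x.min())
    sy = bl / (y.max() - y.min())
    pts = np.column_stack([sx * x, sy * y])
    pts -= (pts.min(axis=0) + pts.max(axis=0)) / 2.0  # box center at origin

    outline = Outline(pts)
    if not np.allclose(outline.vertices, pts):
        raise GeometryError("generated outline lost vertex order (self-intersection?)")
    if not outline.is_star_shaped_from(outline.box_center()):
        raise GeometryError(
            f"template {template.name!r}: generated outline is not star-shaped "
            "from the box center; reduce noise_sd or lobe amplitudes"
        )
    groove_pts = np.array(
        [pts[groove_idx[lbl]] for lbl in ("g6", "g7", "g8", "g9", "g10")]
    )
    groove = GroovePoints(groove_pts, outline)

    truth = dict(_template_ground_truth(template))
    truth.update(
        template=template,
        md_length=float(md),
        bl_breadth=float(bl),
        hypoconulid_inferred=hypo_inferred,
    )
    record = SpecimenRecord(
        specimen_id=specimen_id or f"{template.name}-{rng.integers(1 << 30)}",
        genus="Synthetica",
        species=template.name,
        sex=sex,
        side="left",
    )
    return SyntheticSpecimen(outline=outline, groove=groove, record=record, ground_truth=truth)


def make_dataset(
    templates=None,
    n_per_template: int = 20,
    sex_balance: bool = True,
    seed: int = 0,
):
    """Generate a full analysis-ready dataset.

    Returns ``(table, measurements, specimens)``: a :class:`LandmarkTable`
    with derived 29-landmark configurations, the per-specimen table of the
    nine diagnostic variables (indexed by specimen id, with a ``species``
    metadata column), and the raw synthetic specimens with ground truth.
    """
    if templates is None:
        templates = default_templates()
    if n_per_template < 2:
        raise UsageError("n_per_template must be at least 2")
    rng = np.random.default_rng(seed)
    specimens: list[SyntheticSpecimen] = []
    records: list[tuple[SpecimenRecord, LandmarkConfiguration]] = []
    for template in templates:
        for i in range(n_per_template):
            sex = ("F", "M")[i % 2] if sex_balance else "F"
            spec = generate_crown(
                template, rng, sex=sex, specimen_id=f"{template.name}{i:03d}"
            )
            config = derive_landmarks(
                spec.outline,
                spec.groove,
                hypoconulid_inferred=spec.ground_truth["hypoconulid_inferred"],
                specimen_id=spec.record.specimen_id,
            )
            specimens.append(spec)
            records.append((spec.record, config))
    table = LandmarkTable(records=records)
    meas = measurement_table(
        [c for _, c in records], ids=[r.specimen_id for r, _ in records]
    )
    meas.insert(0, "species", [r.species for r, _ in records])
    return table, meas, specimens


def apply_wear_and_damage(
    spec: SyntheticSpecimen,
    perimeter_jitter_sd: float = 0.0,
    interstitial_flattening: float = 0.0,
    seed: int = 0,
) -> SyntheticSpecimen:
    """Perturb a specimen the way worn/damaged real crowns deviate from ideal.

    Radial jitter (mm SD, from the box center) roughens the perimeter while
    groove vertices are left untouched; ``interstitial_flattening`` clips the
    mesial edge to a vertical chord ``flattening`` mm inside the mesial-most
    extent, emulating uncorrected interstitial wear.  Flattening that would
    swallow a groove point raises, mirroring the method's stated limit of
    landmarkability.
    """
    rng = np.random.default_rng(seed)
    pts = spec.outline.vertices.copy()
    groove_i = [spec.outline.nearest_vertex(p)[0] for p in spec.groove.points]
    if perimeter_jitter_sd > 0:
        center = spec.outline.box_center()
        rel = pts - center
        radii = np.linalg.norm(rel, axis=1)
        jitter = rng.normal(0.0, perimeter_jitter_sd, len(pts))
        jitter[groove_i] = 0.0
        pts = center + rel * ((radii + jitter) / radii)[:, None]
    if interstitial_flattening > 0:
        chord_x = pts[:, 0].min() + interstitial_flattening
        clipped = pts[:, 0] < chord_x
        if any(clipped[i] for i in groove_i):
            raise GeometryError(
                "interstitial flattening removes a groove point; specimen "
                "would be unlandmarkable"
            )
        pts[clipped, 0] = chord_x
    outline = Outline(pts)
    groove = GroovePoints(np.array([pts[i] for i in groove_i]), outline)
    truth = dict(spec.ground_truth)
    truth.update(
        perimeter_jitter_sd=perimeter_jitter_sd,
        interstitial_flattening=interstitial_flattening,
    )
    return replace(spec, outline=outline, groove=groove, ground_truth=truth)
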