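# Methods

## Coordinate convention

All geometry lives in mathematical y-up axes in millimetres: mesial = −x,
distal = +x, lingual = +y, buccal = −y. Inputs digitized in image pixel
coordinates (y growing downward) are flipped on ingest (`pixel_origin=True`).
Right-side teeth are mirrored about the vertical axis into left-side
configuration before any construction; groove labels are preserved under
mirroring. Outlines are stored counterclockwise. Note that the anatomical
groove tour g6 (mesial) → g7 (lingual) → g8 (distolingual) → g9
(distobuccal) → g10 (buccal) is therefore a *clockwise* tour of the
perimeter, and validation enforces exactly that cyclic order.

Inputs are assumed pre-oriented with the MD axis horizontal, as produced by a
standardized imaging protocol. The construction deliberately does **not**
commute with rotation (the bounding box is axis-aligned); the test suite
asserts this as documentation. No automatic principal-axis orientation is
applied, because it could not reproduce a manual anatomical orientation.

## Landmark construction

Landmark 1 is the bounding-box center, 2–5 the box-side midpoints (the spec
of "midway down the side" is read as the box-side midpoint, consistent with
published figures of the scheme). Landmarks 11–15 are groove-chord midpoints
in cusp order (metaconid, entoconid, hypoconulid, hypoconid, protoconid);
16–20 are ray–outline intersections from landmark 1 through 11–15; 21–25 are
the midpoints of segments 1→16 … 1→20; 26–29 extend the mesial (21–25) and
distal (22–24) cusp lines to the outline, labelled lingual/buccal by the
sign of the y-displacement.

Ray–outline intersection solves each polygon edge as an exact 2×2 linear
system and keeps the crossing with the smallest ray parameter t ≥ t(through).
Molar crowns are effectively star-shaped from the box center; if an outline
is not (multiple crossings beyond the through point), the nearest crossing is
used and a `StarShapeWarning` is emitted rather than rejecting a recoverable
specimen. Groove points must coincide with polygon vertices to 1e-9 mm;
upstream digitization should insert them as vertices.

Special cases: on four-cusped crowns the missing hypoconulid is inferred by
placing g8/g9 at ±half-width arc length around the single distal groove
(default half-width 2% of the perimeter — the literature does not quantify
the "small inter-cusp area", and 2% keeps the inferred cusp within the width
range of true reduced hypoconulids); on six-cusped crowns the tuberculum
sextum arc is bisected to site g8. Both set provenance flags on the
configuration.

## Measurements

The nine diagnostic variables are pure functions of the 29 landmarks (see
README). Angles are undirected, reported modulo π, so lingual and buccal
tilts of equal magnitude are equivalent and the values are stable under
mirroring. The default DFA variable set is exactly these nine; ln centroid
size can be appended via a switch but is off by default. An extended catalog
(all pairwise distances among the landmarks named by the nine variables,
plus the maximum BL diameter d(3,5) and centroid size) is provided and
clearly labelled a superset.

## Procrustes and PCA

GPA iterates: center, scale to unit centroid size, rotate each configuration
to the current mean with proper rotations (SVD with reflection guard),
re-estimate and renormalize the mean, until the mean moves less than 1e-10
RMS (cap 100 iterations; non-convergence is flagged, not raised). The
orientation of the final fit is inherited from the first configuration, so
GPA output is defined up to one common rotation; the invariance tests
register two fits by a single optimal rotation before comparing at 1e-9.

Shapespace PCA operates on the aligned coordinates after orthogonal
projection onto the tangent space at the mean (the component along the mean
direction is removed); a flag disables projection for sensitivity checks.
Formspace PCA appends ln centroid size as one extra mean-centered column to
the (projected) coordinates. Component signs follow two conventions: every
component is oriented so its largest-magnitude loading is positive, and
formspace PC1 is additionally oriented so scores correlate positively with
ln centroid size (largest specimens positive). Warps along a component are
linear reconstructions mean + score·eigenvector (ln-size coordinate dropped
for formspace) and are capped at 1.5× the observed score range; being
tangent-plane reconstructions they differ from spherical configurations by
O(score²) curvature.

GPA/PCA run on all 29 landmarks by default; a subset option supports the
14-landmark wireframe set (outer groove pentagon, inner cusp-center pentagon,
MD/BL diameters, two cusp lines) since published analyses are ambiguous
about which set entered the ordination software.

## Stepwise DFA

Wilks' Λ = det(W)/det(T) with within-group and total corrected SSCP
matrices. Entry and removal use the standard partial-F identities (see the
module docstring) with SPSS-default thresholds F-enter = 3.84,
F-remove = 2.71, exposed as options; candidates whose total SSCP goes
singular (collinear with the entered set) are skipped. Canonical functions
solve B v = λ W v with coefficients scaled to unit pooled within-group
variance. Classification maximizes ln(prior) − d²/2 in canonical space; ties
break toward the earlier group label and are logged. Priors default to equal
across groups regardless of group sizes (the convention of the classical
implementations), with proportional priors available. Leave-one-out
cross-validation refits coefficients per fold with the variable set fixed
from the full sample; `selection_inside_loop=True` re-runs selection per
fold for an honest generalization estimate, but is not the default because
reported accuracies in the comparison literature follow the fixed-set
convention.

## Synthetic crowns

Crowns are radial-bump curves r(θ) = 1 + Σᵢ aᵢ·exp(κ(cos(θ−θᵢ)−1)) with one
von-Mises-shaped lobe per cusp (κ = 12, lobe half-width ≈ 16°), sampled on
512 vertices, anisotropically rescaled so the bounding box is exactly the
drawn MD length × (BL/MD ratio · MD), and centered. Groove points are the
radial minima of the noiseless lobe function between adjacent cusps and stay
exact polygon vertices. Radial noise is stationary and correlated along the
perimeter (white noise smoothed with a circular Gaussian kernel, σ = 4
vertices, rescaled to the requested SD): white per-vertex noise would
destroy star-shapedness at realistic amplitudes and resembles no digitized
outline. Template cusp-line angle parameters jointly rotate the mesial
(metaconid/protoconid) and distal (entoconid/hypoconid) lobe pairs so the
chord between lobe apices meets the requested orientation before rescaling;
the stored ground-truth angles are computed analytically from the continuous
scaled curve and recovered by the landmark pipeline within 0.008 rad at zero
noise.

The five default templates (A–E) are caricatures of the contrasts a
multi-taxon hominoid molar study presents — small narrow crowns with
prominent hypoconulids (MD 9.8 mm), small broad crowns with absent
hypoconulids (10.8 mm), medium narrow crowns with swung cusp lines
(11.6 mm), and two large, strongly size-dimorphic crown types (15.8 and
17.6 mm, male offsets 1.0–1.2 mm). Within-template SDs (0.45–0.8 mm) and the
1.2% radial noise are of the order of published intra-taxon molar variation
and digitization error respectively. They are deliberately *not* named after
taxa: the generator emulates separation structure (size spacing ≫ within-SD,
distinct breadth ratios and hypoconulid prominence), not real species
distributions. Passing recovery tests therefore demonstrates the pipeline's
correctness and sensitivity, not field-data classification rates: real
samples have heavier shape-variance tails, asymmetries, wear damage and
digitization artifacts the generator only partly mimics
(`apply_wear_and_damage` adds perimeter jitter and mesial interstitial
flattening, but no enamel chipping or outline-correction bias).

## Numerical choices

- Groove/vertex coincidence and on-outline assertions: 1e-9 mm.
- Ray solver: exact per-edge parametric solution; crossings deduplicated at
  1e-12 relative parameter; independent cross-check against a computational-
  geometry kernel at 1e-6 mm on 1000 random star polygons.
- GPA convergence 1e-10 RMS; PCA eigenvalues below 1e-12 of the leading one
  are treated as null space.
- Wilks' Λ via log-determinants; Λ = 0 returned when W is singular (perfect
  separation).
- Degenerate inputs raise typed errors (`GeometryError`, `UsageError`,
  `CollinearityError`, `DimensionError`, `ParseError`) naming the offending
  specimen, variable or file location.

## Problem sizes

Tests and the acceptance script run 5 templates × 20 specimens (n = 100) for
end-to-end checks, 1000 random polygons for the geometric oracle, and
30-dataset Monte-Carlo batches for statistical inequalities; these sizes give
stable results while keeping the full suite under ten seconds.

## Known limitations

- The package consumes corrected outlines; interstitial-wear correction and
  image segmentation are upstream concerns.
- Reproduction of the published 110-specimen analyses requires the deposited
  coordinate table at `data/file_s1.csv`; without it the reproduction tests
  fail explicitly rather than pass vacuously.
- No thin-plate-spline deformation grids, EDMA, quadratic discriminants, or
  3D/EDJ analyses.
- GPA orientation is defined up to a common rotation (no canonical
  orientation rule is imposed).
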