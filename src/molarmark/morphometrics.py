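"""Generalized Procrustes superimposition and shapespace/formspace PCA.

GPA removes position, scale and rotation: every configuration is centered,
scaled to unit centroid size, and rotated (proper rotations only) to the
iteratively re-estimated mean shape.  Shapespace PCA then decomposes the
covariance of the aligned coordinates, after orthogonal projection onto the
tangent space at the mean; formspace PCA appends the natural logarithm of
centroid size as one extra mean-centered column, so the first component
captures predominantly size, with the smallest specimens at the negative end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .landmarks import LandmarkConfiguration

__all__ = [
    "ProcrustesFit",
    "PCAResult",
    "Wireframe",
    "gpa",
    "shapespace_pca",
    "formspace_pca",
    "warp_along_pc",
    "default_wireframe",
]


@dataclass(frozen=True)
class ProcrustesFit:
    aligned: np.ndarray        # (n, k, 2), centered, unit centroid size
    mean_shape: np.ndarray     # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,), mm
    iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]


@dataclass(frozen=True)
class PCAResult:
    mode: str                      # "shapespace" | "formspace"
    eigenvalues: np.ndarray        # descending
    percent_variance: np.ndarray
    scores: np.ndarray             # (n, m)
    loadings: np.ndarray           # (m, p) rows = components
    variable_labels: tuple[str, ...]
    center: np.ndarray             # column means of the analyzed matrix (p,)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class Wireframe:
    edges: tuple[tuple[int, int], ...]  # 1-based landmark index pairs


def _as_coords(configs) -> np.ndarray:
    """Stack configurations into (n, k, 2)."""
    arrs = [
        c.points if isinstance(c, LandmarkConfiguration) else np.asarray(c, dtype=float)
        for c in configs
    ]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise UsageError(f"configurations differ in landmark count: {sorted(shapes)}")
    return np.stack(arrs).astype(float)


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||x @ R - target||_F (no reflection)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesFit:
    """Iterative full-Procrustes superimposition.

    Each configuration is centered and scaled to unit centroid size, then
    rotated to the current mean; the mean is re-estimated and renormalized to
    unit centroid size until it moves less than ``tol`` (RMS) or ``max_iter``
    iterations are reached (the partial result is returned with
    ``converged=False``).
    """
    coords = _as_coords(configs)
    n = coords.shape[0]
    if n < 2:
        raise UsageError("GPA needs at least 2 configurations")

    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise UsageError("configuration with zero centroid size")
    aligned = centered / sizes[:, None, None]

    mean = aligned[0].copy()
    mean /= np.sqrt((mean**2).sum())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], mean)
        new_mean = aligned.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        shift = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if shift < tol:
            converged = True
            break
    return ProcrustesFit(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


def _coordinate_labels(k: int) -> list[str]:
    labels = []
    for i in range(1, k + 1):
        labels += [f"x{i}", f"y{i}"]
    return labels


def _tangent_project(flat: np.ndarray, mean_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned coordinates onto the tangent space at
    the mean shape (removes the component along the mean direction)."""
    m = mean_flat / np.linalg.norm(mean_flat)
    return flat - np.outer(flat @ m, m)


def _pca(matrix: np.ndarray, labels, mode: str) -> PCAResult:
    center = matrix.mean(axis=0)
    x = matrix - center
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    nonzero = eigenvalues > max(eigenvalues[0], 1.0) * 1e-12 if eigenvalues.size else []
    eigenvalues = eigenvalues[nonzero]
    loadings = vt[nonzero]
    scores = x @ loadings.T
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    # sign convention: orient each component so its largest loading is positive
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        mode=mode,
        eigenvalues=eigenvalues,
        percent_variance=percent,
        scores=scores,
        loadings=loadings,
        variable_labels=tuple(labels),
        center=center,
    )


def shapespace_pca(fit: ProcrustesFit, tangent: bool = True) -> PCAResult:
    """PCA of the Procrustes-aligned (shape-only) coordinates."""
    if fit.n_specimens < 2:
        raise UsageError("PCA needs at least 2 specimens")
    flat = fit.aligned.reshape(fit.n_specimens, -1)
    if tangent:
        flat = _tangent_project(flat, fit.mean_shape.ravel())
    return _pca(flat, _coordinate_labels(fit.n_landmarks), "shapespace")


def formspace_pca(fit: ProcrustesFit, tangent: bool = True) -> PCAResult:
    """PCA of [aligned coordinates | ln centroid size], each column centered.

    The first component's sign is fixed so that larger specimens score
    positive (scores correlate positively with ln centroid size).
    """
    if fit.n_specimens < 2:
        raise UsageError("PCA needs at least 2 specimens")
    if np.any(fit.centroid_sizes <= 0):
        raise UsageError("formspace PCA requires positive centroid sizes")
    flat = fit.aligned.reshape(fit.n_specimens, -1)
    if tangent:
        flat = _tangent_project(flat, fit.mean_shape.ravel())
    lncs = np.log(fit.centroid_sizes)[:, None]
    matrix = np.hstack([flat, lncs])
    labels = _coordinate_labels(fit.n_landmarks) + ["ln_centroid_size"]
    res = _pca(matrix, labels, "formspace")
    if res.n_components:
        spread = lncs.ravel() - lncs.mean()
        if np.dot(res.scores[:, 0], spread) < 0:
            res.loadings[0] *= -1.0
            res.scores[:, 0] *= -1.0
    return res


def warp_along_pc(
    pca: PCAResult, fit: ProcrustesFit, component: int, score: float
) -> np.ndarray:
    """Shape at ``score`` along one component: mean + score * eigenvector.

    For formspace results the trailing ln-centroid-size coordinate of the
    eigenvector is dropped, so the warp is rendered at mean size.  ``score``
    must stay within 1.5x the observed score range of that component.
    """
    if not 0 <= component < pca.n_components:
        raise UsageError(f"component {component} out of range 0..{pca.n_components - 1}")
    observed = np.abs(pca.scores[:, component]).max()
    if observed > 0 and abs(score) > 1.5 * observed:
        raise UsageError(
            f"|score| {abs(score):.3g} exceeds 1.5x the observed range {observed:.3g}"
        )
    k = fit.n_landmarks
    vec = pca.loadings[component][: 2 * k]
    return fit.mean_shape + score * vec.reshape(k, 2)


def default_wireframe() -> Wireframe:
    """The 14-edge wireframe: outer groove polygon, inner cusp-center polygon,
    MD and BL diameters, and the two cusp lines."""
    outer = [(6, 7), (7, 8), (8, 9), (9, 10), (10, 6)]
    inner = [(21, 22), (22, 23), (23, 24), (24, 25), (25, 21)]
    diameters = [(2, 4), (3, 5)]
    cusp_lines = [(26, 29), (27, 28)]
    return Wireframe(edges=tuple(outer + inner + diameters + cusp_lines))
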