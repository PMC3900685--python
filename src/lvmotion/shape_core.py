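"""Procrustes superimposition and Kendall shape-space utilities.

This module implements the static shape machinery underlying the motion
analysis: pre-shape normalization, reflection-free orthogonal Procrustes
rotation, generalized Procrustes analysis (GPA), geodesic and chordal shape
distances, tangent-space projection at the consensus, principal component
analysis of tangent coordinates, and the Euclidean-eligibility diagnostic
(the no-intercept regression of tangent/chordal distance on geodesic
distance whose slope must be close to 1 before the linear shift is a valid
approximation of parallel transport).

Shapes are ``k x m`` landmark matrices (``m`` = 2 or 3).  A *pre-shape* is a
configuration centered at the origin and scaled to unit centroid size
(Frobenius norm 1).  All alignment here excludes reflections, so the
geodesic distance ranges over ``[0, pi/2]`` and attains ``pi/2`` for a
planar configuration and its mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class DegenerateConfigurationError(ValueError):
    """Raised when a configuration has zero centroid size (all landmarks coincident)."""


class DegenerateRegressionError(ValueError):
    """Raised when every shape distance is zero and no regression is possible."""


class GPAConvergenceError(RuntimeError):
    """GPA failed to converge; carries the last consensus displacement."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"GPA consensus did not converge within {max_iter} iterations "
            f"(last consensus displacement {residual:.3e})"
        )


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

SURFACE_LABELS = ("endocardium", "epicardium", "none")


@dataclass
class LandmarkConfiguration:
    """One frame's landmark coordinate set with optional anatomical labels.

    Landmark order is the homology contract: it must be identical across all
    configurations entering one analysis.
    """

    coords: np.ndarray
    landmark_ids: list[str] | None = None
    surface_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be a k x 2 or k x 3 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.surface_labels is not None:
            self.surface_labels = np.asarray(self.surface_labels, dtype=object)
            if len(self.surface_labels) != len(self.coords):
                raise ValueError("one surface label per landmark required")
            bad = set(self.surface_labels) - set(SURFACE_LABELS)
            if bad:
                raise ValueError(f"unknown surface labels: {sorted(bad)}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]


@dataclass
class ShapeSequence:
    """A subject's ordered frames over one full cardiac cycle."""

    subject_id: str
    status: str  # "healthy" | "pathological"
    frames: list[LandmarkConfiguration]
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.status not in ("healthy", "pathological"):
            raise ValueError(f"unknown status {self.status!r}")
        if len(self.frames) != len(self.times_ms):
            raise ValueError("frames and times_ms must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a sequence needs at least two frames")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        ks = {f.k for f in self.frames}
        if len(ks) != 1:
            raise ValueError("all frames must share the same landmark count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def k(self) -> int:
        return self.frames[0].k


@dataclass
class ProcrustesEmbedding:
    """Jointly aligned coordinates after GPA.

    ``aligned`` holds one row per configuration, flattened landmark-major
    (``x1, y1, z1, ...``).  Rows are unit-centroid-size pre-shapes rotated
    to the converged consensus ``grand_mean`` (itself unit size).
    """

    aligned: np.ndarray  # n x (k*m)
    grand_mean: np.ndarray  # (k*m,)
    centroid_sizes: np.ndarray  # (n,)
    k: int
    ndim: int
    labels: np.ndarray | None = None
    n_iterations: int = 0

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def row_shape(self, i: int) -> np.ndarray:
        """Row ``i`` folded back to a ``k x m`` matrix."""
        return self.aligned[i].reshape(self.k, self.ndim)

    def shapes(self) -> np.ndarray:
        """All rows as an ``n x k x m`` array."""
        return self.aligned.reshape(self.n, self.k, self.ndim)

    @property
    def mean_shape(self) -> np.ndarray:
        return self.grand_mean.reshape(self.k, self.ndim)


@dataclass
class TangentPCA:
    """PCA of tangent coordinates: orthonormal loadings, eigenvalues, scores."""

    components: np.ndarray  # m_comp x p, orthonormal rows
    eigenvalues: np.ndarray  # m_comp
    scores: np.ndarray  # n x m_comp, zero column means
    variance_explained: np.ndarray  # m_comp, fractions of *total* variance
    center: np.ndarray  # p
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class EligibilityReport:
    """No-intercept regression of Euclidean/tangent distance on geodesic distance."""

    slope: float
    uncentered_correlation: float
    root_ms_error: float
    n_distances: int
    max_riemannian: float
    mode: str
    distance: str

    def within_band(self, band: tuple[float, float] = (0.98, 1.02)) -> bool:
        return band[0] <= self.slope <= band[1]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Map a configuration to its pre-shape.

    Removes location (centroid to the origin) and scale (Frobenius norm to
    1).  Returns the pre-shape and the original centroid size.

    Raises
    ------
    DegenerateConfigurationError
        If the centroid size is zero (all landmarks coincident).
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a k x m matrix with k >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    centered = x - x.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size <= 0.0 or not np.isfinite(size):
        raise DegenerateConfigurationError("zero centroid size")
    return centered / size, size


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` minimizing ``||a R - b||_F`` (reflections excluded).

    Both arguments must be ``k x m`` with identical shapes and landmark
    order.  Returns an ``m x m`` orthogonal matrix with determinant +1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(a.shape[1])
    flip[-1] = d if d != 0 else 1.0
    return (u * flip) @ vt


def _aligned_inner_product(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes inner product <aR, b> maximized over proper rotations R."""
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    u, _, vt = np.linalg.svd(a.T @ b)
    if np.linalg.det(u @ vt) < 0:
        return float(np.sum(s[:-1]) - s[-1])
    return float(np.sum(s))


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic (arc) Procrustes distance ``rho`` between pre-shapes, in [0, pi/2].

    ``rho = arccos`` of the Procrustes inner product after reflection-free
    optimal rotation.  Symmetric; zero iff the shapes coincide.
    """
    inner = np.clip(_aligned_inner_product(np.asarray(a, float), np.asarray(b, float)), -1.0, 1.0)
    return float(np.arccos(inner))


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Chordal (partial Procrustes) distance between optimally rotated pre-shapes.

    Equals ``||aR - b||_F = 2 sin(rho/2)`` for unit pre-shapes, hence is
    always <= the geodesic arc ``rho``.
    """
    inner = np.clip(_aligned_inner_product(np.asarray(a, float), np.asarray(b, float)), -1.0, 1.0)
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * inner)))


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _as_config_array(configs: Iterable) -> tuple[np.ndarray, int, int]:
    mats = []
    for c in configs:
        mats.append(c.coords if isinstance(c, LandmarkConfiguration) else np.asarray(c, float))
    arr = np.stack(mats)
    return arr, arr.shape[1], arr.shape[2]


def gpa(
    configs: Sequence,
    labels: Sequence | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesEmbedding:
    """Generalized Procrustes analysis of a set of configurations.

    Each configuration is reduced to its pre-shape (unit centroid size) and
    iteratively rotated to the evolving consensus until the consensus
    displacement falls below ``tol``.  Reflections are excluded.  The
    returned consensus is the renormalized mean of the aligned rows.

    Parameters
    ----------
    configs : sequence of ``k x m`` arrays or LandmarkConfiguration
    labels : optional per-configuration identifiers (e.g. subject ids)
    """
    arr, k, m = _as_config_array(configs)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA requires at least two configurations")

    pre = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        pre[i], sizes[i] = center_and_scale(arr[i])

    consensus = pre[0].copy()
    n_iter = 0
    residual = np.inf
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            pre[i] = pre[i] @ optimal_rotation(pre[i], consensus)
        new_consensus = pre.mean(axis=0)
        norm = np.linalg.norm(new_consensus)
        if norm <= 0:
            raise DegenerateConfigurationError("degenerate consensus")
        new_consensus /= norm
        residual = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if residual < tol:
            break
    else:
        raise GPAConvergenceError(residual, max_iter)

    lab = None if labels is None else np.asarray(labels)
    return ProcrustesEmbedding(
        aligned=pre.reshape(n, k * m),
        grand_mean=consensus.ravel(),
        centroid_sizes=sizes,
        k=k,
        ndim=m,
        labels=lab,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# tangent space and PCA
# ---------------------------------------------------------------------------

def tangent_project(emb: ProcrustesEmbedding) -> np.ndarray:
    """Orthogonal projection of aligned pre-shapes onto the tangent space at the consensus.

    The consensus maps to the origin; the projection removes the component
    along the consensus direction and is idempotent.
    """
    mu = emb.grand_mean
    x = emb.aligned
    return x - np.outer(x @ mu, mu)


def pca(tangent: np.ndarray, n_components: int | None = 10,
        variance_threshold: float | None = None) -> TangentPCA:
    """PCA of (tangent) coordinates via SVD of the column-centered matrix.

    Components are ordered by decreasing eigenvalue; each component's sign
    is fixed so its largest-magnitude loading is positive.  ``n_components``
    caps the retained axes (default 10); alternatively keep the smallest
    number of axes whose cumulative explained-variance fraction reaches
    ``variance_threshold``.
    """
    x = np.asarray(tangent, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least three observations")
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total_var = float(xc.var(axis=0, ddof=1).sum())
    keep = int(np.sum(eig > max(eig[0], 1.0) * 1e-14)) if eig.size else 0
    if variance_threshold is not None:
        frac = np.cumsum(eig[:keep]) / total_var
        keep = min(keep, int(np.searchsorted(frac, variance_threshold) + 1))
    elif n_components is not None:
        keep = min(keep, n_components)
    comp = vt[:keep]
    scores = u[:, :keep] * s[:keep]
    # deterministic sign: largest-magnitude loading positive
    for j in range(keep):
        idx = np.argmax(np.abs(comp[j]))
        if comp[j, idx] < 0:
            comp[j] = -comp[j]
            scores[:, j] = -scores[:, j]
    return TangentPCA(
        components=comp,
        eigenvalues=eig[:keep],
        scores=scores,
        variance_explained=eig[:keep] / total_var if total_var > 0 else eig[:keep] * 0.0,
        center=center,
        total_variance=total_var,
    )


def reconstruct_along_pc(tpca: TangentPCA, component: int, score: float,
                         k: int, ndim: int) -> np.ndarray:
    """Shape at ``center + score * loading`` of one component, folded to ``k x m``.

    Used to visualize the deformation each axis encodes (contraction on PC1,
    shearing on PC2, rotation/torsion on PC3 for LV data).
    """
    if not 0 <= component < tpca.n_components:
        raise IndexError(f"component {component} out of range (m={tpca.n_components})")
    flat = tpca.center + score * tpca.components[component]
    return flat.reshape(k, ndim)


# ---------------------------------------------------------------------------
# Euclidean-eligibility diagnostic
# ---------------------------------------------------------------------------

def _pairwise_inner_products(shapes: np.ndarray) -> np.ndarray:
    """Reflection-corrected Procrustes inner products for all shape pairs."""
    n = shapes.shape[0]
    cross = np.einsum("ikm,jkn->ijmn", shapes, shapes)
    s = np.linalg.svd(cross, compute_uv=False)
    dets = np.linalg.det(cross)
    inner = s.sum(axis=-1)
    neg = dets < 0
    inner[neg] -= 2.0 * s[neg][:, -1]
    return inner


def eligibility_diagnostic(
    emb: ProcrustesEmbedding,
    mode: str = "pairwise",
    distance: str = "chordal",
) -> EligibilityReport:
    """Test whether the shape cloud is flat enough for tangent-space (linear-shift) work.

    Computes geodesic distances and Euclidean distances (``chordal`` between
    optimally rotated pre-shapes, or ``tangent`` between projected tangent
    vectors), either for all reciprocal pairs or from each shape to the
    consensus, and fits a regression through the origin of the Euclidean
    distance on the geodesic one.  A slope near 1 licenses the linear
    shift.

    Returns slope, uncentered correlation, and root mean-squared error.
    """
    if mode not in ("pairwise", "from_consensus"):
        raise ValueError(f"unknown mode {mode!r}")
    if distance not in ("chordal", "tangent"):
        raise ValueError(f"unknown distance {distance!r}")

    shapes = emb.shapes()
    if mode == "pairwise":
        inner = _pairwise_inner_products(shapes)
        iu = np.triu_indices(emb.n, k=1)
        rho = np.arccos(np.clip(inner[iu], -1.0, 1.0))
        if distance == "chordal":
            y = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * np.clip(inner[iu], -1.0, 1.0)))
        else:
            t = tangent_project(emb)
            diff = t[:, None, :] - t[None, :, :]
            y = np.linalg.norm(diff, axis=-1)[iu]
    else:
        mu = emb.mean_shape
        inner = np.array([_aligned_inner_product(s, mu) for s in shapes])
        rho = np.arccos(np.clip(inner, -1.0, 1.0))
        if distance == "chordal":
            y = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * np.clip(inner, -1.0, 1.0)))
        else:
            y = np.linalg.norm(tangent_project(emb), axis=1)

    sxx = float(np.sum(rho * rho))
    if sxx <= 0 or np.max(rho) <= 1e-7:  # below arccos round-off resolution
        raise DegenerateRegressionError("all shape distances are zero")
    sxy = float(np.sum(rho * y))
    syy = float(np.sum(y * y))
    slope = sxy / sxx
    corr = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    resid = y - slope * rho
    rmse = float(np.sqrt(np.mean(resid**2)))
    return EligibilityReport(
        slope=slope,
        uncentered_correlation=corr,
        root_ms_error=rmse,
        n_distances=len(rho),
        max_riemannian=float(np.max(rho)),
        mode=mode,
        distance=distance,
    )
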