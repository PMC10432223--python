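"""The shrink-wrap objective: precision-weighted point fidelity plus a
blended discrete bending penalty.

The surface is fit by minimizing, over vertex positions ``v``,

    E(v) = sum_i sum_c r_ic^2  +  lambda^2 sum_k ||B_k(v) / sigma_ref||^2

where the fidelity residual per localization ``i`` and axis ``c`` is

    r_ic = d_ic / [ sigma_ic (d_ic^2 / (2 sigma_ic^2) + 1) ],
    d_ic = p_ic - A(v)_ic,

``A(v)_i`` the proxy point on the nearest face (inverse-distance-weighted
combination of its three vertices), and ``B_k`` the per-vertex curvature
penalty blending the area-shrinking centroid term B1 with the
area-preserving sphere-fit term B2:

    B_k = (1 - alpha_k) B1_k + alpha_k B2_k
        = (v_k - c_k) - alpha_k n_k (1/N) sum_l (v_k - v_l).n_k * 2/(n_k.n_l + 1)

(on an exact sphere the bracketed sphere-fit correction cancels v_k - c_k
to fourth order in the ring opening angle, so B2 exerts no shrinking force)

with ``alpha_k = min((sum_i w_ik)^2, 1)`` measuring how strongly the data
constrain vertex k. Near the data the sphere-fit term keeps the wrap from
shrinking through the membrane; far from data the centroid term contracts
the surface onto the structure.

The residual r(d) grows like d/sigma near the surface, peaks at
d = sqrt(2) sigma and decays like 2 sigma / d beyond — distant
localizations (background) keep only a weak pull on the surface.

Correspondences, weights, the distance deweighting fraction, alpha and
normals are *frozen* while the inner conjugate-gradient solve runs and
refreshed each outer iteration, which makes the inner objective a smooth
weighted least-squares problem whose analytic gradient is exact — and
keeps the fidelity force attractive at all distances. (Differentiating
the full robust residual instead would repel the surface from
localizations beyond sqrt(2) sigma, where r(d) starts decaying; freezing
the deweighting per outer iteration is the iteratively-reweighted
reading of the same objective.)

Both terms are dimensionless: fidelity residuals are distances over
sigma, and the bending vector B (nm) is divided by sigma_ref, the
cloud's median per-axis precision. This keeps lambda a pure number whose
useful range does not drift with the localization precision, and keeps
the two terms' curvatures (Hessians) within a modest factor of each
other so the inner conjugate-gradient solve is well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import FaceLocator
from .cloud import LocalizationCloud
from .mesh import TriangleMesh, VertexRing

#: floor applied to (n_k . n_l + 1) in the sphere-fit term; prevents
#: blow-up where normals approach antipodal (folds are handled by remeshing)
B2_DENOM_FLOOR = 0.1

#: guard for inverse-distance weights when a localization coincides with a vertex
COINCIDENT_EPS = 1e-9


@dataclass(frozen=True)
class FidelityAssignment:
    """Frozen localization-to-mesh correspondence state.

    Attributes
    ----------
    face_index : (N,) int
        Nearest face per localization.
    face_vertices : (N, 3) int
        Vertex indices of that face.
    weights : (N, 3)
        Inverse-distance weights w_ij, normalized to sum to 1 per row.
    influence : (M,)
        Per-vertex accumulated weight s_j = sum_i w_ij.
    alpha : (M,)
        Data-influence blend alpha_j = min(s_j^2, 1) in [0, 1].
    deweight : (N, 3)
        Frozen per-axis deweighting fraction u_ic = 1/(d_ic^2/(2 sigma^2) + 1)
        evaluated at assignment time; the inner solve minimizes
        sum (u d / sigma)^2 with u fixed.
    normals : (M, 3)
        Vertex normals snapshot taken at assignment time.
    ring_center, ring_neighbor : flat int arrays
        One-ring adjacency (each undirected edge in both directions).
    valence : (M,) int
    """

    face_index: np.ndarray
    face_vertices: np.ndarray
    weights: np.ndarray
    influence: np.ndarray
    alpha: np.ndarray
    deweight: np.ndarray
    normals: np.ndarray
    ring_center: np.ndarray
    ring_neighbor: np.ndarray
    valence: np.ndarray

    def proxy_points(self, vertices: np.ndarray) -> np.ndarray:
        """A(v)_i = sum_j w_ij v_j for the current vertex positions."""
        return np.einsum("ij,ijc->ic", self.weights, vertices[self.face_vertices])


def inverse_distance_weights(point: np.ndarray, triangle: np.ndarray) -> np.ndarray:
    """Normalized inverse-distance weights of a localization to the three
    vertices of its nearest face: w_j = (1/|p - v_j|) / sum_j (1/|p - v_j|).

    A localization coinciding with a vertex receives weight ~1 on that
    vertex through the epsilon guard.
    """
    d = np.maximum(np.linalg.norm(np.asarray(point, float)
                                  - np.asarray(triangle, float), axis=-1),
                   COINCIDENT_EPS)
    inv = 1.0 / d
    return inv / inv.sum(axis=-1, keepdims=True)


def _unique_rings(mesh: TriangleMesh):
    e = mesh.edges_unique
    center = np.concatenate([e[:, 0], e[:, 1]])
    nbr = np.concatenate([e[:, 1], e[:, 0]])
    order = np.argsort(center, kind="stable")
    center, nbr = center[order], nbr[order]
    valence = np.bincount(center, minlength=mesh.n_vertices)
    return center, nbr, valence


def assign_correspondences(mesh: TriangleMesh, cloud: LocalizationCloud,
                           k_candidates: int = 12,
                           deweight_floor: float = 0.0) -> FidelityAssignment:
    """Find each localization's nearest face and its proxy-point weights.

    Nearest faces come from exact point-to-triangle distances over KD-tree
    candidates; weights are normalized inverse distances to the face's
    three vertices (a coincident vertex receives weight ~1 via an epsilon
    guard).

    ``deweight_floor`` clamps the frozen robust deweighting from below;
    the optimizer uses a positive floor during its first (approach)
    iterations so the coarse start is pulled onto the data even from many
    sigma away, then drops it to zero for the robust refinement.
    """
    locator = FaceLocator(mesh, k_candidates=k_candidates)
    face_idx, _, _ = locator.query(cloud.positions)
    fv = mesh.faces[face_idx]  # (N, 3)

    w = inverse_distance_weights(cloud.positions[:, None, :],
                                 mesh.vertices[fv])

    influence = np.zeros(mesh.n_vertices)
    np.add.at(influence, fv.ravel(), w.ravel())
    alpha = np.minimum(influence ** 2, 1.0)

    # freeze the robust deweighting at the current surface position
    d0 = cloud.positions - np.einsum("ij,ijc->ic", w, mesh.vertices[fv])
    u = 1.0 / (d0 * d0 / (2.0 * cloud.sigmas ** 2) + 1.0)
    if deweight_floor > 0:
        u = np.maximum(u, deweight_floor)

    center, nbr, valence = _unique_rings(mesh)
    return FidelityAssignment(
        face_index=face_idx,
        face_vertices=fv,
        weights=w,
        influence=influence,
        alpha=alpha,
        deweight=u,
        normals=mesh.vertex_normals.copy(),
        ring_center=center,
        ring_neighbor=nbr,
        valence=valence,
    )


# ----------------------------------------------------------------------
# fidelity term

def residual_and_slope(d: np.ndarray, sigma: np.ndarray):
    """Weighted residual r(d) and its derivative dr/dd (per axis).

    r = d / [sigma (t + 1)], t = d^2/(2 sigma^2); r peaks at d = sqrt(2) sigma
    (value sqrt(1/2)) and decays as 2 sigma / d for large d.
    """
    t = d * d / (2.0 * sigma * sigma)
    denom = sigma * (t + 1.0)
    r = d / denom
    drdd = (1.0 - t) / (sigma * (t + 1.0) ** 2)
    return r, drdd


def fidelity_residuals(assign: FidelityAssignment, cloud: LocalizationCloud,
                       vertices: np.ndarray | None = None) -> np.ndarray:
    """Per-localization, per-axis weighted residuals r_ic (dimensionless)."""
    if vertices is None:
        raise ValueError("vertices required (pass mesh.vertices)")
    d = cloud.positions - assign.proxy_points(vertices)
    r, _ = residual_and_slope(d, cloud.sigmas)
    return r


def _fidelity_cost_grad(assign, cloud, vertices):
    """Inner (frozen-deweight) fidelity cost sum (u d / sigma)^2 and its
    exact gradient; u = assign.deweight."""
    d = cloud.positions - assign.proxy_points(vertices)  # (N, 3)
    usig = assign.deweight / cloud.sigmas
    r = usig * d
    cost = float(np.einsum("ic,ic->", r, r))
    # dE/dv_jc = sum_i 2 r usig * dd/dv_jc, with dd/dv_jc = -w_ij
    per_loc = 2.0 * r * usig  # (N, 3)
    grad = np.zeros_like(vertices)
    contrib = -per_loc[:, None, :] * assign.weights[:, :, None]  # (N, 3verts, 3axes)
    np.add.at(grad, assign.face_vertices.ravel(),
              contrib.reshape(-1, 3))
    return cost, grad


# ----------------------------------------------------------------------
# curvature term — single-ring reference forms (used by tests and docs)

def curvature_b1(ring: VertexRing) -> np.ndarray:
    """Centroid (area-shrinking) penalty: v_k - c_k."""
    if ring.valence < 3:
        raise ValueError("ring valence must be >= 3")
    return ring.position - ring.centroid


def curvature_b2(ring: VertexRing) -> np.ndarray:
    """Sphere-fit (area-preserving) penalty.

    B2 = v_k - c_k - n_k (1/N) sum_l (v_k - v_l).n_k * 2/(n_k.n_l + 1)

    The correction term is the normal offset of the sphere fit through the
    one-ring: for a vertex lying exactly on the neighbors' sphere it cancels
    v_k - c_k (to fourth order in the ring opening angle), so the term does
    not contract a sphere, unlike B1.
    """
    if ring.valence < 3:
        raise ValueError("ring valence must be >= 3")
    nk = ring.normal
    rel = ring.position - ring.neighbor_positions
    g = 2.0 / np.maximum(ring.neighbor_normals @ nk + 1.0, B2_DENOM_FLOOR)
    s = float(np.mean((rel @ nk) * g))
    return ring.position - ring.centroid - s * nk


def blend_curvature(b1: np.ndarray, b2: np.ndarray, alpha: float) -> np.ndarray:
    """B = (1 - alpha) B1 + alpha B2, alpha in [0, 1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return (1.0 - alpha) * np.asarray(b1) + alpha * np.asarray(b2)


def _curvature_cost_grad(assign, vertices, lam, sigma_ref=1.0, alpha=None):
    """Blended curvature cost (lambda/sigma_ref)^2 sum ||B_k||^2 and
    gradient, with the normals and alpha frozen in ``assign``."""
    M = len(vertices)
    center = assign.ring_center
    nbr = assign.ring_neighbor
    N = assign.valence.astype(float)
    n = assign.normals
    if alpha is None:
        alpha = assign.alpha

    # neighbor centroids
    c = np.zeros_like(vertices)
    np.add.at(c, center, vertices[nbr])
    c /= np.maximum(N, 1.0)[:, None]

    nk_e = n[center]
    g_e = 2.0 / np.maximum(np.einsum("ej,ej->e", nk_e, n[nbr]) + 1.0,
                           B2_DENOM_FLOOR)
    proj_e = np.einsum("ej,ej->e", vertices[center] - vertices[nbr], nk_e)

    S = np.zeros(M)
    np.add.at(S, center, g_e * proj_e)
    S /= np.maximum(N, 1.0)
    gbar = np.zeros(M)
    np.add.at(gbar, center, g_e)
    gbar /= np.maximum(N, 1.0)

    B = (vertices - c) - (alpha * S)[:, None] * n
    lam2 = (lam / sigma_ref) ** 2
    cost = lam2 * float(np.einsum("kj,kj->", B, B))

    nB = np.einsum("kj,kj->k", n, B)
    # dB_k/dv_k = I - alpha_k gbar_k n_k n_k^T
    grad = 2.0 * lam2 * (B - (alpha * gbar * nB)[:, None] * n)
    # dB_k/dv_l = -I/N + alpha_k (g_kl / N) n_k n_k^T
    inv_n = 1.0 / np.maximum(N, 1.0)
    upd = 2.0 * lam2 * (
        -(inv_n[center])[:, None] * B[center]
        + ((alpha * inv_n * nB)[center] * g_e)[:, None] * nk_e
    )
    np.add.at(grad, nbr, upd)
    return cost, grad


def total_energy(mesh: TriangleMesh, cloud: LocalizationCloud,
                 assign: FidelityAssignment, lam: float,
                 vertices: np.ndarray | None = None):
    """Objective value and analytic per-vertex gradient.

    Correspondences, weights, alpha and normals are those frozen in
    ``assign``; only vertex positions vary. The gradient is exact for this
    frozen inner problem (verified against central differences in tests).
    """
    v = mesh.vertices if vertices is None else np.asarray(vertices, float)
    cf, gf = _fidelity_cost_grad(assign, cloud, v)
    sigma_ref = float(np.median(cloud.sigmas))
    cc, gc = _curvature_cost_grad(assign, v, lam, sigma_ref=sigma_ref)
    return cf + cc, gf + gc
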