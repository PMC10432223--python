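"""Surface-quality metrics: Q1/Q2/Q, curvature recovery, mesh-to-mesh distance.

Reconstruction error is scored between two point sets: a noise-free
verification sample of the true surface and an area-uniform sample of the
fitted mesh.

    Q1 = mean over verification points of squared distance to the nearest
         mesh sample   (misses of the truth are penalized; blebs are not)
    Q2 = mean over mesh samples of squared distance to the nearest
         verification point   (blebs/extrusions are penalized)
    Q  = sqrt((Q1 + Q2) / 2)   root-mean-square combined surface error, nm

The two directions are deliberately asymmetric: a reconstruction hugging
part of the truth but sprouting a bleb scores well on Q1 and badly on Q2,
and vice versa for a truncated reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import FaceLocator
from .mesh import TriangleMesh
from .simulate import SDFShape


@dataclass(frozen=True)
class QualityReport:
    """Q1, Q2 in nm^2; Q in nm; sample counts used."""

    q1: float
    q2: float
    q: float
    n_verification: int
    n_mesh_samples: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)


def sample_mesh_surface(mesh: TriangleMesh, n: int, seed: int = 0) -> np.ndarray:
    """Area-uniform random sample of the mesh surface (nm)."""
    rng = np.random.default_rng(seed)
    areas = mesh.face_areas
    probs = areas / areas.sum()
    fidx = rng.choice(len(areas), size=n, p=probs)
    t = mesh.triangles[fidx]
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1
    u[flip] = 1 - u[flip]
    v[flip] = 1 - v[flip]
    return t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])


def point_set_error(verification: np.ndarray, mesh_samples: np.ndarray) -> QualityReport:
    """Q1/Q2/Q between the two point sets (exact nearest neighbors)."""
    tree_m = cKDTree(mesh_samples)
    tree_v = cKDTree(verification)
    d1, _ = tree_m.query(verification, workers=-1)
    d2, _ = tree_v.query(mesh_samples, workers=-1)
    q1 = float(np.mean(d1 ** 2))
    q2 = float(np.mean(d2 ** 2))
    return QualityReport(
        q1=q1, q2=q2, q=float(np.sqrt((q1 + q2) / 2.0)),
        n_verification=len(verification), n_mesh_samples=len(mesh_samples),
    )


def surface_error(mesh: TriangleMesh, verification: np.ndarray,
                  mesh_sample_density: float | None = None,
                  seed: int = 0) -> QualityReport:
    """Score a fitted mesh against noise-free verification points.

    The mesh point set is an area-uniform sample at ``mesh_sample_density``
    (nm^-2); by default the verification sampling density is matched so
    both directions see comparable nearest-neighbor spacing.
    """
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    verification = np.asarray(verification, float)
    if len(verification) == 0:
        raise ValueError("empty verification set")
    if mesh_sample_density is None:
        # match the verification set's areal density on the fitted mesh
        mesh_sample_density = len(verification) / max(mesh.area, 1e-9)
    n_mesh = max(int(round(mesh_sample_density * mesh.area)), 10)
    samples = sample_mesh_surface(mesh, n_mesh, seed=seed)
    return point_set_error(verification, samples)


def smooth_vertex_field(mesh: TriangleMesh, values: np.ndarray,
                        rounds: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Iterated one-ring averaging of a per-vertex scalar field.

    Discrete curvature at a single vertex is noisy (its standard error is
    comparable to the signal for radii much larger than the edge length);
    since membrane curvature varies on scales much longer than an edge,
    averaging over a geodesic neighborhood (~sqrt(rounds) edges wide) is
    the appropriate estimator. With ``mask``, only edges between masked
    vertices participate, so high-curvature features outside the region of
    interest (e.g. cap rims) cannot bleed in.
    """
    f = np.asarray(values, float).copy()
    e = mesh.edges_unique
    if mask is not None:
        e = e[mask[e[:, 0]] & mask[e[:, 1]]]
    for _ in range(rounds):
        acc = np.zeros_like(f)
        cnt = np.zeros(len(f))
        for i, j in ((0, 1), (1, 0)):
            np.add.at(acc, e[:, i], f[e[:, j]])
            np.add.at(cnt, e[:, i], 1)
        out = (f + acc) / (1 + cnt)
        f = out if mask is None else np.where(mask, out, f)
    return f


def curvature_recovery(mesh: TriangleMesh, shape: SDFShape,
                       radius_bins: np.ndarray | None = None,
                       smooth_rounds: int = 20,
                       vertex_mask: np.ndarray | None = None):
    """Compare discrete mean curvature on the mesh with the analytic value
    at the nearest true-surface point.

    Vertices are projected onto the shape along the SDF gradient; each is
    paired with the analytic mean curvature there and binned by the true
    curvature radius. Returns a dict with per-vertex arrays and per-bin
    medians of the relative error (est - true)/true.

    ``smooth_rounds`` controls ring-averaging of the discrete H field
    before comparison (see :func:`smooth_vertex_field`); ``vertex_mask``
    restricts both the smoothing support and the bin statistics, e.g. to
    the lateral surface of a capped shape.
    """
    if shape.mean_curvature is None:
        raise ValueError(f"shape {shape.name!r} has no analytic curvature")
    proj = shape.project(mesh.vertices, iterations=10)
    resid = np.abs(shape.sdf(proj))
    ok = resid < 1.0  # projection converged to within 1 nm
    if vertex_mask is not None:
        ok &= vertex_mask
    h_true = shape.mean_curvature(proj)
    h_est = mesh.mean_curvature
    if smooth_rounds > 0:
        h_est = smooth_vertex_field(mesh, h_est, smooth_rounds,
                                    mask=ok if vertex_mask is not None else None)
    r_true = (shape.curvature_radius(proj)
              if shape.curvature_radius is not None
              else 1.0 / np.maximum(np.abs(h_true), 1e-12))

    rel = (h_est - h_true) / np.where(np.abs(h_true) > 1e-12, h_true, np.nan)
    result = {
        "projected": proj,
        "converged": ok,
        "h_true": h_true,
        "h_est": h_est,
        "radius_true": r_true,
        "relative_error": rel,
        "n_excluded": int((~ok).sum()),
    }
    if radius_bins is not None:
        idx = np.digitize(r_true, radius_bins)
        med, bias, counts = [], [], []
        for b in range(1, len(radius_bins)):
            m = ok & (idx == b) & np.isfinite(rel)
            if m.sum() >= 10:
                med.append(float(np.median(np.abs(rel[m]))))
                bias.append(float(np.median(rel[m])))
            else:
                med.append(np.nan)
                bias.append(np.nan)
            counts.append(int(m.sum()))
        result["bin_median_abs_rel_error"] = np.asarray(med)
        result["bin_median_signed_rel_error"] = np.asarray(bias)
        result["bin_counts"] = np.asarray(counts)
    return result


def mesh_to_mesh_distance(a: TriangleMesh, b: TriangleMesh,
                          k_candidates: int = 12) -> np.ndarray:
    """Exact point-to-triangle distance from every vertex of ``a`` to
    surface ``b`` (nm). Directional: distance(a, b) != distance(b, a) in
    general. Attach as a PLY scalar to visualize membrane separations."""
    locator = FaceLocator(b, k_candidates=k_candidates)
    _, _, dist = locator.query(a.vertices)
    return dist
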