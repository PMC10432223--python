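"""Vectorized point/triangle geometry used by correspondence and distance queries."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each point (pairwise by row).

    Parameters
    ----------
    points : (n, 3)
    triangles : (n, 3, 3)

    Returns
    -------
    (n, 3) closest points.

    Standard region-classification algorithm (Ericson), fully vectorized.
    """
    p = np.asarray(points, float)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    out = np.empty_like(p)
    done = np.zeros(len(p), bool)

    # vertex region A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    t = np.divide(d1, denom, out=np.zeros_like(d1), where=denom != 0)
    out[m] = a[m] + ab[m] * t[m, None]
    done |= m

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    t = np.divide(d2, denom, out=np.zeros_like(d2), where=denom != 0)
    out[m] = a[m] + ac[m] * t[m, None]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.divide(d4 - d3, denom, out=np.zeros_like(d4), where=denom != 0)
    out[m] = b[m] + (c[m] - b[m]) * t[m, None]
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + ab[m] * v[m, None] + ac[m] * w[m, None]
    return out


class FaceLocator:
    """Approximate-nearest-face query: KD-tree on face centroids proposes
    candidate faces, exact point-to-triangle distance picks the winner.

    With enough candidates this is exact for all practical purposes on
    well-shaped (near-isotropic) meshes.
    """

    def __init__(self, mesh, k_candidates: int = 12):
        self.mesh = mesh
        self.triangles = mesh.triangles
        self.centroids = self.triangles.mean(axis=1)
        self.k = int(min(k_candidates, len(self.centroids)))
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray):
        """Return (face_index, closest_point, distance) per query point."""
        points = np.asarray(points, float)
        _, cand = self.tree.query(points, k=self.k, workers=-1)
        if self.k == 1:
            cand = cand[:, None]
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tris = self.triangles[cand.ravel()]
        cp = closest_point_on_triangles(flat_pts, flat_tris)
        d2 = np.einsum("ij,ij->i", flat_pts - cp, flat_pts - cp).reshape(n, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        face_idx = cand[rows, best]
        closest = cp.reshape(n, k, 3)[rows, best]
        dist = np.sqrt(d2[rows, best])
        return face_idx, closest, dist
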