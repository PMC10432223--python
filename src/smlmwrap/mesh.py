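"""Triangle mesh core: connectivity, normals, discrete curvature, validity.

The reconstruction operates on closed, oriented, manifold triangle meshes.
Connectivity-derived quantities (one-rings, normals, curvatures, areas) are
cached on first access; meshes are treated as immutable — operations that
change geometry or topology return a new :class:`TriangleMesh`.

Units: vertex coordinates in nanometers, mean curvature in 1/nm, Gaussian
curvature in 1/nm^2.

Sign convention: mean curvature is positive where the surface bends away
from the outward normal, so a sphere with outward orientation has H > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc


class MeshError(ValueError):
    """Raised for operations on structurally invalid meshes."""


@dataclass(frozen=True)
class VertexRing:
    """One-ring neighborhood of a vertex.

    Attributes
    ----------
    center : int
        Index of the central vertex k.
    neighbors : ndarray of int
        Indices of the one-ring vertices (unordered).
    position : ndarray, shape (3,)
        Position of the central vertex, nm.
    neighbor_positions : ndarray, shape (N, 3)
    centroid : ndarray, shape (3,)
        Mean of the neighbor positions, nm.
    normal : ndarray, shape (3,)
        Unit vertex normal at the center.
    neighbor_normals : ndarray, shape (N, 3)
    """

    center: int
    neighbors: np.ndarray
    position: np.ndarray
    neighbor_positions: np.ndarray
    centroid: np.ndarray
    normal: np.ndarray
    neighbor_normals: np.ndarray

    @property
    def valence(self) -> int:
        return len(self.neighbors)


class TriangleMesh:
    """Indexed triangle mesh with halfedge-style queries.

    Parameters
    ----------
    vertices : (M, 3) float array, nm
    faces : (F, 3) int array
        Counter-clockwise as seen from outside for an outward orientation.
    """

    def __init__(self, vertices, faces):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (M, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")

    # ------------------------------------------------------------------
    # basic counts
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices) -> "TriangleMesh":
        """Same connectivity, new vertex positions."""
        v = np.asarray(vertices, dtype=np.float64)
        if v.shape != self.vertices.shape:
            raise MeshError("vertex array shape mismatch")
        return TriangleMesh(v, self.faces)

    def flipped(self) -> "TriangleMesh":
        """Reverse global orientation."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1])

    # ------------------------------------------------------------------
    # edges
    @cached_property
    def halfedges(self) -> np.ndarray:
        """(3F, 2) directed edges; rows 3f, 3f+1, 3f+2 belong to face f."""
        f = self.faces
        return np.stack(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=1
        ).reshape(-1, 2)

    @cached_property
    def edges_unique(self) -> np.ndarray:
        """(E, 2) undirected edges, each sorted low-high, unique."""
        he = np.sort(self.halfedges, axis=1)
        return np.unique(he, axis=0)

    @cached_property
    def n_edges(self) -> int:
        return len(self.edges_unique)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique
        return np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
        )

    # ------------------------------------------------------------------
    # per-face geometry
    @cached_property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @cached_property
    def _face_cross(self) -> np.ndarray:
        t = self.triangles
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @cached_property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self._face_cross, axis=1)

    @cached_property
    def face_normals(self) -> np.ndarray:
        c = self._face_cross
        n = np.linalg.norm(c, axis=1, keepdims=True)
        # zero-area faces contribute a zero normal (and zero weight downstream)
        return np.divide(c, n, out=np.zeros_like(c), where=n > 0)

    @cached_property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @cached_property
    def volume(self) -> float:
        """Signed volume by the divergence theorem; > 0 for outward faces."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    # ------------------------------------------------------------------
    # vertex normals: angle-weighted average of incident face normals
    @cached_property
    def vertex_normals(self) -> np.ndarray:
        t = self.triangles
        fn = self.face_normals
        out = np.zeros_like(self.vertices)
        for c in range(3):
            e1 = t[:, (c + 1) % 3] - t[:, c]
            e2 = t[:, (c + 2) % 3] - t[:, c]
            n1 = np.linalg.norm(e1, axis=1)
            n2 = np.linalg.norm(e2, axis=1)
            denom = n1 * n2
            cosang = np.einsum("ij,ij->i", e1, e2)
            cosang = np.divide(cosang, denom, out=np.zeros_like(cosang), where=denom > 0)
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(out, self.faces[:, c], fn * ang[:, None])
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        return np.divide(out, nrm, out=np.zeros_like(out), where=nrm > 0)

    # ------------------------------------------------------------------
    # one-ring structure in CSR-like flat arrays
    @cached_property
    def _ring_flat(self):
        """(ring_ptr, ring_idx): neighbors of vertex k are
        ring_idx[ring_ptr[k]:ring_ptr[k+1]] (unordered, unique)."""
        he = self.halfedges  # every undirected edge appears in both directions
        order = np.argsort(he[:, 0], kind="stable")
        src = he[order, 0]
        dst = he[order, 1]
        counts = np.bincount(src, minlength=self.n_vertices)
        ptr = np.concatenate([[0], np.cumsum(counts)])
        return ptr, dst

    def vertex_ring(self, k: int) -> VertexRing:
        ptr, idx = self._ring_flat
        nb = np.unique(idx[ptr[k]:ptr[k + 1]])
        if len(nb) < 3:
            raise MeshError(f"vertex {k} has valence {len(nb)} < 3")
        npos = self.vertices[nb]
        vn = self.vertex_normals
        return VertexRing(
            center=k,
            neighbors=nb,
            position=self.vertices[k],
            neighbor_positions=npos,
            centroid=npos.mean(axis=0),
            normal=vn[k],
            neighbor_normals=vn[nb],
        )

    @cached_property
    def vertex_valences(self) -> np.ndarray:
        ptr, _ = self._ring_flat
        # directed halfedges double-count on manifold meshes, but a vertex's
        # outgoing halfedges equal its distinct neighbors on a closed manifold
        return np.diff(ptr)

    # ------------------------------------------------------------------
    # discrete curvature (cotangent Laplacian + angle deficit, Meyer areas)
    @cached_property
    def _curvature_data(self):
        V, F = self.vertices, self.faces
        t = self.triangles
        M = self.n_vertices

        # corner angles and cotangents
        cots = np.empty((len(F), 3))
        angles = np.empty((len(F), 3))
        for c in range(3):
            e1 = t[:, (c + 1) % 3] - t[:, c]
            e2 = t[:, (c + 2) % 3] - t[:, c]
            cross = np.linalg.norm(np.cross(e1, e2), axis=1)
            dot = np.einsum("ij,ij->i", e1, e2)
            cots[:, c] = np.divide(dot, cross, out=np.zeros_like(dot), where=cross > 1e-300)
            angles[:, c] = np.arctan2(cross, dot)

        # mixed Voronoi areas (Meyer et al. rule for obtuse triangles)
        areas = self.face_areas
        amixed = np.zeros(M)
        obtuse_corner = np.argmax(angles, axis=1)
        is_obtuse = angles[np.arange(len(F)), obtuse_corner] > np.pi / 2
        sq = np.empty((len(F), 3))
        for c in range(3):
            sq[:, c] = np.einsum(
                "ij,ij->i",
                t[:, (c + 1) % 3] - t[:, (c + 2) % 3],
                t[:, (c + 1) % 3] - t[:, (c + 2) % 3],
            )
        for c in range(3):
            # Voronoi: (|e_b|^2 cot(beta) + |e_c|^2 cot(gamma)) / 8 at corner c
            vor = (sq[:, (c + 1) % 3] * cots[:, (c + 1) % 3]
                   + sq[:, (c + 2) % 3] * cots[:, (c + 2) % 3]) / 8.0
            contrib = np.where(
                is_obtuse,
                np.where(obtuse_corner == c, areas / 2.0, areas / 4.0),
                vor,
            )
            np.add.at(amixed, F[:, c], contrib)

        # cotangent Laplacian sum_l (cot a + cot b)(v_l - v_k)
        lap = np.zeros((M, 3))
        for c in range(3):
            i = F[:, (c + 1) % 3]
            j = F[:, (c + 2) % 3]
            w = cots[:, c][:, None]  # angle at corner c is opposite edge (i, j)
            np.add.at(lap, i, w * (V[j] - V[i]))
            np.add.at(lap, j, w * (V[i] - V[j]))

        # angle deficit
        deficit = np.full(M, 2 * np.pi)
        for c in range(3):
            np.subtract.at(deficit, F[:, c], angles[:, c])

        return lap, amixed, deficit

    @cached_property
    def mixed_areas(self) -> np.ndarray:
        return self._curvature_data[1]

    @cached_property
    def mean_curvature(self) -> np.ndarray:
        """Per-vertex H in 1/nm; positive for a sphere with outward normals."""
        lap, amixed, _ = self._curvature_data
        safe = np.maximum(amixed, 1e-300)
        hvec = -lap / (2.0 * safe[:, None])  # mean curvature normal, = 2H n
        mag = 0.5 * np.linalg.norm(hvec, axis=1)
        sign = np.sign(np.einsum("ij,ij->i", hvec, self.vertex_normals))
        sign[sign == 0] = 1.0
        return mag * sign

    @cached_property
    def gaussian_curvature(self) -> np.ndarray:
        """Per-vertex K in 1/nm^2 via angle deficit over mixed area."""
        _, amixed, deficit = self._curvature_data
        return deficit / np.maximum(amixed, 1e-300)

    # ------------------------------------------------------------------
    # topology
    @cached_property
    def vertex_components(self) -> np.ndarray:
        e = self.edges_unique
        m = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        _, labels = _cc(m, directed=False)
        return labels

    @cached_property
    def n_components(self) -> int:
        used = np.zeros(self.n_vertices, bool)
        used[self.faces.ravel()] = True
        return int(len(np.unique(self.vertex_components[used])))

    @cached_property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Check closed-oriented-manifold invariants; empty list iff valid.

        Checks: triangles non-degenerate in index space, no duplicate faces,
        every undirected edge shared by exactly two faces with opposite
        direction, every vertex umbrella a single closed fan, no unreferenced
        vertices, Euler characteristic consistent with integer genus >= 0 per
        component.
        """
        problems: list[str] = []
        F = self.faces
        if len(F) == 0:
            return ["empty mesh"]
        if F.min() < 0 or F.max() >= self.n_vertices:
            return ["face index out of range"]

        if (np.diff(np.sort(F, axis=1), axis=1) == 0).any():
            problems.append("degenerate face (repeated vertex index)")

        canon = np.sort(F, axis=1)
        if len(np.unique(canon, axis=0)) != len(F):
            problems.append("duplicate face")

        he = self.halfedges
        und = np.sort(he, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        if (counts != 2).any():
            n_bad = int((counts != 2).sum())
            if (counts == 1).any():
                problems.append(f"unmatched twin halfedge ({n_bad} edges)")
            else:
                problems.append(f"edge shared by != 2 faces ({n_bad} edges)")
        else:
            # orientation: directed edges must be unique (each direction once)
            uniq_dir = np.unique(he, axis=0)
            if len(uniq_dir) != len(he):
                problems.append("inconsistent orientation (repeated directed edge)")

        referenced = np.zeros(self.n_vertices, bool)
        referenced[F.ravel()] = True
        if not referenced.all():
            problems.append(f"{int((~referenced).sum())} unreferenced vertices")

        if not problems:
            problems.extend(self._check_umbrellas())

        if not problems:
            labels = self.vertex_components
            for comp in np.unique(labels):
                vmask = labels == comp
                nV = int(vmask.sum())
                fmask = vmask[F[:, 0]]
                nF = int(fmask.sum())
                e = self.edges_unique
                nE = int(vmask[e[:, 0]].sum())
                chi = nV - nE + nF
                if chi > 2 or chi % 2 != 0:
                    problems.append(f"component {comp}: bad Euler characteristic {chi}")
        return problems

    def _check_umbrellas(self) -> list[str]:
        """Each vertex's incident faces must form one closed fan."""
        F = self.faces
        n_inc = np.bincount(F.ravel(), minlength=self.n_vertices)
        val = np.zeros(self.n_vertices, np.int64)
        ptr, idx = self._ring_flat
        # distinct neighbors per vertex
        for k in range(self.n_vertices):
            val[k] = len(np.unique(idx[ptr[k]:ptr[k + 1]]))
        bad = np.nonzero(n_inc != val)[0]
        if len(bad):
            return [f"non-manifold vertex fan at {len(bad)} vertices"]

        # count cycles of the ring graph: walk opposite-edge successor map
        problems = []
        succ: list[dict] = [dict() for _ in range(self.n_vertices)]
        for (a, b, c) in F:
            succ[a][b] = c
            succ[b][c] = a
            succ[c][a] = b
        n_bad_cycles = 0
        for k in range(self.n_vertices):
            s = succ[k]
            if not s:
                continue
            start = next(iter(s))
            cur = start
            steps = 0
            while True:
                cur = s.get(cur)
                steps += 1
                if cur is None or steps > len(s) + 1:
                    n_bad_cycles += 1
                    break
                if cur == start:
                    break
            else:
                pass
            if cur == start and steps != len(s):
                n_bad_cycles += 1
        if n_bad_cycles:
            problems.append(f"non-manifold vertex (multiple umbrella cycles) at {n_bad_cycles} vertices")
        return problems

    # ------------------------------------------------------------------
    def compact(self) -> "TriangleMesh":
        """Drop unreferenced vertices, remapping face indices."""
        used = np.unique(self.faces.ravel())
        remap = -np.ones(self.n_vertices, np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[self.faces])

    def split_components(self) -> list["TriangleMesh"]:
        labels = self.vertex_components
        out = []
        for comp in np.unique(labels[self.faces[:, 0]]):
            fmask = labels[self.faces[:, 0]] == comp
            out.append(TriangleMesh(self.vertices, self.faces[fmask]).compact())
        return out


# ----------------------------------------------------------------------
# primitive constructors (testing, starting meshes, examples)

def icosphere(subdivisions: int = 3, radius: float = 100.0,
              center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Icosahedral sphere mesh with outward orientation."""
    import trimesh as _tm

    m = _tm.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices) + np.asarray(center, float),
                        np.asarray(m.faces))


def tetrahedron(scale: float = 1.0) -> TriangleMesh:
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * scale
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    m = TriangleMesh(v, f)
    return m if m.volume > 0 else m.flipped()
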