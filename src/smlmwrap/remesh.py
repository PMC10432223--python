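"""Incremental isotropic remeshing and neck removal.

Remeshing keeps the wrap numerically healthy while the optimizer deforms
it: long edges are split, short edges collapsed, edges flipped toward
valence 6, and vertices relaxed tangentially toward their area-weighted
one-ring centroid. Thresholds are the standard 4/3 and 4/5 of the target
edge length, which keeps split and collapse from fighting each other.

Neck removal cuts the thin tubes that form where the starting surface
erroneously joined separate structures: as the wrap tightens, such necks
develop strongly negative Gaussian curvature at radii the mesh cannot
resolve. Vertices with K < -scale / target^2 are deleted and each
resulting boundary loop is stitched with a centroid fan. Components may
split apart here; they are never merged.
"""

from __future__ import annotations

import logging

import numpy as np

from .mesh import TriangleMesh

log = logging.getLogger(__name__)

SPLIT_FACTOR = 4.0 / 3.0
COLLAPSE_FACTOR = 4.0 / 5.0


# ----------------------------------------------------------------------
# edge split (batched)

def _split_long_edges(V: np.ndarray, F: np.ndarray, target: float):
    longest = SPLIT_FACTOR * target
    und = np.sort(np.concatenate(
        [F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    und = np.unique(und, axis=0)
    L = np.linalg.norm(V[und[:, 0]] - V[und[:, 1]], axis=1)
    long_edges = und[L > longest]
    if len(long_edges) == 0:
        return V, F

    mid = {}
    next_idx = len(V)
    for u, v in long_edges:
        mid[(int(u), int(v))] = next_idx
        next_idx += 1
    new_pts = 0.5 * (V[long_edges[:, 0]] + V[long_edges[:, 1]])

    # fast path: faces untouched by any split survive as-is
    k = np.sort(F, axis=1)
    touched = np.zeros(len(F), bool)
    keyset = set(mid)
    for i in range(len(F)):
        a, b, c = k[i]
        if (int(a), int(b)) in keyset or (int(b), int(c)) in keyset \
                or (int(a), int(c)) in keyset:
            touched[i] = True

    def mkey(u, v):
        return (u, v) if u < v else (v, u)

    out = [tuple(f) for f in F[~touched]]
    for (a, b, c) in F[touched]:
        a, b, c = int(a), int(b), int(c)
        splits = tuple(mkey(u, v) in mid for u, v in ((a, b), (b, c), (c, a)))
        n = sum(splits)
        if n == 0:
            out.append((a, b, c))
            continue
        # rotate so split pattern starts at edge (a, b)
        verts = [a, b, c]
        s = list(splits)
        while not s[0] or (n == 2 and s[2]):
            verts = verts[1:] + verts[:1]
            s = s[1:] + s[:1]
        a2, b2, c2 = verts
        if n == 1:
            m = mid[mkey(a2, b2)]
            out += [(a2, m, c2), (m, b2, c2)]
        elif n == 2:  # edges (a2,b2) and (b2,c2) split
            m1 = mid[mkey(a2, b2)]
            m2 = mid[mkey(b2, c2)]
            out += [(a2, m1, c2), (m1, m2, c2), (m1, b2, m2)]
        else:
            m1 = mid[mkey(a2, b2)]
            m2 = mid[mkey(b2, c2)]
            m3 = mid[mkey(c2, a2)]
            out += [(a2, m1, m3), (m1, b2, m2), (m2, c2, m3), (m1, m2, m3)]
    V2 = np.vstack([V, new_pts])
    return V2, np.asarray(out, dtype=np.int64)


# ----------------------------------------------------------------------
# mutable incidence structure for collapse / flip

class _Edit:
    def __init__(self, V: np.ndarray, F: np.ndarray):
        self.V = V.copy()
        self.faces = {i: tuple(f) for i, f in enumerate(F)}
        self.v2f: list[set] = [set() for _ in range(len(V))]
        for i, f in self.faces.items():
            for v in f:
                self.v2f[v].add(i)

    def neighbors(self, v: int) -> set:
        nb = set()
        for fi in self.v2f[v]:
            nb.update(self.faces[fi])
        nb.discard(v)
        return nb

    def edge_faces(self, a: int, b: int) -> list:
        return [fi for fi in self.v2f[a] & self.v2f[b]]

    def result(self) -> tuple[np.ndarray, np.ndarray]:
        F = np.asarray(list(self.faces.values()), dtype=np.int64)
        return self.V, F


def _collapse_short_edges(V: np.ndarray, F: np.ndarray, target: float):
    em = _Edit(V, F)
    lo = COLLAPSE_FACTOR * target
    hi = SPLIT_FACTOR * target

    # undirected edges with lengths, shortest first
    und = np.sort(np.concatenate(
        [F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    und = np.unique(und, axis=0)
    L = np.linalg.norm(V[und[:, 0]] - V[und[:, 1]], axis=1)
    order = np.argsort(L, kind="stable")
    dirty = np.zeros(len(V), bool)
    n_done = 0
    for ei in order:
        if L[ei] >= lo:
            break
        a, b = int(und[ei, 0]), int(und[ei, 1])
        if dirty[a] or dirty[b]:
            continue
        fab = em.edge_faces(a, b)
        if len(fab) != 2:
            continue
        opp = {v for fi in fab for v in em.faces[fi]} - {a, b}
        if len(opp) != 2:
            continue
        na = em.neighbors(a)
        nb = em.neighbors(b)
        if na & nb != opp:
            continue  # link condition: collapse would pinch the surface
        # valence-3 opposite vertices would drop to valence 2
        if any(len(em.neighbors(o)) <= 3 for o in opp):
            continue
        mid = 0.5 * (em.V[a] + em.V[b])
        ring = (na | nb) - {a, b}
        if any(np.linalg.norm(mid - em.V[n]) > hi for n in ring):
            continue  # collapse would create an over-long edge
        # perform: b merges into a at the midpoint
        em.V[a] = mid
        for fi in fab:
            for v in em.faces[fi]:
                em.v2f[v].discard(fi)
            del em.faces[fi]
        for fi in list(em.v2f[b]):
            f = em.faces[fi]
            em.faces[fi] = tuple(a if v == b else v for v in f)
            em.v2f[b].discard(fi)
            em.v2f[a].add(fi)
        dirty[list(ring | {a, b})] = True
        n_done += 1
    if n_done == 0:
        return V, F
    return em.result()


def _flip_for_valence(V: np.ndarray, F: np.ndarray):
    em = _Edit(V, F)
    val = np.zeros(len(V), np.int64)
    for f in em.faces.values():
        for v in f:
            val[v] += 1  # incident faces == valence on closed manifold

    und = np.sort(np.concatenate(
        [F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    und = np.unique(und, axis=0)
    n_done = 0
    for a, b in und:
        a, b = int(a), int(b)
        fab = em.edge_faces(a, b)
        if len(fab) != 2:
            continue
        f1, f2 = fab
        opp = [v for fi in fab for v in em.faces[fi] if v not in (a, b)]
        if len(opp) != 2 or opp[0] == opp[1]:
            continue
        c, d = opp
        before = (val[a] - 6) ** 2 + (val[b] - 6) ** 2 \
            + (val[c] - 6) ** 2 + (val[d] - 6) ** 2
        after = ((val[a] - 7) ** 2 + (val[b] - 7) ** 2
                 + (val[c] - 5) ** 2 + (val[d] - 5) ** 2)
        if after >= before:
            continue
        if d in em.neighbors(c):
            continue  # flip would duplicate edge (c, d)
        # orient: find the face containing directed edge a->b
        def has_dir(face, u, v):
            i = face.index(u)
            return face[(i + 1) % 3] == v
        fa = em.faces[f1] if has_dir(em.faces[f1], a, b) else em.faces[f2]
        fb = em.faces[f2] if fa is em.faces[f1] else em.faces[f1]
        ca = [v for v in fa if v not in (a, b)][0]  # opposite in a->b face
        cb = [v for v in fb if v not in (a, b)][0]
        # faces (a,b,ca) and (b,a,cb) -> (a,cb,ca) and (cb,b,ca)
        newf1 = (a, cb, ca)
        newf2 = (cb, b, ca)
        for fi in fab:
            for v in em.faces[fi]:
                em.v2f[v].discard(fi)
        em.faces[f1] = newf1
        em.faces[f2] = newf2
        for v in newf1:
            em.v2f[v].add(f1)
        for v in newf2:
            em.v2f[v].add(f2)
        val[a] -= 1
        val[b] -= 1
        val[c] += 1
        val[d] += 1
        n_done += 1
    if n_done == 0:
        return V, F
    return em.result()


def _tangential_relax(mesh: TriangleMesh, strength: float = 1.0) -> np.ndarray:
    """Move vertices toward their area-weighted one-ring centroid, projected
    into the tangent plane (no normal drift, so remeshing does not fight the
    shrink-wrap)."""
    V, F = mesh.vertices, mesh.faces
    va = np.zeros(len(V))
    np.add.at(va, F.ravel(), np.repeat(mesh.face_areas / 3.0, 3))

    e = mesh.edges_unique
    wsum = np.zeros(len(V))
    acc = np.zeros_like(V)
    for i, j in ((0, 1), (1, 0)):
        w = va[e[:, j]]
        np.add.at(wsum, e[:, i], w)
        np.add.at(acc, e[:, i], w[:, None] * V[e[:, j]])
    g = acc / np.maximum(wsum, 1e-300)[:, None]
    d = g - V
    n = mesh.vertex_normals
    d -= np.einsum("ij,ij->i", d, n)[:, None] * n
    return V + strength * d


def remesh_pass(mesh: TriangleMesh, target: float) -> TriangleMesh:
    """One split/collapse/flip/relax pass toward edge length ``target`` (nm)."""
    if target <= 0:
        raise ValueError("target edge length must be > 0")
    V, F = mesh.vertices, mesh.faces
    V, F = _split_long_edges(V, F, target)
    V, F = _collapse_short_edges(V, F, target)
    V, F = _flip_for_valence(V, F)
    m = TriangleMesh(V, F).compact()
    return m.with_vertices(_tangential_relax(m))


def drop_tiny_components(mesh: TriangleMesh, target: float,
                         min_faces: int = 16) -> TriangleMesh:
    """Remove closed components too small to be resolvable at the current
    edge-length target (fewer than ``min_faces`` faces or total area below
    a few triangles' worth). Debris of this size is produced when a cut-off
    blob collapses under the bending term. The largest component is always
    kept."""
    labels = mesh.vertex_components
    face_label = labels[mesh.faces[:, 0]]
    comps, counts = np.unique(face_label, return_counts=True)
    if len(comps) <= 1:
        return mesh
    areas = np.zeros(len(comps))
    for i, comp in enumerate(comps):
        areas[i] = mesh.face_areas[face_label == comp].sum()
    min_area = 4.0 * target ** 2
    keep = (counts >= min_faces) & (areas >= min_area)
    keep[np.argmax(areas)] = True
    if keep.all():
        return mesh
    log.info("dropping %d unresolvable component(s)", int((~keep).sum()))
    keep_faces = np.isin(face_label, comps[keep])
    return TriangleMesh(mesh.vertices, mesh.faces[keep_faces]).compact()


# ----------------------------------------------------------------------
# neck removal

def _pinch_vertices(mesh: TriangleMesh, distance: float,
                    normal_dot: float = -0.2) -> np.ndarray:
    """Vertices on an unresolvably thin tube or slab: another vertex with a
    strongly opposing normal lies within ``distance``. At such pinches the
    waist falls between vertices, so the angle-deficit curvature rule alone
    cannot see it."""
    from scipy.spatial import cKDTree

    V = mesh.vertices
    n = mesh.vertex_normals
    pairs = cKDTree(V).query_pairs(r=distance, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros(len(V), bool)
    opposing = np.einsum("ij,ij->i", n[pairs[:, 0]], n[pairs[:, 1]]) < normal_dot
    bad = np.zeros(len(V), bool)
    bad[pairs[opposing].ravel()] = True
    return bad


def _link_violation_vertices(mesh: TriangleMesh, max_len: float) -> np.ndarray:
    """Endpoints of very short edges whose collapse violates the link
    condition. Such edges sit on sub-resolution tubes or handles: their
    hoops can never be simplified away by collapsing, so they mark
    topological debris (e.g. the filament left when a neck outruns the
    curvature detector)."""
    V, F = mesh.vertices, mesh.faces
    em = _Edit(V, F)
    und = np.sort(np.concatenate(
        [F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    und = np.unique(und, axis=0)
    L = np.linalg.norm(V[und[:, 0]] - V[und[:, 1]], axis=1)
    bad = np.zeros(len(V), bool)
    for a, b in und[L < max_len]:
        a, b = int(a), int(b)
        fab = em.edge_faces(a, b)
        if len(fab) != 2:
            bad[[a, b]] = True
            continue
        opp = {v for fi in fab for v in em.faces[fi]} - {a, b}
        if em.neighbors(a) & em.neighbors(b) != opp:
            bad[[a, b]] = True
    return bad


def remove_necks(mesh: TriangleMesh, edge_length: float,
                 scale: float = 2.0, pinch_fraction: float = 0.0) -> TriangleMesh:
    """Delete vertices on unphysically sharp necks and stitch the holes.

    Complementary detectors define "unphysical":

    - saddle curvature below the mesh's own resolution,
      K < -scale / edge_length^2;
    - link-condition violations on sub-resolution edges (tubes or handles
      whose hoops can no longer be simplified by edge collapse);
    - pinches (optional, off by default): opposing-normal vertices within
      ``pinch_fraction * edge_length`` (a waist thinner than an edge has no
      vertex on it, so its discrete K stays moderate). Aggressive — it also
      severs legitimately close membrane walls, so enable deliberately.

    Returns the mesh unchanged when nothing triggers. May split the
    surface into more components; never merges any.
    """
    K = mesh.gaussian_curvature
    bad = K < -scale / edge_length ** 2
    bad |= _link_violation_vertices(mesh, 0.4 * edge_length)
    if pinch_fraction > 0:
        bad |= _pinch_vertices(mesh, pinch_fraction * edge_length)
    if not bad.any():
        return mesh

    F = mesh.faces
    # grow the deletion set until every boundary vertex borders exactly two
    # boundary edges, so holes are disjoint simple loops
    for _ in range(20):
        keep_face = ~bad[F].any(axis=1)
        Fk = F[keep_face]
        if len(Fk) == 0:
            log.warning("neck removal deleted every face; returning input mesh")
            return mesh
        he = np.concatenate([Fk[:, [0, 1]], Fk[:, [1, 2]], Fk[:, [2, 0]]])
        und = np.sort(he, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        if (counts == 1).sum() == 0:
            break
        single = {tuple(e) for e in uniq[counts == 1]}
        is_b = np.array([((u, v) if u < v else (v, u)) in single
                         for u, v in he])
        bdir = he[is_b]
        out_deg = np.bincount(bdir[:, 0], minlength=mesh.n_vertices)
        in_deg = np.bincount(bdir[:, 1], minlength=mesh.n_vertices)
        offenders = np.nonzero((out_deg != in_deg) | (out_deg > 1))[0]
        if len(offenders) == 0:
            break
        bad[offenders] = True
    else:
        log.warning("neck removal could not isolate simple boundary loops")
        return mesh

    keep_face = ~bad[F].any(axis=1)
    Fk = F[keep_face]
    he = np.concatenate([Fk[:, [0, 1]], Fk[:, [1, 2]], Fk[:, [2, 0]]])
    und = np.sort(he, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    single = {tuple(e) for e in uniq[counts == 1]}
    # directed boundary edges (present once): successor map for loop walking
    succ = {}
    for u, v in he:
        if ((u, v) if u < v else (v, u)) in single:
            succ[int(u)] = int(v)

    V = mesh.vertices
    new_faces = list(map(tuple, Fk))
    new_verts = [V]
    next_idx = len(V)
    visited = set()
    n_loops = 0
    for start in list(succ):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = succ[start]
        ok = True
        while cur != start:
            if cur in visited or cur not in succ or len(loop) > len(succ):
                ok = False
                break
            loop.append(cur)
            visited.add(cur)
            cur = succ[cur]
        if not ok or len(loop) < 3:
            log.warning("skipping malformed boundary loop of length %d", len(loop))
            continue
        centroid = V[loop].mean(axis=0)
        m = next_idx
        next_idx += 1
        new_verts.append(centroid[None, :])
        # kept faces traverse u->v on the boundary; fills traverse v->u
        for i, u in enumerate(loop):
            v = loop[(i + 1) % len(loop)]
            new_faces.append((v, u, m))
        n_loops += 1

    out = TriangleMesh(np.vstack(new_verts),
                       np.asarray(new_faces, dtype=np.int64)).compact()
    n_removed = mesh.n_components  # for logging only
    log.info("neck removal: %d vertices deleted, %d holes stitched, "
             "components %d -> %d", int(bad.sum()), n_loops,
             n_removed, out.n_components)
    return out
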