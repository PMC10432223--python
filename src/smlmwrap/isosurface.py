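"""Density-isosurface extraction: the coarse starting mesh.

The octree's stored-leaf densities are rasterized onto a uniform grid at a
chosen depth (unstored regions contribute zero density) and an isosurface
is extracted with marching cubes. This trades the fully adaptive dual
marching cubes construction for a uniform dual grid — acceptable here
because the starting mesh only needs to loosely *enclose* the structure;
the wrapping stage does the actual surface estimation.

The threshold should err low: a conservative (low) density threshold keeps
the initial surface outside the true membrane, which the shrink-wrap then
pulls inward onto the data. Under-segmentation (separate structures joined
by the start surface) is acceptable and is resolved later by neck removal.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure

from .mesh import TriangleMesh
from .octree import DensityField

log = logging.getLogger(__name__)


class EmptySurfaceError(RuntimeError):
    """The threshold exceeds every stored-leaf density; no isosurface exists."""


def choose_conservative_threshold(field: DensityField, quantile: float = 0.2) -> float:
    """A low quantile of stored-leaf densities (nm^-3).

    Picking a low threshold makes the starting surface lie outside the true
    membrane (deliberately more generous than a direct isosurface estimate).
    """
    if len(field) == 0:
        raise ValueError("empty density field")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(field.density, quantile, method="inverted_cdf"))


def auto_density_threshold(field: DensityField, cloud,
                           factor: float = 1.0,
                           low_quantile: float = 0.1,
                           smoothing: float = 1.0) -> float:
    """Self-calibrating conservative threshold from per-point local density.

    Each localization is assigned the (smoothed) voxel density at its own
    position; an Otsu split of the log densities separates membrane points
    (sitting in the dense shell) from background points (sitting in
    near-empty space). The threshold is ``factor`` times a low quantile of
    the membrane class — just under the density at essentially all
    membrane points, so the extracted surface starts outside the membrane
    and encloses the structure regardless of shell thickness or
    background level.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.filters import threshold_otsu

    grid, h, origin = rasterize(field)
    padded = np.pad(grid, 2)
    if smoothing > 0:
        padded = gaussian_filter(padded, smoothing)
    n = grid.shape[0]
    ij = np.clip(((cloud.positions - origin) / h).astype(int), 0, n - 1) + 2
    vi = padded[ij[:, 0], ij[:, 1], ij[:, 2]]
    pos = vi[vi > 0]
    if len(pos) == 0:
        raise EmptySurfaceError("no localization sits in a stored cell")
    logs = np.log10(pos)
    if logs.max() - logs.min() < 1e-6:
        membrane = pos
    else:
        cut = 10.0 ** threshold_otsu(logs)
        membrane = pos[pos >= cut]
    return float(factor * np.quantile(membrane, low_quantile))


def rasterize(field: DensityField, level: int | None = None,
              max_grid: int = 192) -> tuple[np.ndarray, float, np.ndarray]:
    """Rasterize leaf densities onto a uniform grid at octree depth ``level``.

    Returns (grid, cell_side_nm, grid_origin). Leaves coarser than the grid
    fill their voxel block with their density; leaves finer than the grid
    deposit their counts into the containing voxel.
    """
    if len(field) == 0:
        raise ValueError("empty density field")
    if level is None:
        level = field.max_depth
    level = int(min(level, int(np.floor(np.log2(max_grid)))))
    level = max(level, 1)

    n = 2 ** level
    root_lo = field.root_bounds[0]
    root_side = float(field.root_bounds[1, 0] - field.root_bounds[0, 0])
    h = root_side / n
    grid = np.zeros((n, n, n))
    vox_vol = h ** 3

    idx = np.clip(((field.lo - root_lo) / h + 1e-9).astype(int), 0, n - 1)
    span = np.maximum((field.side / h + 1e-9).astype(int), 0)
    for i in range(len(field)):
        i0, j0, k0 = idx[i]
        s = span[i]
        if s >= 1:  # leaf at least as large as a voxel: block fill
            grid[i0:i0 + s, j0:j0 + s, k0:k0 + s] += field.density[i]
        else:  # sub-voxel leaf: deposit its count into the containing voxel
            grid[i0, j0, k0] += field.count[i] / vox_vol
    return grid, h, root_lo


def dual_marching_cubes(field: DensityField, threshold: float | None,
                        level: int | None = None,
                        smoothing: float | None = None,
                        quantile: float = 0.2) -> TriangleMesh:
    """Extract the closed density isosurface separating high from low density.

    Outward normals point toward low density. The mesh may be coarse and may
    join nearby structures (under-segmentation) — by design.

    ``smoothing`` is the sigma (in grid cells) of a Gaussian applied to the
    rasterized density before thresholding: it suppresses spurious
    fenestrations from shot noise in sparsely labeled membrane patches
    while leaving holes spanning several cells open. By default it is on
    (1 cell) for the automatic threshold and off for an explicit one — an
    explicit threshold is stated in raw leaf-density units, which
    smoothing would dilute.

    ``threshold=None`` picks a conservative (low) value automatically: the
    ``quantile`` of the smoothed density over stored cells, so the surface
    starts outside the membrane.
    """
    if threshold is not None and threshold <= 0:
        raise ValueError("threshold must be > 0 (background density is 0)")
    if len(field) == 0:
        raise ValueError("empty density field")
    if threshold is not None and threshold >= field.density.max():
        raise EmptySurfaceError(
            f"threshold {threshold:g} >= max leaf density {field.density.max():g}"
        )

    if smoothing is None:
        smoothing = 1.0 if threshold is None else 0.0
    grid, h, origin = rasterize(field, level=level)
    padded = np.pad(grid, 2)  # zero margin so the isosurface always closes
    stored = padded > 0
    if smoothing > 0:
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(padded, smoothing)
    if threshold is None:
        # low quantile of the (smoothed) density over the stored-leaf
        # region: conservative, so the surface starts outside the membrane
        threshold = float(np.quantile(padded[stored], quantile,
                                      method="inverted_cdf"))
    if threshold >= padded.max():
        raise EmptySurfaceError(
            f"threshold {threshold:g} >= max smoothed density {padded.max():g}"
        )
    verts, faces, _, _ = measure.marching_cubes(padded, level=threshold,
                                                spacing=(h, h, h))
    # padded node (i,j,k) sits at the center of original cell (i-2,j-2,k-2)
    verts = verts + (origin - 1.5 * h)

    mesh = _cleanup(verts, faces)
    if mesh.volume < 0:
        mesh = mesh.flipped()
    return mesh


def _cleanup(verts: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Merge coincident vertices, drop degenerate faces, compact."""
    # exact-coordinate merge (marching cubes emits shared verts per cell pair)
    uniq, inverse = np.unique(verts.round(decimals=9), axis=0, return_inverse=True)
    faces = inverse[np.asarray(faces, np.int64)]
    good = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    mesh = TriangleMesh(uniq, faces[good]).compact()
    mesh = _split_nonmanifold_vertices(mesh)
    problems = mesh.validate()
    if problems:
        log.warning("isosurface cleanup left issues: %s", problems)
    return mesh


def _split_nonmanifold_vertices(mesh: TriangleMesh) -> TriangleMesh:
    """Duplicate vertices whose incident faces form several umbrella fans
    (a rare marching-cubes output); each fan gets its own vertex copy."""
    F = mesh.faces.copy()
    V = [mesh.vertices]
    n_inc = np.bincount(F.ravel(), minlength=mesh.n_vertices)
    # face adjacency around each vertex via shared edges
    changed = False
    next_idx = mesh.n_vertices
    v2f: list[list] = [[] for _ in range(mesh.n_vertices)]
    for fi, f in enumerate(F):
        for v in f:
            v2f[v].append(fi)
    for k in range(mesh.n_vertices):
        inc = v2f[k]
        if len(inc) < 2:
            continue
        # group incident faces into fans connected through edges at k
        parent = {fi: fi for fi in inc}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        edge_owner: dict = {}
        for fi in inc:
            f = F[fi]
            others = [v for v in f if v != k]
            for o in others:
                if o in edge_owner:
                    ra, rb = find(edge_owner[o]), find(fi)
                    if ra != rb:
                        parent[ra] = rb
                else:
                    edge_owner[o] = fi
        roots = {find(fi) for fi in inc}
        if len(roots) <= 1:
            continue
        changed = True
        for extra_root in list(roots)[1:]:
            group = [fi for fi in inc if find(fi) == extra_root]
            V.append(mesh.vertices[k][None, :])
            for fi in group:
                F[fi][F[fi] == k] = next_idx
            next_idx += 1
    if not changed:
        return mesh
    return TriangleMesh(np.vstack(V), F).compact()
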