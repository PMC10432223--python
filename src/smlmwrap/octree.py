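"""Sparse octree over a localization cloud with per-cell density.

The octree adapts cell size to local point density: subdivision recurses
only into children holding at least ``min_points`` localizations, so cells
are small where data are dense and large where they are sparse. Cells below
the occupancy cutoff are not stored at all — the density field is
implicitly zero there, which is what lets the extracted isosurface close
around the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import LocalizationCloud


@dataclass
class OctreeNode:
    """A node of the sparse octree.

    ``bounds`` is ``[lo, hi]`` (2, 3) in nm; boxes are half-open
    ``[lo, hi)`` so a point on an internal boundary lands in exactly one
    child (the lower-index one).
    """

    bounds: np.ndarray
    count: int
    depth: int
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def side(self) -> float:
        return float(self.bounds[1, 0] - self.bounds[0, 0])

    @property
    def volume(self) -> float:
        return self.side ** 3

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


@dataclass(frozen=True)
class DensityField:
    """Stored-leaf densities: box origins ``lo`` (L, 3) nm, ``side`` (L,) nm,
    ``count`` (L,) and ``density = count / side^3`` (L,) nm^-3. Regions not
    covered by a stored leaf have implicit density zero."""

    lo: np.ndarray
    side: np.ndarray
    count: np.ndarray
    density: np.ndarray
    root_bounds: np.ndarray
    max_depth: int

    def __len__(self) -> int:
        return len(self.density)


def root_box(cloud: LocalizationCloud, pad: float | None = None) -> np.ndarray:
    """Cubic root box: the cloud bounding box expanded by ``pad`` on every
    side (default twice the largest precision) and padded out to a cube.
    The margin gives the isosurface empty space in which to close."""
    lo, hi = cloud.bounds
    if pad is None:
        pad = 2.0 * float(cloud.sigmas.max())
    lo = lo - pad
    hi = hi + pad
    center = 0.5 * (lo + hi)
    half = float((hi - lo).max()) / 2.0
    return np.stack([center - half, center + half])


def default_max_depth(cloud: LocalizationCloud, bounds: np.ndarray) -> int:
    """Deepest level whose cell side stays >= the median precision —
    resolving below the localization precision is meaningless."""
    side = float(bounds[1, 0] - bounds[0, 0])
    med_sigma = float(np.median(cloud.sigmas))
    depth = int(np.floor(np.log2(side / max(med_sigma, 1e-9))))
    return max(1, min(depth, 12))


RETENTION = 0.7  # fraction of a cell's points its stored children must keep


def build_octree(cloud: LocalizationCloud, min_points: int,
                 max_depth: int | None = None,
                 bounds: np.ndarray | None = None) -> OctreeNode:
    """Build the sparse octree, truncated at ``min_points`` per cell.

    A node subdivides while its depth is below ``max_depth`` and the
    children holding at least ``min_points`` localizations retain at least
    70% of the node's points between them; children below the cutoff are
    discarded (their points leave the stored structure). The retention
    rule keeps uniformly filled regions from shedding most of their mass
    into sub-threshold octants while still drilling down onto tight
    clusters.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    if len(cloud) < min_points:
        raise ValueError(
            f"cannot build octree: N={len(cloud)} < min_points={min_points}"
        )
    if bounds is None:
        bounds = root_box(cloud)
    bounds = np.asarray(bounds, float)
    if max_depth is None:
        max_depth = default_max_depth(cloud, bounds)
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")

    pts = cloud.positions
    root = OctreeNode(bounds=bounds, count=len(pts), depth=0)
    _subdivide(root, pts, np.arange(len(pts)), min_points, max_depth)
    return root


def _subdivide(node: OctreeNode, pts: np.ndarray, idx: np.ndarray,
               min_points: int, max_depth: int) -> None:
    if node.depth >= max_depth:
        return
    lo, hi = node.bounds
    mid = 0.5 * (lo + hi)
    p = pts[idx]
    # half-open split: coordinates >= mid go to the upper child
    octant = ((p[:, 0] >= mid[0]).astype(np.int8)
              + 2 * (p[:, 1] >= mid[1]).astype(np.int8)
              + 4 * (p[:, 2] >= mid[2]).astype(np.int8))
    sels = [idx[octant == o] for o in range(8)]
    kept_mass = sum(len(s) for s in sels if len(s) >= min_points)
    if kept_mass < RETENTION * node.count:
        return  # splitting would shed too many points into sparse octants
    kept = []
    for o in range(8):
        sel = sels[o]
        if len(sel) < min_points:
            continue
        offs = np.array([o & 1, (o >> 1) & 1, (o >> 2) & 1], float)
        clo = lo + offs * (mid - lo)
        chi = mid + offs * (hi - mid)
        child = OctreeNode(bounds=np.stack([clo, chi]), count=len(sel),
                           depth=node.depth + 1)
        _subdivide(child, pts, sel, min_points, max_depth)
        kept.append(child)
    if kept:
        node.children = kept
        # points in discarded (below-cutoff) children leave the stored
        # structure; an internal node's count is the sum of its children's
        node.count = int(sum(c.count for c in kept))


def leaf_densities(tree: OctreeNode) -> DensityField:
    """Per-leaf localization density (count / leaf volume, nm^-3)."""
    lo, side, count, depth = [], [], [], []
    for leaf in tree.leaves():
        lo.append(leaf.bounds[0])
        side.append(leaf.side)
        count.append(leaf.count)
        depth.append(leaf.depth)
    lo = np.asarray(lo, float)
    side = np.asarray(side, float)
    count = np.asarray(count, float)
    return DensityField(
        lo=lo, side=side, count=count,
        density=count / side ** 3,
        root_bounds=tree.bounds,
        max_depth=int(max(depth)) if depth else 0,
    )


def dump_leaves_json(field: DensityField, path: str) -> None:
    """Debug dump of stored leaf boxes and densities."""
    import json

    records = [
        {"lo": field.lo[i].tolist(), "side": float(field.side[i]),
         "count": int(field.count[i]), "density": float(field.density[i])}
        for i in range(len(field))
    ]
    with open(path, "w") as f:
        json.dump(records, f)
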