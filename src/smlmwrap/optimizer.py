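"""The outer shrink-wrap loop.

Pipeline: build (or accept) a coarse density-isosurface start, then repeat
{ refresh correspondences; inner nonlinear-CG solve of the frozen
objective; every ``remesh_interval`` iterations remesh toward the
scheduled edge length and cut necks } until the surface stops moving or
the iteration budget is reached.

The target edge length decreases linearly from the starting mesh's mean
edge to max(floor, 0.4 x the minimum per-axis localization precision),
reaching the final value at the last remesh event so that a few wrap
iterations still run on the final tessellation. Large-scale shape is
fit early on a coarse mesh; fine detail late on a fine one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .cloud import LocalizationCloud
from .energy import assign_correspondences, total_energy
from .isosurface import auto_density_threshold, dual_marching_cubes
from .mesh import MeshError, TriangleMesh
from .octree import build_octree, leaf_densities
from .remesh import drop_tiny_components, remesh_pass, remove_necks

log = logging.getLogger(__name__)


class FitDivergenceError(RuntimeError):
    """Energy grew over several consecutive outer iterations."""


@dataclass
class FitConfig:
    """Tunable parameters of the reconstruction.

    curvature_weight (lambda) is the primary knob balancing point fidelity
    against bending; its optimum grows with localization density and
    background, but the minimum in surface error is broad.
    """

    curvature_weight: float = 10.0
    max_iterations: int = 60
    remesh_interval: int = 5
    edge_length_floor: float = 5.0
    convergence_tol: float = 0.01
    inner_cg_steps: int = 10
    neck_threshold_scale: float = 2.0
    pinch_fraction: float = 0.0  # enable to sever sub-edge waists/slabs
    approach_iterations: int = 10
    approach_deweight_floor: float = 0.3
    density_threshold: float | None = None  # None = self-calibrating rule
    density_quantile: float = 0.1  # low quantile of membrane-class density
    density_factor: float = 1.0  # scales the auto threshold downward if < 1
    min_points_per_cell: int = 50
    octree_max_depth: int | None = None
    k_candidates: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1 or self.remesh_interval < 1 \
                or self.inner_cg_steps < 1:
            raise ValueError("iteration counts must be positive")
        if not 0 < self.convergence_tol < 1:
            raise ValueError("convergence_tol must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitTrace:
    """Per-outer-iteration record of the fit."""

    records: list = field(default_factory=list)

    def append(self, **kw) -> None:
        if self.records and kw["iteration"] <= self.records[-1]["iteration"]:
            raise ValueError("iteration indices must increase")
        self.records.append(kw)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)


# ----------------------------------------------------------------------

def edge_length_schedule(iteration: int, final_iteration: int,
                         start_length: float, cloud: LocalizationCloud,
                         floor: float = 5.0) -> float:
    """Linear target edge length: ``start_length`` at iteration 0 down to
    max(floor, 0.4 x min per-axis sigma) at the final remesh event."""
    final = max(floor, 0.4 * float(cloud.sigmas.min()))
    final = min(final, start_length)
    if final_iteration <= 0 or iteration >= final_iteration:
        return final
    frac = iteration / final_iteration
    return start_length + (final - start_length) * frac


def check_convergence(previous: np.ndarray, current: np.ndarray,
                      target_edge: float, tol: float = 0.01) -> bool:
    """True iff RMS vertex displacement < tol x current target edge length.
    Not evaluable (returns False) when vertex counts differ."""
    if previous is None or previous.shape != current.shape:
        return False
    rms = float(np.sqrt(np.mean(np.sum((current - previous) ** 2, axis=1))))
    return rms < tol * target_edge


def _jacobi_preconditioner(mesh, cloud, assign, lam):
    """Per-vertex-per-axis diagonal of the frozen Hessian.

    Fidelity contributes sum_i 2 (u w / sigma)^2 at the vertices of each
    localization's face; bending contributes ~2 (lambda/sigma_ref)^2 per
    vertex. Their ratio spans orders of magnitude when precisions are
    anisotropic or data coverage is uneven, which is what makes plain CG
    crawl; dividing the gradient by this diagonal equalizes the modes.
    """
    usig2 = (assign.deweight / cloud.sigmas) ** 2  # (N, 3)
    diag = np.zeros_like(mesh.vertices)
    w2 = assign.weights ** 2  # (N, 3verts)
    contrib = 2.0 * w2[:, :, None] * usig2[:, None, :]
    np.add.at(diag, assign.face_vertices.ravel(), contrib.reshape(-1, 3))
    sigma_ref = float(np.median(cloud.sigmas))
    diag += 2.0 * (lam / sigma_ref) ** 2
    return diag


def conjugate_gradient_solve(mesh: TriangleMesh, cloud: LocalizationCloud,
                             assign, lam: float, steps: int = 10):
    """Inner solve: preconditioned nonlinear CG (Polak-Ribiere with
    restarts, backtracking Armijo line search) on vertex positions with the
    correspondence state frozen. Energy is non-increasing over accepted
    steps; connectivity is untouched.

    Returns (new_vertices, info) where info records energies and whether
    the first line search failed (positions unchanged in that case).
    """
    x = mesh.vertices.copy()
    f, g = total_energy(mesh, cloud, assign, lam, vertices=x)
    energies = [f]
    if float(np.einsum("ij,ij->", g, g)) < 1e-20:  # already stationary
        return x, {"energies": energies, "line_search_failed": False,
                   "final_energy": f}
    precond = np.maximum(_jacobi_preconditioner(mesh, cloud, assign, lam),
                         1e-12)
    z = g / precond
    d = -z
    gg = float(np.einsum("ij,ij->", g, z))
    failed_first = False
    scale = float(np.mean(mesh.edge_lengths()))
    # trust region: no vertex moves more than a fraction of an edge per
    # step, so a face cannot leap onto a distant point cluster within one
    # frozen-correspondence solve
    cap = 0.3 * scale

    for it in range(steps):
        slope = float(np.einsum("ij,ij->", g, d))
        if slope >= 0:  # not a descent direction: restart on gradient
            d = -z
            slope = -gg
        # initial step from the directional second derivative (the frozen
        # objective is nearly quadratic, so this lands close to the line
        # minimum); backtracking protects against the nonquadratic part
        dmax = max(np.abs(d).max(), 1e-300)
        eps = 1e-4 * max(scale, 1e-6) / dmax
        _, g_eps = total_energy(mesh, cloud, assign, lam, vertices=x + eps * d)
        curv = float(np.einsum("ij,ij->", g_eps - g, d)) / eps
        if curv > 0:
            a = -slope / curv
        else:
            a = 0.25 * scale / dmax
        a = min(a, cap / dmax)
        ok = False
        for _ in range(30):
            xn = x + a * d
            fn, gn = total_energy(mesh, cloud, assign, lam, vertices=xn)
            if fn <= f + 1e-4 * a * slope:
                ok = True
                break
            a *= 0.5
        if not ok:
            if it == 0:
                failed_first = True
            break
        x, f = xn, fn
        energies.append(f)
        zn = gn / precond
        ggn = float(np.einsum("ij,ij->", gn, zn))
        beta = max(0.0, float(np.einsum("ij,ij->", zn, gn - g)) / max(gg, 1e-300))
        d = -zn + beta * d
        g, gg = gn, ggn
        if gg < 1e-24:
            break
    info = {"energies": energies, "line_search_failed": failed_first,
            "final_energy": energies[-1]}
    return x, info


def build_starting_mesh(cloud: LocalizationCloud, config: FitConfig) -> TriangleMesh:
    """Octree density field -> conservative threshold -> isosurface."""
    tree = build_octree(cloud, min_points=config.min_points_per_cell,
                        max_depth=config.octree_max_depth)
    fieldd = leaf_densities(tree)
    thr = config.density_threshold
    if thr is None:
        # threshold calibrated on the smoothed grid; extract on the same
        thr = auto_density_threshold(fieldd, cloud,
                                     factor=config.density_factor,
                                     low_quantile=config.density_quantile)
    mesh = dual_marching_cubes(fieldd, thr, smoothing=1.0)
    log.info("starting mesh: %d vertices, %d faces, threshold %.3g nm^-3",
             mesh.n_vertices, mesh.n_faces, thr)
    return mesh


def _drop_unsupported_components(mesh, assign, min_alpha: float = 0.1):
    """Drop closed components whose vertices carry essentially no data
    influence (debris left behind when a neck between wrapped structures is
    cut). The largest-area component is always kept. Returns the reduced
    mesh, or None when nothing was dropped."""
    if mesh.n_components <= 1:
        return None
    labels = mesh.vertex_components
    face_label = labels[mesh.faces[:, 0]]
    comps = np.unique(face_label)
    areas = np.array([mesh.face_areas[face_label == c].sum() for c in comps])
    mean_alpha = np.array([assign.alpha[labels == c].mean() for c in comps])
    keep = mean_alpha >= min_alpha
    keep[np.argmax(areas)] = True
    if keep.all():
        return None
    log.info("dropping %d data-free component(s)", int((~keep).sum()))
    keep_faces = np.isin(face_label, comps[keep])
    return TriangleMesh(mesh.vertices, mesh.faces[keep_faces]).compact()


def fit(cloud: LocalizationCloud, config: FitConfig | None = None,
        start: TriangleMesh | None = None) -> tuple[TriangleMesh, FitTrace]:
    """Reconstruct a closed surface from a localization cloud.

    Returns the fitted mesh and the per-iteration trace. Raises
    :class:`FitDivergenceError` if the inner energy grows across three
    consecutive comparable outer iterations.
    """
    config = config or FitConfig()
    if start is None:
        mesh = build_starting_mesh(cloud, config)
    else:
        problems = start.validate()
        if problems:
            raise MeshError(f"invalid starting mesh: {problems}")
        mesh = start
    if mesh.n_faces == 0:
        raise MeshError("starting mesh is empty")

    start_length = float(np.mean(mesh.edge_lengths()))
    final_iter = max(config.max_iterations - config.remesh_interval,
                     config.remesh_interval)
    trace = FitTrace()
    prev_positions = None
    prev_energy = None
    growth_streak = 0
    lam = config.curvature_weight

    for it in range(1, config.max_iterations + 1):
        floor_u = (config.approach_deweight_floor
                   if it <= config.approach_iterations else 0.0)
        assign = assign_correspondences(mesh, cloud,
                                        k_candidates=config.k_candidates,
                                        deweight_floor=floor_u)
        dropped = _drop_unsupported_components(mesh, assign)
        if dropped is not None:
            mesh = dropped
            assign = assign_correspondences(mesh, cloud,
                                            k_candidates=config.k_candidates,
                                            deweight_floor=floor_u)
        new_v, info = conjugate_gradient_solve(
            mesh, cloud, assign, lam, steps=config.inner_cg_steps)
        target = edge_length_schedule(it, final_iter, start_length, cloud,
                                      config.edge_length_floor)
        rms = float(np.sqrt(np.mean(np.sum((new_v - mesh.vertices) ** 2, axis=1))))
        converged = check_convergence(mesh.vertices, new_v, target,
                                      config.convergence_tol)
        mesh = mesh.with_vertices(new_v)

        remeshed = False
        if it % config.remesh_interval == 0 and it <= final_iter:
            mesh = remesh_pass(mesh, target)
            mesh = remove_necks(mesh, target, config.neck_threshold_scale,
                                pinch_fraction=config.pinch_fraction)
            mesh = drop_tiny_components(mesh, target)
            problems = mesh.validate()
            if problems:
                log.warning("mesh invalid after remesh at iter %d: %s",
                            it, problems)
            remeshed = True

        start_energy = info["energies"][0]
        trace.append(iteration=it, energy=info["final_energy"],
                     start_energy=start_energy,
                     rms_displacement=rms, n_vertices=mesh.n_vertices,
                     n_faces=mesh.n_faces, target_edge=target,
                     remeshed=remeshed,
                     n_components=mesh.n_components if remeshed else -1)

        # divergence guard: the pre-solve energy is a function of the mesh
        # alone (the inner solve only lowers its own frozen objective), so
        # sustained significant growth across non-remesh iterations means
        # the outer iteration is diverging
        if prev_energy is not None and not remeshed \
                and prev_positions is not None \
                and prev_positions.shape == mesh.vertices.shape:
            if start_energy > prev_energy * 1.01:
                growth_streak += 1
                if growth_streak >= 3:
                    raise FitDivergenceError(
                        f"energy grew over 3 consecutive iterations at iter {it}")
            else:
                growth_streak = 0
        prev_energy = None if remeshed else start_energy
        prev_positions = mesh.vertices

        if converged and it > final_iter:
            log.info("converged at iteration %d", it)
            break

    return mesh, trace
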