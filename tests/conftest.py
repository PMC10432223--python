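import logging

import numpy as np
import pytest
from skimage import measure

import smlmwrap as sw
from smlmwrap.isosurface import _cleanup

logging.getLogger("smlmwrap").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sphere_cloud(radius=100.0, n=5000, sigma=10.0, seed=3, sigma_z=None,
                 center=(0.0, 0.0, 0.0)):
    """Noisy localizations on a sphere with per-axis Gaussian displacement."""
    r = np.random.default_rng(seed)
    pts = r.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts = pts * radius + np.asarray(center, float)
    sig = np.full((n, 3), sigma)
    if sigma_z is not None:
        sig[:, 2] = sigma_z
    noisy = pts + r.normal(size=(n, 3)) * sig
    return sw.LocalizationCloud(noisy, sig)


def mesh_from_sdf(sdf, extent, h):
    """Marching-cubes mesh of an SDF over [-extent, extent]^3 (test fixture)."""
    n = int(np.ceil(2 * extent / h))
    ax = (np.arange(n) - n / 2) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = sdf(np.stack([X, Y, Z], -1).reshape(-1, 3)).reshape(n, n, n)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
    mesh = _cleanup(verts - n / 2 * h, faces)
    return mesh if mesh.volume > 0 else mesh.flipped()


def dumbbell_mesh(neck_radius=4.0, sphere_radius=60.0, center_x=70.0,
                  neck_half=20.0, h=3.2):
    """Two spheres joined by an hourglass (catenoid-like) neck."""

    def sdf(p):
        d1 = np.linalg.norm(p - [-center_x, 0, 0], axis=-1) - sphere_radius
        d2 = np.linalg.norm(p - [center_x, 0, 0], axis=-1) - sphere_radius
        rr = neck_radius * np.cosh(
            np.clip(p[..., 0], -neck_half, neck_half) / (2 * neck_radius))
        dneck = np.maximum(np.hypot(p[..., 1], p[..., 2]) - rr,
                           np.abs(p[..., 0]) - neck_half)
        return np.minimum(np.minimum(d1, d2), dneck)

    return mesh_from_sdf(sdf, center_x + sphere_radius + 10, h)


def flat_grid_mesh(n=6, spacing=1.0, lift=None):
    """Open triangulated square sheet in the z=0 plane; ``lift`` optionally
    raises the central vertex by that height."""
    xs = np.arange(n) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            F.append((a, b, d))
            F.append((a, d, c))
    mesh = sw.TriangleMesh(V, np.asarray(F))
    if lift is not None:
        V = mesh.vertices.copy()
        center = (n // 2) * n + n // 2
        V[center, 2] = lift
        mesh = sw.TriangleMesh(V, mesh.faces)
    return mesh


def torus_mesh(ring_radius=150.0, tube_radius=50.0, n_ring=48, n_tube=20):
    """Parametric torus triangulation (closed, genus 1)."""
    u = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    v = np.linspace(0, 2 * np.pi, n_tube, endpoint=False)
    U, V_ = np.meshgrid(u, v, indexing="ij")
    x = (ring_radius + tube_radius * np.cos(V_)) * np.cos(U)
    y = (ring_radius + tube_radius * np.cos(V_)) * np.sin(U)
    z = tube_radius * np.sin(V_)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    F = []
    for i in range(n_ring):
        for j in range(n_tube):
            a = i * n_tube + j
            b = ((i + 1) % n_ring) * n_tube + j
            c = i * n_tube + (j + 1) % n_tube
            d = ((i + 1) % n_ring) * n_tube + (j + 1) % n_tube
            F.append((a, b, d))
            F.append((a, d, c))
    mesh = sw.TriangleMesh(verts, np.asarray(F))
    return mesh if mesh.volume > 0 else mesh.flipped()
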