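"""Ground-truth membrane shapes and synthetic SMLM point clouds.

Shapes are signed distance functions (SDFs, negative inside). The study
shapes are a figure-eight of two touching tori (~800 nm across, 100 nm
tube thickness — an idealized organelle pair) and a tapered cylinder whose
radius runs from 30 to 200 nm over 2000 nm (an ER-tubule-like object with
a known curvature profile along its length).

The cloud generator emulates the dominant statistical features of SMLM
membrane data: localizations sampled area-uniformly on the membrane at a
chosen surface density (nm^-2), displaced per axis by Gaussian noise with
each point's own precision sigma (drawn from a lognormal, median 10 nm by
default; axial inflation configurable for astigmatic-like data), plus a
fraction of uniform background localizations in the bounding volume. It
does not model fluorophore photophysics (blinking clusters) or label
linkage error.

A separate, noise-free "verification" sample of the surface supports the
Q1/Q2/Q surface-error metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cloud import LocalizationCloud


@dataclass(frozen=True)
class SDFShape:
    """A closed surface defined as the zero level set of a signed distance
    function (negative inside), with analytic area and, where available,
    analytic curvature along the surface."""

    name: str
    sdf: Callable[[np.ndarray], np.ndarray]
    bounds: np.ndarray  # (2, 3) nm
    area: float  # nm^2
    mean_curvature: Callable[[np.ndarray], np.ndarray] | None = None
    curvature_radius: Callable[[np.ndarray], np.ndarray] | None = None

    def gradient(self, pts: np.ndarray, h: float = 0.05) -> np.ndarray:
        """Numeric central-difference gradient of the SDF."""
        pts = np.asarray(pts, float)
        g = np.empty_like(pts)
        for c in range(3):
            dp = np.zeros(3)
            dp[c] = h
            g[:, c] = (self.sdf(pts + dp) - self.sdf(pts - dp)) / (2 * h)
        return g

    def project(self, pts: np.ndarray, iterations: int = 6) -> np.ndarray:
        """Newton projection of points onto the zero level set along the
        SDF gradient."""
        x = np.asarray(pts, float).copy()
        for _ in range(iterations):
            d = self.sdf(x)
            g = self.gradient(x)
            gn = np.maximum(np.einsum("ij,ij->i", g, g), 1e-12)
            x -= (d / gn)[:, None] * g
        return x


# ----------------------------------------------------------------------
# shape constructors

def make_sphere(radius: float = 100.0, center=(0.0, 0.0, 0.0)) -> SDFShape:
    center = np.asarray(center, float)

    def sdf(p):
        return np.linalg.norm(np.asarray(p, float) - center, axis=-1) - radius

    bounds = np.stack([center - radius, center + radius])
    return SDFShape(
        name="sphere",
        sdf=sdf,
        bounds=bounds,
        area=4.0 * np.pi * radius ** 2,
        mean_curvature=lambda p: np.full(len(np.atleast_2d(p)), 1.0 / radius),
        curvature_radius=lambda p: np.full(len(np.atleast_2d(p)), radius),
    )


def _torus_sdf(p, center_x, ring_radius, tube_radius):
    x = p[:, 0] - center_x
    rho = np.hypot(x, p[:, 1])
    return np.hypot(rho - ring_radius, p[:, 2]) - tube_radius


def make_figure_eight(diameter: float = 800.0, thickness: float = 100.0,
                      blend: float = 0.0) -> SDFShape:
    """Two touching tori in the xy-plane; overall x-extent = ``diameter``,
    tube diameter = ``thickness``.

    ``blend`` > 0 applies a polynomial smooth-min of that radius (nm) at
    the junction; the default hard min keeps each lobe's SDF exact.
    """
    if thickness >= diameter:
        raise ValueError("thickness must be < diameter")
    r = thickness / 2.0
    R = diameter / 4.0 - r
    if R <= 0:
        raise ValueError("diameter too small for this thickness")
    cx = R + r  # lobes touch at the origin

    def sdf(p):
        p = np.atleast_2d(np.asarray(p, float))
        d1 = _torus_sdf(p, -cx, R, r)
        d2 = _torus_sdf(p, +cx, R, r)
        if blend <= 0:
            return np.minimum(d1, d2)
        h = np.clip(0.5 + 0.5 * (d2 - d1) / blend, 0.0, 1.0)
        return d2 + (d1 - d2) * h - blend * h * (1.0 - h)

    def mean_curvature(p):
        p = np.atleast_2d(np.asarray(p, float))
        d1 = _torus_sdf(p, -cx, R, r)
        d2 = _torus_sdf(p, +cx, R, r)
        cxs = np.where(d1 <= d2, -cx, cx)
        x = p[:, 0] - cxs
        rho = np.hypot(x, p[:, 1])
        cosphi = (rho - R) / r  # tube angle; valid on the surface
        k1 = 1.0 / r
        k2 = cosphi / np.maximum(R + r * cosphi, 1e-9)
        return 0.5 * (k1 + k2)

    half = np.array([cx + R + r, R + r, r], float)
    bounds = np.stack([-half, half])
    return SDFShape(
        name="figure_eight",
        sdf=sdf,
        bounds=bounds,
        area=2.0 * 4.0 * np.pi ** 2 * R * r,
        mean_curvature=mean_curvature,
        curvature_radius=lambda p: np.full(len(np.atleast_2d(p)), r),
    )


def make_tapered_cylinder(r0: float = 30.0, r1: float = 200.0,
                          length: float = 2000.0) -> SDFShape:
    """Capped cone along z: radius r0 at z=0 growing linearly to r1 at
    z=length. Analytic circumferential curvature 1/r(z) on the lateral
    surface makes this the curvature-recovery test object."""
    if not 0 < r0 < r1:
        raise ValueError("need 0 < r0 < r1")
    slope = (r1 - r0) / length
    cosb = 1.0 / np.hypot(1.0, slope)

    def sdf(p):
        p = np.atleast_2d(np.asarray(p, float))
        s = np.hypot(p[:, 0], p[:, 1])
        z = p[:, 2]
        # 2D signed distance in the (s, z) half-plane to the region
        # {0 <= z <= length, s <= r(z)} bounded by two caps and the slant
        inside = (z >= 0) & (z <= length) & (s <= r0 + slope * z)
        d_bottom = _segment_distance(s, z, 0.0, 0.0, r0, 0.0)
        d_top = _segment_distance(s, z, 0.0, length, r1, length)
        d_slant = _segment_distance(s, z, r0, 0.0, r1, length)
        d = np.minimum(np.minimum(d_bottom, d_top), d_slant)
        return np.where(inside, -d, d)

    def radius(p):
        p = np.atleast_2d(np.asarray(p, float))
        z = np.clip(p[:, 2], 0.0, length)
        return r0 + slope * z

    def mean_curvature(p):
        # lateral surface: principal curvatures cos(beta)/r(z) and 0
        return 0.5 * cosb / radius(p)

    rmax = r1
    bounds = np.array([[-rmax, -rmax, 0.0], [rmax, rmax, length]])
    slant = np.hypot(length, r1 - r0)
    area = np.pi * (r0 + r1) * slant + np.pi * (r0 ** 2 + r1 ** 2)
    return SDFShape(
        name="tapered_cylinder",
        sdf=sdf,
        bounds=bounds,
        area=area,
        mean_curvature=mean_curvature,
        curvature_radius=radius,
    )


def _segment_distance(px, py, ax, ay, bx, by):
    """Vectorized 2D point-to-segment distance."""
    apx, apy = px - ax, py - ay
    abx, aby = bx - ax, by - ay
    t = np.clip((apx * abx + apy * aby) / (abx * abx + aby * aby), 0.0, 1.0)
    return np.hypot(apx - t * abx, apy - t * aby)


# ----------------------------------------------------------------------
# cloud generation

@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of a simulated acquisition.

    density: membrane localizations per nm^2 of true surface.
    background_ratio: background / (background + surface) count fraction.
    sigma_median, sigma_shape: lognormal localization-precision draw (nm).
    axial_inflation: sigma_z = axial_inflation * sigma_xy (1 = isotropic).
    verification_density: density of the noise-free verification sample
        (defaults to the localization density, min 0.02 nm^-2).
    background_pad: margin (nm) added to the shape bounds to form the
        bounding volume for background points.
    """

    shape: SDFShape
    density: float = 6e-2
    background_ratio: float = 0.2
    sigma_median: float = 10.0
    sigma_shape: float = 0.3
    axial_inflation: float = 1.0
    verification_density: float | None = None
    background_pad: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not 0 <= self.background_ratio < 1:
            raise ValueError("background_ratio must be in [0, 1)")


def sample_surface(shape: SDFShape, n: int, rng: np.random.Generator,
                   shell: float = 2.0) -> np.ndarray:
    """Area-uniform sample of the zero level set: rejection sampling in a
    thin shell |SDF| < ``shell`` followed by Newton projection. The shell
    is thin relative to every curvature radius, so the area bias is
    negligible (O((shell * curvature)^2))."""
    lo = shape.bounds[0] - 2 * shell
    hi = shape.bounds[1] + 2 * shell
    vol = float(np.prod(hi - lo))
    p_hit = max(shape.area * 2 * shell / vol, 1e-6)
    out = []
    have = 0
    while have < n:
        m = int((n - have) / p_hit * 1.25) + 256
        m = min(m, 4_000_000)
        cand = rng.uniform(lo, hi, size=(m, 3))
        keep = np.abs(shape.sdf(cand)) < shell
        pts = cand[keep]
        if len(pts):
            out.append(pts)
            have += len(pts)
    pts = np.vstack(out)[:n]
    return shape.project(pts)


def simulate_localizations(spec: SimulationSpec) -> tuple[LocalizationCloud, np.ndarray]:
    """Generate (localization cloud, noise-free verification points).

    Fully determined by ``spec.seed``. Warns if fewer than 100 surface
    points result (the fit would be essentially unconstrained).
    """
    rng = np.random.default_rng(spec.seed)
    n_surface = int(round(spec.density * spec.shape.area))
    if n_surface < 100:
        import warnings

        warnings.warn(f"only {n_surface} surface localizations; "
                      "fit likely unconstrained")
    surf = sample_surface(spec.shape, n_surface, rng)

    # per-point precisions: lognormal scalar, expanded per axis
    s = rng.lognormal(mean=np.log(spec.sigma_median), sigma=spec.sigma_shape,
                      size=n_surface)
    sig_surface = np.column_stack([s, s, spec.axial_inflation * s])
    noisy = surf + rng.normal(size=surf.shape) * sig_surface

    # uniform background in the padded bounding volume
    n_bg = int(round(n_surface * spec.background_ratio
                     / (1.0 - spec.background_ratio)))
    lo = spec.shape.bounds[0] - spec.background_pad
    hi = spec.shape.bounds[1] + spec.background_pad
    bg = rng.uniform(lo, hi, size=(n_bg, 3))
    sb = rng.lognormal(np.log(spec.sigma_median), spec.sigma_shape, size=n_bg)
    sig_bg = np.column_stack([sb, sb, spec.axial_inflation * sb])

    positions = np.vstack([noisy, bg])
    sigmas = np.vstack([sig_surface, sig_bg])

    vdens = spec.verification_density
    if vdens is None:
        vdens = max(spec.density, 0.02)
    n_ver = int(round(vdens * spec.shape.area))
    verification = sample_surface(spec.shape, n_ver, rng)
    return LocalizationCloud(positions, sigmas), verification
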