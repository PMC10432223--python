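# Methods

`smlmwrap` reconstructs closed membrane surfaces from 3D single-molecule
localization microscopy (SMLM) point clouds. This note records the model,
the numerical choices, and what the synthetic-data validation does and
does not establish.

## Problem setting

SMLM yields a sparse, noisy point cloud: one localization per detected
blink, each with a per-axis precision σ = (σx, σy, σz) that varies from
point to point (axially inflated for astigmatic 3D, near-isotropic for
4Pi-type systems). A membrane-targeted label samples a closed surface;
background localizations from nonspecific binding and autofluorescence are
scattered through the volume. The task is to interpolate a closed,
oriented, manifold triangle mesh through the membrane localizations while
ignoring background — weighting each point's pull by its own precision
rather than adhering to every point.

## Objective

Vertex positions `v` minimize

    E(v) = Σ_i Σ_c r_ic²  +  λ² Σ_k ‖B_k(v) / σ_ref‖²

**Point fidelity.** Each localization `p_i` is attached to its nearest
face (exact point-to-triangle distance, KD-tree candidate pre-filter). Its
distance to the surface is approximated through a proxy point
`A_i = Σ_j w_ij v_j`, a combination of the face's three vertices with
normalized inverse-distance weights `w_ij ∝ 1/‖p_i − v_j‖`. Near the
surface the proxy distance approaches the true distance and the pull
concentrates on the closest vertex; far away the proxy tends to the face
centroid and the pull spreads evenly. The per-axis residual is

    r_ic = d_ic / [σ_ic (d_ic²/(2σ_ic²) + 1)],   d_i = p_i − A_i,

dimensionless, rising like d/σ, peaking at d = √2·σ and decaying like
2σ/d: a localization exerts most of its influence within ~2σ of its
position, so far-away background keeps only a weak hold on the surface.
Axes are treated independently, matching the camera/optical-axis alignment
of SMLM error ellipsoids.

**Bending penalty.** Per vertex k with one-ring neighbors `v_l`, centroid
`c_k`, and unit normals `n`:

    B1_k = v_k − c_k                                  (umbrella / Laplacian)
    B2_k = v_k − c_k − n_k (1/N) Σ_l (v_k − v_l)·n_k · 2/(n_k·n_l + 1)
    B_k  = (1 − α_k) B1_k + α_k B2_k

B1 is the discrete Laplacian smoothing derived from the quadratic
(Canham–Helfrich-type) bending energy; the membrane stiffness and area
prefactors are absorbed into λ. Driving ‖B1‖² to zero contracts the
surface — a closed surface under pure B1 shrinks toward a point. B2
instead penalizes deviation from the sphere locally fit through the
one-ring: on an exact sphere the normal-projection correction cancels
`v_k − c_k` to fourth order in the ring opening angle, so B2 smooths
without shrinking (verified by construction in the tests: one B2 step on a
point-free sphere changes area by <0.1%, while a B1 step of the same size
shrinks it by >1%). The blend weight

    α_k = min((Σ_i w_ik)², 1)

measures how strongly the data hold vertex k: well-constrained regions get
the area-preserving B2, data-free regions (slack, bridges between
structures) get the contracting B1 and shrink onto the data.

Dividing B by `σ_ref` (the cloud's median per-axis precision) makes both
terms dimensionless, so λ is a pure number whose useful range (~3–30)
does not drift with the precision scale, and the two terms' stiffnesses
stay within a modest factor of each other — important for the inner
solver's conditioning.

## Pipeline

1. **Octree density field.** Localizations go into a sparse octree
   truncated at `min_points` per cell (default 50). A cell subdivides
   while the children above the cutoff retain ≥70% of its points; this
   drills down on dense membrane regions without shedding uniformly
   filled cells' mass into sub-threshold octants. Unstored cells have
   implicit density zero. The root box is the cloud's bounding box padded
   by twice the largest σ and squared to a cube; the maximum depth keeps
   the finest cell at or above the median precision.
2. **Starting isosurface.** Leaf densities are rasterized onto a uniform
   grid at the deepest leaf level, lightly smoothed (Gaussian, σ = 1
   cell) to suppress shot-noise fenestrations, and an isosurface is
   extracted by marching cubes, cleaned to a closed oriented manifold.
   The default threshold is self-calibrating: each localization is
   assigned the grid density at its own position, an Otsu split of the
   log densities separates membrane from background points, and the
   threshold is set at the 10% quantile of the membrane class — low
   enough that the surface starts *outside* the membrane and encloses
   nearly all of it, high enough to hug the data and exclude background.
   The threshold remains the primary user-facing knob besides λ: thick
   noise shells (large σ relative to the structure) warrant a lower
   factor, and the tapered-cylinder analyses here use 0.6× with the 5%
   quantile. Under-segmentation (nearby structures joined) is accepted
   and corrected later; over-segmentation is deliberately avoided.
3. **Outer loop.** Repeat until convergence or `max_iterations` (60):
   refresh correspondences, run the inner solve, and every 5 iterations
   remesh toward the scheduled edge length and remove necks. The target
   edge length decreases linearly from the start mesh's mean edge to
   `max(floor, 0.4 × min_i min-axis σ_i)` — sampling just below the best
   localization precision — reaching the final value one remesh interval
   before the end so a few wrap iterations run on the final tessellation.
   The floor defaults to 5 nm; analyses in this repository run at 8–20 nm
   floors, which keeps meshes at a few tens of thousands of faces (the
   extra discretization error, ~ℓ²/8r, is a fraction of a nanometer for
   the structures used). Convergence: RMS vertex displacement below
   `tol × current target edge` (tol = 0.01), evaluated once the final
   tessellation is reached. A divergence guard aborts if the pre-solve
   energy grows >1% across three consecutive comparable iterations.
4. **Inner solve.** The correspondences, weights w, the robust
   deweighting fraction u = 1/(d²/(2σ²)+1), α, and the normals are frozen;
   the inner objective Σ(u·d/σ)² + λ²Σ‖B/σ_ref‖² is then smooth with an
   analytic gradient (verified against central differences to <1e-4
   relative). Freezing u is the iteratively-reweighted reading of the
   robust residual: differentiating r directly would make points repel
   the surface beyond √2σ, stalling the wrap a few σ from the data.
   Minimization is nonlinear conjugate gradients (Polak–Ribière+ with
   restarts), Jacobi-preconditioned by the frozen Hessian diagonal —
   without preconditioning, data-poor or axially-imprecise regions are
   orders of magnitude softer than the bending modes and crawl. A
   backtracking Armijo line search starts from the directional
   second-derivative step; a per-step trust region (0.3× mean edge)
   prevents a face from leaping onto a distant point cluster within one
   frozen-correspondence solve.

## Remeshing and neck removal

Incremental isotropic remeshing with the standard thresholds: split edges
>4/3 of target, collapse edges <4/5 (rejecting collapses that break the
link condition or create over-long edges), flip edges toward valence 6,
then relax vertices toward their area-weighted one-ring centroid
projected into the tangent plane (tangential only, so remeshing does not
fight the optimizer). Each pass preserves closedness, orientation, and
manifoldness, and the Euler characteristic is untouched by construction.

Neck removal deletes vertices the mesh cannot physically represent and
stitches each resulting boundary loop with a centroid fan (the deletion
set is grown until the loops are disjoint simple cycles). Detectors:

- Gaussian curvature below −`scale`/ℓ² (scale = 2): a saddle with
  curvature radius under the current edge length ℓ.
- Endpoints of sub-0.4ℓ edges whose collapse violates the link condition:
  tubes or handles that remeshing provably cannot simplify.
- Optional (`pinch_fraction` > 0): vertices with an opposing-normal
  vertex within `pinch_fraction × ℓ`. A waist thinner than one edge has
  no vertex on it, so its discrete K stays moderate — this detector
  catches those sub-resolution waists and squeezed slabs. It is off by
  default because it also severs legitimately close membrane walls;
  enable it when wrapping structures known to be separate.

Components that carry essentially no data influence (mean α < 0.1) or
that fall below a few triangles at the current resolution are dropped as
debris; the largest component is always kept.

## Synthetic data

Shapes are signed distance functions: sphere; figure-eight built as the
hard min of two exact torus SDFs touching at a point (overall extent
800 nm, tube thickness 100 nm; ring radius 150 nm, tube radius 50 nm);
tapered cylinder (capped cone, radius 30→200 nm over 2000 nm) with
analytic circumferential curvature for recovery tests. Localizations are
area-uniform surface samples (thin-shell rejection + Newton projection;
the area bias is O((shell×curvature)²), negligible here), displaced per
axis by Gaussian noise with per-point σ drawn from a lognormal (median
10 nm, shape 0.3 — a realistic precision spread; not varied in the
validation since rescaling σ is equivalent to rescaling the structure).
Background points are uniform in the padded bounding box at a count set
by the background fraction. Verification points are a separate, denser,
noise-free surface sample. Everything is a pure function of the seed.

Not modeled: fluorophore blinking clusters (one fluorophore appearing as
several correlated localizations), label linkage error, and structured
(non-uniform) background. Passing the synthetic suite therefore shows
correct behavior under independent-noise conditions; on real data,
blinking clusters effectively raise local density and correlate errors,
which the precision weighting does not explicitly model.

## Quality metrics

Q1 is the mean squared distance from noise-free verification points to
their nearest neighbors in an area-uniform sample of the fitted mesh
(misses of the true structure); Q2 the reverse (spurious surface: blebs,
slack, debris); Q = √((Q1+Q2)/2) in nm. Mesh sampling density defaults to
matching the verification density so both directions see comparable
nearest-neighbor spacing. Curvature recovery compares ring-averaged
discrete mean curvature (cotangent Laplacian with Meyer mixed areas;
angle-deficit Gaussian curvature) against the analytic value at each
vertex's projection onto the true surface, binned by true radius. The
ring averaging (20–30 rounds ≈ a 5-edge geodesic window) is part of the
estimator: single-vertex discrete curvature has noise comparable to the
signal whenever the radius is much larger than the edge length, while
membrane curvature varies on much longer scales.

## Known limitations

- Nearest-correspondence fitting of noisy points on a convex surface has
  an intrinsic outward bias of order 2σ_n²/R (σ_n = precision along the
  normal, R = curvature radius): points displaced outward occupy larger
  shells. For σ = 10 nm on 50 nm tubes this is ~4 nm — part of why the
  surface error approaches but does not vanish below σ. With strongly
  anisotropic precision (σz = 3σxy) the bias at surface poles is set by
  σz and dominates the error there; reconstructions remain well below σz
  but do not reach the planar-precision floor.
- Holes and fenestrations below ~3× the precision are biased closed by
  the conservative start, by design: spanning membranes over unresolved
  holes (drums and squeezed slabs) are flat and exert no bending force,
  so nothing reopens them once formed.
- A bridge between two distant wrapped structures contracts under B1 as a
  local diffusion process (rate ~ℓ²/2ρ per sweep); widely separated
  structures joined by a long fat bridge may not pinch within the
  iteration budget. In practice the density start only joins *nearby*
  structures, whose short bridges pinch quickly.
- λ trades fidelity against smoothness; its optimum grows with density
  and background (the surface must average more, and harder). The minimum
  is broad: on the figure-eight study condition, λ = 10 and λ = 30 differ
  in Q by ~2×, and the grid {3, 10, 30} brackets the optimum across the
  tested density/background grid.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script reconstruct at edge-length
floors of 8–20 nm with 25–60 outer iterations (meshes of 10⁴–10⁵ faces,
clouds of 4×10³–7×10⁴ localizations), chosen as the package's standard
desk-scale configuration; the 5 nm production floor is exercised through
the schedule tests. Simulation conditions (shape dimensions, densities,
background fractions, precisions) are never scaled.
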