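"""Map membrane curvature along a tapered tubule and compare with truth.

The tapered cylinder's radius runs 30 -> 200 nm over 2000 nm, so the
circumferential curvature sweeps over nearly an order of magnitude. The
reconstruction tracks it where the radius exceeds ~3x the localization
precision and underestimates it below — the resolution limit of
curvature from point-cloud wrapping.
"""

import numpy as np

import smlmwrap as sw

shape = sw.make_tapered_cylinder(r0=30.0, r1=200.0, length=2000.0)
spec = sw.SimulationSpec(shape=shape, density=2e-2, background_ratio=0.0,
                         sigma_median=15.0, sigma_shape=1e-6, seed=5,
                         verification_density=0.02)
cloud, verification = sw.simulate_localizations(spec)
print(f"simulated {len(cloud)} localizations at sigma = 15 nm")

config = sw.FitConfig(curvature_weight=30.0, max_iterations=50,
                      edge_length_floor=20.0,
                      density_factor=0.6, density_quantile=0.05)
mesh, _ = sw.fit(cloud, config)
print(f"fitted surface: {mesh.n_vertices} vertices, "
      f"Q = {sw.surface_error(mesh, verification, seed=1).q:.2f} nm")

# pair each vertex's (smoothed) discrete mean curvature with the analytic
# value at its projection onto the true surface, binned by true radius
proj = shape.project(mesh.vertices, iterations=10)
lateral = (proj[:, 2] > 120) & (proj[:, 2] < 1800) \
    & (np.abs(shape.sdf(mesh.vertices)) < 40)
bins = np.array([20.0, 45.0, 80.0, 120.0, 160.0, 210.0])
res = sw.curvature_recovery(mesh, shape, radius_bins=bins,
                            smooth_rounds=30, vertex_mask=lateral)
print("radius bin (nm)   median |rel error|   median signed error")
for b in range(len(bins) - 1):
    print(f"  {bins[b]:4.0f}-{bins[b + 1]:4.0f}          "
          f"{res['bin_median_abs_rel_error'][b]:+.2f}              "
          f"{res['bin_median_signed_rel_error'][b]:+.2f}")
print("(negative signed error below ~45 nm = 3 sigma: curvature there is "
      "systematically underestimated)")
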