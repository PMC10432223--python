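"""Reconstruct a figure-eight membrane from a simulated SMLM cloud.

Simulates localizations on two touching tori (~800 nm across, 100 nm
thick tubes) with 10 nm median precision and 20% background, wraps a
surface onto them, and scores it against noise-free verification points.
A surface error Q below the localization precision means the wrap
averaged out the per-point noise.
"""

import numpy as np

import smlmwrap as sw

shape = sw.make_figure_eight(diameter=800.0, thickness=100.0)
spec = sw.SimulationSpec(shape=shape, density=6e-2, background_ratio=0.2,
                         sigma_median=10.0, sigma_shape=0.3, seed=42)
cloud, verification = sw.simulate_localizations(spec)
print(f"simulated {len(cloud)} localizations "
      f"({spec.background_ratio:.0%} background)")

config = sw.FitConfig(curvature_weight=30.0, max_iterations=50,
                      edge_length_floor=12.0)
mesh, trace = sw.fit(cloud, config)
print(f"fitted surface: {mesh.n_vertices} vertices, "
      f"{mesh.n_components} component(s), "
      f"genus {(2 * mesh.n_components - mesh.euler_characteristic) // 2}")

report = sw.surface_error(mesh, verification, seed=1)
print(f"surface error: Q1={report.q1:.1f} nm^2  Q2={report.q2:.1f} nm^2  "
      f"Q={report.q:.2f} nm  (localization precision: 10 nm)")

sw.write_mesh(mesh, "figure_eight_fit.ply",
              scalars={"mean_curvature": mesh.mean_curvature})
print("wrote figure_eight_fit.ply with per-vertex mean curvature (1/nm); "
      "color by it to see tube curvature ~1/50 nm^-1")
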