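"""Two-color analysis: distance between two independently fitted membranes.

Emulates a membrane-contact-site measurement: two concentric spherical
membranes 30 nm apart are imaged as separate channels, each channel is
wrapped independently, and the separation is read off as the per-vertex
distance from one surface to the other — the quantity visualized as a
color map on real two-color data.
"""

import numpy as np

import smlmwrap as sw

config = sw.FitConfig(curvature_weight=30.0, max_iterations=30,
                      edge_length_floor=10.0)
meshes = []
for radius, seed in ((100.0, 1), (130.0, 2)):
    shape = sw.make_sphere(radius)
    spec = sw.SimulationSpec(shape=shape, density=4e-2, background_ratio=0.1,
                             sigma_median=8.0, seed=seed)
    cloud, _ = sw.simulate_localizations(spec)
    mesh, _ = sw.fit(cloud, config)
    meshes.append(mesh)
    r = np.linalg.norm(mesh.vertices, axis=1)
    print(f"channel radius {radius:.0f} nm: fitted {mesh.n_vertices} "
          f"vertices, median radius {np.median(r):.1f} nm")

inner, outer = meshes
d = sw.mesh_to_mesh_distance(inner, outer)
print(f"membrane separation: median {np.median(d):.1f} nm "
      f"(truth: 30 nm), IQR {np.percentile(d, 25):.1f}-"
      f"{np.percentile(d, 75):.1f} nm")
sw.write_mesh(inner, "inner_membrane.ply", scalars={"separation_nm": d})
print("wrote inner_membrane.ply with the separation as a per-vertex scalar")
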