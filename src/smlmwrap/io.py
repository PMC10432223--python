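"""Reading and writing localization tables and surface meshes.

Localization tables are delimited text (CSV/TSV, header row required) or
HDF5 column tables. All coordinates and precisions are interpreted as
nanometers; a ``unit_scale`` factor converts on read if the file is in
other units (e.g. 1000 for micrometers).

Meshes are written as PLY (binary or ascii; supports per-vertex scalar
channels such as mean curvature for rendering) or STL.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .cloud import LocalizationCloud
from .mesh import TriangleMesh

log = logging.getLogger(__name__)

#: candidate column names tried (case-insensitively) when no explicit
#: column_map entry is given
_DEFAULT_CANDIDATES = {
    "x": ("x", "x_nm", "xnm", "pos_x"),
    "y": ("y", "y_nm", "ynm", "pos_y"),
    "z": ("z", "z_nm", "znm", "pos_z"),
    "sx": ("sx", "sigma_x", "sigmax", "x_sigma", "error_x", "lpx"),
    "sy": ("sy", "sigma_y", "sigmay", "y_sigma", "error_y", "lpy"),
    "sz": ("sz", "sigma_z", "sigmaz", "z_sigma", "error_z", "lpz"),
    "sigma": ("sigma", "error", "locprec", "precision", "uncertainty"),
}


class SchemaError(ValueError):
    """A required column could not be resolved in the input table."""


def _resolve(columns, key, column_map):
    if column_map and key in column_map:
        name = column_map[key]
        return name if name in columns else None
    lower = {c.lower(): c for c in columns}
    for cand in _DEFAULT_CANDIDATES[key]:
        if cand in lower:
            return lower[cand]
    return None


def _read_table(path: str, hdf5_key: str) -> pd.DataFrame:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5", ".hdf"):
        import h5py

        with h5py.File(path, "r") as f:
            if hdf5_key not in f:
                raise SchemaError(f"HDF5 key {hdf5_key!r} not found in {path}")
            node = f[hdf5_key]
            if isinstance(node, h5py.Group):
                return pd.DataFrame({k: np.asarray(node[k]) for k in node})
            arr = np.asarray(node)
            if arr.dtype.names:  # compound table
                return pd.DataFrame({k: arr[k] for k in arr.dtype.names})
            raise SchemaError("HDF5 node is neither a column group nor a compound table")
    sep = "\t" if ext in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_localizations(
    path: str,
    column_map: dict | None = None,
    default_sigma=None,
    axial_inflation: float = 1.0,
    unit_scale: float = 1.0,
    hdf5_key: str = "localizations",
) -> LocalizationCloud:
    """Read a localization table into a :class:`LocalizationCloud`.

    Parameters
    ----------
    column_map : dict, optional
        Maps the logical names ``x, y, z, sx, sy, sz, sigma`` to column
        names in the file. Unmapped names are resolved from common aliases.
    default_sigma : length-3 sequence, optional
        Per-axis precision (nm) used when the table carries no precision
        columns at all.
    axial_inflation : float
        When only a scalar ``sigma`` column is present, precisions are
        expanded to ``(sigma, sigma, axial_inflation * sigma)``; use ~3 for
        astigmatic 3D data, 1 for near-isotropic (4Pi) data.
    unit_scale : float
        Multiplied into all coordinates and precisions (file units -> nm).

    Rows with non-finite coordinates are dropped (counted in the log);
    non-positive precisions raise a validation error.
    """
    df = _read_table(path, hdf5_key)

    coord_cols = []
    for key in ("x", "y", "z"):
        col = _resolve(df.columns, key, column_map)
        if col is None:
            raise SchemaError(f"coordinate column {key!r} not found in {list(df.columns)}")
        coord_cols.append(col)
    positions = df[coord_cols].to_numpy(dtype=np.float64)

    per_axis = [_resolve(df.columns, k, column_map) for k in ("sx", "sy", "sz")]
    scalar = _resolve(df.columns, "sigma", column_map)
    if all(c is not None for c in per_axis):
        sigmas = df[per_axis].to_numpy(dtype=np.float64)
    elif scalar is not None:
        s = df[scalar].to_numpy(dtype=np.float64)
        sigmas = np.column_stack([s, s, axial_inflation * s])
    elif default_sigma is not None:
        ds = np.asarray(default_sigma, dtype=np.float64).reshape(3)
        sigmas = np.tile(ds, (len(positions), 1))
    else:
        raise SchemaError(
            "no precision columns (sx/sy/sz or sigma) and no default_sigma given"
        )

    keep = np.isfinite(positions).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d rows with non-finite coordinates", n_dropped)
        positions, sigmas = positions[keep], sigmas[keep]

    if not np.isfinite(sigmas).all() or (sigmas <= 0).any():
        raise ValueError("localization precisions must be finite and > 0")

    return LocalizationCloud(positions * unit_scale, sigmas * unit_scale)


def write_localizations(cloud: LocalizationCloud, path: str,
                        hdf5_key: str = "localizations") -> None:
    """Write a cloud in the same schema the reader consumes (CSV/TSV/HDF5)."""
    df = pd.DataFrame(
        np.hstack([cloud.positions, cloud.sigmas]),
        columns=["x", "y", "z", "sx", "sy", "sz"],
    )
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5", ".hdf"):
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group(hdf5_key)
            for c in df.columns:
                g.create_dataset(c, data=df[c].to_numpy())
    else:
        sep = "\t" if ext in (".tsv", ".txt") else ","
        df.to_csv(path, sep=sep, index=False)


# ----------------------------------------------------------------------
# meshes

def write_mesh(mesh: TriangleMesh, path: str, file_format: str | None = None,
               scalars: dict | None = None, binary: bool = True) -> None:
    """Write a mesh as PLY or STL (inferred from the extension by default).

    Per-vertex scalar channels (``scalars={"mean_curvature": H}``) are
    stored as PLY vertex properties; STL cannot carry them.
    """
    import trimesh as _tm

    fmt = (file_format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt not in ("ply", "stl"):
        raise ValueError(f"unsupported mesh format {fmt!r} (use PLY or STL)")
    tm = _tm.Trimesh(mesh.vertices, mesh.faces, process=False)
    if scalars:
        if fmt == "stl":
            log.warning("STL cannot store per-vertex scalars; dropping %s",
                        sorted(scalars))
        else:
            for name, vals in scalars.items():
                vals = np.asarray(vals, dtype=np.float32)
                if len(vals) != mesh.n_vertices:
                    raise ValueError(f"scalar {name!r} length mismatch")
                tm.vertex_attributes[name] = vals
    if fmt == "ply":
        from trimesh.exchange.ply import export_ply

        data = export_ply(tm, encoding="binary" if binary else "ascii",
                          include_attributes=True)
        with open(path, "wb") as f:
            f.write(data)
    else:
        tm.export(path, file_type="stl")


def read_mesh(path: str) -> tuple[TriangleMesh, dict]:
    """Read a PLY/STL mesh; returns (mesh, per-vertex scalar channels)."""
    import trimesh as _tm

    tm = _tm.load(path, process=False)
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if os.path.splitext(path)[1].lower() == ".stl":
        # STL stores loose triangles; merge coincident corners
        tm.merge_vertices()
        verts = np.asarray(tm.vertices, dtype=np.float64)
        faces = np.asarray(tm.faces, dtype=np.int64)
    scalars = {}
    raw = tm.metadata.get("_ply_raw")
    if raw and "vertex" in raw:
        data = raw["vertex"]["data"]
        if isinstance(data, dict):
            items = data.items()
        elif getattr(data, "dtype", None) is not None and data.dtype.names:
            items = ((n, data[n]) for n in data.dtype.names)
        else:
            items = ()
        for name, arr in items:
            if name in ("x", "y", "z", "nx", "ny", "nz"):
                continue
            arr = np.asarray(arr).reshape(-1)
            if len(arr) == len(verts) and np.issubdtype(arr.dtype, np.number):
                scalars[name] = arr.astype(np.float64)
    return TriangleMesh(verts, faces), scalars
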