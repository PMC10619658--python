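"""Config files, CSV outputs and legacy-ASCII VTK field export."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

__all__ = ["save_config", "load_config", "write_vtk_fields",
           "write_probe_csv", "export_frame_meshes"]


def save_config(obj, path):
    """YAML dump of a (nested) dataclass configuration."""
    def clean(x):
        if dataclasses.is_dataclass(x):
            return {k: clean(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x
    Path(path).write_text(yaml.safe_dump(clean(obj), sort_keys=False))
    return str(path)


def load_config(cls, path):
    """Instantiate a dataclass from a YAML mapping (extra keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**data)


def write_vtk_fields(path, scaling, rho=None, u=None, nu_t=None,
                     vorticity=None):
    """Legacy-ASCII VTK STRUCTURED_POINTS file with the given fields
    (physical units), readable by ParaView and meshio."""
    fields = {}
    shape = None
    if rho is not None:
        fields["density"] = np.asarray(rho) * scaling.rho_phys
    if u is not None:
        fields["velocity"] = scaling.u_to_physical(np.asarray(u))
        shape = fields["velocity"].shape[1:]
    if nu_t is not None:
        fields["eddy_viscosity"] = np.asarray(nu_t) * scaling.dx ** 2 / scaling.dt
    if vorticity is not None:
        fields["vorticity"] = np.asarray(vorticity) / scaling.dt
    if not fields:
        raise ValueError("nothing to write")
    for v in fields.values():
        shape = v.shape[-3:]
    nx, ny, nz = shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncanopyflow fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {scaling.dx} {scaling.dx} {scaling.dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            if arr.ndim == 4:  # vector
                fh.write(f"VECTORS {name} double\n")
                # VTK expects x varying fastest
                v = arr.transpose(0, 3, 2, 1).reshape(3, -1)
                for i in range(v.shape[1]):
                    fh.write(f"{v[0, i]:.6e} {v[1, i]:.6e} {v[2, i]:.6e}\n")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                v = arr.transpose(2, 1, 0).ravel()
                fh.write("\n".join(f"{x:.6e}" for x in v))
                fh.write("\n")
    return str(path)


def write_probe_csv(path, table):
    table.to_csv(path, index=False)
    return str(path)


def export_frame_meshes(record, out_dir, leaves_only=True, step=1):
    """OBJ sequence of the deformed shell, one file per frame."""
    import trimesh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(0, len(record.frames), step):
        verts, faces = record.frame_mesh(i, leaves_only=leaves_only)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        p = out / f"frame_{i:04d}.obj"
        mesh.export(p)
        paths.append(str(p))
    return paths
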