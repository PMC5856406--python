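"""Field container I/O and interoperability exports.

The native container is an HDF5 file holding the grid metadata, the lumen
mask, the per-(phase, replicate) velocity arrays and a provenance block
(generator parameters, seeds, software version).  Round trips are
bitwise.  Single fields can additionally be exported to legacy-ASCII VTK
structured points and to a plain column table for PIV-community tools
(both lossy: float32 / fixed-precision text).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np

from rootflow.geometry import Grid
from rootflow.synth import PhaseEnsemble, VelocityField

__all__ = [
    "FieldContainer",
    "SchemaError",
    "write_fields",
    "read_fields",
    "container_from_ensemble",
    "export_vtk",
    "export_table",
]

MAGIC = "ROOTFLOW-FIELDS"
SCHEMA_VERSION = 1


class SchemaError(IOError):
    """Container file does not match the expected schema/version."""


@dataclass
class FieldContainer:
    """In-memory image of the field container."""

    grid: Grid
    mask: np.ndarray
    phase_times: np.ndarray
    fields: dict[tuple[int, int], np.ndarray]  # (j, k) -> (3, nx, ny, nz)
    provenance: dict = dc_field(default_factory=dict)

    def velocity_field(self, j: int, k: int) -> VelocityField:
        return VelocityField(
            grid=self.grid, u=self.fields[(j, k)], mask=self.mask,
            t=float(self.phase_times[j]), replicate=k,
        )


def container_from_ensemble(ensemble: PhaseEnsemble) -> FieldContainer:
    """Materialize a synthetic ensemble into a container (generates every
    field; intended for grids that fit in memory)."""
    fields = {
        (j, k): ensemble.field(j, k).u
        for j in range(ensemble.n_phases)
        for k in range(ensemble.n_replicates)
    }
    return FieldContainer(
        grid=ensemble.grid,
        mask=ensemble.mask,
        phase_times=ensemble.phase_times,
        fields=fields,
        provenance=ensemble.provenance,
    )


def write_fields(container: FieldContainer, path) -> None:
    """Write a container to HDF5 (bitwise round-trip with
    :func:`read_fields`)."""
    from rootflow import __version__

    with h5py.File(path, "w") as f:
        f.attrs["magic"] = MAGIC
        f.attrs["schema_version"] = SCHEMA_VERSION
        prov = dict(container.provenance)
        prov.setdefault("software", f"rootflow {__version__}")
        f.attrs["provenance"] = json.dumps(prov)
        g = f.create_group("grid")
        g.attrs["origin_mm"] = container.grid.origin
        g.attrs["spacing_mm"] = container.grid.spacing
        g.attrs["counts"] = container.grid.counts
        g.attrs["axis_convention"] = "Y is the vessel axis; front sinus at +Z"
        f.create_dataset("mask", data=container.mask, compression="gzip")
        f.create_dataset("phase_times_s", data=container.phase_times)
        grp = f.create_group("fields")
        for (j, k), u in sorted(container.fields.items()):
            grp.create_dataset(f"j{j:02d}_k{k:02d}", data=u, compression="gzip")


def read_fields(path) -> FieldContainer:
    """Read a container written by :func:`write_fields`.

    Raises :class:`SchemaError` naming the versions on mismatch.
    """
    with h5py.File(path, "r") as f:
        if f.attrs.get("magic") != MAGIC:
            raise SchemaError(
                f"not a rootflow field container (magic {f.attrs.get('magic')!r})"
            )
        ver = int(f.attrs.get("schema_version", -1))
        if ver != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {ver} not supported (expected {SCHEMA_VERSION})"
            )
        g = f["grid"]
        grid = Grid(
            origin=tuple(float(v) for v in g.attrs["origin_mm"]),
            spacing=tuple(float(v) for v in g.attrs["spacing_mm"]),
            counts=tuple(int(v) for v in g.attrs["counts"]),
        )
        mask = f["mask"][()].astype(bool)
        phase_times = f["phase_times_s"][()]
        fields = {}
        for name, ds in f["fields"].items():
            j, k = int(name[1:3]), int(name[5:7])
            fields[(j, k)] = ds[()]
        provenance = json.loads(f.attrs.get("provenance", "{}"))
    return FieldContainer(grid=grid, mask=mask, phase_times=phase_times,
                          fields=fields, provenance=provenance)


def export_vtk(field: VelocityField, path) -> None:
    """Legacy-ASCII VTK structured-points export of one field (float32
    precision; validity encoded as a separate scalar array)."""
    grid = field.grid
    nx, ny, nz = grid.counts
    u = field.u.astype(np.float32)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("rootflow velocity field (lossy float32 export)\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write("ORIGIN {:.6g} {:.6g} {:.6g}\n".format(*grid.origin))
        f.write("SPACING {:.6g} {:.6g} {:.6g}\n".format(*grid.spacing))
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("VECTORS velocity float\n")
        # VTK expects x fastest: iterate z, y, x -> transpose to (z, y, x)
        vec = np.stack([u[0], u[1], u[2]], axis=-1).transpose(2, 1, 0, 3)
        for row in vec.reshape(-1, 3):
            f.write("{:.7g} {:.7g} {:.7g}\n".format(*row))
        f.write("SCALARS valid int 1\nLOOKUP_TABLE default\n")
        for v in field.mask.transpose(2, 1, 0).ravel():
            f.write(f"{int(v)}\n")


def export_table(field: VelocityField, path) -> None:
    """Column-text export: one row per voxel with X_mm, Y_mm, Z_mm,
    Ux_ms, Uy_ms, Uz_ms, valid."""
    x, y, z = field.grid.meshgrid()
    cols = np.column_stack(
        [
            x.ravel(), y.ravel(), z.ravel(),
            field.u[0].ravel(), field.u[1].ravel(), field.u[2].ravel(),
            field.mask.ravel().astype(int),
        ]
    )
    header = "X_mm Y_mm Z_mm Ux_ms Uy_ms Uz_ms valid"
    np.savetxt(path, cols, header=header,
               fmt=["%.4f", "%.4f", "%.4f", "%.6e", "%.6e", "%.6e", "%d"])
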