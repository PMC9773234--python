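"""File I/O: extended-XYZ and legacy-VTK snapshots, event CSV, manifests.

Snapshot columns (extended-XYZ ``Properties`` string):

=========  =======================================================
species    ``P`` microparticle / ``E`` cell element
pos        x y z (dimensionless)
diameter   sphere diameter
density    relative density (particles) or mass scale (elements)
flag       particles: 1 mobile / 0 immobile; elements: layer index
=========  =======================================================
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .dem import GranularBed

__all__ = [
    "write_xyz",
    "read_xyz_bed",
    "write_vtk_points",
    "write_event_log",
    "write_manifest",
]


def write_xyz(path, bed: GranularBed, cell=None, comment: str = "", append: bool = False) -> None:
    """Write one extended-XYZ frame (bed, optionally followed by the cell)."""
    n = bed.n + (cell.n_elements if cell is not None else 0)
    lat = f'Lattice="{bed.box[0]:.17g} 0 0 0 {bed.box[1]:.17g} 0 0 0 {bed.box[2]:.17g}"'
    props = "Properties=species:S:1:pos:R:3:diameter:R:1:density:R:1:flag:I:1"
    lines = [str(n), f"{lat} {props} floor_z={bed.floor_z:.17g} {comment}".rstrip()]
    for i in range(bed.n):
        p = bed.positions[i]
        lines.append(
            f"P {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {bed.diameters[i]:.17g} "
            f"{bed.relative_density[i]:.17g} {1 if bed.mobile[i] else 0}"
        )
    if cell is not None:
        for i in range(cell.n_elements):
            p = cell.positions[i]
            lines.append(
                f"E {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                f"{cell.element_diameter:.17g} {cell.mass_scale[i]:.17g} "
                f"{cell.template.layer_index[i]}"
            )
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz_bed(path) -> GranularBed:
    """Read the first frame of an extended-XYZ file back into a bed.

    Particle rows only (species ``P``); positions and diameters round-trip
    exactly (written with 17 significant digits).
    """
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        rows = [fh.readline().split() for _ in range(n)]
    box = (20.0, 20.0, 20.0)
    if 'Lattice="' in header:
        lat = header.split('Lattice="')[1].split('"')[0].split()
        box = (float(lat[0]), float(lat[4]), float(lat[8]))
    floor_z = 1.0
    for tok in header.split():
        if tok.startswith("floor_z="):
            floor_z = float(tok.split("=")[1])
    rows = [r for r in rows if r[0] == "P"]
    pos = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    diam = np.array([float(r[4]) for r in rows])
    dens = np.array([float(r[5]) for r in rows])
    mob = np.array([int(r[6]) == 1 for r in rows])
    return GranularBed(
        positions=pos,
        diameters=diam,
        relative_density=dens,
        mobile=mob,
        box=box,
        floor_z=floor_z,
    )


def write_vtk_points(path, bed: GranularBed, cell=None) -> None:
    """Legacy-VTK point cloud with per-point diameter and body type."""
    pts = [bed.positions]
    diam = [bed.diameters]
    kind = [np.zeros(bed.n)]
    if cell is not None:
        pts.append(cell.positions)
        diam.append(np.full(cell.n_elements, cell.element_diameter))
        kind.append(np.ones(cell.n_elements))
    pts = np.vstack(pts)
    diam = np.concatenate(diam)
    kind = np.concatenate(kind)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngranulocell snapshot\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS diameter double 1\nLOOKUP_TABLE default\n")
        for d in diam:
            fh.write(f"{d:.17g}\n")
        fh.write("SCALARS body_type int 1\nLOOKUP_TABLE default\n")
        for k in kind:
            fh.write(f"{int(k)}\n")


def write_event_log(path, events) -> None:
    """Bond event log as CSV: step, element, particle, event, force."""
    df = pd.DataFrame(
        [
            {
                "step": e.step,
                "element_id": e.element_id,
                "particle_id": e.particle_id,
                "event": e.event,
                "force": e.force,
            }
            for e in events
        ]
    )
    df.to_csv(path, index=False)


def write_manifest(path, params: dict, seeds: dict) -> None:
    """JSON run manifest: full parameter set, resolved seeds, version."""
    from . import __version__

    payload = {
        "package": "granulocell",
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": params,
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
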