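"""Small deterministic scenes for tests and examples.

Each fixture is sub-second to simulate and fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import init_cell
from .dem import GranularBed, generate_particles

__all__ = ["Scene", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "two_particle_collision",
    "three_particle_pocket",
    "flat_rigid_plane",
    "mini_bed_4x4",
)


@dataclass
class Scene:
    name: str
    bed: GranularBed
    cell_L_i: float | None = None
    drop_position: tuple[float, float] | None = None


def make_fixture(name: str, seed: int = 0) -> Scene:
    """Build one of the named miniature scenes.

    two_particle_collision
        One particle resting on the floor (immobile) and one dropped from a
        seed-dependent height above it, head on — the restitution probe.
    three_particle_pocket
        Three mutually touching immobile unit spheres; a cell template fits
        the pocket above their centroid.
    flat_rigid_plane
        An empty bed: the floor plane is the only support.
    mini_bed_4x4
        One-layer 16-particle bed in a (4d)^3 box, unsettled.
    """
    rng = np.random.default_rng(seed)
    if name == "two_particle_collision":
        h = rng.uniform(0.3, 0.8)
        box = (6.0, 6.0, 10.0)
        pos = np.array(
            [
                [3.0, 3.0, 1.5],
                [3.0, 3.0, 2.5 + h],
            ]
        )
        bed = GranularBed(
            positions=pos,
            diameters=np.ones(2),
            mobile=np.array([False, True]),
            box=box,
            floor_z=1.0,
            target_layers=1,
            seed=seed,
        )
        return Scene(name, bed)
    if name == "three_particle_pocket":
        box = (8.0, 8.0, 8.0)
        c = np.array([4.0, 4.0])
        # equilateral triangle of touching unit spheres
        ang = np.array([90.0, 210.0, 330.0]) * np.pi / 180.0
        r_tri = 1.0 / np.sqrt(3.0)
        pos = np.column_stack(
            [
                c[0] + r_tri * np.cos(ang),
                c[1] + r_tri * np.sin(ang),
                np.full(3, 1.5),
            ]
        )
        bed = GranularBed(
            positions=pos,
            diameters=np.ones(3),
            mobile=np.zeros(3, dtype=bool),
            relative_density=np.full(3, np.inf),
            box=box,
            floor_z=1.0,
            target_layers=1,
            seed=seed,
        )
        return Scene(name, bed, cell_L_i=1.0, drop_position=(float(c[0]), float(c[1])))
    if name == "flat_rigid_plane":
        bed = GranularBed(
            positions=np.zeros((0, 3)),
            diameters=np.zeros(0),
            box=(8.0, 8.0, 8.0),
            floor_z=1.0,
            target_layers=0,
            seed=seed,
        )
        return Scene(name, bed, cell_L_i=1.0, drop_position=(4.0, 4.0))
    if name == "mini_bed_4x4":
        bed = generate_particles(1, box=(4.0, 4.0, 8.0), seed=seed)
        return Scene(name, bed)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
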