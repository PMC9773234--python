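"""Granular bed: polydisperse microsphere generation and gravity settling.

The bed is a loose random packing obtained by dropping non-overlapping,
randomly placed spheres under gravity in a box that is periodic in x/y and
bounded below by a plane.  Collisions are normal-only linear springs with a
stiffer loading than unloading branch (Walton-Braun type hysteresis), which
makes every collision inelastic with restitution ``sqrt(Y_l/Y_u)`` and lets
the packing relax quickly.  There are no rotational degrees of freedom, no
friction and no cohesion.

All lengths are in units of the mean particle diameter ``d``; gravity is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PlacementError

__all__ = [
    "ContactLaw",
    "GranularBed",
    "generate_particles",
    "contact_force",
    "floor_contact_force",
    "settle_bed",
]

#: default bed relaxation threshold: mean kinetic energy per particle
KE_THRESHOLD = 2e-3
#: default integration time step (dimensionless)
DT = 5e-5


@dataclass(frozen=True)
class ContactLaw:
    """Hysteretic normal contact stiffnesses, per unit contact diameter.

    The force on an overlapping pair is ``Y * delta`` with ``Y = y_u * s``
    while the pair approaches and ``Y = y_l * s`` while it separates, where
    ``s`` is the mean diameter of the pair (the particle's own diameter for
    wall contacts).
    """

    y_u: float = 5e4
    y_l: float = 5e3

    def __post_init__(self) -> None:
        if not (self.y_u > self.y_l > 0):
            raise ValueError(
                f"need y_u > y_l > 0, got y_u={self.y_u}, y_l={self.y_l}"
            )

    @property
    def restitution(self) -> float:
        """Restitution coefficient implied by the two branches."""
        return float(np.sqrt(self.y_l / self.y_u))


@dataclass
class GranularBed:
    """A collection of microspheres in a periodic box above a floor plane.

    Positions and diameters are dimensionless (units of the mean diameter).
    ``relative_density`` is the density contrast relative to the polystyrene
    baseline (1 = polystyrene, 2 = glass, ``inf`` = sintered/immobile);
    immobile particles are excluded from the dynamics entirely.
    """

    positions: np.ndarray
    diameters: np.ndarray
    velocities: np.ndarray = None  # type: ignore[assignment]
    relative_density: np.ndarray = None  # type: ignore[assignment]
    mobile: np.ndarray = None  # type: ignore[assignment]
    box: tuple[float, float, float] = (20.0, 20.0, 20.0)
    periodic_xy: bool = True
    floor_z: float = 1.0
    target_layers: int = 3
    seed: int = 0
    relaxed: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.diameters = np.asarray(self.diameters, dtype=float).ravel()
        n = self.n
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        else:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if self.relative_density is None:
            self.relative_density = np.ones(n)
        else:
            self.relative_density = np.asarray(self.relative_density, dtype=float)
        if self.mobile is None:
            self.mobile = np.isfinite(self.relative_density)
        else:
            self.mobile = np.asarray(self.mobile, dtype=bool)
        self.velocities[~self.mobile] = 0.0

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def masses(self) -> np.ndarray:
        """Effective (buoyancy-reduced) masses; 1 for a mean baseline sphere.

        Immobile (sintered) particles get a placeholder mass of 1; they are
        never integrated.
        """
        m = self.diameters**3
        rho = np.where(np.isfinite(self.relative_density), self.relative_density, 1.0)
        return m * rho

    @property
    def height_above_floor(self) -> float:
        """Largest particle-centre height above the floor plane."""
        return float(self.positions[:, 2].max() - self.floor_z)

    def mean_kinetic_energy(self) -> float:
        mob = self.mobile
        if not mob.any():
            return 0.0
        v2 = (self.velocities[mob] ** 2).sum(axis=1)
        return float(0.5 * (self.masses[mob] * v2).mean())

    def max_pair_overlap_fraction(self) -> float:
        """Largest pair overlap as a fraction of the smaller diameter."""
        from scipy.spatial import cKDTree

        pos = self.positions
        boxsize = None
        if self.periodic_xy:
            # cKDTree periodic boxes wrap all axes; lift z well clear instead
            zspan = pos[:, 2].max() - pos[:, 2].min() + 10.0 * self.diameters.max()
            boxsize = (self.box[0], self.box[1], zspan + self.box[2] * 10)
            pos = pos.copy()
            pos[:, 2] -= pos[:, 2].min()
        tree = cKDTree(pos, boxsize=boxsize)
        pairs = tree.query_pairs(float(self.diameters.max()), output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        if self.periodic_xy:
            for k in (0, 1):
                d[:, k] -= self.box[k] * np.round(d[:, k] / self.box[k])
        dist = np.linalg.norm(d, axis=1)
        sumr = 0.5 * (self.diameters[pairs[:, 0]] + self.diameters[pairs[:, 1]])
        dmin = np.minimum(self.diameters[pairs[:, 0]], self.diameters[pairs[:, 1]])
        overlap = (sumr - dist) / dmin
        return float(max(overlap.max(), 0.0))

    def copy(self) -> "GranularBed":
        return GranularBed(
            positions=self.positions.copy(),
            diameters=self.diameters.copy(),
            velocities=self.velocities.copy(),
            relative_density=self.relative_density.copy(),
            mobile=self.mobile.copy(),
            box=self.box,
            periodic_xy=self.periodic_xy,
            floor_z=self.floor_z,
            target_layers=self.target_layers,
            seed=self.seed,
            relaxed=self.relaxed,
        )

    def with_relative_density(self, value: float) -> "GranularBed":
        """Copy of the bed with all particles set to one relative density.

        ``inf`` yields the sintered condition: every particle immobile.  The
        static packing is unchanged (masses rescale, geometry does not).
        """
        out = self.copy()
        out.relative_density = np.full(self.n, float(value))
        out.mobile = np.isfinite(out.relative_density)
        out.velocities[~out.mobile] = 0.0
        return out


def generate_particles(
    n_target_layers: int,
    d_mean: float = 1.0,
    dispersion: float = 0.05,
    box: tuple[float, float, float] = (20.0, 20.0, 20.0),
    seed: int = 0,
    fill_fraction: float = 0.15,
    max_tries: int = 2000,
) -> GranularBed:
    """Random non-overlapping placement of a polydisperse particle set.

    The particle count is ``n_target_layers * floor(Lx/d) * floor(Ly/d)`` so
    the settled bed is about ``n_target_layers`` particles high.  Diameters
    are i.i.d. uniform on ``[1 - dispersion, 1 + dispersion] * d_mean``.
    Placement is rejection sampling in the lower part of the box (a slab
    sized for packing fraction ``fill_fraction``, which shortens the free
    fall without changing the settled packing).
    """
    if not 0.0 <= dispersion <= 0.2:
        raise ValueError(f"dispersion must be in [0, 0.2], got {dispersion}")
    if min(box) <= 2.0 * d_mean:
        raise ValueError(f"box {box} too small for particles of diameter {d_mean}")
    if n_target_layers < 1:
        raise ValueError("n_target_layers must be >= 1")
    rng = np.random.default_rng(seed)
    count = n_target_layers * int(box[0] / d_mean) * int(box[1] / d_mean)
    diam = d_mean * rng.uniform(1.0 - dispersion, 1.0 + dispersion, size=count)
    floor_z = 1.0
    slab = count * (np.pi / 6.0) * d_mean**3 / (fill_fraction * box[0] * box[1])
    slab = min(max(slab, 3.0 * n_target_layers * d_mean), box[2] - d_mean)

    # grid hash for O(1) overlap queries during insertion
    cell = float(diam.max())
    nx = max(int(box[0] / cell), 1)
    ny = max(int(box[1] / cell), 1)
    grid: dict[tuple[int, int, int], list[int]] = {}
    pos = np.empty((count, 3))

    def neighbours(ix: int, iy: int, iz: int):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    yield ((ix + dx) % nx, (iy + dy) % ny, iz + dz)

    for i in range(count):
        r = diam[i] / 2.0
        placed = False
        for _ in range(max_tries):
            x = rng.uniform(0.0, box[0])
            y = rng.uniform(0.0, box[1])
            z = rng.uniform(floor_z + r, floor_z + slab)
            ix, iy, iz = int(x / cell) % nx, int(y / cell) % ny, int(z / cell)
            ok = True
            for key in neighbours(ix, iy, iz):
                for j in grid.get(key, ()):
                    dx = x - pos[j, 0]
                    dy = y - pos[j, 1]
                    dx -= box[0] * round(dx / box[0])
                    dy -= box[1] * round(dy / box[1])
                    dz_ = z - pos[j, 2]
                    if dx * dx + dy * dy + dz_ * dz_ < (r + diam[j] / 2.0) ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                pos[i] = (x, y, z)
                grid.setdefault((ix, iy, iz), []).append(i)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place particle {i + 1}/{count} without overlap "
                f"after {max_tries} tries (box {box}, slab height {slab:.2f})"
            )
    return GranularBed(
        positions=pos,
        diameters=diam,
        box=tuple(float(b) for b in box),
        floor_z=floor_z,
        target_layers=n_target_layers,
        seed=seed,
        relaxed=False,
    )


def contact_force(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    diam_i: float,
    diam_j: float,
    vel_i: np.ndarray,
    vel_j: np.ndarray,
    law: ContactLaw = ContactLaw(),
) -> np.ndarray:
    """Hysteretic normal contact force on body ``i`` (reference version).

    Zero when the spheres do not overlap.  The stiffness is the loading
    branch while the pair approaches (``d|r_ij|/dt < 0``), the softer
    unloading branch otherwise, each scaled by the pair's mean diameter.
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    d = pos_i - pos_j
    dist = float(np.linalg.norm(d))
    sumr = 0.5 * (diam_i + diam_j)
    if dist >= sumr:
        return np.zeros(3)
    if dist < 1e-12:
        raise DegenerateGeometryError("coincident sphere centres")
    nhat = d / dist
    vn = float(np.dot(np.asarray(vel_i) - np.asarray(vel_j), nhat))
    y = law.y_u if vn < 0.0 else law.y_l
    return y * sumr * (sumr - dist) * nhat


def floor_contact_force(
    pos: np.ndarray,
    diam: float,
    vel: np.ndarray,
    floor_z: float = 1.0,
    law: ContactLaw = ContactLaw(),
) -> np.ndarray:
    """Same hysteretic law against the floor plane; stiffness scales with
    the particle's own diameter."""
    delta = floor_z - (float(pos[2]) - diam / 2.0)
    if delta <= 0:
        return np.zeros(3)
    y = law.y_u if float(vel[2]) < 0.0 else law.y_l
    return np.array([0.0, 0.0, y * diam * delta])


def settle_bed(
    bed: GranularBed,
    law: ContactLaw = ContactLaw(),
    dt: float = DT,
    ke_threshold: float = KE_THRESHOLD,
    max_steps: int = 3_000_000,
    check_every: int = 500,
) -> GranularBed:
    """Relax a bed under gravity until the mean kinetic energy per particle
    falls below ``ke_threshold``.

    Returns a new bed with ``relaxed=True``.  Raises
    :class:`~granulocell.errors.RelaxationError` if the budget is exhausted.
    """
    from .errors import RelaxationError
    from .world import World

    out = bed.copy()
    world = World(out, cell=None, law=law, dt=dt)
    # let the pack actually fall before testing the kinetic-energy
    # criterion; an already-relaxed bed passes the check immediately
    if bed.relaxed or out.n == 0:
        min_steps = 0
    else:
        drop_height = max(out.positions[:, 2].max() - out.floor_z, 1.0)
        min_steps = min(int(2.0 * np.sqrt(2.0 * drop_height) / dt), max_steps // 2)
    if min_steps:
        world.run(min_steps)
    res = world.run(
        max_steps - min_steps,
        stop_mode=1,
        stop_value=ke_threshold,
        check_every=check_every,
    )
    world.sync_bed(out)
    if res["metric"] >= ke_threshold:
        raise RelaxationError(
            f"bed did not relax within {max_steps} steps "
            f"(mean KE {res['metric']:.3e} >= {ke_threshold:.3e})",
            final_metric=res["metric"],
        )
    out.relaxed = True
    return out
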