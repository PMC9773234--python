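"""Fused simulation state: bed particles + cell elements + bonds.

:class:`World` owns the flat arrays consumed by the numba kernels in
:mod:`granulocell._core` and keeps them in sync with the user-facing
:class:`~granulocell.dem.GranularBed`, :class:`~granulocell.cell.Cell` and
:class:`~granulocell.adhesion.Bond` objects.  Bodies are indexed particles
first, then cell elements; the body count never changes (inactive cell
layers are present from the start with tiny mass), so only topology arrays
(springs, tethers, bonds) are rebuilt when the cell spreads or binds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .adhesion import AdhesionParams, Bond, BondState, bind_on_contact
from .cell import Cell, INACTIVE_MASS_SCALE
from .dem import ContactLaw, GranularBed

__all__ = ["World", "BondEvent"]

_STATE_CODE = {
    BondState.ENGAGED: _core.ENGAGED,
    BondState.REINFORCED: _core.REINFORCED,
    BondState.BROKEN: _core.BROKEN,
}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}
_EVENT_NAME = {_core.EV_REINFORCE: "reinforce", _core.EV_BREAK: "break"}


@dataclass(frozen=True)
class BondEvent:
    step: int
    element_id: int
    particle_id: int
    event: str  # bind | reinforce | break
    force: float


class World:
    """Flat-array simulation state driving the numba time loop."""

    def __init__(
        self,
        bed: GranularBed,
        cell: Cell | None = None,
        adhesion: AdhesionParams | None = None,
        law: ContactLaw = ContactLaw(),
        dt: float = 5e-5,
        g: float = 1.0,
    ):
        self.bed = bed
        self.cell = cell
        self.adhesion = adhesion
        self.law = law
        self.dt = float(dt)
        self.g = float(g)
        self.step = 0
        self.bonds: list[Bond] = []
        self.events: list[BondEvent] = []

        n_p = bed.n
        n_e = cell.n_elements if cell is not None else 0
        n = n_p + n_e
        self.n_particles = n_p
        self.n = n

        self.pos = np.empty((n, 3))
        self.pos[:n_p] = bed.positions
        self.rad = np.empty(n)
        self.rad[:n_p] = bed.diameters / 2.0
        self.mass = np.empty(n)
        self.mass[:n_p] = bed.masses
        self.kind = np.zeros(n, dtype=np.uint8)
        self.kind[n_p:] = 1
        self.mobile = np.ones(n, dtype=np.uint8)
        self.mobile[:n_p] = bed.mobile.astype(np.uint8)
        self.frozen = np.zeros(n, dtype=np.uint8)
        self.terminal = np.zeros(n, dtype=np.uint8)
        self.cscale = np.ones(n)
        self.active = np.ones(n, dtype=np.uint8)

        self.r1 = np.zeros((n, 3))
        self.r1[:n_p] = bed.velocities * self.dt
        self.r2 = np.zeros((n, 3))
        self.r3 = np.zeros((n, 3))
        self.r4 = np.zeros((n, 3))

        if cell is not None:
            self.pos[n_p:] = cell.positions
            self.rad[n_p:] = cell.element_diameter / 2.0
            self.r1[n_p:] = cell.velocities * self.dt
            self.center_idx = n_p + cell.center_index
            self.ee_ok = cell.template.collision_mask()
        else:
            self.center_idx = 0
            self.ee_ok = np.zeros((1, 1), dtype=np.uint8)
        self.refresh_topology()

        # spatial binning sized by the largest interaction diameter
        self.Lx, self.Ly, self.Lz = bed.box
        self.floor_z = bed.floor_z
        self.periodic = 1 if bed.periodic_xy else 0
        self.skin = float(0.3 * self.rad.max())
        cutoff = float(2.0 * self.rad.max() + self.skin)
        nx = max(int(self.Lx / cutoff), 1)
        ny = max(int(self.Ly / cutoff), 1)
        z_hi = self.floor_z + self.Lz + 4.0 * cutoff
        nz = int((z_hi - (self.floor_z - 2.0 * cutoff)) / cutoff) + 2
        self.use_cells = 1 if (nx >= 3 and ny >= 3 and n > 32) else 0
        self.cutoff, self.nx, self.ny, self.nz = cutoff, nx, ny, nz
        self.head = np.full(nx * ny * nz, -1, dtype=np.int64)
        self.nxt = np.full(n, -1, dtype=np.int64)
        self.binx = np.zeros(n, dtype=np.int64)
        self.biny = np.zeros(n, dtype=np.int64)
        self.binz = np.zeros(n, dtype=np.int64)

        # preallocated event buffers for the kernel
        self._ev_step = np.zeros(8192, dtype=np.int64)
        self._ev_bond = np.zeros(8192, dtype=np.int64)
        self._ev_type = np.zeros(8192, dtype=np.int64)
        self._ev_force = np.zeros(8192)

        # warm-start the Gear acceleration so constant forces integrate
        # without a half-step velocity offset
        integ = (self.mobile == 1) & (self.frozen == 0)
        if integ.any():
            F0 = self.compute_forces()
            self.r2[integ] = (
                F0[integ] / self.mass[integ, None] * (0.5 * self.dt**2)
            )

    # ------------------------------------------------------------------ setup

    def refresh_topology(self) -> None:
        """Rebuild spring/tether/bond arrays from the cell and bond list."""
        n_p = self.n_particles
        cell = self.cell
        if cell is None:
            self.sp_i = np.zeros(0, dtype=np.int64)
            self.sp_j = np.zeros(0, dtype=np.int64)
            self.sp_k = np.zeros(0)
            self.sp_c = np.zeros(0)
            self.sp_l0 = np.zeros(0)
            self.th_e = np.zeros(0, dtype=np.int64)
            self.th_off = np.zeros((0, 3))
            self.th_k = np.zeros(0)
            self.th_c = np.zeros(0)
            self.th_on = np.zeros(0, dtype=np.uint8)
        else:
            self.active[n_p:] = cell.active.astype(np.uint8)
            self.terminal[n_p:] = cell.terminal.astype(np.uint8)
            self.frozen[n_p:] = cell.frozen.astype(np.uint8)
            self.mass[n_p:] = cell.masses
            # inactive layers do not touch anything until activated
            self.cscale[n_p:] = np.where(cell.active, 1.0, 0.0)
            self.sp_i = cell.sp_i + n_p
            self.sp_j = cell.sp_j + n_p
            m = len(cell.sp_i)
            self.sp_k = np.full(m, cell.k_s)
            self.sp_c = np.full(m, cell.c_s)
            self.sp_l0 = cell.sp_l0  # shared: kernel shrinking mutates it
            inactive = np.nonzero(~cell.active)[0]
            self.th_e = inactive + n_p
            self.th_off = cell.template.offsets[inactive]
            self.th_k = np.full(len(inactive), cell.k_s)
            m_in = cell.element_diameter**3 * INACTIVE_MASS_SCALE
            self.th_c = np.full(len(inactive), 2.0 * np.sqrt(cell.k_s * m_in))
            self.th_on = np.ones(len(inactive), dtype=np.uint8)
        self.sp_rate = np.zeros_like(self.sp_l0)
        self.sp_state = np.zeros(len(self.sp_l0), dtype=np.uint8)
        self._refresh_bonds()

    def _refresh_bonds(self) -> None:
        nb = len(self.bonds)
        self.b_e = np.array(
            [b.element_id + self.n_particles for b in self.bonds], dtype=np.int64
        ).reshape(nb)
        self.b_p = np.array([b.particle_id for b in self.bonds], dtype=np.int64).reshape(nb)
        self.b_offe = (
            np.array([b.anchor_element for b in self.bonds]).reshape(nb, 3)
            if nb
            else np.zeros((0, 3))
        )
        self.b_offp = (
            np.array([b.anchor_particle for b in self.bonds]).reshape(nb, 3)
            if nb
            else np.zeros((0, 3))
        )
        self.b_k = np.array([b.k_b for b in self.bonds]).reshape(nb)
        self.b_c = np.array([b.c_b for b in self.bonds]).reshape(nb)
        self.b_state = np.array(
            [_STATE_CODE[b.state] for b in self.bonds], dtype=np.uint8
        ).reshape(nb)
        self.b_dist0 = np.array([b.dist0 for b in self.bonds]).reshape(nb)
        self.b_cref = (
            np.array([b.center_ref for b in self.bonds]).reshape(nb, 3)
            if nb
            else np.zeros((0, 3))
        )

    # ------------------------------------------------------------- dynamics

    def run(
        self,
        n_steps: int,
        stop_mode: int = 0,
        stop_value: float = 0.0,
        check_every: int = 500,
        adhesion_on: bool = False,
        shrinking: bool = False,
        gdamp: float = 0.0,
    ) -> dict:
        """Advance up to ``n_steps``; see :func:`granulocell._core.advance`.

        ``gdamp`` applies a global exponential velocity quench (rate per
        dimensionless time) — used only to shorten overdamped relaxation
        phases; it does not change the static equilibria being sought.
        """
        f_reinforce = self.adhesion.reinforcement_threshold if self.adhesion else 0.0
        detach = self.adhesion.detachment_distance if self.adhesion else 0.04
        steps, ev_n, metric = _core.advance(
            n_steps,
            self.step,
            self.pos, self.r1, self.r2, self.r3, self.r4,
            self.rad, self.mass, self.cscale, self.active,
            self.mobile, self.frozen, self.kind, self.terminal,
            self.Lx, self.Ly, self.floor_z, self.periodic,
            self.law.y_u, self.law.y_l, self.g, self.dt,
            self.sp_i, self.sp_j, self.sp_k, self.sp_c, self.sp_l0,
            self.sp_rate, self.sp_state, 1 if shrinking else 0,
            self.th_e, self.th_off, self.th_k, self.th_c, self.th_on,
            self.center_idx,
            self.b_e, self.b_p, self.b_offe, self.b_offp,
            self.b_k, self.b_c, self.b_state, self.b_dist0, self.b_cref,
            1 if adhesion_on else 0, f_reinforce, detach, gdamp,
            stop_mode, stop_value, check_every,
            self._ev_step, self._ev_bond, self._ev_type, self._ev_force,
            self.head, self.nxt, self.binx, self.biny, self.binz,
            self.nx, self.ny, self.nz,
            self.cutoff, self.skin, self.use_cells,
            self.ee_ok, self.n_particles,
        )
        self.step += steps
        self._absorb_kernel_events(ev_n)
        return {"steps": steps, "metric": metric}

    def _absorb_kernel_events(self, ev_n: int) -> None:
        for i in range(ev_n):
            m = int(self._ev_bond[i])
            bond = self.bonds[m]
            bond.state = _CODE_STATE[int(self.b_state[m])]
            if bond.state is BondState.REINFORCED:
                # mirror the kernel's freeze into the cell object
                if self.cell is not None:
                    self.cell.frozen[bond.element_id] = True
            elif bond.state is BondState.BROKEN:
                if self.cell is not None:
                    self.cell.terminal[bond.element_id] = True
            self.events.append(
                BondEvent(
                    step=int(self._ev_step[i]),
                    element_id=bond.element_id,
                    particle_id=bond.particle_id,
                    event=_EVENT_NAME[int(self._ev_type[i])],
                    force=float(self._ev_force[i]),
                )
            )

    def compute_forces(self) -> np.ndarray:
        """One force evaluation at the current state (diagnostics)."""
        vel = self.r1 / self.dt
        F, _ = _core.forces_once(
            self.pos, vel, self.rad, self.mass, self.cscale,
            self.mobile, self.frozen, self.kind,
            self.Lx, self.Ly, self.floor_z, self.periodic,
            self.law.y_u, self.law.y_l, self.g, self.dt,
            self.sp_i, self.sp_j, self.sp_k, self.sp_c, self.sp_l0,
            self.th_e, self.th_off, self.th_k, self.th_c, self.th_on,
            self.center_idx,
            self.b_e, self.b_p, self.b_offe, self.b_offp,
            self.b_k, self.b_c, self.b_state,
            self.head, self.nxt, self.binx, self.biny, self.binz,
            self.nx, self.ny, self.nz,
            self.cutoff, self.use_cells,
            self.ee_ok, self.n_particles,
        )
        return F

    # ------------------------------------------------------------- adhesion

    def bind(self, refresh_existing: bool = False) -> int:
        """Instantaneous integrin binding for all touching elements.

        Optionally refreshes the anchors and binding distances of existing
        engaged bonds — done at the start of each spreading/contraction
        cycle, where the bond population turns over within its lifetime.
        Returns the number of new bonds.
        """
        if self.cell is None or self.adhesion is None:
            return 0
        self.sync_all()
        if refresh_existing:
            box = self.bed.box[:2] if self.bed.periodic_xy else None
            center = self.cell.positions[self.cell.center_index]
            # recompute anchors/distances for engaged bonds in place
            for b in self.bonds:
                if b.state is not BondState.ENGAGED:
                    continue
                e, p = b.element_id, b.particle_id
                dvec = self.bed.positions[p] - self.cell.positions[e]
                if box is not None:
                    for k in (0, 1):
                        dvec[k] -= box[k] * np.round(dvec[k] / box[k])
                dist = np.linalg.norm(dvec)
                if dist > 1e-12:
                    u = dvec / dist
                    r_e = self.cell.element_diameter / 2.0
                    delta = r_e + self.bed.diameters[p] / 2.0 - dist
                    contact = (r_e - 0.5 * delta) * u
                    b.anchor_element = contact
                    b.anchor_particle = contact - dvec
                rvec = self.cell.positions[e] - center
                if box is not None:
                    for k in (0, 1):
                        rvec[k] -= box[k] * np.round(rvec[k] / box[k])
                b.dist0 = float(np.linalg.norm(rvec))
                b.center_ref = self.cell.positions[e] - rvec
        new = bind_on_contact(self.cell, self.bed, self.adhesion, existing=self.bonds)
        for b in new:
            self.bonds.append(b)
            self.events.append(
                BondEvent(self.step, b.element_id, b.particle_id, "bind", 0.0)
            )
        if new or refresh_existing:
            self._refresh_bonds()
        return len(new)

    @property
    def n_engaged(self) -> int:
        return sum(1 for b in self.bonds if b.state is BondState.ENGAGED)

    @property
    def n_reinforced(self) -> int:
        return sum(1 for b in self.bonds if b.state is BondState.REINFORCED)

    @property
    def n_broken(self) -> int:
        return sum(1 for b in self.bonds if b.state is BondState.BROKEN)

    # ----------------------------------------------------------------- sync

    def sync_bed(self, bed: GranularBed | None = None) -> None:
        bed = bed or self.bed
        n_p = self.n_particles
        bed.positions[:] = self.pos[:n_p]
        bed.velocities[:] = self.r1[:n_p] / self.dt

    def sync_cell(self) -> None:
        if self.cell is None:
            return
        n_p = self.n_particles
        self.cell.positions[:] = self.pos[n_p:]
        self.cell.velocities[:] = self.r1[n_p:] / self.dt

    def sync_all(self) -> None:
        self.sync_bed()
        self.sync_cell()

    # ------------------------------------------------------------- measures

    def mean_kinetic_energy(self) -> float:
        integ = (self.mobile == 1) & (self.frozen == 0)
        if not integ.any():
            return 0.0
        v2 = ((self.r1[integ] / self.dt) ** 2).sum(axis=1)
        return float(0.5 * (self.mass[integ] * v2).mean())

    def max_active_element_speed(self) -> float:
        sel = (self.kind == 1) & (self.active == 1) & (self.frozen == 0)
        if not sel.any():
            return 0.0
        return float(np.abs(self.r1[sel] / self.dt).max())

    def mean_active_element_speed(self) -> float:
        sel = (self.kind == 1) & (self.active == 1) & (self.frozen == 0)
        if not sel.any():
            return 0.0
        return float(np.linalg.norm(self.r1[sel] / self.dt, axis=1).mean())
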