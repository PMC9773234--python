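"""Integrin binding, talin reinforcement, and detachment kinetics.

Three mechanisms couple the cell to the microparticles:

* **binding** — whenever an active element touches a particle, a
  viscoelastic *binding spring* engages instantaneously between the contact
  anchors;
* **reinforcement** — if the elastic force carried by an engaged binding
  spring reaches the maximum cell force, the adhesion matures instantly
  (talin unfolds, vinculin locks it): both the element and the particle are
  frozen in place and the bond can never break;
* **detachment** — the integrin lifetime is encoded geometrically: if an
  element moves closer to the centre element by more than 4% of its
  distance at binding time before reinforcing, the bond breaks and the cell
  stops spreading in that direction (the element becomes *terminal*).

The binding spring constant is the maximum cell force divided by
``2.5e-5 * L_i``, so the force threshold is reached at a stretch of 0.0025%
of the cell diameter — far below the 4% unbinding threshold, which is what
lets a cell on immobile particles always reach reinforcement first.  The
damping constant is the maximum cell force divided by ``1.25e-2 * L_i``.

Bond states form an absorbing machine: engaged -> reinforced | broken.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import BondStateError
from .units import max_cell_force_dimless

__all__ = [
    "BondState",
    "Bond",
    "AdhesionParams",
    "bond_force",
    "check_reinforcement",
    "check_detachment",
    "find_contacts",
    "bind_on_contact",
]

#: binding-spring stretch (fraction of L_i) at which the force equals W_max
BINDING_STRETCH_FRACTION = 2.5e-5
#: damping divisor (fraction of L_i)
BINDING_DAMPING_FRACTION = 1.25e-2
#: fractional radial contraction that breaks an engaged bond
DETACHMENT_FRACTION = 0.04


class BondState(enum.Enum):
    ENGAGED = "engaged"
    REINFORCED = "reinforced"
    BROKEN = "broken"


@dataclass(frozen=True)
class AdhesionParams:
    """Adhesion constants for a cell of dimensionless diameter ``L_i``.

    ``f_max`` is the maximum cell force (dimensionless buoyant weight of a
    sphere 82/32 times the cell diameter); it doubles as the reinforcement
    threshold and as the "maximum weight an element can lift" that sets the
    binding-spring constants.  ``engagement_lifetime_s`` (2-4 s) and
    ``contraction_velocity_nm_s`` (110 nm/s) are the experimental figures
    the 4% threshold collapses; they are informational only.
    """

    L_i: float
    f_max: float = None  # type: ignore[assignment]
    detachment_fraction: float = DETACHMENT_FRACTION
    engagement_lifetime_s: tuple[float, float] = (2.0, 4.0)
    contraction_velocity_nm_s: float = 110.0

    def __post_init__(self) -> None:
        if self.L_i <= 0:
            raise ValueError("L_i must be positive")
        if self.f_max is None:
            object.__setattr__(self, "f_max", max_cell_force_dimless(self.L_i))
        # binding spring maxes out far below the unbinding displacement
        if BINDING_STRETCH_FRACTION * self.L_i >= self.detachment_fraction * (
            self.L_i / 6.0
        ):
            raise ValueError(
                "binding-spring max displacement must stay below the "
                "detachment threshold displacement"
            )

    @property
    def reinforcement_threshold(self) -> float:
        return self.f_max

    @property
    def detachment_distance(self) -> float:
        """Absolute radial contraction that breaks a bond: 4% of L_i.

        The integrin lifetime (2-4 s) at the cell contraction velocity
        (~110 nm/s) is collapsed into this one cell-scale distance.
        """
        return self.detachment_fraction * self.L_i

    @property
    def k_b(self) -> float:
        """Binding spring elastic constant, W_max / (2.5e-5 L_i)."""
        return self.f_max / (BINDING_STRETCH_FRACTION * self.L_i)

    @property
    def c_b(self) -> float:
        """Binding spring damping constant, W_max / (1.25e-2 L_i)."""
        return self.f_max / (BINDING_DAMPING_FRACTION * self.L_i)


@dataclass
class Bond:
    """One element-particle binding spring.

    ``center_ref`` is the centre element's position at binding time and
    ``dist0`` the element's distance to it then; the 4% detachment budget
    is measured against this fixed reference, so only real dragging of the
    adhesion counts as contraction.
    """

    element_id: int
    particle_id: int
    anchor_element: np.ndarray
    anchor_particle: np.ndarray
    k_b: float
    c_b: float
    dist0: float
    center_ref: np.ndarray = field(default_factory=lambda: np.zeros(3))
    state: BondState = BondState.ENGAGED


def bond_force(
    bond: Bond,
    pos_e: np.ndarray,
    pos_p: np.ndarray,
    vel_e: np.ndarray,
    vel_p: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Viscoelastic force pair of an engaged binding spring.

    The spring acts between the stored anchor points (zero natural length),
    with isotropic damping of the relative body velocity; returns
    ``(F_element, F_particle)``, equal and opposite.  Querying a broken bond
    is a state error.
    """
    if bond.state is BondState.BROKEN:
        raise BondStateError("cannot evaluate force of a broken bond")
    u = (
        np.asarray(pos_e, dtype=float)
        + bond.anchor_element
        - np.asarray(pos_p, dtype=float)
        - bond.anchor_particle
    )
    f = -bond.k_b * u - bond.c_b * (
        np.asarray(vel_e, dtype=float) - np.asarray(vel_p, dtype=float)
    )
    return f, -f


def elastic_force_magnitude(bond: Bond, pos_e, pos_p) -> float:
    """Magnitude of the elastic (talin-loading) component of the bond force."""
    u = (
        np.asarray(pos_e, dtype=float)
        + bond.anchor_element
        - np.asarray(pos_p, dtype=float)
        - bond.anchor_particle
    )
    return float(bond.k_b * np.linalg.norm(u))


def check_reinforcement(bond: Bond, elastic_force: float, threshold: float) -> Bond:
    """Reinforce the bond if its elastic force reaches the threshold.

    Only engaged bonds may transition; the caller is responsible for
    freezing both bonded bodies when the transition fires.
    """
    if bond.state is not BondState.ENGAGED:
        raise BondStateError(f"cannot reinforce a {bond.state.value} bond")
    if elastic_force >= threshold:
        bond.state = BondState.REINFORCED
    return bond


def check_detachment(
    bond: Bond, current_radial_distance: float, detachment_distance: float
) -> Bond:
    """Break the bond if the element contracted past the integrin budget.

    ``current_radial_distance`` is the element's present distance to the
    centre reference recorded at binding; the bond breaks when it has
    decreased by more than ``detachment_distance`` (4% of the initial cell
    diameter) from ``dist0``.  Reinforced bonds never break.
    """
    if bond.state is BondState.REINFORCED:
        return bond
    if bond.state is BondState.BROKEN:
        raise BondStateError("bond already broken")
    if bond.dist0 - current_radial_distance > detachment_distance:
        bond.state = BondState.BROKEN
    return bond


def find_contacts(
    element_pos: np.ndarray,
    element_radius: float,
    particle_pos: np.ndarray,
    particle_radii: np.ndarray,
    box: tuple[float, float] | None = None,
) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """All overlapping (element, particle) pairs with contact anchors.

    Returns ``(e, p, anchor_offset_element, anchor_offset_particle)`` per
    pair; the anchor is the midpoint of the overlap on the line of centres,
    stored as body-frame offsets.  ``box`` enables x/y minimum image.
    """
    element_pos = np.atleast_2d(element_pos)
    particle_pos = np.atleast_2d(particle_pos)
    if element_pos.shape[0] == 0 or particle_pos.shape[0] == 0:
        return []
    d = particle_pos[None, :, :] - element_pos[:, None, :]
    if box is not None:
        for k in (0, 1):
            d[:, :, k] -= box[k] * np.round(d[:, :, k] / box[k])
    dist = np.linalg.norm(d, axis=2)
    sumr = element_radius + np.asarray(particle_radii)[None, :]
    ee, pp = np.nonzero(dist < sumr)
    out = []
    for e, p in zip(ee, pp):
        dd = dist[e, p]
        if dd < 1e-12:
            continue
        u = d[e, p] / dd
        delta = sumr[0, p] - dd
        contact_vec = (element_radius - 0.5 * delta) * u
        # anchor on the particle expressed from the particle centre
        out.append((int(e), int(p), contact_vec, contact_vec - d[e, p]))
    return out


def bind_on_contact(cell, bed, params: AdhesionParams, existing=None) -> list[Bond]:
    """Create engaged bonds for every touching, eligible element.

    Eligible elements are active, not terminal, not frozen and not already
    bonded; each binds to at most one microparticle — the deepest current
    contact.  (A broken bond marks its element terminal, and reinforcement
    freezes the pair, so the one-bond-per-element rule matches the
    per-element detachment and freezing semantics.)  Binding is
    instantaneous: the bond records the current contact anchors and the
    element's current distance to the centre element.
    """
    bonded = set()
    if existing:
        bonded = {b.element_id for b in existing}
    mask = cell.active & ~cell.terminal & ~cell.frozen
    eligible = np.array([e for e in np.nonzero(mask)[0] if e not in bonded])
    if len(eligible) == 0 or bed.n == 0:
        return []
    box = bed.box[:2] if bed.periodic_xy else None
    contacts = find_contacts(
        cell.positions[eligible],
        cell.element_diameter / 2.0,
        bed.positions,
        bed.diameters / 2.0,
        box=box,
    )
    # keep only the deepest contact per element
    best: dict[int, tuple] = {}
    for le, p, off_e, off_p in contacts:
        depth = (
            cell.element_diameter / 2.0
            + bed.diameters[p] / 2.0
            - np.linalg.norm(
                np.asarray(off_e, dtype=float) - np.asarray(off_p, dtype=float)
            )
        )
        if le not in best or depth > best[le][0]:
            best[le] = (depth, p, off_e, off_p)
    center = cell.positions[cell.center_index]
    bonds = []
    for le, (_, p, off_e, off_p) in sorted(best.items()):
        e = int(eligible[le])
        dvec = cell.positions[e] - center
        if box is not None:
            for k in (0, 1):
                dvec[k] -= box[k] * np.round(dvec[k] / box[k])
        bonds.append(
            Bond(
                element_id=e,
                particle_id=int(p),
                anchor_element=np.asarray(off_e, dtype=float),
                anchor_particle=np.asarray(off_p, dtype=float),
                k_b=params.k_b,
                c_b=params.c_b,
                dist0=float(np.linalg.norm(dvec)),
                center_ref=cell.positions[e] - dvec,
            )
        )
    return bonds
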