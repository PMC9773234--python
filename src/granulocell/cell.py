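"""Spring-network cell: hexagonal element template, spreading, contraction.

The cell is a planar sheet of spherical elements connected by viscoelastic
springs.  It starts as seven elements in a hexagon whose smallest enclosing
circle has the initial cell diameter ``L_i``; two further concentric rings
(12 and 24 elements) are precomputed so the fully spread cell reaches
``L_f = 2 L_i``.  Spreading activates one ring per stretch phase, two
children per non-terminal periphery element; contraction shrinks every
structural spring's natural length to zero at a steady rate.

Element diameter is ``L_i / 3`` (forced by the enclosing-circle definition
of ``L_i``); elements have the same material density as the microparticles.
Inactive rings carry a 1e-3 mass (and contact-stiffness) scale and are
tethered to the template frame that translates with the centre element, so
they perturb the bed negligibly until activated.

The heavy dynamics (relaxation, contraction) run through
:class:`granulocell.world.World`; this module owns geometry and topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, UnbondedCellError

__all__ = [
    "CellTemplate",
    "Cell",
    "build_template",
    "init_cell",
    "add_layer",
    "structural_force",
    "min_enclosing_circle",
    "enclosing_diameter",
]

#: structural spring elastic constant per L_i^2
K_S_COEF = 6.25
#: structural spring damping constant per L_i^2
C_S_COEF = 6.25e-2
#: mass (and contact-stiffness) reduction factor of inactive layers
INACTIVE_MASS_SCALE = 1e-3

RING_COUNTS = (6, 12, 24)


@dataclass(frozen=True)
class CellTemplate:
    """Precomputed positions and topology of all 43 elements.

    ``offsets`` are planar positions relative to the centre element;
    ``layer_index`` is 0 for the centre, 1..3 for the rings; ``parent`` maps
    each ring element to the element that spawns it (the centre for ring 1).
    """

    L_i: float
    offsets: np.ndarray
    layer_index: np.ndarray
    parent: np.ndarray

    @property
    def n_elements(self) -> int:
        return self.offsets.shape[0]

    def full_spring_edges(self) -> list[tuple[int, int]]:
        """Every structural spring of the fully spread cell."""
        edges = [(0, int(i)) for i in self.ring_indices(1)]
        allon = np.ones(self.n_elements, dtype=bool)
        for ring in (1, 2, 3):
            edges += _ring_adjacency_springs(self, ring, allon)
            if ring > 1:
                edges += [
                    (int(self.parent[c]), int(c)) for c in self.ring_indices(ring)
                ]
        return edges

    def collision_mask(self) -> np.ndarray:
        """(n, n) uint8 matrix: 1 where two elements collide as spheres.

        Elements within graph distance 2 of each other in the full spring
        network are excluded (their template spacings are below one element
        diameter, so the sheet could not exist otherwise); everything
        farther apart collides, which stops the sheet from collapsing
        through itself.
        """
        n = self.n_elements
        adj = [[] for _ in range(n)]
        for a, b in self.full_spring_edges():
            adj[a].append(b)
            adj[b].append(a)
        mask = np.ones((n, n), dtype=np.uint8)
        for i in range(n):
            mask[i, i] = 0
            for j in adj[i]:
                mask[i, j] = 0
                for k in adj[j]:
                    mask[i, k] = 0
        return mask

    @property
    def element_diameter(self) -> float:
        return self.L_i / 3.0

    @property
    def L_f(self) -> float:
        """Fully spread diameter (enclosing circle of all 43 elements)."""
        r3 = np.linalg.norm(self.offsets[self.layer_index == 3], axis=1).max()
        return float(2.0 * r3 + self.element_diameter)

    def ring_indices(self, ring: int) -> np.ndarray:
        return np.nonzero(self.layer_index == ring)[0]


def build_template(L_i: float) -> CellTemplate:
    """Hexagonal template of 7 + 12 + 24 elements.

    Ring radii interpolate the enclosing diameter linearly from ``L_i``
    (ring 1) to ``2 L_i`` (ring 3): with element diameter ``L_i/3`` the
    radii are ``L_i/3``, ``7 L_i/12`` and ``5 L_i/6``.  Each periphery
    element spawns two children at half the parent's angular spacing on
    either side, so the rings hold 6, 12 and 24 elements.
    """
    if L_i <= 0:
        raise ValueError(f"L_i must be positive, got {L_i}")
    d_e = L_i / 3.0
    radii = [(L_i * (1.0 + 0.5 * (k - 1)) - d_e) / 2.0 for k in (1, 2, 3)]
    offsets = [np.zeros(2)]
    layer = [0]
    parent = [-1]
    angles_prev = None
    index_prev = None
    for ring, (count, radius) in enumerate(zip(RING_COUNTS, radii), start=1):
        if ring == 1:
            angles = np.arange(6) * (math.pi / 3.0)
            parents = np.zeros(6, dtype=int)
        else:
            half = math.pi / count
            angles = np.concatenate([[a - half, a + half] for a in angles_prev])
            parents = np.repeat(index_prev, 2)
        start = len(offsets)
        for a, p in zip(angles, parents):
            offsets.append(radius * np.array([math.cos(a), math.sin(a)]))
            layer.append(ring)
            parent.append(int(p))
        angles_prev = angles
        index_prev = np.arange(start, start + count)
    off3 = np.zeros((len(offsets), 3))
    off3[:, :2] = np.asarray(offsets)
    return CellTemplate(
        L_i=float(L_i),
        offsets=off3,
        layer_index=np.asarray(layer, dtype=int),
        parent=np.asarray(parent, dtype=int),
    )


@dataclass
class Cell:
    """Dynamic state and spring topology of one cell."""

    template: CellTemplate
    positions: np.ndarray
    velocities: np.ndarray
    active: np.ndarray
    terminal: np.ndarray
    frozen: np.ndarray
    sp_i: np.ndarray
    sp_j: np.ndarray
    sp_l0: np.ndarray
    rings_active: int = 1
    center_index: int = 0

    @property
    def L_i(self) -> float:
        return self.template.L_i

    @property
    def n_elements(self) -> int:
        return self.template.n_elements

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def element_diameter(self) -> float:
        return self.template.element_diameter

    @property
    def k_s(self) -> float:
        return K_S_COEF * self.L_i**2

    @property
    def c_s(self) -> float:
        return C_S_COEF * self.L_i**2

    @property
    def mass_scale(self) -> np.ndarray:
        return np.where(self.active, 1.0, INACTIVE_MASS_SCALE)

    @property
    def masses(self) -> np.ndarray:
        """Effective masses: baseline density at element diameter."""
        return self.element_diameter**3 * self.mass_scale

    def enclosing_diameter(self, box: tuple[float, float] | None = None) -> float:
        """Smallest-circle diameter (element radius included) of the active
        elements, in the cell plane (x, y)."""
        return enclosing_diameter(self, box=box)

    def copy(self) -> "Cell":
        return Cell(
            template=self.template,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            active=self.active.copy(),
            terminal=self.terminal.copy(),
            frozen=self.frozen.copy(),
            sp_i=self.sp_i.copy(),
            sp_j=self.sp_j.copy(),
            sp_l0=self.sp_l0.copy(),
            rings_active=self.rings_active,
            center_index=self.center_index,
        )


def _ring_adjacency_springs(template: CellTemplate, ring: int, active: np.ndarray):
    """Consecutive active pairs around one ring (wrapping)."""
    idx = template.ring_indices(ring)
    ang = np.arctan2(template.offsets[idx, 1], template.offsets[idx, 0])
    idx = idx[np.argsort(ang)]
    pairs = []
    n = len(idx)
    for a in range(n):
        i, j = idx[a], idx[(a + 1) % n]
        if active[i] and active[j]:
            pairs.append((i, j))
    return pairs


def _initial_springs(template: CellTemplate):
    pairs = [(0, int(i)) for i in template.ring_indices(1)]
    pairs += _ring_adjacency_springs(
        template, 1, np.ones(template.n_elements, dtype=bool)
    )
    return pairs


def init_cell(
    L_i: float,
    drop_position: tuple[float, float],
    bed,
    clearance: float = 0.1,
) -> Cell:
    """Place a fresh 7-element cell just above the highest bed particle.

    The full 3-ring template is laid out horizontally, centred on
    ``drop_position`` (which must lie inside the bed's box); only the centre
    and first ring are active.  The cell then falls freely onto the bed
    under the world's dynamics.
    """
    template = build_template(L_i)
    x, y = float(drop_position[0]), float(drop_position[1])
    if not (0.0 <= x <= bed.box[0] and 0.0 <= y <= bed.box[1]):
        raise ValueError(
            f"drop position {drop_position} outside box {bed.box[:2]}"
        )
    if bed.n > 0:
        top = float((bed.positions[:, 2] + bed.diameters / 2.0).max())
    else:
        top = bed.floor_z
    z0 = top + template.element_diameter / 2.0 + clearance
    pos = template.offsets + np.array([x, y, z0])
    active = template.layer_index <= 1
    pairs = _initial_springs(template)
    sp_i = np.array([p[0] for p in pairs], dtype=np.int64)
    sp_j = np.array([p[1] for p in pairs], dtype=np.int64)
    sp_l0 = np.linalg.norm(
        template.offsets[sp_i] - template.offsets[sp_j], axis=1
    )
    return Cell(
        template=template,
        positions=pos,
        velocities=np.zeros_like(pos),
        active=active,
        terminal=np.zeros(template.n_elements, dtype=bool),
        frozen=np.zeros(template.n_elements, dtype=bool),
        sp_i=sp_i,
        sp_j=sp_j,
        sp_l0=sp_l0,
    )


def add_layer(cell: Cell, n_bonds: int, bed=None) -> Cell:
    """Activate the next ring (stretch phase), in place.

    Each active, non-terminal element of the current outer ring spawns its
    two precomputed children; children appear at the template position
    relative to the current centre element (lifted just clear of any bed
    particle, so the new protrusion drapes onto the bed from above), tied
    to their parent and to adjacent new elements by fresh structural
    springs at template natural lengths.  A cell with no engaged bond does
    not spread.
    """
    if cell.rings_active >= 3:
        raise ValueError("cell already fully spread (3 rings active)")
    if n_bonds <= 0:
        raise UnbondedCellError("cell has no bonds and cannot spread")
    template = cell.template
    new_ring = cell.rings_active + 1
    children = template.ring_indices(new_ring)
    activated = []
    for c in children:
        p = template.parent[c]
        if cell.active[p] and not cell.terminal[p]:
            activated.append(int(c))
    center_pos = cell.positions[cell.center_index]
    center_vel = cell.velocities[cell.center_index]
    for c in activated:
        cell.active[c] = True
        pos = center_pos + template.offsets[c]
        if bed is not None and bed.n > 0:
            pos[2] = max(pos[2], _clear_z(pos, cell.element_diameter / 2.0, bed))
        cell.positions[c] = pos
        cell.velocities[c] = center_vel
    # a stretch phase re-extends the actomyosin network: every existing
    # spring's natural length returns to its template value before the next
    # contraction ramps them down again
    cell.sp_l0 = np.linalg.norm(
        template.offsets[cell.sp_i] - template.offsets[cell.sp_j], axis=1
    )
    new_pairs = [(int(template.parent[c]), c) for c in activated]
    new_pairs += _ring_adjacency_springs(template, new_ring, cell.active)
    if new_pairs:
        ni = np.array([p[0] for p in new_pairs], dtype=np.int64)
        nj = np.array([p[1] for p in new_pairs], dtype=np.int64)
        nl0 = np.linalg.norm(
            template.offsets[ni] - template.offsets[nj], axis=1
        )
        cell.sp_i = np.concatenate([cell.sp_i, ni])
        cell.sp_j = np.concatenate([cell.sp_j, nj])
        cell.sp_l0 = np.concatenate([cell.sp_l0, nl0])
    cell.rings_active = new_ring
    return cell


def _clear_z(pos: np.ndarray, r_e: float, bed, eps: float = 0.02) -> float:
    """Smallest z at (x, y) where a sphere of radius ``r_e`` clears the bed."""
    d = bed.positions[:, :2] - pos[:2]
    if bed.periodic_xy:
        for k in (0, 1):
            d[:, k] -= bed.box[k] * np.round(d[:, k] / bed.box[k])
    r2 = (d**2).sum(axis=1)
    sumr = r_e + bed.diameters / 2.0
    hit = r2 < sumr**2
    if not hit.any():
        return -np.inf
    dz = np.sqrt(sumr[hit] ** 2 - r2[hit])
    return float((bed.positions[hit, 2] + dz).max() + eps)


def structural_force(
    k: float,
    c: float,
    l0: float,
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    vel_i: np.ndarray,
    vel_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Kelvin-Voigt force pair of one structural spring.

    Returns ``(F_i, F_j)`` with ``F_j = -F_i``: elastic restoring toward
    the natural length ``l0`` along the spring axis, plus viscous damping
    of the full relative velocity (so transverse swings of the network are
    overdamped too, not just axial vibrations).
    """
    d = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    ell = float(np.linalg.norm(d))
    if ell < 1e-12:
        raise DegenerateGeometryError("coincident elements in structural spring")
    nhat = d / ell
    vrel = np.asarray(vel_i, dtype=float) - np.asarray(vel_j, dtype=float)
    f = -k * (ell - l0) * nhat - c * vrel
    return f, -f


# ---------------------------------------------------------------------------
# smallest enclosing circle (Welzl) for the spread-diameter observable


def _circle_two(a, b):
    c = (a + b) / 2.0
    return c, float(np.linalg.norm(a - c))


def _circle_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = (
        (ax**2 + ay**2) * (by - cy)
        + (bx**2 + by**2) * (cy - ay)
        + (cx**2 + cy**2) * (ay - by)
    ) / d
    uy = (
        (ax**2 + ay**2) * (cx - bx)
        + (bx**2 + by**2) * (ax - cx)
        + (cx**2 + cy**2) * (bx - ax)
    ) / d
    ctr = np.array([ux, uy])
    return ctr, float(np.linalg.norm(a - ctr))


def min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing circle of 2-D points (Welzl, iterative)."""
    pts = [np.asarray(p, dtype=float) for p in np.atleast_2d(points)]
    if len(pts) == 0:
        raise ValueError("no points")
    eps = 1e-10
    c, r = pts[0], 0.0
    for i, p in enumerate(pts):
        if np.linalg.norm(p - c) <= r + eps:
            continue
        c, r = p, 0.0
        for j in range(i):
            q = pts[j]
            if np.linalg.norm(q - c) <= r + eps:
                continue
            c, r = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if np.linalg.norm(s - c) <= r + eps:
                    continue
                res = _circle_three(p, q, s)
                if res is not None:
                    c, r = res
    return c, r


def enclosing_diameter(cell: Cell, box: tuple[float, float] | None = None) -> float:
    """Diameter of the smallest circle containing the active elements
    (spheres, not centres) in the x-y plane.

    With a periodic ``box``, positions are first unwrapped relative to the
    centre element by minimum image.
    """
    pos = cell.positions[cell.active][:, :2].copy()
    if box is not None:
        ref = cell.positions[cell.center_index, :2]
        d = pos - ref
        for k in (0, 1):
            d[:, k] -= box[k] * np.round(d[:, k] / box[k])
        pos = ref + d
    _, r = min_enclosing_circle(pos)
    return 2.0 * r + cell.element_diameter
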