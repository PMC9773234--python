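"""Numba kernels: contact/spring/bond forces and the fused Gear time loop.

Everything here operates on flat numpy arrays owned by
:class:`granulocell.world.World`.  The kernels are deliberately monomorphic
(one signature each) so they compile once and can be disk-cached.

Conventions
-----------
* bodies are microparticles (``kind == 0``) and cell elements (``kind == 1``),
* x/y are periodic (minimum image), z is bounded below by a floor plane,
* Gear derivatives are stored in scaled form ``r_k = dt^k / k! * d^k r/dt^k``,
* contact candidates come from a Verlet neighbour list (cell-binned build,
  rebuilt whenever any body has moved more than half the skin),
* contact stiffness is ``Y_base * (d_i + d_j)/2`` scaled by the smaller of
  the two bodies' contact scales (inactive cell layers carry scale 0: they
  do not interact until activated),
* the binding- and structural-spring dashpots are far stiffer than an
  explicit force integrator tolerates, so their viscous part is integrated
  exactly once per step as a pairwise exponential relaxation of the
  relative velocity (momentum-conserving, unconditionally stable); elastic
  terms always go through the Gear corrector unaltered.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# bond states
ENGAGED = 0
REINFORCED = 1
BROKEN = 2

# event codes for the bond log
EV_REINFORCE = 1
EV_BREAK = 2

# Gear 5-value corrector coefficients for second-order ODEs with
# velocity-dependent forces (alpha0 = 19/90 variant).
GEAR_A0 = 19.0 / 90.0
GEAR_A1 = 3.0 / 4.0
GEAR_A3 = 1.0 / 2.0
GEAR_A4 = 1.0 / 12.0


@njit(cache=True, inline="always")
def _mimg(d, L):
    # displacements are always < 1.5 L in magnitude, so one shift suffices
    if d > 0.5 * L:
        return d - L
    elif d < -0.5 * L:
        return d + L
    return d


# half stencil: 13 of the 26 neighbour bins, so each pair is visited once
_STENCIL = np.array(
    [
        [1, 0, 0], [-1, 1, 0], [0, 1, 0], [1, 1, 0],
        [-1, -1, 1], [0, -1, 1], [1, -1, 1], [-1, 0, 1],
        [0, 0, 1], [1, 0, 1], [-1, 1, 1], [0, 1, 1], [1, 1, 1],
    ],
    dtype=np.int64,
)


@njit(cache=True)
def build_pairs(
    pos, Lx, Ly, floor_z, periodic, cutoff, nx, ny, nz, head, nxt, bx, by, bz
):
    """Verlet pair list: all body pairs within ``cutoff`` (skin included).

    Cell-binned two-pass build; pairs are returned as two index arrays.
    Falls back gracefully for any box at least 3 bins wide in x and y
    (callers use the all-pairs path otherwise).
    """
    n = pos.shape[0]
    head[:] = -1
    zlo = floor_z - 2.0 * cutoff
    for i in range(n):
        ix = int(pos[i, 0] / cutoff) % nx
        iy = int(pos[i, 1] / cutoff) % ny
        iz = int((pos[i, 2] - zlo) / cutoff)
        if iz < 0:
            iz = 0
        elif iz >= nz:
            iz = nz - 1
        bx[i] = ix
        by[i] = iy
        bz[i] = iz
        b = ix + nx * (iy + ny * iz)
        nxt[i] = head[b]
        head[b] = i
    c2 = cutoff * cutoff
    out_i = np.empty(0, dtype=np.int64)
    out_j = np.empty(0, dtype=np.int64)
    for phase in range(2):
        cnt = 0
        for i in range(n):
            j = nxt[i]
            while j >= 0:
                dx = _mimg(pos[i, 0] - pos[j, 0], Lx) if periodic == 1 else pos[i, 0] - pos[j, 0]
                dy = _mimg(pos[i, 1] - pos[j, 1], Ly) if periodic == 1 else pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx * dx + dy * dy + dz * dz < c2:
                    if phase == 1:
                        out_i[cnt] = i
                        out_j[cnt] = j
                    cnt += 1
                j = nxt[j]
            for s in range(13):
                jz = bz[i] + _STENCIL[s, 2]
                if jz < 0 or jz >= nz:
                    continue
                jx = (bx[i] + _STENCIL[s, 0]) % nx
                jy = (by[i] + _STENCIL[s, 1]) % ny
                b1 = jx + nx * (jy + ny * jz)
                j = head[b1]
                while j >= 0:
                    dx = _mimg(pos[i, 0] - pos[j, 0], Lx) if periodic == 1 else pos[i, 0] - pos[j, 0]
                    dy = _mimg(pos[i, 1] - pos[j, 1], Ly) if periodic == 1 else pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    if dx * dx + dy * dy + dz * dz < c2:
                        if phase == 1:
                            out_i[cnt] = i
                            out_j[cnt] = j
                        cnt += 1
                    j = nxt[j]
        if phase == 0:
            out_i = np.empty(cnt, dtype=np.int64)
            out_j = np.empty(cnt, dtype=np.int64)
    return out_i, out_j


@njit(cache=True)
def build_pairs_all(pos, n):
    """All-pairs candidate list for tiny systems."""
    m = n * (n - 1) // 2
    out_i = np.empty(m, dtype=np.int64)
    out_j = np.empty(m, dtype=np.int64)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            out_i[c] = i
            out_j[c] = j
            c += 1
    return out_i, out_j


@njit(cache=True)
def _forces(
    pos,
    vel,
    F,
    rad,
    mass,
    cscale,
    mobile,
    frozen,
    kind,
    Lx,
    Ly,
    floor_z,
    periodic,
    yu,
    yl,
    g,
    dt,
    pi,
    pj,
    sp_i,
    sp_j,
    sp_k,
    sp_c,
    sp_l0,
    th_e,
    th_off,
    th_k,
    th_c,
    th_on,
    center_idx,
    b_e,
    b_p,
    b_offe,
    b_offp,
    b_k,
    b_c,
    b_state,
    b_fel,
    ee_ok,
    n_part,
):
    n = pos.shape[0]
    any_ep = 0
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    # gravity (effective, buoyancy-reduced masses) and floor contact
    for i in range(n):
        if mobile[i] == 1 and frozen[i] == 0:
            F[i, 2] -= mass[i] * g
            delta = floor_z - (pos[i, 2] - rad[i])
            if delta > 0.0:
                ybase = yu if vel[i, 2] < 0.0 else yl
                F[i, 2] += ybase * (2.0 * rad[i]) * cscale[i] * delta
    # hysteretic normal contacts over the candidate pair list
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        if periodic == 1:
            dx = _mimg(dx, Lx)
            dy = _mimg(dy, Ly)
        dz = pos[i, 2] - pos[j, 2]
        sumr = rad[i] + rad[j]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= sumr * sumr or d2 < 1e-24:
            continue
        dist = np.sqrt(d2)
        delta = sumr - dist
        nxv = dx / dist
        nyv = dy / dist
        nzv = dz / dist
        vn = (
            (vel[i, 0] - vel[j, 0]) * nxv
            + (vel[i, 1] - vel[j, 1]) * nyv
            + (vel[i, 2] - vel[j, 2]) * nzv
        )
        # approaching means |r_ij| decreasing: vn < 0 -> stiff loading branch
        ybase = yu if vn < 0.0 else yl
        cs = cscale[i] if cscale[i] < cscale[j] else cscale[j]
        if cs <= 0.0:
            continue  # inactive cell layers do not interact
        if kind[i] == 1 and kind[j] == 1:
            # near-neighbour elements in the spring network are excluded
            # from collision (their template spacing is below one element
            # diameter); distant pairs collide, so the sheet cannot fold
            # through itself
            if ee_ok[i - n_part, j - n_part] == 0:
                continue
        f = ybase * sumr * cs * delta
        if mobile[i] == 1 and frozen[i] == 0:
            F[i, 0] += f * nxv
            F[i, 1] += f * nyv
            F[i, 2] += f * nzv
        if mobile[j] == 1 and frozen[j] == 0:
            F[j, 0] -= f * nxv
            F[j, 1] -= f * nyv
            F[j, 2] -= f * nzv
        if kind[i] != kind[j]:
            any_ep = 1
    # structural springs: elastic part (viscous part is integrated exactly
    # in the time loop, like the binding-spring dashpots)
    for m in range(sp_i.shape[0]):
        i = sp_i[m]
        j = sp_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        if periodic == 1:
            dx = _mimg(dx, Lx)
            dy = _mimg(dy, Ly)
        dz = pos[i, 2] - pos[j, 2]
        ell = np.sqrt(dx * dx + dy * dy + dz * dz)
        if ell < 1e-12:
            continue
        fi = 1 if (mobile[i] == 1 and frozen[i] == 0) else 0
        fj = 1 if (mobile[j] == 1 and frozen[j] == 0) else 0
        if fi == 0 and fj == 0:
            continue
        f = -sp_k[m] * (ell - sp_l0[m]) / ell
        if fi == 1:
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
        if fj == 1:
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
    # fictitious tethers of inactive elements to the template frame that
    # translates with the centre element (no reaction force: they stand in
    # for a binding to the bed)
    for m in range(th_e.shape[0]):
        if th_on[m] == 0:
            continue
        e = th_e[m]
        if mobile[e] == 0 or frozen[e] == 1:
            continue
        dx = pos[e, 0] - pos[center_idx, 0]
        dy = pos[e, 1] - pos[center_idx, 1]
        if periodic == 1:
            dx = _mimg(dx, Lx)
            dy = _mimg(dy, Ly)
        dz = pos[e, 2] - pos[center_idx, 2]
        ux = dx - th_off[m, 0]
        uy = dy - th_off[m, 1]
        uz = dz - th_off[m, 2]
        ceff = th_c[m]
        clim = 0.2 * mass[e] / dt
        if ceff > clim:
            ceff = clim
        F[e, 0] += -th_k[m] * ux - ceff * (vel[e, 0] - vel[center_idx, 0])
        F[e, 1] += -th_k[m] * uy - ceff * (vel[e, 1] - vel[center_idx, 1])
        F[e, 2] += -th_k[m] * uz - ceff * (vel[e, 2] - vel[center_idx, 2])
    # binding springs: elastic part only (the dashpot c_b is far too stiff
    # for an explicit force and is integrated exactly in the time loop as a
    # pairwise exponential velocity relaxation)
    for m in range(b_e.shape[0]):
        b_fel[m] = 0.0
        if b_state[m] != ENGAGED:
            continue
        e = b_e[m]
        p = b_p[m]
        dx = pos[e, 0] - pos[p, 0]
        dy = pos[e, 1] - pos[p, 1]
        if periodic == 1:
            dx = _mimg(dx, Lx)
            dy = _mimg(dy, Ly)
        dz = pos[e, 2] - pos[p, 2]
        ux = dx + b_offe[m, 0] - b_offp[m, 0]
        uy = dy + b_offe[m, 1] - b_offp[m, 1]
        uz = dz + b_offe[m, 2] - b_offp[m, 2]
        b_fel[m] = b_k[m] * np.sqrt(ux * ux + uy * uy + uz * uz)
        fe = 1 if (mobile[e] == 1 and frozen[e] == 0) else 0
        fp = 1 if (mobile[p] == 1 and frozen[p] == 0) else 0
        if fe == 0 and fp == 0:
            continue
        fx = -b_k[m] * ux
        fy = -b_k[m] * uy
        fz = -b_k[m] * uz
        if fe == 1:
            F[e, 0] += fx
            F[e, 1] += fy
            F[e, 2] += fz
        if fp == 1:
            F[p, 0] -= fx
            F[p, 1] -= fy
            F[p, 2] -= fz
    return any_ep


@njit(cache=True)
def _pair_drag(r1, mass, mobile, frozen, b_e, b_p, b_c, b_state, dt):
    """Exactly integrated pairwise dashpots (binding and structural).

    For each engaged pair the relative velocity decays by
    ``exp(-c dt / mu)`` over one step (mu the reduced mass of the movable
    bodies); the momentum transfer is split by mass.  Unconditionally
    stable and exactly dissipative, which force-based damping is not at
    the binding springs' damping rates.
    """
    for m in range(b_e.shape[0]):
        if b_state[m] != ENGAGED:
            continue
        e = b_e[m]
        p = b_p[m]
        fe = 1 if (mobile[e] == 1 and frozen[e] == 0) else 0
        fp = 1 if (mobile[p] == 1 and frozen[p] == 0) else 0
        if fe == 0 and fp == 0:
            continue
        if fe == 1 and fp == 1:
            mu = mass[e] * mass[p] / (mass[e] + mass[p])
        elif fe == 1:
            mu = mass[e]
        else:
            mu = mass[p]
        f = np.exp(-b_c[m] * dt / mu)
        for k in range(3):
            dv = (1.0 - f) * (r1[e, k] - r1[p, k])
            if fe == 1:
                r1[e, k] -= dv * mu / mass[e]
            if fp == 1:
                r1[p, k] += dv * mu / mass[p]


@njit(cache=True)
def advance(
    n_steps,
    step0,
    pos,
    r1,
    r2,
    r3,
    r4,
    rad,
    mass,
    cscale,
    active,
    mobile,
    frozen,
    kind,
    terminal,
    Lx,
    Ly,
    floor_z,
    periodic,
    yu,
    yl,
    g,
    dt,
    sp_i,
    sp_j,
    sp_k,
    sp_c,
    sp_l0,
    sp_rate,
    sp_state,
    shrinking,
    th_e,
    th_off,
    th_k,
    th_c,
    th_on,
    center_idx,
    b_e,
    b_p,
    b_offe,
    b_offp,
    b_k,
    b_c,
    b_state,
    b_dist0,
    b_cref,
    adhesion_on,
    f_reinforce,
    detach_dist,
    gdamp,
    stop_mode,
    stop_value,
    check_every,
    ev_step,
    ev_bond,
    ev_type,
    ev_force,
    head,
    nxt,
    bxa,
    bya,
    bza,
    nx,
    ny,
    nz,
    cutoff,
    skin,
    use_cells,
    ee_ok,
    n_part,
):
    """Integrate ``n_steps`` Gear predictor-corrector steps.

    stop_mode: 0 none; 1 stop when mean kinetic energy per integrated body
    drops below ``stop_value``; 2 stop when the mean active-element speed
    drops below ``stop_value``; 3 stop at the first element-particle contact.
    Returns (steps_done, n_events, last_metric).
    """
    n = pos.shape[0]
    nb = b_e.shape[0]
    vel = np.empty((n, 3))
    F = np.empty((n, 3))
    b_fel = np.zeros(nb)
    pos_ref = pos.copy()
    if use_cells == 1:
        pi, pj = build_pairs(
            pos, Lx, Ly, floor_z, periodic, cutoff, nx, ny, nz,
            head, nxt, bxa, bya, bza,
        )
    else:
        pi, pj = build_pairs_all(pos, n)
    half_skin2 = (0.5 * skin) ** 2
    ev_cap = ev_step.shape[0]
    ev_n = 0
    metric = 1.0e30
    steps_done = 0
    inv_dt = 1.0 / dt
    half_dt2 = 0.5 * dt * dt
    for s in range(n_steps):
        # --- predict
        for i in range(n):
            if mobile[i] == 1 and frozen[i] == 0:
                for k in range(3):
                    pos[i, k] += r1[i, k] + r2[i, k] + r3[i, k] + r4[i, k]
                    r1[i, k] += 2.0 * r2[i, k] + 3.0 * r3[i, k] + 4.0 * r4[i, k]
                    r2[i, k] += 3.0 * r3[i, k] + 6.0 * r4[i, k]
                    r3[i, k] += 4.0 * r4[i, k]
        if periodic == 1:
            for i in range(n):
                pos[i, 0] = pos[i, 0] % Lx
                pos[i, 1] = pos[i, 1] % Ly
        for i in range(n):
            for k in range(3):
                vel[i, k] = r1[i, k] * inv_dt
        # --- refresh the neighbour list if anything moved half a skin
        if use_cells == 1:
            moved = 0.0
            for i in range(n):
                if mobile[i] == 1 and frozen[i] == 0:
                    dx = _mimg(pos[i, 0] - pos_ref[i, 0], Lx)
                    dy = _mimg(pos[i, 1] - pos_ref[i, 1], Ly)
                    dz = pos[i, 2] - pos_ref[i, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 > moved:
                        moved = d2
            if moved > half_skin2:
                pi, pj = build_pairs(
                    pos, Lx, Ly, floor_z, periodic, cutoff, nx, ny, nz,
                    head, nxt, bxa, bya, bza,
                )
                pos_ref[:, :] = pos
        # --- evaluate forces
        any_ep = _forces(
            pos, vel, F, rad, mass, cscale, mobile, frozen, kind,
            Lx, Ly, floor_z, periodic, yu, yl, g, dt, pi, pj,
            sp_i, sp_j, sp_k, sp_c, sp_l0,
            th_e, th_off, th_k, th_c, th_on, center_idx,
            b_e, b_p, b_offe, b_offp, b_k, b_c, b_state, b_fel,
            ee_ok, n_part,
        )
        # --- correct
        for i in range(n):
            if mobile[i] == 1 and frozen[i] == 0:
                im = 1.0 / mass[i]
                for k in range(3):
                    acc = F[i, k] * im * half_dt2
                    dr = acc - r2[i, k]
                    pos[i, k] += GEAR_A0 * dr
                    r1[i, k] += GEAR_A1 * dr
                    r2[i, k] = acc
                    r3[i, k] += GEAR_A3 * dr
                    r4[i, k] += GEAR_A4 * dr
        # --- exactly integrated spring/bond dashpots
        _pair_drag(r1, mass, mobile, frozen, sp_i, sp_j, sp_c, sp_state, dt)
        if nb > 0:
            _pair_drag(r1, mass, mobile, frozen, b_e, b_p, b_c, b_state, dt)
        # --- optional global quench (overdamped relaxation phases only)
        if gdamp > 0.0:
            fq = np.exp(-gdamp * dt)
            for i in range(n):
                if mobile[i] == 1 and frozen[i] == 0:
                    r1[i, 0] *= fq
                    r1[i, 1] *= fq
                    r1[i, 2] *= fq
        # --- contraction: steady shrink of natural lengths, floored at zero
        if shrinking == 1:
            for m in range(sp_l0.shape[0]):
                if sp_l0[m] > 0.0:
                    l0 = sp_l0[m] - sp_rate[m]
                    sp_l0[m] = l0 if l0 > 0.0 else 0.0
        # --- adhesion kinetics (reinforcement and detachment), every step
        if adhesion_on == 1:
            for m in range(nb):
                if b_state[m] != ENGAGED:
                    continue
                if b_fel[m] >= f_reinforce:
                    # talin reinforcement: freeze element and particle
                    b_state[m] = REINFORCED
                    e = b_e[m]
                    p = b_p[m]
                    frozen[e] = 1
                    frozen[p] = 1
                    for k in range(3):
                        r1[e, k] = 0.0
                        r2[e, k] = 0.0
                        r3[e, k] = 0.0
                        r4[e, k] = 0.0
                        r1[p, k] = 0.0
                        r2[p, k] = 0.0
                        r3[p, k] = 0.0
                        r4[p, k] = 0.0
                    if ev_n < ev_cap:
                        ev_step[ev_n] = step0 + s
                        ev_bond[ev_n] = m
                        ev_type[ev_n] = EV_REINFORCE
                        ev_force[ev_n] = b_fel[m]
                        ev_n += 1
                    continue
                if b_dist0[m] > 0.0:
                    # radial reference: the centre element's position at
                    # binding time, so a pinned element never "contracts";
                    # detach_dist is the absolute budget 4% of L_i
                    e = b_e[m]
                    dx = pos[e, 0] - b_cref[m, 0]
                    dy = pos[e, 1] - b_cref[m, 1]
                    if periodic == 1:
                        dx = _mimg(dx, Lx)
                        dy = _mimg(dy, Ly)
                    dz = pos[e, 2] - b_cref[m, 2]
                    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if b_dist0[m] - dist > detach_dist:
                        # integrin lifetime exceeded: unbind, stop spreading
                        # in this direction
                        b_state[m] = BROKEN
                        terminal[e] = 1
                        if ev_n < ev_cap:
                            ev_step[ev_n] = step0 + s
                            ev_bond[ev_n] = m
                            ev_type[ev_n] = EV_BREAK
                            ev_force[ev_n] = b_fel[m]
                            ev_n += 1
        steps_done = s + 1
        # --- stop conditions
        if stop_mode == 3 and any_ep > 0:
            metric = 1.0
            break
        if (stop_mode == 1 or stop_mode == 2) and steps_done % check_every == 0:
            if stop_mode == 1:
                ke = 0.0
                cnt = 0
                for i in range(n):
                    if mobile[i] == 1 and frozen[i] == 0:
                        v2 = (
                            r1[i, 0] * r1[i, 0]
                            + r1[i, 1] * r1[i, 1]
                            + r1[i, 2] * r1[i, 2]
                        ) * inv_dt * inv_dt
                        ke += 0.5 * mass[i] * v2
                        cnt += 1
                metric = ke / cnt if cnt > 0 else 0.0
            else:
                vsum = 0.0
                cnt = 0
                for i in range(n):
                    if (
                        kind[i] == 1
                        and active[i] == 1
                        and mobile[i] == 1
                        and frozen[i] == 0
                    ):
                        vsum += np.sqrt(
                            r1[i, 0] * r1[i, 0]
                            + r1[i, 1] * r1[i, 1]
                            + r1[i, 2] * r1[i, 2]
                        ) * inv_dt
                        cnt += 1
                metric = vsum / cnt if cnt > 0 else 0.0
            if metric < stop_value:
                break
    return steps_done, ev_n, metric


@njit(cache=True)
def forces_once(
    pos,
    vel,
    rad,
    mass,
    cscale,
    mobile,
    frozen,
    kind,
    Lx,
    Ly,
    floor_z,
    periodic,
    yu,
    yl,
    g,
    dt,
    sp_i,
    sp_j,
    sp_k,
    sp_c,
    sp_l0,
    th_e,
    th_off,
    th_k,
    th_c,
    th_on,
    center_idx,
    b_e,
    b_p,
    b_offe,
    b_offp,
    b_k,
    b_c,
    b_state,
    head,
    nxt,
    bxa,
    bya,
    bza,
    nx,
    ny,
    nz,
    cutoff,
    use_cells,
    ee_ok,
    n_part,
):
    """Single force evaluation; returns (forces, bond elastic magnitudes)."""
    n = pos.shape[0]
    F = np.empty((n, 3))
    b_fel = np.zeros(b_e.shape[0])
    if use_cells == 1:
        pi, pj = build_pairs(
            pos, Lx, Ly, floor_z, periodic, cutoff, nx, ny, nz,
            head, nxt, bxa, bya, bza,
        )
    else:
        pi, pj = build_pairs_all(pos, n)
    _forces(
        pos, vel, F, rad, mass, cscale, mobile, frozen, kind,
        Lx, Ly, floor_z, periodic, yu, yl, g, dt, pi, pj,
        sp_i, sp_j, sp_k, sp_c, sp_l0,
        th_e, th_off, th_k, th_c, th_on, center_idx,
        b_e, b_p, b_offe, b_offp, b_k, b_c, b_state, b_fel,
        ee_ok, n_part,
    )
    return F, b_fel
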