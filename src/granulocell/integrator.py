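"""Fourth-order Gear predictor-corrector for second-order dynamics.

The integrator stores, per body, the position and four higher derivatives in
scaled form ``r_k = dt^k / k! * d^k r / dt^k`` (the classic 5-value Gear
scheme).  A step predicts all values by a Taylor expansion, evaluates forces
at the predicted state and corrects every stored derivative with the
acceleration defect.  The corrector weights are the second-order-ODE set with
``alpha_0 = 19/90``, appropriate when forces depend on velocities (all the
viscoelastic springs here do).

This module is the small, transparent implementation used for unit systems
of a few bodies; the production loop in :mod:`granulocell._core` applies the
identical arithmetic fused with force evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._core import GEAR_A0, GEAR_A1, GEAR_A3, GEAR_A4

__all__ = ["GearState", "gear_step"]


@dataclass
class GearState:
    """Integrator state for ``n`` bodies in ``dim`` dimensions.

    ``r1``..``r4`` are the scaled derivatives; velocities are ``r1 / dt``.
    ``mobile`` masks bodies that are integrated; the rest stay put.
    """

    pos: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    r3: np.ndarray
    r4: np.ndarray
    mass: np.ndarray
    dt: float
    mobile: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.mobile is None:
            self.mobile = np.ones(self.pos.shape[0], dtype=bool)

    @classmethod
    def from_initial(
        cls,
        pos: np.ndarray,
        vel: np.ndarray,
        mass: np.ndarray,
        dt: float,
        mobile: np.ndarray | None = None,
    ) -> "GearState":
        pos = np.atleast_2d(np.asarray(pos, dtype=float)).copy()
        vel = np.atleast_2d(np.asarray(vel, dtype=float))
        z = np.zeros_like(pos)
        state = cls(pos, vel * dt, z.copy(), z.copy(), z.copy(),
                    np.asarray(mass, dtype=float), dt)
        if mobile is not None:
            state.mobile = np.asarray(mobile, dtype=bool)
        return state

    @property
    def vel(self) -> np.ndarray:
        return self.r1 / self.dt

    def prime(self, forces_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> "GearState":
        """Warm-start the stored acceleration from the initial forces.

        Without this the first corrector step leaves a permanent half-step
        velocity offset on trajectories driven by a constant force.
        """
        acc = np.asarray(forces_fn(self.pos, self.vel), dtype=float) / self.mass[:, None]
        self.r2[self.mobile] = acc[self.mobile] * (0.5 * self.dt**2)
        return self


def gear_step(state: GearState, forces_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> GearState:
    """Advance ``state`` by one predictor-corrector step in place.

    ``forces_fn(pos, vel)`` must return the force array for all bodies at
    the supplied (predicted) state.  Immobile bodies are untouched.  Raises
    on non-finite forces, reporting which bodies misbehaved.
    """
    m = state.mobile
    pos, r1, r2, r3, r4 = state.pos, state.r1, state.r2, state.r3, state.r4
    # predictor (Pascal-triangle Taylor shift of the scaled derivatives)
    pos[m] += r1[m] + r2[m] + r3[m] + r4[m]
    r1[m] += 2.0 * r2[m] + 3.0 * r3[m] + 4.0 * r4[m]
    r2[m] += 3.0 * r3[m] + 6.0 * r4[m]
    r3[m] += 4.0 * r4[m]
    forces = np.asarray(forces_fn(pos, state.vel), dtype=float)
    if not np.all(np.isfinite(forces[m])):
        bad = np.nonzero(~np.isfinite(forces).all(axis=-1))[0]
        raise FloatingPointError(f"non-finite forces on bodies {bad.tolist()}")
    acc_scaled = forces / state.mass[:, None] * (0.5 * state.dt**2)
    dr = acc_scaled - r2
    pos[m] += GEAR_A0 * dr[m]
    r1[m] += GEAR_A1 * dr[m]
    r2[m] = acc_scaled[m]
    r3[m] += GEAR_A3 * dr[m]
    r4[m] += GEAR_A4 * dr[m]
    return state
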