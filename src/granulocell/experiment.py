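"""Full simulations: bed -> cell drop -> spread/contract cycles -> fate.

A *scenario* is one cell dropped at one position on one settled bed.  The
spreading protocol repeats up to the third element ring:

1. recompute bindings (the bond population turns over each cycle),
2. stretch: activate the next ring and relax until the cell is at rest,
3. contract: shrink every structural spring's natural length to zero at a
   steady rate while reinforcement/detachment fire every step.

Cell fate is quantified by the **volume ratio**: the union-of-spheres
volume of the final active elements divided by the volume of a reference
cell run through the same schedule with contraction disabled (the
no-contraction upper bound).  The ratio is ~1 for a cell whose adhesions
hold and drops toward its contracted minimum when all bonds break.

Sweeps run a grid of (aspect ratio, relative density, bed layers) with
``n_drop_positions x n_bed_configs`` replicates per grid cell and report
mean +/- standard error.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .adhesion import AdhesionParams
from .cell import Cell, add_layer, init_cell
from .dem import DT, KE_THRESHOLD, ContactLaw, GranularBed, generate_particles, settle_bed
from .errors import RelaxationError
from .seeding import derive_seed
from .world import World

__all__ = [
    "ScenarioConfig",
    "Simulation",
    "run_scenario",
    "run_sweep",
    "SweepResult",
    "union_of_spheres_volume",
    "cell_volume",
    "volume_ratio",
    "drop_grid",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario / sweep cell.

    ``aspect_ratio`` is the cell-to-particle size ratio ``L_i/d`` (the bed
    is always unit mean diameter, so the cell diameter equals the ratio).
    ``relative_density`` is 1 (polystyrene), 2 (glass) or ``inf``
    (sintered, immobile).  Replicates come from ``n_bed_configs``
    independent beds times ``n_drop_positions`` drop sites on a square
    grid.
    """

    aspect_ratio: float = 1.0
    relative_density: float = 1.0
    bed_layers: int = 3
    box_size: float = 20.0
    dispersion: float = 0.05
    n_drop_positions: int = 16
    n_bed_configs: int = 10
    master_seed: int = 0
    # numerics
    dt: float = DT
    ke_threshold: float = KE_THRESHOLD
    settle_max_steps: int = 3_000_000
    drop_max_steps: int = 200_000
    relax_chunk: int = 2_000
    relax_min_steps: int = 10_000
    relax_max_steps: int = 60_000
    relax_speed_tol: float = 5e-3
    relax_quench: float = 2.0
    contraction_steps: int = 50_000
    post_contract_steps: int = 4_000
    volume_samples: int = 2**16

    @property
    def samples_per_cell(self) -> int:
        return self.n_drop_positions * self.n_bed_configs

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------- volumes


def union_of_spheres_volume(
    centers: np.ndarray,
    radii: np.ndarray | float,
    seed: int = 0,
    n_samples: int = 2**16,
) -> float:
    """Union volume of a set of spheres by scrambled-Sobol sampling.

    Quasi-random points fill the bounding box; the hit fraction times the
    box volume estimates the union to well under 1% relative error at the
    default sample count for the sphere counts used here.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        raise ValueError("empty sphere set")
    radii = np.broadcast_to(np.asarray(radii, dtype=float), centers.shape[0])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    span = hi - lo
    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    pts = lo + sampler.random(n_samples) * span
    inside = np.zeros(n_samples, dtype=bool)
    r2 = radii**2
    for c, rr in zip(centers, r2):
        inside |= ((pts - c) ** 2).sum(axis=1) <= rr
    return float(inside.mean() * span.prod())


def cell_volume(
    cell: Cell,
    box: tuple[float, float] | None = None,
    seed: int = 0,
    n_samples: int = 2**16,
) -> float:
    """Union-of-spheres volume of the active elements (periodic-unwrapped)."""
    pos = cell.positions[cell.active].copy()
    if box is not None:
        ref = cell.positions[cell.center_index]
        d = pos - ref
        for k in (0, 1):
            d[:, k] -= box[k] * np.round(d[:, k] / box[k])
        pos = ref + d
    return union_of_spheres_volume(
        pos, cell.element_diameter / 2.0, seed=seed, n_samples=n_samples
    )


def volume_ratio(
    cell_final: Cell,
    cell_reference: Cell,
    box: tuple[float, float] | None = None,
    seed: int = 0,
    n_samples: int = 2**16,
) -> float:
    """Final over no-contraction-reference union volume, in (0, 1]."""
    v_f = cell_volume(cell_final, box=box, seed=seed, n_samples=n_samples)
    v_r = cell_volume(cell_reference, box=box, seed=seed, n_samples=n_samples)
    return min(v_f / v_r, 1.0)


def drop_grid(n: int, box: tuple[float, float, float]) -> np.ndarray:
    """``n`` drop positions on a uniform square grid over the box section."""
    g = round(math.sqrt(n))
    if g * g != n:
        raise ValueError(f"n_drop_positions must be a perfect square, got {n}")
    xs = (np.arange(g) + 0.5) * box[0] / g
    ys = (np.arange(g) + 0.5) * box[1] / g
    return np.array([(x, y) for x in xs for y in ys])


# ------------------------------------------------------------- simulation


class Simulation:
    """One cell on one bed: drop, spreading cycles, contraction, fate."""

    def __init__(
        self,
        bed: GranularBed,
        aspect_ratio: float,
        drop_position: tuple[float, float],
        config: ScenarioConfig | None = None,
        law: ContactLaw = ContactLaw(),
    ):
        self.config = config or ScenarioConfig(aspect_ratio=aspect_ratio)
        self.bed = bed.copy()
        self.cell = init_cell(aspect_ratio, drop_position, self.bed)
        self.adhesion = AdhesionParams(L_i=aspect_ratio)
        # keep the stiffest elastic mode of the binding springs inside the
        # integrator's stability region (h * omega <= 0.22); the worst mode
        # couples one element to a light particle carrying several bonds
        m_e = self.cell.element_diameter**3
        m_p = (0.95 * 1.0) ** 3
        omega2 = self.adhesion.k_b * (6.0 / m_p + 1.0 / m_e)
        dt_bond = 0.22 / math.sqrt(omega2)
        dt = min(self.config.dt, dt_bond)
        self.world = World(
            self.bed, self.cell, adhesion=self.adhesion, law=law, dt=dt
        )
        self.converged = True

    # -- phases --------------------------------------------------------

    def drop(self) -> None:
        """Free fall until the first element-particle contact, then bind."""
        cfg = self.config
        if self.bed.n > 0:
            self.world.run(cfg.drop_max_steps, stop_mode=3)
        else:
            # flat rigid plane: fall until floor contact, handled by relax
            pass
        self.world.bind()

    def relax(self, max_steps: int | None = None) -> bool:
        """Integrate until the cell is at rest (bind checks throughout).

        Rest is detected as the mean active-element speed dropping below
        the tolerance; that is the practical proxy for "net force zero" on
        a hysteretic contact bed, where instantaneous forces chatter at the
        branch switch even in mechanical equilibrium.  A weak global
        velocity quench accelerates the overdamped approach to the static
        state without changing it.
        """
        cfg = self.config
        budget = max_steps if max_steps is not None else cfg.relax_max_steps
        done = 0
        while done < budget:
            chunk = min(cfg.relax_chunk, budget - done)
            res = self.world.run(
                chunk,
                stop_mode=2,
                stop_value=cfg.relax_speed_tol,
                check_every=min(500, chunk),
                gdamp=cfg.relax_quench,
            )
            done += res["steps"]
            self.world.bind()
            if res["metric"] < cfg.relax_speed_tol and done >= cfg.relax_min_steps:
                return True
        self.converged = False
        return False

    def contract(self) -> None:
        """One contraction phase: natural lengths -> 0 at a steady rate.

        Reinforcement and detachment checks run every step.  After the
        shrink schedule a short settling window lets the network finish
        relaxing onto its (possibly frozen) anchors.
        """
        cfg = self.config
        n = cfg.contraction_steps
        self.world.sp_rate[:] = self.world.sp_l0 / n
        done = 0
        # one integrin lifetime, in steps: during a lifetime the cell
        # contracts 4% of L_i, while a full phase contracts the outer
        # radius (5/6 L_i); bonds turn over on this timescale, so slip
        # budgets (and anchors) renew and only elements dragged along with
        # the contraction exceed 4% within one lifetime
        lifetime = max(int(n * self.adhesion.detachment_fraction / (5.0 / 6.0)), 200)
        while done < n:
            m = min(lifetime, n - done)
            self.world.run(m, adhesion_on=True, shrinking=True)
            done += m
            # integrin turnover: engaged bonds re-anchor with a fresh slip
            # budget; new contacts engage instantaneously
            self.world.bind(refresh_existing=True)
            if self._all_active_frozen():
                self.world.sp_l0[self.world.sp_l0 > 0] = 0.0
                break
        self.world.sp_rate[:] = 0.0
        if not self._all_active_frozen():
            self.world.run(
                cfg.post_contract_steps,
                stop_mode=2,
                stop_value=cfg.relax_speed_tol,
                check_every=500,
                adhesion_on=True,
            )
            self.world.bind()

    def _all_active_frozen(self) -> bool:
        sel = (self.world.kind == 1) & (self.world.active == 1)
        return bool((self.world.frozen[sel] == 1).all())

    def _periphery_all_terminal(self) -> bool:
        ring = self.cell.template.ring_indices(self.cell.rings_active)
        act = self.cell.active[ring]
        if not act.any():
            return True
        return bool(self.cell.terminal[ring][act].all())

    # -- protocol ------------------------------------------------------

    def _stretch(self) -> bool:
        """One stretch phase: rebind, activate the next ring, relax.

        Returns False (without spreading) when the cell is fully detached,
        fully spread, or every periphery direction is terminal.
        """
        self.world.bind(refresh_existing=True)
        if self.world.n_engaged == 0 and self.world.n_reinforced == 0:
            return False  # fully detached: the cell cannot spread
        if self.cell.rings_active >= 3 or self._periphery_all_terminal():
            return False
        self.world.sync_all()
        add_layer(
            self.cell,
            n_bonds=self.world.n_engaged + self.world.n_reinforced,
            bed=self.bed,
        )
        # push snapped child positions into the world state
        n_p = self.world.n_particles
        self.world.pos[n_p:] = self.cell.positions
        self.world.r1[n_p:] = self.cell.velocities * self.world.dt
        self.world.refresh_topology()
        self.relax()
        return True

    def _summary(self, cycles: int) -> dict:
        self.world.sync_all()
        return {
            "cycles": cycles,
            "n_active": self.cell.n_active,
            "n_reinforced": self.world.n_reinforced,
            "n_broken": self.world.n_broken,
            "n_bonds": len(self.world.bonds),
            "converged": self.converged,
        }

    def fork(self) -> "Simulation":
        """Deep copy of the current state (for the no-contraction branch)."""
        self.world.sync_all()
        other = object.__new__(Simulation)
        other.config = self.config
        other.bed = self.bed.copy()
        other.cell = self.cell.copy()
        other.adhesion = self.adhesion
        other.converged = self.converged
        other.world = World(
            other.bed,
            other.cell,
            adhesion=other.adhesion,
            law=self.world.law,
            dt=self.world.dt,
        )
        other.world.frozen[:] = self.world.frozen
        other.world.step = self.world.step
        other.world.bonds = [
            dataclasses.replace(
                b,
                anchor_element=b.anchor_element.copy(),
                anchor_particle=b.anchor_particle.copy(),
            )
            for b in self.world.bonds
        ]
        other.world._refresh_bonds()
        return other

    def run_protocol(self, contract_enabled: bool = True) -> dict:
        """Drop the cell and run the spreading/contraction cycles."""
        self.drop()
        self.relax()
        cycles = 0
        for _ in range(2):  # rings 2 and 3
            if not self._stretch():
                break
            if contract_enabled:
                self.contract()
            cycles += 1
        return self._summary(cycles)

    def run_pair(self) -> tuple[dict, "Simulation", dict]:
        """Run the contraction scenario and its no-contraction reference.

        Both branches share the drop, first relaxation and first stretch
        (they are identical up to the first contraction); the reference is
        forked there and completes the spreading schedule without any
        contraction.  Returns (info, reference_sim, reference_info).
        """
        self.drop()
        self.relax()
        cycles = 0
        ref = None
        if self._stretch():
            cycles += 1
            ref = self.fork()
            self.contract()
            if self._stretch():
                cycles += 1
                self.contract()
        info = self._summary(cycles)
        if ref is None:
            ref = self.fork()
            ref_info = ref._summary(cycles)
        else:
            ref._stretch()
            ref_info = ref._summary(cycles)
        return info, ref, ref_info


# ------------------------------------------------------------------ sweeps


def _bed_cache_key(cfg: ScenarioConfig, bed_index: int) -> tuple:
    return (cfg.bed_layers, cfg.box_size, cfg.dispersion, cfg.master_seed, bed_index)


def make_bed(cfg: ScenarioConfig, bed_index: int) -> GranularBed:
    """Generate and settle one bed of the sweep (deterministic per index)."""
    seed = derive_seed(cfg.master_seed, 1, bed_index)
    bed = generate_particles(
        cfg.bed_layers,
        dispersion=cfg.dispersion,
        box=(cfg.box_size, cfg.box_size, cfg.box_size),
        seed=seed,
    )
    return settle_bed(
        bed,
        dt=cfg.dt,
        ke_threshold=cfg.ke_threshold,
        max_steps=cfg.settle_max_steps,
    )


def run_scenario(
    cfg: ScenarioConfig,
    bed_index: int = 0,
    drop_index: int = 0,
    bed_cache: dict | None = None,
    keep_simulation: bool = False,
) -> dict:
    """One sample: settle/load the bed, drop, spread, contract, measure.

    The no-contraction reference replays the identical scenario with
    contraction (and adhesion kinetics) disabled; the volume ratio compares
    final to reference union volumes with a common sampling seed.
    """
    key = _bed_cache_key(cfg, bed_index)
    if bed_cache is not None and key in bed_cache:
        bed = bed_cache[key]
    else:
        bed = make_bed(cfg, bed_index)
        if bed_cache is not None:
            bed_cache[key] = bed
    bed = bed.with_relative_density(cfg.relative_density)
    drop = drop_grid(cfg.n_drop_positions, bed.box)[drop_index]
    vol_seed = derive_seed(cfg.master_seed, 2, bed_index, drop_index)

    sim = Simulation(bed, cfg.aspect_ratio, drop, config=cfg)
    info, ref, ref_info = sim.run_pair()

    ratio = volume_ratio(
        sim.cell,
        ref.cell,
        box=bed.box[:2],
        seed=vol_seed,
        n_samples=cfg.volume_samples,
    )
    record = {
        "aspect_ratio": cfg.aspect_ratio,
        "relative_density": cfg.relative_density,
        "bed_layers": cfg.bed_layers,
        "bed_index": bed_index,
        "drop_index": drop_index,
        "volume_ratio": ratio,
        "n_active_final": info["n_active"],
        "n_active_reference": ref_info["n_active"],
        "n_reinforced": info["n_reinforced"],
        "n_broken": info["n_broken"],
        "n_bonds": info["n_bonds"],
        "converged": info["converged"] and ref_info["converged"],
        "bed_seed": derive_seed(cfg.master_seed, 1, bed_index),
        "volume_seed": vol_seed,
    }
    if keep_simulation:
        record["simulation"] = sim
        record["reference"] = ref
    return record


@dataclass
class SweepResult:
    """Per-sample records plus per-cell aggregates of a sweep."""

    samples: pd.DataFrame
    n_failed: int = 0

    @property
    def aggregate(self) -> pd.DataFrame:
        g = self.samples.groupby(
            ["aspect_ratio", "relative_density", "bed_layers"], dropna=False
        )["volume_ratio"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        out = out.rename(columns={"count": "n"})
        out["sem"] = out["sem"].fillna(0.0)
        return out

    def mean_ratio(self, aspect_ratio=None, relative_density=None, bed_layers=None):
        df = self.samples
        if aspect_ratio is not None:
            df = df[df.aspect_ratio == aspect_ratio]
        if relative_density is not None:
            df = df[df.relative_density == relative_density]
        if bed_layers is not None:
            df = df[df.bed_layers == bed_layers]
        return float(df.volume_ratio.mean())


def run_sweep(
    base: ScenarioConfig,
    aspect_ratios=(1.0,),
    relative_densities=(1.0,),
    bed_layers=(3,),
    bed_cache: dict | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run the full (ratio x density x layers x bed x position) grid.

    Beds are settled once per (layers, bed index) and shared across ratios
    and densities (a density variant only rescales masses, not the static
    packing).  Failed samples are excluded with a warning count.
    """
    if bed_cache is None:
        bed_cache = {}
    records = []
    n_failed = 0
    for layers in bed_layers:
        for ratio in aspect_ratios:
            for density in relative_densities:
                cfg = base.replace(
                    aspect_ratio=float(ratio),
                    relative_density=float(density),
                    bed_layers=int(layers),
                )
                for b in range(cfg.n_bed_configs):
                    for p in range(cfg.n_drop_positions):
                        try:
                            rec = run_scenario(cfg, b, p, bed_cache=bed_cache)
                        except (RelaxationError, FloatingPointError) as exc:
                            n_failed += 1
                            warnings.warn(
                                f"sample (ratio={ratio}, density={density}, "
                                f"layers={layers}, bed={b}, drop={p}) failed: {exc}"
                            )
                            continue
                        records.append(rec)
                        if progress:
                            print(
                                f"ratio={ratio} rho={density} layers={layers} "
                                f"bed={b} drop={p}: vr={rec['volume_ratio']:.3f}",
                                flush=True,
                            )
    return SweepResult(samples=pd.DataFrame.from_records(records), n_failed=n_failed)
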