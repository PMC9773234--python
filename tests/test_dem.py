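"""Granular bed: generation, hysteretic contacts, settling."""

import numpy as np
import pytest

from granulocell import (
    ContactLaw,
    GranularBed,
    contact_force,
    floor_contact_force,
    generate_particles,
    make_fixture,
    settle_bed,
)
from granulocell.errors import DegenerateGeometryError, RelaxationError
from granulocell.world import World


class TestGenerateParticles:
    def test_count_rule_three_layers(self):
        bed = generate_particles(3, box=(20.0, 20.0, 20.0), seed=1)
        assert bed.n == 3 * 20 * 20

    def test_zero_dispersion_is_monodisperse(self):
        bed = generate_particles(1, dispersion=0.0, box=(4.0, 4.0, 8.0), seed=5)
        assert bed.n == 16
        assert np.allclose(bed.diameters, 1.0)

    def test_dispersion_bounds(self):
        bed = generate_particles(2, dispersion=0.05, box=(8.0, 8.0, 8.0), seed=2)
        assert bed.diameters.min() >= 0.95
        assert bed.diameters.max() <= 1.05

    def test_no_initial_overlap(self):
        bed = generate_particles(3, box=(8.0, 8.0, 8.0), seed=4)
        assert bed.max_pair_overlap_fraction() == 0.0

    def test_same_seed_identical(self):
        a = generate_particles(2, box=(6.0, 6.0, 8.0), seed=9)
        b = generate_particles(2, box=(6.0, 6.0, 8.0), seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.diameters, b.diameters)

    def test_all_above_floor(self):
        bed = generate_particles(2, box=(6.0, 6.0, 8.0), seed=9)
        assert (bed.positions[:, 2] > bed.floor_z).all()

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            generate_particles(1, dispersion=0.5, box=(6.0, 6.0, 6.0), seed=0)

    def test_too_small_box_rejected(self):
        with pytest.raises(ValueError):
            generate_particles(1, box=(1.5, 6.0, 6.0), seed=0)


class TestContactLaw:
    def test_defaults_and_restitution(self):
        law = ContactLaw()
        assert law.y_u == 5e4 and law.y_l == 5e3
        assert law.restitution == pytest.approx(np.sqrt(0.1), rel=1e-12)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ContactLaw(y_u=1.0, y_l=2.0)


class TestContactForce:
    def test_zero_outside_contact(self):
        f = contact_force([0, 0, 0], [0, 0, 2.0], 1.0, 1.0, [0, 0, 0], [0, 0, 0])
        assert np.allclose(f, 0.0)

    def test_separating_branch_at_rest(self):
        # overlapping pair at rest uses the soft unloading stiffness
        delta = 0.01
        f = contact_force(
            [0, 0, 1.0 - delta], [0, 0, 0], 1.0, 1.0, [0, 0, 0], [0, 0, 0]
        )
        law = ContactLaw()
        assert f[2] == pytest.approx(law.y_l * 1.0 * delta, rel=1e-12)

    def test_loading_branch_while_approaching(self):
        delta = 0.01
        f = contact_force(
            [0, 0, 1.0 - delta], [0, 0, 0], 1.0, 1.0, [0, 0, -1.0], [0, 0, 0]
        )
        law = ContactLaw()
        assert f[2] == pytest.approx(law.y_u * 1.0 * delta, rel=1e-12)

    def test_stiffness_scales_with_pair_mean_diameter(self):
        delta = 0.01
        gap = (1.0 + 3.0) / 2 - delta
        f = contact_force([0, 0, gap], [0, 0, 0], 1.0, 3.0, [0, 0, 0], [0, 0, 0])
        assert f[2] == pytest.approx(ContactLaw().y_l * 2.0 * delta, rel=1e-12)

    def test_coincident_centres_raise(self):
        with pytest.raises(DegenerateGeometryError):
            contact_force([0, 0, 0], [0, 0, 0], 1.0, 1.0, [0, 0, 0], [0, 0, 0])

    def test_floor_contact_uses_own_diameter(self):
        f = floor_contact_force([0, 0, 1.4], 1.0, [0, 0, 0], floor_z=1.0)
        assert f[2] == pytest.approx(ContactLaw().y_l * 1.0 * 0.1, rel=1e-12)


class TestRestitution:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_body_drop_recovers_sqrt_stiffness_ratio(self, seed):
        """Head-on drop onto a fixed particle: e = sqrt(Y_l/Y_u)."""
        scene = make_fixture("two_particle_collision", seed=seed)
        w = World(scene.bed)
        dt = w.dt
        impact, rebound = None, None
        prev_gap = None
        for _ in range(2000):
            w.run(50)
            gap = w.pos[1, 2] - w.pos[0, 2] - 0.5 * (
                scene.bed.diameters[0] + scene.bed.diameters[1]
            )
            v = w.r1[1, 2] / dt
            if gap <= 0 and impact is None:
                impact = abs(v)
            if impact is not None and gap > 1e-4 and v > 0:
                rebound = v
                break
            prev_gap = gap
        assert impact is not None and rebound is not None
        e = rebound / impact
        assert e == pytest.approx(ContactLaw().restitution, rel=0.05)


class TestSettleBed:
    def test_single_particle_comes_to_rest_on_floor(self):
        bed = GranularBed(
            positions=[[2.0, 2.0, 3.0]], diameters=[1.0], box=(4.0, 4.0, 8.0)
        )
        out = settle_bed(bed, max_steps=500_000)
        assert out.relaxed
        assert out.mean_kinetic_energy() < 2e-3
        assert out.positions[0, 2] == pytest.approx(out.floor_z + 0.5, abs=1e-3)

    def test_mini_bed_relaxes_below_threshold(self, mini_bed_settled):
        assert mini_bed_settled.relaxed
        assert mini_bed_settled.mean_kinetic_energy() < 2e-3
        assert (mini_bed_settled.positions[:, 2] > mini_bed_settled.floor_z).all()

    def test_rest_overlaps_below_one_percent(self, small_bed_settled):
        assert small_bed_settled.max_pair_overlap_fraction() < 0.01

    def test_settled_height_consistent_with_three_layers(self, small_bed_settled):
        assert 2.5 <= small_bed_settled.height_above_floor <= 4.5

    def test_resettling_returns_quickly(self, mini_bed_settled):
        again = settle_bed(mini_bed_settled, max_steps=200_000)
        assert again.relaxed
        # an already-relaxed bed barely moves (minimum-image displacement)
        d = again.positions - mini_bed_settled.positions
        for k in (0, 1):
            d[:, k] -= mini_bed_settled.box[k] * np.round(
                d[:, k] / mini_bed_settled.box[k]
            )
        assert np.abs(d).max() < 0.05

    def test_bitwise_reproducible_for_fixed_seed(self):
        a = settle_bed(generate_particles(1, box=(4.0, 4.0, 8.0), seed=21), max_steps=600_000)
        b = settle_bed(generate_particles(1, box=(4.0, 4.0, 8.0), seed=21), max_steps=600_000)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_particle_count_conserved_under_periodic_wrap(self, small_bed_settled):
        assert small_bed_settled.n == 3 * 10 * 10
        assert (small_bed_settled.positions[:, 0] >= 0).all()
        assert (small_bed_settled.positions[:, 0] < 10.0).all()

    def test_unconverged_budget_raises(self):
        bed = generate_particles(1, box=(4.0, 4.0, 8.0), seed=1)
        with pytest.raises(RelaxationError):
            settle_bed(bed, max_steps=2_000)


class TestEnergyDissipation:
    def test_total_energy_non_increasing_during_settling(self):
        bed = generate_particles(1, box=(4.0, 4.0, 8.0), seed=13)
        w = World(bed)
        def total_energy():
            ke = 0.5 * (w.mass[:, None] * (w.r1 / w.dt) ** 2).sum()
            pe = (w.mass * w.g * w.pos[:, 2]).sum()
            return ke + pe
        energies = [total_energy()]
        for _ in range(40):
            w.run(2_000)
            energies.append(total_energy())
        diffs = np.diff(energies)
        # inelastic contacts dissipate; free-fall stretches conserve energy
        # to integrator tolerance, collisions only ever remove it
        assert (diffs < 1e-4 * abs(energies[0])).all()
        assert energies[-1] < energies[0]


class TestKernelMatchesReferenceForces:
    def test_pairwise_contact_forces_match_numpy_reference(self, rng):
        """The fused kernel reproduces the pure-python contact law."""
        n = 25
        bed = GranularBed(
            positions=rng.uniform(1.2, 4.8, size=(n, 3)) + [[0, 0, 1.0]],
            diameters=rng.uniform(0.95, 1.05, size=n),
            velocities=rng.normal(0, 0.3, size=(n, 3)),
            box=(6.0, 6.0, 8.0),
            periodic_xy=False,
        )
        w = World(bed)
        F_kernel = w.compute_forces()
        law = ContactLaw()
        F_ref = np.zeros((n, 3))
        for i in range(n):
            F_ref[i, 2] -= bed.masses[i]
            F_ref[i] += floor_contact_force(
                bed.positions[i], bed.diameters[i], bed.velocities[i], 1.0, law
            )
            for j in range(n):
                if i == j:
                    continue
                d = np.linalg.norm(bed.positions[i] - bed.positions[j])
                if 0 < d < 0.5 * (bed.diameters[i] + bed.diameters[j]):
                    F_ref[i] += contact_force(
                        bed.positions[i], bed.positions[j],
                        bed.diameters[i], bed.diameters[j],
                        bed.velocities[i], bed.velocities[j], law,
                    )
        assert np.allclose(F_kernel, F_ref, rtol=1e-10, atol=1e-10)
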