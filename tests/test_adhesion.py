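"""Binding, reinforcement and detachment kinetics."""

import numpy as np
import pytest

from granulocell import make_fixture
from granulocell.adhesion import (
    AdhesionParams,
    Bond,
    BondState,
    bind_on_contact,
    bond_force,
    check_detachment,
    check_reinforcement,
    elastic_force_magnitude,
    find_contacts,
)
from granulocell.cell import init_cell
from granulocell.errors import BondStateError
from granulocell.units import max_cell_force_dimless


def make_bond(L=1.0, dist0=0.5):
    p = AdhesionParams(L_i=L)
    return (
        Bond(
            element_id=0,
            particle_id=0,
            anchor_element=np.zeros(3),
            anchor_particle=np.zeros(3),
            k_b=p.k_b,
            c_b=p.c_b,
            dist0=dist0,
        ),
        p,
    )


class TestAdhesionParams:
    @pytest.mark.parametrize("L", [0.5, 1.0, 2.0, 4.0])
    def test_spring_maxes_out_at_quarter_permille_stretch(self, L):
        p = AdhesionParams(L_i=L)
        assert p.k_b * (2.5e-5 * L) == pytest.approx(p.f_max, rel=1e-12)

    def test_f_max_is_buoyant_weight_of_82_over_32_sphere(self):
        p = AdhesionParams(L_i=1.0)
        assert p.f_max == pytest.approx(max_cell_force_dimless(1.0), rel=1e-12)
        assert p.f_max == pytest.approx((82.0 / 32.0) ** 3, rel=1e-12)

    def test_damping_constant(self):
        p = AdhesionParams(L_i=2.0)
        assert p.c_b == pytest.approx(p.f_max / (1.25e-2 * 2.0), rel=1e-12)

    def test_detachment_budget_is_four_percent_of_cell_diameter(self):
        p = AdhesionParams(L_i=2.0)
        assert p.detachment_distance == pytest.approx(0.08)

    def test_binding_displacement_below_detachment_threshold(self):
        p = AdhesionParams(L_i=1.0)
        assert 2.5e-5 * p.L_i < p.detachment_distance


class TestBondForce:
    def test_zero_at_rest(self):
        bond, _ = make_bond()
        f_e, f_p = bond_force(bond, [0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0])
        assert np.allclose(f_e, 0) and np.allclose(f_p, 0)

    def test_static_stretch_at_max_displacement_gives_w_max(self):
        bond, p = make_bond(L=1.0)
        x = 2.5e-5 * 1.0
        f_e, f_p = bond_force(bond, [x, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0])
        assert np.linalg.norm(f_e) == pytest.approx(p.f_max, rel=1e-12)
        assert np.allclose(f_e, -f_p)

    def test_linearity_at_half_displacement(self):
        bond, p = make_bond(L=1.0)
        x = 0.5 * 2.5e-5
        assert elastic_force_magnitude(bond, [x, 0, 0], [0, 0, 0]) == pytest.approx(
            p.f_max / 2, rel=1e-12
        )

    def test_broken_bond_query_raises(self):
        bond, _ = make_bond()
        bond.state = BondState.BROKEN
        with pytest.raises(BondStateError):
            bond_force(bond, [0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0])


class TestStateMachine:
    def test_reinforce_at_threshold(self):
        bond, p = make_bond()
        check_reinforcement(bond, 1.01 * p.f_max, p.f_max)
        assert bond.state is BondState.REINFORCED

    def test_no_reinforce_below_threshold(self):
        bond, p = make_bond()
        check_reinforcement(bond, 0.99 * p.f_max, p.f_max)
        assert bond.state is BondState.ENGAGED

    def test_reinforced_bond_never_breaks(self):
        bond, p = make_bond(dist0=0.5)
        bond.state = BondState.REINFORCED
        check_detachment(bond, 0.0, p.detachment_distance)
        assert bond.state is BondState.REINFORCED

    def test_detachment_beyond_budget(self):
        bond, p = make_bond(L=1.0, dist0=0.5)
        check_detachment(bond, 0.5 - 0.041, p.detachment_distance)
        assert bond.state is BondState.BROKEN

    def test_no_detachment_within_budget(self):
        bond, p = make_bond(L=1.0, dist0=0.5)
        check_detachment(bond, 0.5 - 0.039, p.detachment_distance)
        assert bond.state is BondState.ENGAGED

    def test_transitions_are_absorbing(self):
        bond, p = make_bond()
        bond.state = BondState.BROKEN
        with pytest.raises(BondStateError):
            check_reinforcement(bond, 2 * p.f_max, p.f_max)
        with pytest.raises(BondStateError):
            check_detachment(bond, 0.0, p.detachment_distance)
        bond.state = BondState.REINFORCED
        with pytest.raises(BondStateError):
            check_reinforcement(bond, 2 * p.f_max, p.f_max)


class TestBindOnContact:
    def test_touching_element_binds_once(self):
        scene = make_fixture("three_particle_pocket")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        # lower the cell so the centre elements overlap the pocket spheres
        cell.positions[:, 2] = 2.05
        params = AdhesionParams(L_i=1.0)
        bonds = bind_on_contact(cell, scene.bed, params)
        assert len(bonds) >= 3  # the pocket supports at least three contacts
        assert all(b.state is BondState.ENGAGED for b in bonds)
        # no duplicates on rebinding
        again = bind_on_contact(cell, scene.bed, params, existing=bonds)
        assert again == []

    def test_one_bond_per_element(self):
        scene = make_fixture("three_particle_pocket")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        cell.positions[:, 2] = 2.05
        bonds = bind_on_contact(cell, scene.bed, AdhesionParams(L_i=1.0))
        elems = [b.element_id for b in bonds]
        assert len(elems) == len(set(elems))

    def test_terminal_and_frozen_elements_do_not_bind(self):
        scene = make_fixture("three_particle_pocket")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        cell.positions[:, 2] = 2.05
        cell.terminal[:] = True
        assert bind_on_contact(cell, scene.bed, AdhesionParams(L_i=1.0)) == []

    def test_bond_records_binding_geometry(self):
        scene = make_fixture("three_particle_pocket")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        cell.positions[:, 2] = 2.05
        bonds = bind_on_contact(cell, scene.bed, AdhesionParams(L_i=1.0))
        for b in bonds:
            # anchors coincide at creation: zero initial extension
            u = (
                cell.positions[b.element_id]
                + b.anchor_element
                - scene.bed.positions[b.particle_id]
                - b.anchor_particle
            )
            # particle anchor may be expressed through a periodic image
            u[:2] -= scene.bed.box[0] * np.round(u[:2] / scene.bed.box[0])
            assert np.linalg.norm(u) < 1e-10
            d = np.linalg.norm(
                cell.positions[b.element_id] - cell.positions[cell.center_index]
            )
            assert b.dist0 == pytest.approx(d, abs=1e-12)


class TestFindContacts:
    def test_gap_means_no_contact(self):
        out = find_contacts(
            np.array([[0.0, 0.0, 2.0]]), 0.5, np.array([[0.0, 0.0, 0.0]]), np.array([0.5])
        )
        assert out == []

    def test_overlap_detected_with_anchor_midway(self):
        out = find_contacts(
            np.array([[0.0, 0.0, 0.9]]), 0.5, np.array([[0.0, 0.0, 0.0]]), np.array([0.5])
        )
        assert len(out) == 1
        _, p, off_e, off_p = out[0]
        contact_z = 0.9 + off_e[2]
        assert contact_z == pytest.approx(0.45, abs=1e-12)
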