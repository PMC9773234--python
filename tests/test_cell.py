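"""Cell template geometry, spreading topology and structural springs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from granulocell import make_fixture
from granulocell.cell import (
    C_S_COEF,
    K_S_COEF,
    Cell,
    add_layer,
    build_template,
    enclosing_diameter,
    init_cell,
    min_enclosing_circle,
    structural_force,
)
from granulocell.errors import DegenerateGeometryError, UnbondedCellError


class TestTemplate:
    def test_ring_populations(self):
        t = build_template(1.0)
        assert t.n_elements == 43
        counts = np.bincount(t.layer_index)
        assert list(counts) == [1, 6, 12, 24]

    def test_element_diameter_is_one_third(self):
        t = build_template(0.9)
        assert t.element_diameter == pytest.approx(0.3)

    def test_initial_enclosing_diameter_equals_L_i(self):
        t = build_template(1.3)
        first = t.offsets[t.layer_index <= 1][:, :2]
        _, r = min_enclosing_circle(first)
        assert 2 * r + t.element_diameter == pytest.approx(1.3, abs=1e-9)

    def test_full_template_enclosing_diameter_is_twice_L_i(self):
        t = build_template(1.0)
        _, r = min_enclosing_circle(t.offsets[:, :2])
        assert 2 * r + t.element_diameter == pytest.approx(2.0, abs=1e-9)
        assert t.L_f == pytest.approx(2.0, abs=1e-9)

    def test_sixfold_symmetry_of_first_shell(self):
        t = build_template(1.0)
        ring1 = t.offsets[t.ring_indices(1)][:, :2]
        rot = np.array(
            [[np.cos(np.pi / 3), -np.sin(np.pi / 3)], [np.sin(np.pi / 3), np.cos(np.pi / 3)]]
        )
        rotated = ring1 @ rot.T
        for p in rotated:
            assert np.min(np.linalg.norm(ring1 - p, axis=1)) < 1e-9

    def test_each_child_has_two_per_parent(self):
        t = build_template(1.0)
        for ring in (2, 3):
            parents, counts = np.unique(t.parent[t.ring_indices(ring)], return_counts=True)
            assert (counts == 2).all()
            assert len(parents) == len(t.ring_indices(ring - 1))

    def test_collision_mask_excludes_near_graph_neighbours(self):
        t = build_template(1.0)
        mask = t.collision_mask()
        assert mask[0, 1] == 0  # centre and first ring are connected
        # colliding pairs never overlap in the template
        for i in range(43):
            for j in range(i + 1, 43):
                if mask[i, j]:
                    d = np.linalg.norm(t.offsets[i] - t.offsets[j])
                    assert d > t.element_diameter


class TestInitCell:
    def test_seven_active_elements_hexagonal(self):
        scene = make_fixture("three_particle_pocket")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        assert cell.n_active == 7
        assert enclosing_diameter(cell) == pytest.approx(1.0, abs=1e-9)

    def test_cell_starts_above_bed(self):
        scene = make_fixture("three_particle_pocket")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        top = (scene.bed.positions[:, 2] + scene.bed.diameters / 2).max()
        assert (cell.positions[:, 2] > top).all()

    def test_drop_outside_box_rejected(self):
        scene = make_fixture("three_particle_pocket")
        with pytest.raises(ValueError):
            init_cell(1.0, (99.0, 0.0), scene.bed)

    def test_spring_constants(self):
        scene = make_fixture("flat_rigid_plane")
        cell = init_cell(2.0, scene.drop_position, scene.bed)
        assert cell.k_s == pytest.approx(K_S_COEF * 4.0)
        assert cell.c_s / cell.k_s == pytest.approx(1e-2, rel=1e-12)


class TestAddLayer:
    def _fresh(self, L=1.0):
        scene = make_fixture("flat_rigid_plane")
        return init_cell(L, scene.drop_position, scene.bed)

    def test_element_count_sequence_7_19_43(self):
        cell = self._fresh()
        assert cell.n_active == 7
        add_layer(cell, n_bonds=1)
        assert cell.n_active == 19
        add_layer(cell, n_bonds=1)
        assert cell.n_active == 43

    def test_cannot_spread_past_three_rings(self):
        cell = self._fresh()
        add_layer(cell, 1)
        add_layer(cell, 1)
        with pytest.raises(ValueError):
            add_layer(cell, 1)

    def test_unbonded_cell_does_not_spread(self):
        cell = self._fresh()
        with pytest.raises(UnbondedCellError):
            add_layer(cell, n_bonds=0)

    def test_terminal_parents_spawn_no_children(self):
        cell = self._fresh()
        cell.terminal[cell.template.ring_indices(1)] = True
        add_layer(cell, n_bonds=1)
        assert cell.n_active == 7  # all periphery terminal: nothing spawned

    def test_partial_terminal_gives_partial_ring(self):
        cell = self._fresh()
        ring1 = cell.template.ring_indices(1)
        cell.terminal[ring1[:3]] = True
        add_layer(cell, n_bonds=1)
        assert cell.n_active == 7 + 2 * 3

    def test_natural_lengths_reset_to_template_on_stretch(self):
        cell = self._fresh()
        cell.sp_l0[:] = 0.0  # as if fully contracted
        add_layer(cell, n_bonds=1)
        t = cell.template
        expected = np.linalg.norm(t.offsets[cell.sp_i] - t.offsets[cell.sp_j], axis=1)
        assert np.allclose(cell.sp_l0, expected)


class TestStructuralForce:
    def test_zero_at_natural_length_and_rest(self):
        f_i, f_j = structural_force(
            6.25, 0.0625, 1.0, [0, 0, 0], [1, 0, 0], [0, 0, 0], [0, 0, 0]
        )
        assert np.allclose(f_i, 0) and np.allclose(f_j, 0)

    def test_static_stretch_magnitude(self):
        f_i, _ = structural_force(
            6.25, 0.0625, 1.0, [1.01, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]
        )
        assert np.linalg.norm(f_i) == pytest.approx(0.0625, rel=1e-10)

    def test_force_pair_sums_to_zero(self, rng):
        p1, p2 = rng.normal(size=3), rng.normal(size=3)
        v1, v2 = rng.normal(size=3), rng.normal(size=3)
        f_i, f_j = structural_force(2.0, 0.1, 0.5, p1, p2, v1, v2)
        assert np.allclose(f_i + f_j, 0.0, atol=1e-14)

    def test_coincident_elements_raise(self):
        with pytest.raises(DegenerateGeometryError):
            structural_force(1.0, 0.1, 1.0, [0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0])


class TestSpringVibrations:
    def test_pair_vibrations_decay_within_a_few_periods(self):
        """A stretched spring pair rings down fast enough that vibrations
        are negligible on the timescale of a spreading cycle."""
        from granulocell.world import World

        scene = make_fixture("flat_rigid_plane")
        cell = init_cell(1.0, scene.drop_position, scene.bed)
        w = World(scene.bed, cell)
        # disable gravity to watch the pure spring mode
        w.g = 0.0
        i, j = int(w.sp_i[0]), int(w.sp_j[0])
        l0 = w.sp_l0[0]
        # stretch the first spring by 20%
        direction = w.pos[j] - w.pos[i]
        w.pos[j] = w.pos[i] + direction * 1.2
        amp0 = 0.2 * l0
        # three natural periods of the pair mode
        mu = cell.masses[0] / 2.0
        period = 2 * np.pi / np.sqrt(cell.k_s / mu)
        n = int(3 * period / w.dt)
        w.run(n)
        ell = np.linalg.norm(w.pos[j] - w.pos[i])
        assert abs(ell - l0) < 0.5 * amp0


class TestMinEnclosingCircle:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 25), st.integers(0, 10_000))
    def test_contains_all_points_and_is_minimal(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        c, r = min_enclosing_circle(pts)
        dists = np.linalg.norm(pts - c, axis=1)
        assert (dists <= r + 1e-8).all()
        # minimality: some point lies on the boundary
        assert dists.max() >= r - 1e-6
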