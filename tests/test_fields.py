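"""Field engine: grids, probe energies, similarity indices, assembly."""

import math

import numpy as np
import pytest

from fieldqsar.fields import (
    COULOMB_KCAL,
    FieldParams,
    GridSpec,
    ProbeSpec,
    assemble_descriptor_matrix,
    build_grid,
    comfa_electrostatic_field,
    comfa_steric_field,
    comsia_field,
)

PROBE = ProbeSpec()
PARAMS = FieldParams()


# ----------------------------------------------------------------------
# independent brute-force oracle: plain python loops over atoms and nodes
# ----------------------------------------------------------------------
def brute_force_fields(structure, grid, probe, params):
    pts = grid.points()
    steric = np.zeros(len(pts))
    elec = np.zeros(len(pts))
    sim_s = np.zeros(len(pts))
    for pi, p in enumerate(pts):
        e_s = 0.0
        e_e = 0.0
        a_s = 0.0
        for ai in range(structure.n_atoms):
            r = math.dist(p, structure.coords[ai])
            R = structure.vdw_radii[ai] + probe.vdw_radius
            eps = math.sqrt(params.atom_epsilon * probe.steric_epsilon)
            if r == 0:
                e_s = math.inf
            else:
                e_s += eps * ((R / r) ** 12 - 2 * (R / r) ** 6)
                e_e += params.coulomb_constant * probe.charge * structure.partial_charges[ai] / r**2
            w = (structure.vdw_radii[ai] / 1.7) ** 3
            a_s -= probe.steric_weight * w * math.exp(-params.attenuation_alpha * r * r)
        steric[pi] = min(max(e_s, -params.energy_cutoff), params.energy_cutoff)
        elec[pi] = min(max(e_e, -params.energy_cutoff), params.energy_cutoff)
        sim_s[pi] = a_s
    return steric, elec, sim_s


class TestBuildGrid:
    def test_single_atom_coverage(self, make_structure):
        s = make_structure([[0.0, 0.0, 0.0]])
        grid = build_grid([s], spacing=2.0, margin=4.0)
        assert grid.contains(s.coords).all()
        assert np.all(np.asarray(grid.origin) <= -4.0)
        assert np.all(grid.upper >= 4.0)

    def test_covers_all_structures(self, make_structure, rng):
        a = make_structure(rng.normal(size=(5, 3)) * 3)
        b = make_structure(rng.normal(size=(5, 3)) * 3 + 10)
        grid = build_grid([a, b], spacing=2.0, margin=4.0)
        assert grid.contains(np.vstack([a.coords, b.coords])).all()

    def test_zero_margin_node_on_lattice_included(self, make_structure):
        """Closed bounds: an atom exactly on a lattice node stays inside."""
        s = make_structure([[2.0, 4.0, -2.0], [6.0, 6.0, 0.0]])
        grid = build_grid([s], spacing=2.0, margin=0.0)
        pts = grid.points()
        for atom in s.coords:
            assert np.any(np.all(np.isclose(pts, atom, atol=1e-9), axis=1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestComfaSteric:
    def test_empty_molecule_zero(self, make_structure):
        s = make_structure(np.empty((0, 3)))
        grid = GridSpec(origin=(-2, -2, -2), spacing=2.0, shape=(3, 3, 3))
        assert np.all(comfa_steric_field(s, grid, PROBE, PARAMS) == 0)

    def test_minimum_at_contact_distance(self, make_structure):
        """At r = r_atom + r_probe the 6-12 form sits at exactly -eps."""
        s = make_structure([[0.0, 0.0, 0.0]], radii=[1.7])
        R = 1.7 + PROBE.vdw_radius
        grid = GridSpec(origin=(R, 0, 0), spacing=1.0, shape=(2, 2, 2))
        e = comfa_steric_field(s, grid, PROBE, PARAMS)[0]
        eps = math.sqrt(PARAMS.atom_epsilon * PROBE.steric_epsilon)
        assert e == pytest.approx(-eps, rel=1e-10)

    def test_core_clamps_to_cutoff(self, make_structure):
        s = make_structure([[0.0, 0.0, 0.0]])
        grid = GridSpec(origin=(0, 0, 0), spacing=0.5, shape=(2, 2, 2))
        e = comfa_steric_field(s, grid, PROBE, PARAMS)
        assert e[0] == pytest.approx(30.0)  # node on the atom: clamp
        assert np.max(np.abs(e)) <= 30.0


class TestComfaElectrostatic:
    def test_zero_charges_zero_field(self, make_structure):
        s = make_structure([[0, 0, 0], [1, 1, 1]])
        grid = GridSpec(origin=(-2, -2, -2), spacing=2.0, shape=(3, 3, 3))
        assert np.all(comfa_electrostatic_field(s, grid, PROBE, PARAMS) == 0)

    def test_closed_form_with_distance_dielectric(self, make_structure):
        """+1 e at 2 Å from the +1 probe with eps(r)=r: 332.0636/4 = 83.016,
        clamped to the 30 kcal/mol cutoff; without the clamp the raw value
        appears."""
        s = make_structure([[0.0, 0.0, 0.0]], charges=[1.0])
        grid = GridSpec(origin=(2.0, 0, 0), spacing=2.0, shape=(2, 2, 2))
        clamped = comfa_electrostatic_field(s, grid, PROBE, PARAMS)[0]
        assert clamped == pytest.approx(30.0)
        loose = FieldParams(energy_cutoff=1000.0)
        raw = comfa_electrostatic_field(s, grid, PROBE, loose)[0]
        assert raw == pytest.approx(COULOMB_KCAL / 4.0, rel=1e-12)

    def test_sign_symmetry(self, make_structure, rng):
        coords = rng.normal(size=(5, 3)) * 2
        q = rng.uniform(-0.3, 0.3, 5)
        grid = GridSpec(origin=(-6, -6, -6), spacing=3.0, shape=(5, 5, 5))
        loose = FieldParams(energy_cutoff=1e9)  # avoid clamp asymmetry
        e_pos = comfa_electrostatic_field(make_structure(coords, charges=q), grid, PROBE, loose)
        e_neg = comfa_electrostatic_field(make_structure(coords, charges=-q), grid, PROBE, loose)
        np.testing.assert_allclose(e_neg, -e_pos, atol=1e-10)


class TestComsia:
    def test_single_atom_closed_form(self, make_structure):
        s = make_structure([[0.0, 0.0, 0.0]], radii=[1.7])  # steric weight 1
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(2, 2, 2))
        a = comsia_field(s, grid, PROBE, PARAMS, kind="S")
        assert a[0] == pytest.approx(-1.0, rel=1e-12)  # r = 0
        # r = 1 along z: -exp(-0.3)
        assert a[1] == pytest.approx(-math.exp(-0.3), rel=1e-12)

    def test_additivity_of_superposed_atoms(self, make_structure):
        grid = GridSpec(origin=(-2, -2, -2), spacing=2.0, shape=(3, 3, 3))
        one = comsia_field(make_structure([[0.3, 0.1, 0.0]]), grid, PROBE, PARAMS, "S")
        two = comsia_field(
            make_structure([[0.3, 0.1, 0.0], [0.3, 0.1, 0.0]]), grid, PROBE, PARAMS, "S"
        )
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_magnitude_monotone_in_alpha(self, make_structure, rng):
        s = make_structure(rng.normal(size=(6, 3)))
        grid = GridSpec(origin=(-4, -4, -4), spacing=2.0, shape=(5, 5, 5))
        prev = None
        for alpha in (0.1, 0.3, 0.6, 1.0):
            a = comsia_field(s, grid, PROBE, FieldParams(attenuation_alpha=alpha), "S")
            assert np.all(a <= 1e-15)  # nonpositive for positive weights
            if prev is not None:
                assert np.all(a >= prev - 1e-12)  # decays toward 0
            prev = a

    def test_unknown_kind_rejected(self, make_structure):
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(2, 2, 2))
        with pytest.raises(ValueError, match="kind"):
            comsia_field(make_structure([[0, 0, 0]]), grid, PROBE, PARAMS, kind="Q")


def test_translation_invariance(make_structure, rng):
    coords = rng.normal(size=(8, 3)) * 2
    q = rng.uniform(-0.4, 0.4, 8)
    shift = np.array([7.3, -2.1, 4.4])
    g0 = GridSpec(origin=(-6, -6, -6), spacing=2.0, shape=(7, 7, 7))
    g1 = GridSpec(origin=tuple(np.array(g0.origin) + shift), spacing=2.0, shape=(7, 7, 7))
    s0 = make_structure(coords, charges=q)
    s1 = make_structure(coords + shift, charges=q)
    for fn in (comfa_steric_field, comfa_electrostatic_field):
        np.testing.assert_allclose(
            fn(s0, g0, PROBE, PARAMS), fn(s1, g1, PROBE, PARAMS), atol=1e-10
        )
    np.testing.assert_allclose(
        comsia_field(s0, g0, PROBE, PARAMS, "S"),
        comsia_field(s1, g1, PROBE, PARAMS, "S"),
        atol=1e-10,
    )


def test_engine_matches_brute_force_oracle(make_structure, rng):
    """Vectorised fields equal a naive per-atom double loop to 1e-10."""
    coords = rng.normal(size=(20, 3)) * 3
    s = make_structure(
        coords,
        charges=rng.uniform(-0.5, 0.5, 20),
        radii=rng.uniform(1.2, 1.9, 20),
    )
    grid = GridSpec(origin=(-5, -5, -5), spacing=2.5, shape=(5, 5, 5))
    bf_steric, bf_elec, bf_sim = brute_force_fields(s, grid, PROBE, PARAMS)
    np.testing.assert_allclose(comfa_steric_field(s, grid, PROBE, PARAMS), bf_steric, atol=1e-10)
    np.testing.assert_allclose(
        comfa_electrostatic_field(s, grid, PROBE, PARAMS), bf_elec, atol=1e-10
    )
    np.testing.assert_allclose(comsia_field(s, grid, PROBE, PARAMS, "S"), bf_sim, atol=1e-10)


class TestAssemble:
    def _pair(self, make_structure):
        a = make_structure([[0.0, 0.0, 0.0]], radii=[1.5], compound_id="a")
        b = make_structure([[1.0, 0.0, 0.0]], radii=[1.8], compound_id="b")
        return [a, b]

    def test_constant_columns_masked(self, make_structure):
        s = self._pair(make_structure)
        # identical structures: every column constant across compounds
        twin = [s[0], s[0].with_coords(s[0].coords)]
        twin[1].compound_id = "b"
        block = assemble_descriptor_matrix(
            twin, comfa_kinds="S", filtering_sigma=0.001, margin=3.0
        )
        assert block.column_mask.sum() == 0

    def test_zero_sigma_keeps_everything(self, make_structure):
        block = assemble_descriptor_matrix(
            self._pair(make_structure), comfa_kinds="S", filtering_sigma=0.0, margin=3.0
        )
        assert block.column_mask.all()
        assert block.matrix().shape[0] == 2

    def test_mask_matches_direct_std(self, make_structure):
        structures = self._pair(make_structure)
        sigma = 0.5
        block = assemble_descriptor_matrix(
            structures, comfa_kinds="S", filtering_sigma=sigma, margin=3.0
        )
        X = block.full_matrix()
        np.testing.assert_array_equal(block.column_mask, X.std(axis=0) >= sigma)

    def test_buried_electrostatic_replaced_by_train_mean(self, make_structure):
        """A node inside one compound's core takes the mean electrostatic
        value of the unburied training compounds, not the clamp value."""
        grid_probe_atom = [[0.0, 0.0, 0.0]]
        buried_owner = make_structure(grid_probe_atom, charges=[0.5], compound_id="a")
        far_b = make_structure([[0.0, 0.0, 3.0]], charges=[0.2], compound_id="b")
        far_c = make_structure([[0.0, 0.0, -3.0]], charges=[-0.4], compound_id="c")
        structures = [buried_owner, far_b, far_c]
        block = assemble_descriptor_matrix(
            structures, comfa_kinds="SE", filtering_sigma=0.0, margin=2.0, spacing=2.0
        )
        pts = block.grid.points()
        node = int(np.where(np.all(np.isclose(pts, [0, 0, 0]), axis=1))[0][0])
        j = block.kinds.index(("comfa", "E"))
        e_vals = block.values[:, j, node]
        # compound a is buried at its own node -> replaced by mean of b, c there
        assert e_vals[0] == pytest.approx(np.mean(e_vals[1:]), abs=1e-10)

    def test_block_scaling_equalises_kind_variance(self, make_structure, rng):
        structures = [
            make_structure(
                rng.normal(size=(4, 3)), charges=rng.uniform(-0.4, 0.4, 4),
                radii=rng.uniform(1.3, 1.8, 4), compound_id=f"c{i}",
            )
            for i in range(5)
        ]
        block = assemble_descriptor_matrix(
            structures, comfa_kinds="SE", filtering_sigma=0.0, block_scaling=True
        )
        stds = block.values.std(axis=0)
        for j in range(len(block.kinds)):
            rms = np.sqrt(np.mean(stds[j] ** 2))
            assert rms == pytest.approx(1.0, rel=1e-6)

    def test_inconsistent_request_rejected(self, make_structure):
        with pytest.raises(ValueError, match="kind"):
            assemble_descriptor_matrix(self._pair(make_structure), comfa_kinds="X")
        with pytest.raises(ValueError, match="no field kinds"):
            assemble_descriptor_matrix(self._pair(make_structure), comfa_kinds="")


def test_dx_export_roundtrip(make_structure, tmp_path):
    """Volumetric export preserves grid geometry and values."""
    from gridData import Grid

    from fieldqsar.fields import export_dx

    s = make_structure([[0.0, 0.0, 0.0]])
    grid = GridSpec(origin=(-2, -2, -2), spacing=2.0, shape=(3, 3, 3))
    vals = comfa_steric_field(s, grid, PROBE, PARAMS)
    path = tmp_path / "field.dx"
    export_dx(grid, vals, path)
    g = Grid(str(path))
    np.testing.assert_allclose(g.grid.ravel(), vals, rtol=1e-6)
    np.testing.assert_allclose(g.origin, grid.origin, atol=1e-9)
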