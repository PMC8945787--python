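"""Finite-difference PB solver: analytic benchmarks and table building."""

import numpy as np
import pytest

import redoxmc as rx
from redoxmc.constants import COULOMB_K
from redoxmc.fragments import Conformer
from redoxmc.pb import (
    PBConvergenceError,
    SoluteCavity,
    _ScreenedField,
    lennard_jones_energy,
    solve_poisson_boltzmann,
)

ORIGIN = np.zeros((1, 3))
UNIT_Q = np.array([1.0])


def _born_rf(spacing, focusing=1, eps_in=1.0, radius=2.0):
    """Reaction-field energy of a unit charge centered in a sphere."""
    env = rx.DielectricEnvironment(eps_protein=eps_in, eps_water=80.0, ionic_strength=0.0)
    grid = rx.GridSpec(spacing=spacing, padding=8.0, focusing_levels=focusing)
    cav = SoluteCavity(ORIGIN, np.array([radius]), env.probe_radius)
    het = solve_poisson_boltzmann(ORIGIN, UNIT_Q, cav, env, grid)
    hom = solve_poisson_boltzmann(ORIGIN, UNIT_Q, None, env, grid, uniform_eps=eps_in)
    return 0.5 * float(het.potential(ORIGIN)[0] - hom.potential(ORIGIN)[0])


class TestSolver:
    def test_zero_charges_give_zero_potential(self):
        env = rx.DielectricEnvironment()
        sol = solve_poisson_boltzmann(
            ORIGIN, np.array([0.0]), None, env, rx.GridSpec(spacing=1.0, padding=6.0)
        )
        assert np.all(sol.phi == 0.0)

    def test_uniform_medium_reproduces_coulomb_within_2pct(self):
        env = rx.DielectricEnvironment(eps_protein=4, eps_water=4, ionic_strength=0.0)
        sol = solve_poisson_boltzmann(
            ORIGIN, UNIT_Q, None, env, rx.GridSpec(spacing=0.25, padding=8.0), uniform_eps=4.0
        )
        for r in (2.0, 3.0, 5.0):
            p = np.array([[r / np.sqrt(3)] * 3])  # off-grid-axis direction
            assert sol.potential(p)[0] == pytest.approx(COULOMB_K / (4 * r), rel=0.02)

    def test_born_sphere_converges_monotonically_to_analytic(self):
        exact = -0.5 * COULOMB_K * (1.0 - 1.0 / 80.0) / 2.0  # -166.03*(1-1/80)/R, R=2
        errors = [abs(_born_rf(h) - exact) / abs(exact) for h in (1.0, 0.5, 0.25)]
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 0.02

    def test_charge_outside_grid_raises(self):
        env = rx.DielectricEnvironment()
        cav = SoluteCavity(ORIGIN, np.array([2.0]), 1.4)
        with pytest.raises(ValueError, match="outside"):
            solve_poisson_boltzmann(
                np.array([[30.0, 0.0, 0.0]]), UNIT_Q, cav, env,
                rx.GridSpec(spacing=0.5, padding=6.0),
            )

    def test_nonconvergence_raises_with_residual(self):
        env = rx.DielectricEnvironment()
        cav = SoluteCavity(ORIGIN, np.array([2.0]), 1.4)
        with pytest.raises(PBConvergenceError, match="kcal"):
            solve_poisson_boltzmann(
                ORIGIN, UNIT_Q, cav, env,
                rx.GridSpec(spacing=0.5, padding=6.0, max_iter=3),
            )

    def test_two_level_focusing_matches_unfocused_within_1pct(self):
        direct = _born_rf(0.25, focusing=1)
        focused = _born_rf(0.25, focusing=2)
        assert focused == pytest.approx(direct, rel=0.01)

    def test_salt_screening_weakens_interactions_monotonically(self):
        pa, pb_ = ORIGIN, np.array([[8.0, 0.0, 0.0]])
        cav_atoms = np.vstack([pa, pb_])
        energies = []
        for ionic in (0.0, 0.15, 1.0):
            env = rx.DielectricEnvironment(eps_protein=2, eps_water=80, ionic_strength=ionic)
            cav = SoluteCavity(cav_atoms, np.array([1.5, 1.5]), env.probe_radius)
            grid = rx.GridSpec(spacing=0.5, padding=10.0)
            het = solve_poisson_boltzmann(pa, UNIT_Q, cav, env, grid)
            hom = solve_poisson_boltzmann(pa, UNIT_Q, None, env, grid, uniform_eps=2.0)
            e = float(het.potential(pb_)[0] - hom.potential(pb_)[0]) + COULOMB_K / (2 * 8.0)
            energies.append(e)
        assert energies[0] > energies[1] > energies[2] > 0.0


def _conf(fid, pos, q, r=1.5, idx=0):
    pos = np.atleast_2d(np.asarray(pos, float))
    n = pos.shape[0]
    return Conformer(
        fragment_id=fid, index=idx, charge_state=int(round(float(np.sum(q)))),
        positions=pos, atom_charges=np.asarray(q, float).ravel(),
        atom_radii=np.full(n, r), lj_rmin=np.full(n, 2.0), lj_eps=np.full(n, 0.1),
    )


class TestReactionField:
    def test_zero_charge_conformer_is_exactly_zero(self, cubane_model):
        c = _conf("X", [0.0, 0.0, 0.0], [0.0])
        env = rx.DielectricEnvironment()
        assert rx.reaction_field_energy(c, cubane_model, env, rx.GridSpec()) == 0.0

    def test_burial_matches_two_born_media_difference(self):
        # +1 ion (cavity radius 2) at the center of a 10 A protein sphere:
        # ddG = (k/2) (1/eps_p - 1/eps_w) (1/r - 1/Rp)
        env = rx.DielectricEnvironment(eps_protein=4, eps_water=80, ionic_strength=0.0)
        grid = rx.GridSpec(spacing=0.25, padding=8.0, focusing_levels=2)
        prot = SoluteCavity(ORIGIN, np.array([10.0]), env.probe_radius)
        own = SoluteCavity(ORIGIN, np.array([2.0]), env.probe_radius)
        sp = solve_poisson_boltzmann(ORIGIN, UNIT_Q, prot, env, grid)
        sa = solve_poisson_boltzmann(ORIGIN, UNIT_Q, own, env, grid)
        ddg = 0.5 * float(sp.potential(ORIGIN)[0] - sa.potential(ORIGIN)[0])
        exact = 0.5 * COULOMB_K * (1 / 4 - 1 / 80) * (1 / 2.0 - 1 / 10.0)
        assert ddg == pytest.approx(exact, rel=0.05)
        assert ddg > 0.0  # burial of net charge is always unfavorable


class TestBackboneEnergy:
    def _dipole_structure(self):
        from redoxmc.fragments import AtomRecord, Fragment, StructureModel

        conf = _conf("X", [0.0, 0.0, 0.0], [1.0])
        frag = Fragment(id="X", kind="residue_sidechain", atoms=[], allowed_charge_states=[1])
        bb = [
            AtomRecord(1, "NP", "BBD", "B", 1, np.array([6.0, 0.0, 0.0]), 1.5, 0.4, "N"),
            AtomRecord(2, "OM", "BBD", "B", 1, np.array([6.0, 1.2, 0.0]), 1.4, -0.4, "O"),
        ]
        return StructureModel(fragments=[frag], conformers=[conf], backbone=bb), conf

    def test_neutral_conformer_gives_zero(self):
        structure, _ = self._dipole_structure()
        c = _conf("X", [0.0, 0.0, 0.0], [0.0])
        env = rx.DielectricEnvironment(eps_protein=4, eps_water=4, ionic_strength=0.0)
        assert rx.backbone_energy(c, structure, env, rx.GridSpec(spacing=0.5)) == 0.0

    def test_uniform_medium_matches_coulomb_sum_within_2pct(self):
        structure, conf = self._dipole_structure()
        env = rx.DielectricEnvironment(eps_protein=4, eps_water=4, ionic_strength=0.0)
        got = rx.backbone_energy(conf, structure, env, rx.GridSpec(spacing=0.5, padding=8.0))
        exact = COULOMB_K * (0.4 / (4 * 6.0) + (-0.4) / (4 * np.hypot(6.0, 1.2)))
        assert got == pytest.approx(exact, rel=0.02)

    def test_flipping_backbone_charges_negates_energy_exactly(self):
        structure, conf = self._dipole_structure()
        env = rx.DielectricEnvironment(eps_protein=4, eps_water=80, ionic_strength=0.15)
        grid = rx.GridSpec(spacing=0.5, padding=8.0)
        e1 = rx.backbone_energy(conf, structure, env, grid)
        for a in structure.backbone:
            a.partial_charge = -a.partial_charge
        e2 = rx.backbone_energy(conf, structure, env, grid)
        assert e2 == pytest.approx(-e1, abs=1e-9)


class TestPairwiseEnergy:
    def setup_method(self):
        self.env = rx.DielectricEnvironment(eps_protein=4, eps_water=4, ionic_strength=0.0)
        self.grid = rx.GridSpec(spacing=0.5, padding=8.0)
        self.cav = SoluteCavity(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), np.array([1.5, 1.5]), 1.4
        )

    def test_opposite_unit_charges_at_5A_in_eps4(self):
        ci = _conf("A", [0.0, 0.0, 0.0], [1.0])
        cj = _conf("B", [5.0, 0.0, 0.0], [-1.0], idx=1)
        e = rx.pairwise_energy(ci, cj, self.env, self.grid, cavity=self.cav, include_lj=False)
        assert e == pytest.approx(-COULOMB_K / (4 * 5.0), rel=0.02)

    def test_symmetric_under_argument_swap(self):
        ci = _conf("A", [0.0, 0.0, 0.0], [1.0])
        cj = _conf("B", [5.0, 0.0, 0.0], [-1.0], idx=1)
        e1 = rx.pairwise_energy(ci, cj, self.env, self.grid, cavity=self.cav, include_lj=False)
        e2 = rx.pairwise_energy(cj, ci, self.env, self.grid, cavity=self.cav, include_lj=False)
        assert e1 == pytest.approx(e2, abs=5e-3)

    def test_neutral_distant_conformers_interact_negligibly(self):
        ci = _conf("A", [0.0, 0.0, 0.0], [0.0])
        cj = _conf("B", [12.0, 0.0, 0.0], [0.0], idx=1)
        e = rx.pairwise_energy(ci, cj, self.env, self.grid, cavity=self.cav)
        assert abs(e) < 1e-3  # residual is the far LJ tail

    def test_same_fragment_pair_returns_sentinel(self):
        ci = _conf("A", [0.0, 0.0, 0.0], [1.0])
        cj = _conf("A", [1.0, 0.0, 0.0], [0.0], idx=1)
        assert np.isnan(rx.pairwise_energy(ci, cj, self.env, self.grid))


class TestEnergyTables:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_structure():
        model, _, _ = rx.make_toy_cluster(
            rx.ToySystemSpec(n_fe=1, ligands=True, ligand_distance=3.0,
                             shell_charges=[(1, 6.0, 1)], seed=4)
        )
        return model

    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_tables(tiny_structure):
        env = rx.DielectricEnvironment()
        grid = rx.GridSpec(spacing=0.8, padding=6.0)
        return rx.build_energy_tables(tiny_structure, env, grid)

    def test_shapes_and_sentinels(self, tiny_structure, tiny_tables):
        m = len(tiny_structure.conformers)
        t = tiny_tables
        assert t.dG_rxn.shape == (m,) and t.dG_pol.shape == (m,) and t.dG_pair.shape == (m, m)
        assert np.allclose(np.diag(t.dG_pair), 0.0)
        for i in range(m):
            for j in range(m):
                if i != j and t.fragment_ids[i] == t.fragment_ids[j]:
                    assert np.isnan(t.dG_pair[i, j])

    def test_pair_matrix_is_symmetric(self, tiny_tables):
        p = tiny_tables.dG_pair
        finite = np.isfinite(p)
        assert np.allclose(p[finite], p.T[finite])

    def test_buried_charged_conformers_have_positive_desolvation(self, tiny_tables):
        assert np.all(tiny_tables.dG_rxn >= -1e-6)
        assert tiny_tables.dG_rxn.max() > 1.0

    def test_elementwise_match_with_direct_pairwise_calls(self, tiny_structure, tiny_tables):
        from redoxmc.pb import _structure_cavity, _structure_extent

        env = rx.DielectricEnvironment()
        grid = rx.GridSpec(spacing=0.8, padding=6.0)
        cav = _structure_cavity(tiny_structure, env)
        extent = _structure_extent(tiny_structure, grid)
        confs = tiny_structure.conformers
        for i in (0, 1):
            for j in (2, 3):
                eij = rx.pairwise_energy(confs[i], confs[j], env, grid, cavity=cav, extent=extent)
                eji = rx.pairwise_energy(confs[j], confs[i], env, grid, cavity=cav, extent=extent)
                assert tiny_tables.dG_pair[i, j] == pytest.approx(0.5 * (eij + eji), abs=1e-9)

    def test_zero_charge_system_has_zero_electrostatic_tables(self):
        from redoxmc.fragments import AtomRecord, Fragment, StructureModel

        confs = [
            _conf("A", [0.0, 0.0, 0.0], [0.0]),
            _conf("B", [5.0, 0.0, 0.0], [0.0], idx=1),
        ]
        frags = [
            Fragment(id="A", kind="residue_sidechain", atoms=[], allowed_charge_states=[0]),
            Fragment(id="B", kind="residue_sidechain", atoms=[], allowed_charge_states=[0]),
        ]
        # fragments need one placed atom for the cavity
        frags[0].atoms = [AtomRecord(1, "C", "ALA", "A", 1, np.zeros(3), 1.5)]
        frags[1].atoms = [AtomRecord(2, "C", "ALA", "A", 2, np.array([5.0, 0, 0]), 1.5)]
        model = StructureModel(fragments=frags, conformers=confs, backbone=[])
        t = rx.build_energy_tables(model, rx.DielectricEnvironment(),
                                   rx.GridSpec(spacing=0.8, padding=6.0))
        assert np.all(t.dG_rxn == 0.0) and np.all(t.dG_pol == 0.0)
        assert np.allclose(t.dG_pair_elec[np.isfinite(t.dG_pair_elec)], 0.0)

    def test_tables_roundtrip_through_tsv(self, tiny_tables, tmp_path):
        prefix = str(tmp_path / "tables")
        tiny_tables.save(prefix)
        loaded = rx.EnergyTables.load(prefix)
        assert loaded.conformer_ids == tiny_tables.conformer_ids
        assert np.allclose(loaded.dG_rxn, tiny_tables.dG_rxn)
        fin = np.isfinite(tiny_tables.dG_pair)
        assert np.allclose(loaded.dG_pair[fin], tiny_tables.dG_pair[fin])


def test_lennard_jones_minimum_depth():
    a = _conf("A", [0.0, 0.0, 0.0], [0.0])
    b = _conf("B", [4.0, 0.0, 0.0], [0.0], idx=1)  # at rmin_ij = 2.0 + 2.0
    assert lennard_jones_energy(a, b) == pytest.approx(-0.1, abs=1e-12)
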