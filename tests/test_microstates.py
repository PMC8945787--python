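"""Microstate energies, Boltzmann occupancies, Monte Carlo and midpoints."""

import numpy as np
import pytest

import redoxmc as rx
from redoxmc.constants import FARADAY, KT_298
from redoxmc.fragments import Conformer
from redoxmc.microstates import (
    MCSchedule,
    Microstate,
    TitrationCondition,
    enumerate_occupancies,
    extract_cluster_em,
    mc_sample,
    microstate_energy,
)
from redoxmc.pb import SAME_FRAGMENT, EnergyTables

from conftest import random_titration_system


def _tables(n, pair=None, rxn=None, pol=None, frag_ids=None):
    frag_ids = frag_ids or [f"F{k}" for k in range(n)]
    return EnergyTables(
        conformer_ids=[f"c{k}" for k in range(n)],
        fragment_ids=frag_ids,
        dG_rxn=np.zeros(n) if rxn is None else np.asarray(rxn, float),
        dG_pol=np.zeros(n) if pol is None else np.asarray(pol, float),
        dG_pair=np.zeros((n, n)) if pair is None else np.asarray(pair, float),
    )


class TestMicrostateEnergy:
    def test_neutral_conformer_zero_tables_gives_zero(self):
        confs = [Conformer(fragment_id="F0", index=0, charge_state=0)]
        e = microstate_energy(Microstate((0,)), _tables(1), confs, TitrationCondition(7.0, 0.0))
        assert e == 0.0

    def test_reduced_conformer_at_its_solution_midpoint_is_zero(self):
        confs = [Conformer(fragment_id="F0", index=0, charge_state=2, n=1, em_sol=-170.0)]
        e = microstate_energy(
            Microstate((0,)), _tables(1), confs, TitrationCondition(7.0, -170.0)
        )
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_hand_summed_two_fragment_system(self):
        # site A: acid conformer m=-1, pK 5.2; site B: reduced n=1, Em -250 mV
        confs = [
            Conformer(fragment_id="A", index=0, charge_state=-1, m=-1, pk_sol=5.2),
            Conformer(fragment_id="B", index=1, charge_state=2, n=1, em_sol=-250.0),
        ]
        rxn = [1.7, 2.4]
        pol = [-0.6, 0.9]
        pair = np.array([[0.0, -3.3], [-3.3, 0.0]])
        cond = TitrationCondition(pH=7.0, Eh=-100.0)
        expected = (
            np.log(10.0) * (-1) * KT_298 * (7.0 - 5.2)
            + 1 * FARADAY * (-100.0 - (-250.0)) / 1000.0
            + (1.7 + 2.4) + (-0.6 + 0.9) + (-3.3)
        )
        got = microstate_energy(
            Microstate((0, 1)), _tables(2, pair, rxn, pol, ["A", "B"]), confs, cond
        )
        assert got == pytest.approx(expected, abs=1e-12)


class TestEnumeration:
    def test_isoenergetic_pair_splits_evenly(self):
        confs = [
            Conformer(fragment_id="F0", index=0, charge_state=0),
            Conformer(fragment_id="F0", index=1, charge_state=0),
        ]
        occ = enumerate_occupancies(
            _tables(2, frag_ids=["F0", "F0"]), confs, TitrationCondition()
        )
        assert np.allclose(occ, [0.5, 0.5])

    def test_1p364_kcal_split_gives_ten_to_one(self):
        confs = [
            Conformer(fragment_id="F0", index=0, charge_state=0),
            Conformer(fragment_id="F0", index=1, charge_state=0),
        ]
        tab = _tables(2, rxn=[0.0, np.log(10.0) * KT_298], frag_ids=["F0", "F0"])
        occ = enumerate_occupancies(tab, confs, TitrationCondition())
        assert occ[0] / occ[1] == pytest.approx(10.0, rel=1e-9)
        assert np.log(10.0) * KT_298 == pytest.approx(1.364, abs=5e-4)

    def test_occupancies_sum_to_one_per_fragment(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            tables, confs = random_titration_system(rng)
            occ = enumerate_occupancies(tables, confs, TitrationCondition(7.0, -250.0))
            for fid in {c.fragment_id for c in confs}:
                mask = [c.fragment_id == fid for c in confs]
                assert occ[mask].sum() == pytest.approx(1.0, abs=1e-12)

    def test_state_space_overflow_instructs_mc(self):
        tables, confs = rx.make_titration_system([-300.0] * 21)
        with pytest.raises(ValueError, match="Monte Carlo"):
            enumerate_occupancies(tables, confs, TitrationCondition(), max_states=10**6)


class TestMonteCarlo:
    def test_same_seed_is_bit_identical(self):
        tables, confs = rx.make_titration_system([-300.0, -250.0], W=1.0)
        occ1, err1 = mc_sample(tables, confs, TitrationCondition(7.0, -270.0), seed=5)
        occ2, err2 = mc_sample(tables, confs, TitrationCondition(7.0, -270.0), seed=5)
        assert np.array_equal(occ1, occ2) and np.array_equal(err1, err2)

    def test_isoenergetic_pair_near_half(self):
        confs = [
            Conformer(fragment_id="F0", index=0, charge_state=0),
            Conformer(fragment_id="F0", index=1, charge_state=0),
        ]
        occ, err = mc_sample(_tables(2, frag_ids=["F0", "F0"]), confs,
                             TitrationCondition(), seed=3)
        assert abs(occ[0] - 0.5) < max(3 * err.max(), 1e-6) + 0.02

    def test_matches_enumeration_within_mc_noise(self):
        rng = np.random.default_rng(2024)
        for k in range(20):
            tables, confs = random_titration_system(rng)
            cond = TitrationCondition(7.0, float(rng.uniform(-400, -100)))
            exact = enumerate_occupancies(tables, confs, cond)
            occ, err = mc_sample(tables, confs, cond, seed=int(rng.integers(2**31)))
            assert np.abs(occ - exact).max() < 3.0 * max(err.max(), 1e-4)

    def test_zero_acceptance_warns_nonergodic(self):
        # two fragments locked by a huge repulsion from flipping
        pair = np.array(
            [
                [0.0, SAME_FRAGMENT, 0.0, 1e9],
                [SAME_FRAGMENT, 0.0, 1e9, 1e9],
                [0.0, 1e9, 0.0, SAME_FRAGMENT],
                [1e9, 1e9, SAME_FRAGMENT, 0.0],
            ]
        )
        confs = [
            Conformer(fragment_id="A", index=0, charge_state=0),
            Conformer(fragment_id="A", index=1, charge_state=0),
            Conformer(fragment_id="B", index=2, charge_state=0),
            Conformer(fragment_id="B", index=3, charge_state=0),
        ]
        tab = _tables(4, pair, frag_ids=["A", "A", "B", "B"])
        with pytest.warns(RuntimeWarning, match="non-ergodic"):
            mc_sample(tab, confs, TitrationCondition(), MCSchedule(50, 100), seed=0)


class TestTitration:
    def test_isolated_site_midpoint_is_reference(self):
        tables, confs = rx.make_titration_system([-170.0])
        res = rx.titrate(tables, confs, 7.0, np.arange(-400.0, 100.0, 5.0))
        assert res.midpoints["FE1"] == pytest.approx(-170.0, abs=0.5)

    def test_oxidized_fraction_is_nondecreasing_in_eh(self):
        tables, confs = rx.make_titration_system([-250.0])
        res = rx.titrate(tables, confs, 7.0, np.arange(-500.0, 100.0, 5.0))
        ox = res.occupancy[:, 1]
        assert np.all(np.diff(ox) >= -1e-12)

    def test_nernst_slope_59_mv_per_decade(self):
        tables, confs = rx.make_titration_system([-200.0])
        eh = np.arange(-400.0, 0.0, 1.0)
        res = rx.titrate(tables, confs, 7.0, eh)
        ratio = res.occupancy[:, 1] / res.occupancy[:, 0]  # ox / red
        e1 = np.interp(1.0, ratio, eh)
        e10 = np.interp(10.0, ratio, eh)
        assert e10 - e1 == pytest.approx(1000.0 * KT_298 * np.log(10.0) / FARADAY, abs=0.05)

    def test_monotone_eh_grid_required(self):
        tables, confs = rx.make_titration_system([-200.0])
        with pytest.raises(ValueError):
            rx.titrate(tables, confs, 7.0, np.array([0.0, -10.0, 10.0]))

    def test_mc_engine_reproducible_and_close_to_enumeration(self):
        tables, confs = rx.make_titration_system([-300.0, -250.0], W=0.8)
        eh = np.arange(-400.0, -100.0, 25.0)
        r1 = rx.titrate(tables, confs, 7.0, eh, engine="mc", seed=9)
        r2 = rx.titrate(tables, confs, 7.0, eh, engine="mc", seed=9)
        assert np.array_equal(r1.occupancy, r2.occupancy)
        r3 = rx.titrate(tables, confs, 7.0, eh)
        assert np.abs(r1.occupancy - r3.occupancy).max() < 3 * max(r1.mc_error.max(), 1e-4)


class TestClusterEm:
    def test_independent_sites_second_midpoint(self):
        tables, confs = rx.make_titration_system([-400.0, -200.0])
        res = rx.titrate(tables, confs, 7.0, np.arange(-600.0, 100.0, 5.0))
        em = extract_cluster_em(res, confs, ["FE1", "FE2"])
        assert em == pytest.approx(-200.0, abs=1.0)

    def test_coupling_shift_for_separated_sites(self):
        # separated sites: second oxidation is a pure single-site event of the
        # higher-Em site with the first site already oxidized, so the shift is
        # exactly 1000*W/F mV
        for W in (1.0, 2.3061):
            tables, confs = rx.make_titration_system([-450.0, -300.0], W=W)
            res = rx.titrate(tables, confs, 7.0, np.arange(-700.0, 300.0, 2.0))
            em = extract_cluster_em(res, confs, ["FE1", "FE2"])
            assert em == pytest.approx(-300.0 + 1000.0 * W / FARADAY, abs=1.0)

    def test_positive_coupling_never_lowers_second_oxidation(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ems = list(rng.uniform(-400, -200, 2))
            tables, confs = rx.make_titration_system(ems, W=0.0)
            res = rx.titrate(tables, confs, 7.0, np.arange(-700.0, 400.0, 5.0))
            em0 = extract_cluster_em(res, confs, ["FE1", "FE2"])
            prev = em0
            for W in (0.5, 1.5, 3.0):
                tables, confs = rx.make_titration_system(ems, W=W)
                res = rx.titrate(tables, confs, 7.0, np.arange(-700.0, 400.0, 5.0))
                em = extract_cluster_em(res, confs, ["FE1", "FE2"])
                assert em >= prev - 1e-9
                prev = em

    def test_relabeling_symmetric_sites_preserves_em(self):
        tables, confs = rx.make_titration_system([-300.0, -300.0], W=1.2)
        res = rx.titrate(tables, confs, 7.0, np.arange(-600.0, 100.0, 2.0))
        em_ab = extract_cluster_em(res, confs, ["FE1", "FE2"])
        em_ba = extract_cluster_em(res, confs, ["FE2", "FE1"])
        assert em_ab == em_ba

    def test_crossing_outside_grid_reports_range(self):
        tables, confs = rx.make_titration_system([-400.0, -200.0])
        res = rx.titrate(tables, confs, 7.0, np.arange(-600.0, -500.0, 5.0))
        with pytest.raises(ValueError, match="Eh grid"):
            extract_cluster_em(res, confs, ["FE1", "FE2"])

    def test_parameter_recovery_of_injected_protein_shift(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            shift = float(rng.uniform(-4, 4))
            tables, confs = rx.make_titration_system([-300.0], protein_shift=[shift])
            res = rx.titrate(tables, confs, 7.0, np.arange(-700.0, 200.0, 2.0))
            expected = -300.0 + 1000.0 * shift / FARADAY
            assert res.midpoints["FE1"] == pytest.approx(expected, abs=5.0)
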