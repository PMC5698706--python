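"""Reduction-potential differences, chain averaging, and the mutant screen."""

from __future__ import annotations

import math

import numpy as np
import pytest

import cupredox as cx
from cupredox import constants as K
from cupredox.redox import RedoxResult, average_chains, candidate_positions, ddE, screen
from cupredox.solver import state_energy
from cupredox.structure import StructureError


class TestAverageChains:
    def test_identical_values(self):
        assert average_chains([10.0, 10.0, 10.0, 10.0]) == (10.0, 0.0)

    def test_two_values_closed_form(self):
        mean, sd = average_chains([0.0, 10.0])
        assert mean == 5.0
        assert sd == pytest.approx(math.sqrt(50.0))  # sample sd 7.07

    def test_single_value_sd_zero(self):
        assert average_chains([42.0]) == (42.0, 0.0)

    def test_permutation_invariance(self, rng):
        vals = list(rng.normal(0, 30, size=6))
        shuffled = list(rng.permutation(vals))
        assert average_chains(vals) == pytest.approx(average_chains(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_chains([])


def _result(label, values, meta=None):
    mean, sd = average_chains(values)
    return RedoxResult(label, dict(zip("ABCD", values)), mean, sd,
                       meta or {"grid": (26.0, 0.4), "solver": ()})


class TestDdE:
    def test_identity_is_zero(self):
        wt = _result("WT", [10.0, 12.0])
        assert ddE(wt, wt)[0] == 0.0

    def test_antisymmetry(self):
        a = _result("WT", [10.0, 12.0])
        b = _result("D11A", [95.0, 99.0])
        assert ddE(a, b)[0] == -ddE(b, a)[0]

    def test_mismatched_settings_rejected(self):
        a = _result("WT", [10.0], {"grid": (26.0, 0.4), "solver": ()})
        b = _result("M", [10.0], {"grid": (57.8, 0.2), "solver": ()})
        with pytest.raises(ValueError, match="grid"):
            ddE(a, b)

    def test_chain_average_of_identical_chains(self):
        wt = _result("WT", [7.0, 7.0, 7.0, 7.0])
        assert wt.mean == 7.0 and wt.sd == 0.0


class TestReductionEnergy:
    def test_identical_charges_exactly_zero(self, toy_site_states, toy_grid):
        ox, _ = toy_site_states
        assert cx.reduction_energy(ox, ox, toy_grid) == 0.0

    def test_coordinate_mismatch_rejected(self, toy_site_states, toy_grid):
        ox, red = toy_site_states
        moved = cx.as_parameterized(red.structure.translated([0.5, 0, 0]))
        with pytest.raises(StructureError, match="identical coordinates"):
            cx.reduction_energy(ox, moved, toy_grid)

    def test_unit_conversion_contract(self, toy_site_states, toy_grid, no_salt):
        """The mV result equals (E_ox - E_red in kcal/mol) * 43.364."""
        ox, red = toy_site_states
        e_ox = state_energy(ox, toy_grid, no_salt)
        e_red = state_energy(red, toy_grid, no_salt)
        expect = (e_ox - e_red) * K.MV_PER_KCAL
        got = cx.reduction_energy(ox, red, toy_grid, no_salt)
        assert got == pytest.approx(expect, abs=1e-6)


class TestScreen:
    def test_empty_position_set(self, mini_protein):
        assert screen(mini_protein, [], lambda m: 0.0) == []

    def test_combinatorics_with_identity_excluded(self, mini_protein):
        # ADKLS: positions 2 (ASP) and 3 (LYS); targets LYS/ASP/ALA
        rows = screen(mini_protein, [2, 3], lambda m: 30.0)
        assert len(rows) == 4  # 2x3 minus D2D-type identities (K->K, D->D)
        labels = [r.mutant for r in rows]
        assert labels == ["D2K", "D2A", "K3D", "K3A"]
        assert all(r.exceeds_threshold for r in rows)

    def test_threshold_strict_on_rounded_value(self, mini_protein):
        rows = screen(mini_protein, [2], lambda m: 20.4)
        assert not any(r.exceeds_threshold for r in rows)
        rows = screen(mini_protein, [2], lambda m: -20.6)
        assert all(r.exceeds_threshold for r in rows)

    def test_first_sphere_positions_rejected(self, toy_site):
        structure, _ = toy_site
        with pytest.raises(StructureError, match="first-sphere"):
            screen(structure, [112], lambda m: 0.0)

    def test_rows_sorted_and_carry_distance(self, toy_site):
        structure, _ = toy_site
        rows = screen(structure, [121], lambda m: 5.0)
        assert [r.mutant for r in rows] == ["M121K", "M121D", "M121A"]
        assert rows[0].distance_A == pytest.approx(3.2)

    def test_candidate_positions_exclude_site(self, toy_site):
        structure, _ = toy_site
        # 46/112/117 are ligands, 121 is axial: nothing remains in the toy site
        assert candidate_positions(structure) == []


class TestChargePerturbationSign:
    def test_positive_charge_closer_to_cu_raises_potential(
            self, toy_site_states, toy_grid, no_salt):
        """Moving a +1 test charge toward the site stabilizes the reduced
        (less positive) state and must increase the computed potential."""
        from cupredox.structure import Atom, Structure

        def with_probe(ps, x):
            atoms = [a.copy() for a in ps.structure.atoms]
            atoms.append(Atom(0, "Q", "X", "ION", 300, "A",
                              np.array([x, 0.0, 0.0]), charge=1.0, radius=1.5))
            return cx.as_parameterized(Structure(atoms))

        ox, red = toy_site_states
        far = cx.reduction_energy(with_probe(ox, 9.5), with_probe(red, 9.5),
                                  toy_grid, no_salt)
        near = cx.reduction_energy(with_probe(ox, 7.0), with_probe(red, 7.0),
                                   toy_grid, no_salt)
        assert near > far
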