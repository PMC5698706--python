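"""LPBE solver: limiting cases, linearity, Coulomb and Born oracles."""

from __future__ import annotations

import numpy as np
import pytest

import cupredox as cx
from cupredox import constants as K
from cupredox.grid import GridSpec, ScalarField, spread_charges
from cupredox.solver import SolverError, solve_lpbe, grid_energy


def uniform_fields(grid, eps=4.0):
    return (ScalarField(grid, np.full(grid.shape, eps), "dielectric"),
            ScalarField(grid, np.zeros(grid.shape), "screening"))


@pytest.fixture(scope="module")
def small_grid():
    return GridSpec((0, 0, 0), 16.0, 0.5)


class TestSolveLpbe:
    def test_zero_charge_zero_bc_gives_zero(self, small_grid):
        eps, kap = uniform_fields(small_grid)
        rho = ScalarField(small_grid, np.zeros(small_grid.shape), "charge_density")
        sol = solve_lpbe(eps, kap, rho, cx.SolverOptions(boundary="zero"))
        assert sol.converged
        np.testing.assert_array_equal(sol.potential.values, 0.0)

    def test_uniform_dielectric_matches_coulomb(self):
        """Potential of a single charge in uniform eps, no salt, within 3%
        of q/(eps*r) at 5 A (0.4 A spacing)."""
        grid = GridSpec((0, 0, 0), 20.0, 0.4)
        eps, kap = uniform_fields(grid, 4.0)
        ps = cx.as_parameterized(cx.make_fixture("born_ion", {"q": 1.0, "radius": 1.0}))
        rho = spread_charges(ps, grid)
        sol = solve_lpbe(eps, kap, rho, cx.SolverOptions(ionic_strength=0.0),
                         bc_sources=ps, bc_eps=4.0)
        fac = K.COULOMB_KCAL_A / K.kT_kcal()
        from cupredox.grid import interpolate
        for r in (4.0, 5.0, 6.0):
            u = interpolate(sol.potential, np.array([[r, 0.0, 0.0]]))[0]
            assert u == pytest.approx(fac / (4.0 * r), rel=0.03)

    def test_linearity_in_charge(self, small_grid):
        eps, kap = uniform_fields(small_grid)
        ps1 = cx.as_parameterized(cx.make_fixture("born_ion", {"q": 1.0, "radius": 1.0}))
        rho1 = spread_charges(ps1, small_grid)
        lam = 3.7
        rho2 = ScalarField(small_grid, lam * rho1.values, "charge_density")
        opts = cx.SolverOptions(boundary="zero")
        u1 = solve_lpbe(eps, kap, rho1, opts).potential.values
        u2 = solve_lpbe(eps, kap, rho2, opts).potential.values
        np.testing.assert_allclose(u2, lam * u1, rtol=1e-5, atol=1e-10)

    def test_superposition(self, small_grid):
        eps, kap = uniform_fields(small_grid)
        a = cx.as_parameterized(cx.make_fixture(
            "born_ion", {"q": 1.0, "radius": 1.0, "center": (-2.0, 0, 0)}))
        b = cx.as_parameterized(cx.make_fixture(
            "born_ion", {"q": -0.5, "radius": 1.0, "center": (2.0, 1.0, 0)}))
        rho_a = spread_charges(a, small_grid)
        rho_b = spread_charges(b, small_grid)
        rho_ab = ScalarField(small_grid, rho_a.values + rho_b.values, "charge_density")
        opts = cx.SolverOptions(boundary="zero", tolerance=1e-10)
        u_a = solve_lpbe(eps, kap, rho_a, opts).potential.values
        u_b = solve_lpbe(eps, kap, rho_b, opts).potential.values
        u_ab = solve_lpbe(eps, kap, rho_ab, opts).potential.values
        scale = np.max(np.abs(u_ab))
        assert np.max(np.abs(u_ab - (u_a + u_b))) / scale < 1e-8

    def test_sor_agrees_with_cg(self, small_grid):
        eps, kap = uniform_fields(small_grid)
        ps = cx.as_parameterized(cx.make_fixture("born_ion", {"q": 1.0, "radius": 1.0}))
        rho = spread_charges(ps, small_grid)
        u_cg = solve_lpbe(eps, kap, rho, cx.SolverOptions(boundary="zero"),
                          ).potential.values
        u_sor = solve_lpbe(eps, kap, rho,
                           cx.SolverOptions(boundary="zero", method="sor",
                                            max_iterations=200000),
                           ).potential.values
        np.testing.assert_allclose(u_sor, u_cg, atol=1e-4 * np.max(np.abs(u_cg)))

    def test_mismatched_grids_rejected(self, small_grid):
        other = GridSpec((0, 0, 0), 16.0, 0.4)
        eps, kap = uniform_fields(small_grid)
        rho = ScalarField(other, np.zeros(other.shape), "charge_density")
        with pytest.raises(SolverError, match="share a grid"):
            solve_lpbe(eps, kap, rho)


class TestEnergies:
    def test_zero_charges_zero_energy(self, small_grid):
        eps, kap = uniform_fields(small_grid)
        neutral = cx.as_parameterized(cx.make_fixture(
            "born_ion", {"q": 0.0, "radius": 1.0}))
        rho = spread_charges(neutral, small_grid)
        sol = solve_lpbe(eps, kap, rho, cx.SolverOptions(boundary="zero"))
        assert grid_energy(sol, neutral, small_grid) == 0.0

    def test_quadratic_charge_scaling(self, no_salt):
        grid = GridSpec((0, 0, 0), 16.0, 0.4)
        e1 = cx.state_energy(cx.as_parameterized(
            cx.make_fixture("born_ion", {"q": 1.0, "radius": 2.0})), grid, no_salt)
        e2 = cx.state_energy(cx.as_parameterized(
            cx.make_fixture("born_ion", {"q": 2.0, "radius": 2.0})), grid, no_salt)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-4)

    def test_no_dielectric_contrast_zero_energy(self):
        grid = GridSpec((0, 0, 0), 16.0, 0.4)
        ps = cx.as_parameterized(cx.make_fixture("born_ion", {"q": 1.0, "radius": 2.0}))
        e = cx.state_energy(ps, grid, cx.SolverOptions(ionic_strength=0.0),
                            eps_in=4.0, eps_out=4.0)
        assert abs(e) < 0.05  # kcal/mol; only solver tolerance survives

    def test_born_oracle_coarse(self, no_salt, born_ion_ps):
        grid = GridSpec((0, 0, 0), 16.0, 0.4)
        e = cx.state_energy(born_ion_ps(1.0, 2.0), grid, no_salt)
        assert e == pytest.approx(cx.born_analytic(1.0, 2.0, 4.0, 78.0), rel=0.05)

    def test_salt_makes_solvation_more_favourable(self, born_ion_ps):
        grid = GridSpec((0, 0, 0), 16.0, 0.4)
        e0 = cx.state_energy(born_ion_ps(), grid, cx.SolverOptions(ionic_strength=0.0))
        e15 = cx.state_energy(born_ion_ps(), grid, cx.SolverOptions(ionic_strength=0.15))
        assert e15 < e0


class TestBornAnalytic:
    def test_reference_value(self):
        # (332.0637/4) * (1/78 - 1/4) = -19.69 kcal/mol
        assert cx.born_analytic(1.0, 2.0, 4.0, 78.0) == pytest.approx(-19.69, abs=0.005)

    def test_no_contrast_is_zero(self):
        assert cx.born_analytic(1.0, 2.0, 4.0, 4.0) == 0.0

    def test_monotone_in_ionic_strength(self):
        es = [cx.born_analytic(1.0, 2.0, ionic_strength=i)
              for i in (0.0, 0.05, 0.15, 0.5)]
        assert all(b < a for a, b in zip(es, es[1:]))

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            cx.born_analytic(1.0, 0.0)
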