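"""Finite-difference solution of the linearized Poisson-Boltzmann equation.

The equation  div(eps grad u) - kappa_bar^2 u = -4 pi C rho  is discretized
on the 7-point stencil with harmonic-mean face dielectrics; ``u`` is the
dimensionless potential (kT/e), ``rho`` the B-spline charge density (e/A^3)
and ``C`` converts e/A to kT/e.  Dirichlet boundary values come from the sum
of Debye-Hueckel potentials of all source charges ("multiple sphere"
approximation) or are zero.  The symmetric positive-definite system is
solved with Jacobi-preconditioned conjugate gradients (a damped SOR sweep
solver is available for cross-checking); both are deterministic.

Energies are computed as G = 1/2 sum_i q_i u(r_i) with the same B-spline
interpolation.  A raw grid energy contains the (discretization-dependent)
self-energy of each charge; :func:`state_energy` cancels it by subtracting a
second solve on identical maps with a uniform interior dielectric and no
salt, so that only the reaction-field (solvation) part survives.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from . import constants as K
from .forcefield import ParameterizedStructure
from .grid import GridSpec, ScalarField, build_dielectric_map, build_screening_map, \
    interpolate, spread_charges


class SolverError(RuntimeError):
    pass


@dataclasses.dataclass
class SolverOptions:
    """Numerical and physical settings for one LPBE solve."""

    tolerance: float = 1e-6          # relative residual
    max_iterations: int = 20000
    method: str = "cg"               # "cg" or "sor"
    boundary: str = "mdh"            # "mdh" (multiple Debye-Hueckel) or "zero"
    temperature: float = K.DEFAULT_TEMPERATURE
    ionic_strength: float = K.DEFAULT_IONIC_STRENGTH
    stern_layer: float = K.DEFAULT_STERN_LAYER

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")


@dataclasses.dataclass
class PBSolution:
    potential: ScalarField           # dimensionless, kT/e
    iterations: int
    residual: float
    converged: bool


def _face_eps(eps: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic mean of adjacent node dielectrics along one axis."""
    a = np.swapaxes(eps, 0, axis)
    face = 2.0 * a[:-1] * a[1:] / (a[:-1] + a[1:])
    return np.swapaxes(face, 0, axis)


def _charge_factor(temperature: float) -> float:
    """Converts a potential in e/A to kT/e at the given temperature."""
    return K.COULOMB_KCAL_A / K.kT_kcal(temperature)


def dh_boundary(grid: GridSpec, pstructure: ParameterizedStructure,
                eps_ref: float, kappa: float, temperature: float) -> np.ndarray:
    """Dirichlet values on the grid boundary: sum of screened-Coulomb
    potentials of every source charge (kT/e)."""
    u = np.zeros(grid.shape)
    x, y, z = grid.axes()
    fac = _charge_factor(temperature)
    faces = []
    n = grid.n_points
    for axis in range(3):
        for side in (0, n - 1):
            sl = [slice(None)] * 3
            sl[axis] = side
            faces.append(tuple(sl))
    for face in faces:
        grids = np.meshgrid(x[face[0]], y[face[1]], z[face[2]], indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.zeros(len(pts))
        for a in pstructure.atoms:
            if a.charge == 0.0:
                continue
            r = np.linalg.norm(pts - a.position, axis=1)
            r = np.maximum(r, 1e-6)
            if kappa > 0:
                vals += fac * a.charge * np.exp(-kappa * r) / (eps_ref * r)
            else:
                vals += fac * a.charge / (eps_ref * r)
        u[face] = vals.reshape(u[face].shape)
    return u


def _apply_operator(u: np.ndarray, fe: tuple[np.ndarray, ...],
                    kbar2: np.ndarray, h2: float) -> np.ndarray:
    """A u = -div(eps grad u)/h^2 + kappa_bar^2 u on the full array."""
    out = kbar2 * u
    inv_h2 = 1.0 / h2
    for axis, eps_f in enumerate(fe):
        ua = np.swapaxes(u, 0, axis)
        oa = np.swapaxes(out, 0, axis)
        ea = np.swapaxes(eps_f, 0, axis)
        flux = ua[1:] - ua[:-1]
        flux *= ea
        flux *= inv_h2
        oa[1:] += flux
        oa[:-1] -= flux
    return out


def solve_lpbe(
    dielectric: ScalarField,
    screening: ScalarField,
    charge: ScalarField,
    options: SolverOptions | None = None,
    bc_sources: ParameterizedStructure | None = None,
    bc_eps: float | None = None,
    bc_kappa: float = 0.0,
) -> PBSolution:
    """Solve the LPBE for the dimensionless potential on the grid.

    ``bc_sources``/``bc_eps``/``bc_kappa`` define the Debye-Hueckel Dirichlet
    boundary; with ``options.boundary == "zero"`` (or no sources) the
    boundary potential is zero.
    """
    if options is None:
        options = SolverOptions()
    grid = dielectric.grid
    if screening.grid != grid or charge.grid != grid:
        raise SolverError("dielectric, screening and charge maps must share a grid")
    h = grid.spacing
    h2 = h * h
    eps = dielectric.values
    kbar2 = screening.values
    fac = _charge_factor(options.temperature)
    b = 4.0 * math.pi * fac * charge.values

    fe = tuple(_face_eps(eps, axis) for axis in range(3))

    u0 = np.zeros(grid.shape)
    if options.boundary == "mdh" and bc_sources is not None:
        if bc_eps is None:
            raise SolverError("mdh boundary needs bc_eps")
        u0 = dh_boundary(grid, bc_sources, bc_eps, bc_kappa, options.temperature)
    elif options.boundary not in ("mdh", "zero"):
        raise SolverError(f"unknown boundary condition {options.boundary!r}")

    interior = (slice(1, -1),) * 3
    # move boundary values to the right-hand side
    lift = _apply_operator(u0, fe, kbar2, h2)
    rhs = (b - lift)[interior].ravel()

    shape_int = tuple(s - 2 for s in grid.shape)

    def matvec(x: np.ndarray) -> np.ndarray:
        w = np.zeros(grid.shape)
        w[interior] = x.reshape(shape_int)
        return _apply_operator(w, fe, kbar2, h2)[interior].ravel()

    # Jacobi diagonal for preconditioning
    diag = kbar2.copy()
    for axis, eps_f in enumerate(fe):
        ea = np.swapaxes(eps_f, 0, axis)
        da = np.swapaxes(diag, 0, axis)
        da[:-1] += ea / h2
        da[1:] += ea / h2
    dint = diag[interior].ravel()

    nunk = rhs.size
    A = LinearOperator((nunk, nunk), matvec=matvec, dtype=float)
    M = LinearOperator((nunk, nunk), matvec=lambda x: x / dint, dtype=float)

    if options.method == "cg":
        iters = 0

        def cb(_xk):
            nonlocal iters
            iters += 1

        x, info = cg(A, rhs, rtol=0.5 * options.tolerance, atol=0.0,
                     maxiter=options.max_iterations, M=M, callback=cb)
        bnorm = np.linalg.norm(rhs)
        resid = float(np.linalg.norm(rhs - A @ x) / bnorm) if bnorm > 0 else 0.0
        converged = bnorm == 0 or (info == 0 and resid <= options.tolerance)
    elif options.method == "sor":
        ii, jj, kk = np.indices(shape_int)
        red = ((ii + jj + kk) % 2 == 0).ravel()
        x, iters, resid, converged = _sor(matvec, rhs, dint, red, options)
    else:
        raise SolverError(f"unknown solver method {options.method!r}")

    if not converged:
        raise SolverError(
            f"LPBE solver did not converge: residual {resid:.3e} after "
            f"{iters} iterations (tolerance {options.tolerance:.1e})"
        )
    u = u0.copy()
    u[interior] = x.reshape(shape_int)
    return PBSolution(ScalarField(grid, u, kind="potential"), iters, resid, converged)


def _sor(matvec, rhs, diag, red: np.ndarray, options: SolverOptions,
         omega: float = 1.8):
    """Red-black successive over-relaxation (reference fallback solver)."""
    x = np.zeros_like(rhs)
    bnorm = np.linalg.norm(rhs)
    if bnorm == 0:
        return x, 0, 0.0, True
    black = ~red
    resid = math.inf
    for it in range(1, options.max_iterations + 1):
        r = rhs - matvec(x)
        x[red] += omega * r[red] / diag[red]
        r = rhs - matvec(x)
        x[black] += omega * r[black] / diag[black]
        if it % 5 == 0:
            resid = float(np.linalg.norm(rhs - matvec(x)) / bnorm)
            if resid <= options.tolerance:
                return x, it, resid, True
    return x, options.max_iterations, resid, False


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def grid_energy(solution: PBSolution, pstructure: ParameterizedStructure,
                grid: GridSpec | None = None, force: bool = False) -> float:
    """G = 1/2 sum_i q_i u(r_i) in kT.  Contains the grid self-energy, which
    is only meaningful after reference-state subtraction."""
    if not solution.converged and not force:
        raise SolverError("refusing to evaluate energy of an unconverged solution")
    if grid is None:
        grid = solution.potential.grid
    pos = pstructure.positions()
    q = pstructure.charges()
    nz = q != 0.0
    if not np.any(nz):
        return 0.0
    u = interpolate(solution.potential, pos[nz])
    return float(0.5 * np.sum(q[nz] * u))


def state_energy(
    pstructure: ParameterizedStructure,
    grid: GridSpec,
    options: SolverOptions | None = None,
    eps_in: float = K.DEFAULT_EPS_IN,
    eps_out: float = K.DEFAULT_EPS_OUT,
    probe: float = K.DEFAULT_PROBE_RADIUS,
    smoothing: str = "harmonic9",
) -> float:
    """Electrostatic (reaction-field) energy of one state in kcal/mol.

    Two solves on the identical grid and charge discretization: the solvated
    system, and a uniform ``eps_in`` reference without salt.  Their
    difference cancels the grid self-energy, which otherwise would not cancel
    between oxidation states with different charge sets.
    """
    if options is None:
        options = SolverOptions()
    rho = spread_charges(pstructure, grid)
    eps = build_dielectric_map(pstructure, grid, eps_in, eps_out, probe, smoothing)
    kap = build_screening_map(pstructure, grid, options.ionic_strength,
                              options.temperature, eps_out, options.stern_layer)
    lam = K.debye_length(options.ionic_strength, eps_out, options.temperature)
    kappa = 0.0 if math.isinf(lam) else 1.0 / lam

    solvated = solve_lpbe(eps, kap, rho, options, bc_sources=pstructure,
                          bc_eps=eps_out, bc_kappa=kappa)
    e_solv = grid_energy(solvated, pstructure, grid)

    eps_ref = ScalarField(grid, np.full(grid.shape, float(eps_in)), kind="dielectric")
    kap_ref = ScalarField(grid, np.zeros(grid.shape), kind="screening")
    reference = solve_lpbe(eps_ref, kap_ref, rho, options, bc_sources=pstructure,
                           bc_eps=eps_in, bc_kappa=0.0)
    e_ref = grid_energy(reference, pstructure, grid)

    # the reference solve cancels the grid self-energy but also removes the
    # charge-charge Coulomb interaction at eps_in, which is physical: restore
    # it from the exact pairwise sum on the same coordinates
    e_coul = coulomb_energy(pstructure, eps_in)
    return (e_solv - e_ref) * K.kT_kcal(options.temperature) + e_coul


def coulomb_energy(pstructure: ParameterizedStructure, eps: float) -> float:
    """Exact pairwise Coulomb interaction energy in a uniform dielectric,
    kcal/mol (no self terms)."""
    q = pstructure.charges()
    nz = q != 0.0
    if np.count_nonzero(nz) < 2:
        return 0.0
    pos = pstructure.positions()[nz]
    q = q[nz]
    from scipy.spatial.distance import pdist
    inv_r = 1.0 / pdist(pos)
    i, j = np.triu_indices(len(q), k=1)
    return float(K.COULOMB_KCAL_A / eps * np.sum(q[i] * q[j] * inv_r))


def uniform_interaction_energy(
    pstructure: ParameterizedStructure,
    grid: GridSpec,
    eps: float,
    options: SolverOptions | None = None,
) -> float:
    """Interaction energy (kcal/mol) between the atoms of a structure in a
    uniform dielectric: E(all) - sum_i E(atom i), cancelling self-energies."""
    if options is None:
        options = SolverOptions(ionic_strength=0.0)

    def solve_for(ps: ParameterizedStructure) -> float:
        rho = spread_charges(ps, grid)
        eps_f = ScalarField(grid, np.full(grid.shape, float(eps)), kind="dielectric")
        kap_f = ScalarField(grid, np.zeros(grid.shape), kind="screening")
        sol = solve_lpbe(eps_f, kap_f, rho, options, bc_sources=ps,
                         bc_eps=eps, bc_kappa=0.0)
        return grid_energy(sol, ps, grid)

    total = solve_for(pstructure)
    from .structure import Structure
    for a in pstructure.atoms:
        single = ParameterizedStructure(
            Structure([a.copy()]), pstructure.oxidation_state, a.charge or 0.0
        )
        total -= solve_for(single)
    return total * K.kT_kcal(options.temperature)


def born_analytic(
    q: float,
    radius: float,
    eps_in: float = K.DEFAULT_EPS_IN,
    eps_out: float = K.DEFAULT_EPS_OUT,
    ionic_strength: float = 0.0,
    temperature: float = K.DEFAULT_TEMPERATURE,
    stern_layer: float = K.DEFAULT_STERN_LAYER,
) -> float:
    """Closed-form Born/Kirkwood energy (kcal/mol) matching state_energy.

    Transfer of a charge-q ion of radius R from a uniform ``eps_in`` medium
    into an ``eps_in`` cavity in ``eps_out`` solvent with Debye screening
    beyond the ion-exclusion radius R + Stern:

    ``G = C q^2/2 [ (1/eps_out - 1/eps_in)/R - kappa/(eps_out (1+kappa a)) ]``
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lam = K.debye_length(ionic_strength, eps_out, temperature)
    kappa = 0.0 if math.isinf(lam) else 1.0 / lam
    a = radius + stern_layer
    g = (1.0 / eps_out - 1.0 / eps_in) / radius
    g -= kappa / (eps_out * (1.0 + kappa * a))
    return K.COULOMB_KCAL_A * q * q / 2.0 * g
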