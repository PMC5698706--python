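# Methods

## Scope and model

`cupredox` predicts changes in the Cu(II)/Cu(I) formal reduction potential of
azurin-like blue copper proteins upon point mutation. The physical model is a
thermodynamic cycle: for each structure (wildtype or mutant) the electrostatic
energy of the oxidized and the reduced copper site is computed with a
finite-difference linearized Poisson-Boltzmann (FD-LPBE) continuum model, and

    dE   = -(E_red - E_ox)            (per structure, in mV)
    ddE  = dE(mutant) - dE(wildtype)  (the reported shift)

Only *relative* potentials are reported; the large systematic offsets of a
continuum model (and the absolute reference to a standard electrode) cancel in
the difference. The protein is treated as rigid: cupredoxin sites are entatic
and crystal structures of azurin mutants superpose closely on wildtype, so
mutants are built by side-chain replacement on a fixed backbone rather than by
sampling conformations.

Two classes of mutation break the purely electrostatic picture and are routed
elsewhere by the workflow module:

* mutations that create or delete hydrogen bonds to the Cys112 thiolate or
  its neighbourhood (curated positions 47 and 114) redistribute covalent
  electron density in the redox-active orbital; their shifts are taken from a
  bundled table of quantum-chemical (DFT) values — no electronic-structure
  calculation is performed by this package;
* hydrophobic substitutions of the axial Met121 are dominated by desolvation
  of the site and are handled by an empirical linear correction in the
  Kyte-Doolittle hydropathy change, dE_hydro = a*dKD + b, with
  a = 25.8 mV/KD and b = 64.7 mV from calibration against the experimental
  M121{G,A,L,V,I} series. For a multi-point mutant M/A containing an axial
  point A the combination rule is
  ddE(M/A) = ddE_comp(M/A) - ddE_comp(A) + dE_hydro(A); for a single axial
  mutant the two computed terms cancel identically.

Multi-point mutants resolve the table-covered subset first; the remaining
points are evaluated as one joint continuum-electrostatics mutant (not a sum
of singles), and the prediction is the sum of the components.

## Continuum electrostatics

The LPBE  div(eps grad u) - kbar^2 u = -4 pi C rho  is discretized on a cubic
lattice (default edge 57.8 A, spacing 0.2 A, i.e. 290 nodes per edge) with the
7-point stencil and harmonic-mean face dielectrics. Internally `u` is the
dimensionless potential (kT/e); charges are in e, lengths in A, energies
reported in kcal/mol; 1 kcal/mol corresponds to 43.364 mV for a one-electron
couple at 298.15 K.

* **Dielectric map.** eps_in = 4 inside the molecular (solvent-excluded)
  surface, eps_out = 78 outside. The surface is built in two passes on the
  lattice: nodes within r_atom + 1.4 A (probe) of any atom are probe-excluded;
  of those, nodes farther than the probe radius from the nearest accessible
  node (Euclidean distance transform) are interior. This keeps re-entrant
  necks between atoms interior, unlike an accessible-surface test. The binary
  map is then smoothed by 9-point harmonic averaging — the harmonic mean over
  the node (weight 3) and its six face neighbours — with an arithmetic variant
  available behind a flag for sensitivity checks.
* **Screening map.** kbar^2 = eps_out / lambda_D^2 at ion-accessible nodes and
  zero within atom radius + 2.0 A (Stern ion-exclusion layer). The Debye
  length is computed from the ionic strength (default 0.15 M, 1:1 salt) at
  298.15 K: lambda_D = 7.83 A at 0.15 M.
* **Charges.** Point charges are spread over a 4x4x4 neighbourhood with cubic
  B-spline weights (exact partition of unity, verified to 1e-9 e), and
  potentials are read back at atom positions with the same stencil.
* **Boundary condition.** Dirichlet values on the box faces from the sum of
  Debye-Hueckel potentials of all source charges ("multiple sphere"), with a
  zero-boundary option for testing.
* **Solver.** The Dirichlet system is symmetric positive definite and is
  solved with Jacobi-preconditioned conjugate gradients to a relative
  residual of 1e-6 (deterministic; typically 100-300 iterations). A red-black
  SOR sweep solver is retained as an independent cross-check
  (`method="sor"`); the two agree to well below the energy tolerances. CG was
  chosen over plain SOR because it converges much faster on a single CPU at
  identical determinism.
* **Energies.** G = 1/2 sum_i q_i u(r_i) on the grid contains a large,
  discretization-dependent self-energy per charge. Because the oxidized and
  reduced charge sets differ, this artifact does not cancel between states.
  Each state energy is therefore computed as (solvated grid energy) minus
  (grid energy with uniform eps_in and no salt, identical grid and charge
  discretization) plus the exact pairwise Coulomb interaction at eps_in.
  The reference solve cancels the self-energy exactly; the analytic Coulomb
  term restores the physical charge-charge interaction the reference also
  removed.

### Numerical accuracy

Against the Born/Kirkwood closed form (ion of radius R, eps 4 -> 78, with the
screening term for I > 0) the engine agrees within 2 % at 0.2 A spacing and
5 % at 0.4 A for q in {+-1, +-2}, R in [1.5, 3] A; Coulomb pair interactions
in a uniform dielectric agree within 3 % after self-energy subtraction. The
operator is verified linear (superposition to 1e-8, exact quadratic charge
scaling). Rigid sub-spacing translation of the toy copper site changes a
computed ddE by ~2 mV at 0.4 A spacing — the residual staircase noise of
re-rasterizing the dielectric cavity — which sets the grid-artifact floor of
the desk-scale configuration.

## Structure preparation

* **Input.** PDB files are read through gemmi (MODEL 1 only). Alternate
  locations resolve to the highest occupancy (ties: first altloc
  alphabetically); insertion codes are rejected; waters are flagged and
  stripped before electrostatics (they are part of the solvent continuum).
  Structures missing backbone atoms are rejected rather than rebuilt.
* **Mutation.** Side chains are rebuilt from ideal internal-coordinate
  templates; a bundled backbone-independent rotamer library (canonical
  gauche-/trans/gauche+ combinations per sp3 torsion, +-90/0 for sp2
  terminals) is searched exhaustively and the rotamer minimizing a soft-sphere
  clash score (sum of squared vdW overlaps against all atoms within 8 A) is
  kept, ties broken by library rank. Backbone atoms, and CB where both
  residues share one, never move. The search is deterministic; the `seed`
  argument is interface metadata only. Tryptophan has no template (never a
  target in these workflows) and raises a clear error.
* **Protonation.** Fixed pH-7 rules rather than a pKa calculation: Asp/Glu
  anionic, Arg/Lys protonated, every histidine singly protonated at N-delta,
  cysteines classified by geometry (thiol, disulfide, or Cu-bound thiolate).
  The engineered axial lysine of M121K is kept neutral (buried amine), applied
  automatically by the CE engine. Hydrogens are placed with ideal geometry.
  Chain termini default to neutral; charged termini are available per rule.
* **Parameters.** The bundled charge/radius table is a simplified
  polar-hydrogen set written for continuum work: aliphatic/aromatic hydrogens
  are implicit, polar hydrogens explicit, and each residue variant's charges
  sum to its formal charge (validated to 1e-4 e at load). Radii: C 1.70,
  N 1.50, O 1.40, S 1.85, polar H 1.00 A. The copper site takes
  oxidation-state-dependent charges from a separate set; the published
  NBO-derived charges are not available, so the bundled set is a documented
  synthetic stand-in spreading the redox electron over Cu, S(Cys112) and the
  coordinating His nitrogens with total(OX) - total(RED) = +1.000 e exactly
  and a copper radius of 1.71 A in both states. Continuum results are
  therefore charge-set dependent; the set can be overridden from file.

## Synthetic fixtures

The generator produces the study systems used by the tests and the
acceptance script: a Born ion (single pseudo-atom of given charge/radius), a
fixed charge pair, a short ideal alpha-helical peptide with real residue
types, a toy copper site (Cu with two truncated His ligands through N-epsilon2,
a Cys thiolate and an axial Met121, numbered as in azurin so the real charge
set applies), and multi-chain translated copies. All are deterministic per
seed. They emulate the geometry and charge bookkeeping of the real problem
but not its size, irregular surface, or conformational detail: passing tests
demonstrate correctness of the numerics and the combination rules, not
prediction accuracy on real proteins, which additionally depends on the
copper-site charge set and rotamer placement.

## Problem sizes and defaults

Production-style settings (57.8 A box, 0.2 A spacing, four chains) are
implemented but expensive; the test suite and the acceptance script run the
same code on desk-scale systems: 16-26 A boxes at 0.2-0.5 A spacing chosen so
every oracle check completes in seconds to a couple of minutes. The
full-protein benchmark path (PDB 4AZU, all four chains averaged) is exercised
only when a local copy of the structure is present.

## Design choices on open points

* Distance to copper is reported as the minimum over the residue's heavy
  atoms (the reference atom convention is not fixed by the source data);
  outputs record the convention.
* The secondary-sphere screen enumerates all Arg/Lys/Asp/Glu/Gln/Asn/Ser/
  Thr/Met positions excluding the three copper ligands, position 121 and all
  cysteines; the exact published membership list is unavailable, so outputs
  always carry the position list used.
* Experimental ranges collapse to midpoints for the hydrophobicity fit
  (endpoints selectable); the fit is unweighted OLS. dKD is mutant minus
  methionine — with the published (a, b) this reproduces the experimental
  anchors M121G ~ 7 mV and M121I ~ 138 mV to within a few mV.
* Two calibration-set members (M121A, M121I) are not published in the main
  text; the bundled file reconstructs them so that OLS reproduces the
  published constants, and is labelled synthetic.
* The screen threshold compares the integer-rounded |shift| strictly against
  20 mV, matching the integer presentation of the published table.
* The M121Q experimental range is printed ambiguously ("-64-91") and is
  stored verbatim but excluded from range-aware scoring.
* Evaluation lists are explicit inputs (the published benchmark set is
  variously counted as 30 or 34 mutants).

## Known limitations

* No pKa computation, no nonlinear PB, no multigrid focusing, no membrane or
  periodic boundaries; nucleic acids and non-copper ligands unsupported.
* Continuum shifts depend on the synthetic copper-site charge set; absolute
  potentials are out of scope by construction.
* Hydrogen placement is ideal-geometry, single-conformer; no hydrogen-bond
  network optimization.
* The rotamer library is coarse (canonical torsions only), adequate for
  clash-free placement, not for packing-quality side-chain prediction.
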