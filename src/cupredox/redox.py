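"""Reduction-potential shifts from oxidized/reduced state energies.

The relative reduction potential of one structure is the Born-Haber
difference ``-(E_red - E_ox)`` of the two oxidation-state electrostatic
energies, converted to mV; the shift of a mutant against wildtype is the
difference of those values (mutant minus wildtype).  Absolute potentials
against a reference electrode are out of scope: the systematic offsets of a
continuum model cancel only in differences.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Callable, Iterable, Sequence

import numpy as np

from . import constants as K
from .forcefield import (
    OXIDIZED,
    REDUCED,
    CopperSiteChargeSet,
    ForceFieldTable,
    ParameterizedStructure,
    parameterize,
)
from .grid import GridSpec
from .mutate import RotamerLibrary, build_mutant
from .protonate import ProtonationRules, assign_protonation
from .solver import SolverOptions, state_energy
from .structure import (
    MutationSpec,
    Structure,
    StructureError,
    distance_to_copper,
    extract_chain,
    find_copper,
)


@dataclasses.dataclass
class RedoxResult:
    """Per-chain and chain-averaged relative reduction potential (mV)."""

    label: str
    per_chain: dict[str, float]
    mean: float
    sd: float
    metadata: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class ScreenRow:
    mutant: str
    ddE_mV: float
    distance_A: float
    exceeds_threshold: bool


def average_chains(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (0 for one value)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no per-chain values to average")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return mean, sd


def reduction_energy(
    pstructure_ox: ParameterizedStructure,
    pstructure_red: ParameterizedStructure,
    grid: GridSpec,
    options: SolverOptions | None = None,
    **energy_kwargs,
) -> float:
    """Relative reduction potential of one OX/RED pair in mV.

    The two states must share coordinates and radii (they differ only in
    charges); a more favourable reduction (lower reduced-state energy) gives
    a higher potential.
    """
    pos_ox = pstructure_ox.positions()
    pos_red = pstructure_red.positions()
    if pos_ox.shape != pos_red.shape or not np.allclose(pos_ox, pos_red, atol=1e-8):
        raise StructureError("OX and RED states must have identical coordinates")
    if np.array_equal(pstructure_ox.charges(), pstructure_red.charges()):
        return 0.0
    e_ox = state_energy(pstructure_ox, grid, options, **energy_kwargs)
    e_red = state_energy(pstructure_red, grid, options, **energy_kwargs)
    return (e_ox - e_red) * K.MV_PER_KCAL


def ddE(wt: RedoxResult, mutant: RedoxResult) -> tuple[float, float]:
    """Mutant-minus-wildtype potential shift and propagated sd (mV)."""
    for key in ("grid", "solver"):
        if wt.metadata.get(key) != mutant.metadata.get(key):
            raise ValueError(f"mismatched {key} settings between WT and mutant results")
    return mutant.mean - wt.mean, math.hypot(wt.sd, mutant.sd)


class CEEngine:
    """Continuum-electrostatics shift calculator for one parent structure.

    Prepares each requested chain once (waters stripped, hydrogens and
    charges assigned), computes and caches the wildtype potential, and
    evaluates mutants on an identically centered grid so that grid
    artifacts cancel in the difference.
    """

    def __init__(
        self,
        structure: Structure,
        chains: Iterable[str] | None = None,
        grid_length: float = 57.8,
        grid_spacing: float = 0.2,
        options: SolverOptions | None = None,
        fftable: ForceFieldTable | None = None,
        cu_set: CopperSiteChargeSet | None = None,
        rules: ProtonationRules | None = None,
        rotamer_library: RotamerLibrary | None = None,
        eps_in: float = K.DEFAULT_EPS_IN,
        eps_out: float = K.DEFAULT_EPS_OUT,
    ):
        self.structure = structure.without_waters()
        self.chains = sorted(chains if chains is not None else structure.chains)
        self.options = options or SolverOptions()
        self.fftable = fftable or ForceFieldTable.load()
        self.cu_set = cu_set or CopperSiteChargeSet.load()
        self.rules = rules or ProtonationRules()
        self.rotlib = rotamer_library or RotamerLibrary.load()
        self.eps_in = eps_in
        self.eps_out = eps_out
        self._chain_structures = {c: extract_chain(self.structure, c)
                                  for c in self.chains}
        self._grids = {}
        for c, s in self._chain_structures.items():
            try:
                center = find_copper(s).position
            except StructureError:
                center = s.coordinates().mean(axis=0)
            self._grids[c] = GridSpec(tuple(center), grid_length, grid_spacing)
        self._wt: RedoxResult | None = None

    # -- internals ----------------------------------------------------------
    def _metadata(self) -> dict:
        g = next(iter(self._grids.values()))
        return {
            "grid": (g.length, g.spacing),
            "solver": dataclasses.astuple(self.options),
            "chains": tuple(self.chains),
            "distance_reference": "min-heavy-atom",
        }

    def _chain_potential(self, chain: str, spec: MutationSpec | None) -> float:
        base = self._chain_structures[chain]
        rules = self.rules
        if spec is not None:
            base = build_mutant(base, spec, self.rotlib, chain_id=chain)
            # engineered axial lysine stays neutral (buried amine)
            if any(p.res_seq == 121 and p.new_res == "LYS" for p in spec.points):
                rules = dataclasses.replace(
                    rules, exceptions=rules.exceptions + ((chain, 121, "neutral"),)
                )
        prot = assign_protonation(base, rules)
        ps_ox = parameterize(prot, self.fftable, self.cu_set, OXIDIZED)
        ps_red = parameterize(prot, self.fftable, self.cu_set, REDUCED)
        return reduction_energy(ps_ox, ps_red, self._grids[chain], self.options,
                                eps_in=self.eps_in, eps_out=self.eps_out)

    def _result(self, label: str, spec: MutationSpec | None) -> RedoxResult:
        per_chain = {c: self._chain_potential(c, spec) for c in self.chains}
        mean, sd = average_chains(list(per_chain.values()))
        return RedoxResult(label, per_chain, mean, sd, self._metadata())

    # -- public surface -----------------------------------------------------
    def wildtype(self) -> RedoxResult:
        if self._wt is None:
            self._wt = self._result("WT", None)
        return self._wt

    def mutant(self, spec: MutationSpec | str) -> RedoxResult:
        if isinstance(spec, str):
            spec = MutationSpec.parse(spec)
        return self._result(spec.label, spec)

    def shift(self, spec: MutationSpec | str) -> float:
        """Mutant-minus-wildtype reduction-potential shift in mV."""
        value, _sd = ddE(self.wildtype(), self.mutant(spec))
        return value

    def __call__(self, spec: MutationSpec | str) -> float:
        return self.shift(spec)


#: residue types enumerated for the predictive screen
SCREEN_SOURCE_TYPES = ("ARG", "LYS", "ASP", "GLU", "GLN", "ASN", "SER", "THR", "MET")
FIRST_SPHERE = (46, 112, 117)
AXIAL_POSITION = 121


def candidate_positions(structure: Structure, chain_id: str | None = None) -> list[int]:
    """Secondary-coordination-sphere screen positions.

    All residues of the screened polar/charged types, excluding the copper
    ligands, the axial position, and cysteines (free or disulfide-bonded).
    This enumeration approximates a membership list the source data does not
    publish; outputs always carry the position list actually used.
    """
    positions = []
    for (ch, seq), atoms in structure.residues().items():
        if chain_id is not None and ch != chain_id:
            continue
        res = atoms[0].res_name
        if res not in SCREEN_SOURCE_TYPES:
            continue
        if seq in FIRST_SPHERE or seq == AXIAL_POSITION:
            continue
        positions.append(seq)
    return sorted(set(positions))


def screen(
    structure: Structure,
    position_set: Iterable[int],
    engine: Callable[[str], float],
    target_residues: Sequence[str] = ("LYS", "ASP", "ALA"),
    threshold: float = 20.0,
    chain_id: str | None = None,
) -> list[ScreenRow]:
    """Exhaustive single-mutant scan: one row per (position, target).

    Identity substitutions are skipped; the threshold flag uses a strict
    ``>`` on the integer-rounded shift; the full table is always returned
    (filtering to the exceeders is a view on the result).
    """
    from .structure import THREE_TO_ONE

    positions = sorted(set(position_set))
    for seq in positions:
        if seq in FIRST_SPHERE:
            raise StructureError(
                f"position {seq} is a first-sphere copper ligand and cannot be screened"
            )
        res = structure.residue(seq, chain_id)[0].res_name
        if res == "CYS":
            raise StructureError(f"position {seq} is a cysteine (excluded from screen)")

    has_cu = any(a.name.upper() == "CU" or a.element.upper() == "CU"
                 for a in structure.atoms)
    rows: list[ScreenRow] = []
    for seq in positions:
        wt_res = structure.residue(seq, chain_id)[0].res_name
        dist = distance_to_copper(structure, seq, chain_id) if has_cu else math.nan
        for target in target_residues:
            if target == wt_res:
                continue
            label = f"{THREE_TO_ONE[wt_res]}{seq}{THREE_TO_ONE[target]}"
            value = float(engine(label))
            rows.append(
                ScreenRow(label, value, dist, abs(round(value)) > threshold)
            )
    return rows
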