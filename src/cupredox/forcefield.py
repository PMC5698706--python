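"""Charge/radius assignment: forcefield table, copper-site charge sets.

The bundled parameter file is a simplified polar-hydrogen set written for
continuum electrostatics: aliphatic/aromatic hydrogens are implicit, polar
hydrogens are explicit, and each residue's charges sum to its formal charge.
The copper site is parameterized separately per oxidation state; atoms of the
ligating residues not listed in the copper-site set fall back to the table.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import Structure, StructureError

_DATA = resources.files("cupredox") / "data"

#: formal charges per (res_name, variant); anything absent is neutral
FORMAL_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "default"): -1.0,
    ("GLU", "default"): -1.0,
    ("LYS", "default"): +1.0,
    ("ARG", "default"): +1.0,
    ("LYS", "neutral"): 0.0,
    ("CYS", "thiolate"): -1.0,
    ("HIS", "protonated"): +1.0,
}

OXIDIZED = "OX"
REDUCED = "RED"


class ForceFieldTable:
    """Mapping (res_name, atom_name, variant) -> (charge e, radius A)."""

    def __init__(self, frame: pd.DataFrame):
        self._map: dict[tuple[str, str, str], tuple[float, float]] = {}
        for row in frame.itertuples(index=False):
            key = (str(row.res_name), str(row.atom_name), str(row.variant))
            self._map[key] = (float(row.charge), float(row.radius))
        self.validate()

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ForceFieldTable":
        if path is None:
            path = _DATA / "forcefield.tsv"
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(frame)

    def lookup(self, res_name: str, atom_name: str, variant: str = "default"
               ) -> tuple[float, float]:
        for key in ((res_name, atom_name, variant), (res_name, atom_name, "default")):
            if key in self._map:
                return self._map[key]
        raise KeyError(
            f"no forcefield entry for atom {atom_name!r} of {res_name!r} "
            f"(variant {variant!r})"
        )

    def has(self, res_name: str, atom_name: str, variant: str = "default") -> bool:
        return (res_name, atom_name, variant) in self._map or (
            res_name, atom_name, "default") in self._map

    def residue_variants(self) -> set[tuple[str, str]]:
        return {(r, v) for (r, _a, v) in self._map}

    def validate(self, tol: float = 1e-4) -> None:
        """Per-(residue, variant) charges must sum to the formal charge."""
        sums: dict[tuple[str, str], float] = {}
        for (res, _atom, var), (q, _r) in self._map.items():
            if res in ("*", "CU"):
                continue  # terminal patches / metal handled separately
            sums[(res, var)] = sums.get((res, var), 0.0) + q
        for (res, var), total in sums.items():
            # variant rows are complete residue definitions in the bundled set
            formal = FORMAL_CHARGES.get((res, var), 0.0)
            if abs(total - formal) > tol:
                raise ValueError(
                    f"{res}/{var}: charges sum to {total:+.4f}, expected {formal:+.1f}"
                )


@dataclasses.dataclass
class CopperSiteChargeSet:
    """Oxidation-state dependent charges for Cu and its direct ligands.

    Roles are ``CU``, ``HIS46``, ``CYS112``, ``HIS117``; the mapping is from
    ``(role, atom_name)`` to partial charge.  Atoms of the ligand residues not
    listed here keep their forcefield charges.
    """

    charges: dict[str, dict[tuple[str, str], float]]
    copper_radius: float = 1.71

    def __post_init__(self) -> None:
        diff = self.total(OXIDIZED) - self.total(REDUCED)
        if abs(diff - 1.0) > 1e-4:
            raise ValueError(
                f"total(OX) - total(RED) must be +1.000 e, got {diff:+.4f}"
            )

    def total(self, state: str) -> float:
        return sum(self.charges[state].values())

    @classmethod
    def load(cls, path: str | Path | None = None) -> "CopperSiteChargeSet":
        if path is None:
            path = _DATA / "copper_site.tsv"
        frame = pd.read_csv(path, sep="\t", comment="#")
        charges: dict[str, dict[tuple[str, str], float]] = {OXIDIZED: {}, REDUCED: {}}
        radius: dict[str, float] = {}
        for row in frame.itertuples(index=False):
            state = str(row.oxidation_state)
            charges[state][(str(row.role), str(row.atom_name))] = float(row.charge)
            if str(row.role) == "CU" and not pd.isna(row.radius):
                radius[state] = float(row.radius)
        if radius and len(set(radius.values())) != 1:
            raise ValueError("copper radius must be identical in both states")
        return cls(charges, copper_radius=next(iter(radius.values()), 1.71))

    #: residue-number anchors for the ligand roles (azurin numbering)
    ROLE_SEQ = {"HIS46": 46, "CYS112": 112, "HIS117": 117}

    def role_of(self, res_name: str, res_seq: int) -> str | None:
        if res_name == "CU" or (res_name in ("HET", "ION") and res_seq >= 200):
            return "CU"
        for role, seq in self.ROLE_SEQ.items():
            if res_seq == seq and res_name == role[:3]:
                return role
        return None


@dataclasses.dataclass
class ParameterizedStructure:
    """Structure with charges/radii assigned and an oxidation-state tag."""

    structure: Structure
    oxidation_state: str | None
    total_charge: float

    @property
    def atoms(self):
        return self.structure.atoms

    def positions(self) -> np.ndarray:
        return self.structure.coordinates()

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


def parameterize(
    structure: Structure,
    fftable: ForceFieldTable | None = None,
    cu_set: CopperSiteChargeSet | None = None,
    oxidation_state: str | None = None,
    strip_waters: bool = True,
) -> ParameterizedStructure:
    """Assign charges and radii to every atom.

    Copper-site atoms take state-dependent charges from ``cu_set``; all other
    atoms are resolved in the forcefield table using the per-residue
    protonation variant recorded on the structure.  Crystallographic waters
    are stripped (they are represented by the solvent continuum).
    """
    if fftable is None:
        fftable = ForceFieldTable.load()
    if cu_set is not None and oxidation_state not in (OXIDIZED, REDUCED):
        raise ValueError(f"oxidation_state must be OX or RED, got {oxidation_state!r}")

    work = structure.without_waters() if strip_waters else structure.copy()
    residues = work.residues()
    total = 0.0
    for (chain, seq), atoms in residues.items():
        res_name = atoms[0].res_name
        variant = work.protonation_states.get((chain, seq), "default")
        names = {a.name for a in atoms}
        nter = {"H1", "H2", "H3"} <= names
        cter = "OXT" in names
        role = cu_set.role_of(res_name, seq) if cu_set is not None else None
        for a in atoms:
            charge = radius = None
            if role is not None and (role, a.name) in cu_set.charges[oxidation_state]:
                charge = cu_set.charges[oxidation_state][(role, a.name)]
                if role == "CU":
                    radius = cu_set.copper_radius
            if charge is None:
                if nter and fftable.has("*", a.name, "nter") and a.name in (
                        "N", "H1", "H2", "H3", "CA"):
                    charge, radius = fftable.lookup("*", a.name, "nter")
                elif cter and a.name in ("C", "O", "OXT"):
                    charge, radius = fftable.lookup("*", a.name, "cter")
                else:
                    try:
                        charge, radius = fftable.lookup(res_name, a.name, variant)
                    except KeyError as exc:
                        raise StructureError(str(exc)) from exc
            if radius is None:
                _q, radius = fftable.lookup(res_name, a.name, variant)
            a.charge = float(charge)
            a.radius = float(radius)
            total += a.charge
    return ParameterizedStructure(work, oxidation_state, total)


def as_parameterized(structure: Structure,
                     oxidation_state: str | None = None) -> ParameterizedStructure:
    """Wrap a structure whose atoms already carry charges and radii."""
    for a in structure.atoms:
        if a.charge is None or a.radius is None:
            raise StructureError(f"atom {a.name} lacks charge/radius")
    total = float(sum(a.charge for a in structure.atoms))
    return ParameterizedStructure(structure.copy(), oxidation_state, total)
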