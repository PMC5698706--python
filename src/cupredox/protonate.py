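"""Rule-based protonation at fixed pH with ideal-geometry polar hydrogens.

Protonation follows fixed pH-7 rules rather than a pKa calculation: Asp/Glu
anionic, Arg/Lys protonated, every His singly protonated at N-delta.
Exceptions (e.g. a neutral engineered lysine at the axial copper position)
are listed explicitly per residue.  Only hydrogen atoms are added or removed;
heavy atoms are never touched.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import bisector_h, place_atom
from .structure import Atom, Structure, StructureError

#: default forcefield variant per titratable residue type at pH 7
DEFAULT_STATES = {
    "ASP": "default",   # anionic
    "GLU": "default",   # anionic
    "LYS": "default",   # protonated
    "ARG": "default",   # protonated
    "HIS": "default",   # neutral, proton on N-delta
    "CYS": "default",   # thiol (overridden to thiolate/disulfide by geometry)
}


@dataclasses.dataclass
class ProtonationRules:
    """pH, per-residue default states and an explicit exception list."""

    pH: float = 7.0
    exceptions: tuple[tuple[str, int, str], ...] = ()
    #: add charged N-terminal hydrogens (NH3+) instead of a single amide-like H
    charged_termini: bool = False

    def state_for(self, chain: str, res_seq: int, res_name: str) -> str:
        for ch, seq, state in self.exceptions:
            if ch == chain and seq == res_seq:
                return state
        return DEFAULT_STATES.get(res_name, "default")


def _sg_environment(structure: Structure, atom: Atom) -> str:
    """Classify a cysteine sulfur: thiol, disulfide partner, or Cu-bound."""
    for other in structure.atoms:
        if other is atom:
            continue
        d = float(np.linalg.norm(other.position - atom.position))
        if other.name == "SG" and other.res_name == "CYS" and d < 2.5:
            return "disulfide"
        if (other.element.upper() == "CU" or other.name.upper() == "CU") and d < 2.8:
            return "thiolate"
    return "default"


def assign_protonation(structure: Structure,
                       rules: ProtonationRules | None = None) -> Structure:
    """Return a copy with polar hydrogens placed and variant tags recorded."""
    if rules is None:
        rules = ProtonationRules()
    for ch, seq, _state in rules.exceptions:
        if not any(a.chain_id == ch and a.res_seq == seq for a in structure.atoms):
            raise StructureError(f"protonation exception references absent residue "
                                 f"{ch}/{seq}")

    residues = structure.residues()
    chain_order: dict[str, list[tuple[str, int]]] = {}
    for key in residues:
        chain_order.setdefault(key[0], []).append(key)

    out_atoms: list[Atom] = []
    states: dict[tuple[str, int], str] = {}
    serial = 0

    def add(atom: Atom) -> None:
        nonlocal serial
        serial += 1
        atom.serial = serial
        out_atoms.append(atom)

    def add_h(name: str, pos: np.ndarray, ref: Atom) -> None:
        add(Atom(0, name, "H", ref.res_name, ref.res_seq, ref.chain_id,
                 np.asarray(pos, float), is_hydrogen=True))

    for chain_id, keys in chain_order.items():
        protein_keys = [k for k in keys if not residues[k][0].is_water]
        for key in keys:
            atoms = residues[key]
            res_name = atoms[0].res_name
            heavy = {a.name: a for a in atoms if not a.is_hydrogen}
            pos = {n: a.position for n, a in heavy.items()}
            is_water = atoms[0].is_water

            state = rules.state_for(chain_id, key[1], res_name)
            if res_name == "CYS" and state == "default" and "SG" in heavy:
                state = _sg_environment(structure, heavy["SG"])
            if res_name in DEFAULT_STATES or state != "default":
                states[key] = state

            for a in atoms:  # heavy atoms pass through unchanged
                if not a.is_hydrogen:
                    add(a.copy())
            if is_water or not {"N", "CA", "C"} <= set(pos):
                continue  # waters / non-amino-acid groups: no hydrogen model

            ref = heavy["CA"]
            # backbone amide hydrogen
            if res_name != "PRO":
                idx = protein_keys.index(key) if key in protein_keys else 0
                prev_c = None
                if idx > 0:
                    prev = residues[protein_keys[idx - 1]]
                    prev_c = next((a.position for a in prev if a.name == "C"), None)
                if prev_c is not None:
                    add_h("H", bisector_h(pos["N"], prev_c, pos["CA"], 1.01), ref)
                elif rules.charged_termini:
                    for i, tors in enumerate((60.0, 180.0, -60.0), start=1):
                        add_h(f"H{i}",
                              place_atom(pos["C"], pos["CA"], pos["N"], 1.01, 109.5, tors),
                              ref)
                else:
                    add_h("H", place_atom(pos["C"], pos["CA"], pos["N"], 1.01, 109.5, 180.0),
                          ref)

            sc = _sidechain_hydrogens(res_name, state, pos)
            for name, p in sc:
                add_h(name, p, ref)

    out = Structure(out_atoms, structure.title, structure.source)
    out.protonation_states = states
    return out


def _sidechain_hydrogens(res_name: str, state: str,
                         pos: dict[str, np.ndarray]) -> list[tuple[str, np.ndarray]]:
    h: list[tuple[str, np.ndarray]] = []
    have = pos.__contains__
    if res_name == "SER" and have("OG"):
        h.append(("HG", place_atom(pos["CA"], pos["CB"], pos["OG"], 0.96, 109.5, 180.0)))
    elif res_name == "THR" and have("OG1"):
        h.append(("HG1", place_atom(pos["CA"], pos["CB"], pos["OG1"], 0.96, 109.5, 180.0)))
    elif res_name == "TYR" and have("OH"):
        h.append(("HH", place_atom(pos["CE1"], pos["CZ"], pos["OH"], 0.96, 110.0, 0.0)))
    elif res_name == "CYS" and state == "default" and have("SG"):
        h.append(("HG", place_atom(pos["CA"], pos["CB"], pos["SG"], 1.34, 96.0, 180.0)))
    elif res_name == "ASN" and have("ND2"):
        h.append(("HD21", place_atom(pos["OD1"], pos["CG"], pos["ND2"], 1.01, 120.0, 180.0)))
        h.append(("HD22", place_atom(pos["OD1"], pos["CG"], pos["ND2"], 1.01, 120.0, 0.0)))
    elif res_name == "GLN" and have("NE2"):
        h.append(("HE21", place_atom(pos["OE1"], pos["CD"], pos["NE2"], 1.01, 120.0, 180.0)))
        h.append(("HE22", place_atom(pos["OE1"], pos["CD"], pos["NE2"], 1.01, 120.0, 0.0)))
    elif res_name == "TRP" and have("NE1"):
        h.append(("HE1", bisector_h(pos["NE1"], pos["CD1"], pos["CE2"], 1.01)))
    elif res_name == "HIS" and have("ND1"):
        if state in ("default", "protonated"):  # proton on N-delta
            h.append(("HD1", bisector_h(pos["ND1"], pos["CG"], pos["CE1"], 1.01)))
        if state in ("ne2", "protonated"):
            h.append(("HE2", bisector_h(pos["NE2"], pos["CD2"], pos["CE1"], 1.01)))
    elif res_name == "ARG" and have("NE"):
        h.append(("HE", bisector_h(pos["NE"], pos["CD"], pos["CZ"], 1.01)))
        for nh, tags in (("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))):
            if have(nh):
                h.append((tags[0], place_atom(pos["NE"], pos["CZ"], pos[nh], 1.01, 120.0, 0.0)))
                h.append((tags[1], place_atom(pos["NE"], pos["CZ"], pos[nh], 1.01, 120.0, 180.0)))
    elif res_name == "LYS" and have("NZ"):
        torsions = (60.0, 180.0, -60.0) if state == "default" else (60.0, 180.0)
        for i, tors in enumerate(torsions, start=1):
            h.append((f"HZ{i}", place_atom(pos["CD"], pos["CE"], pos["NZ"], 1.01, 109.5, tors)))
    return h
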