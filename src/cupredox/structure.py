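"""Protein structure container, PDB I/O and mutation specifications.

The in-memory model is a flat, ordered list of :class:`Atom` records grouped
implicitly by ``(chain_id, res_seq)``.  PDB files are read and written through
gemmi; only ``MODEL 1`` of multi-model files is considered and alternate
locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import dataclasses
import re
from collections.abc import Iterable, Iterator
from pathlib import Path

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: three-letter <-> one-letter residue code tables (standard amino acids)
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3"}


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclasses.dataclass
class Atom:
    """One atom record.

    ``charge`` and ``radius`` stay ``None`` until the structure is
    parameterized against a forcefield table.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    position: np.ndarray
    charge: float | None = None
    radius: float | None = None
    is_hydrogen: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if self.radius is not None and self.radius < 0:
            raise StructureError(f"atom {self.name}: negative radius")
        if not self.is_hydrogen:
            self.is_hydrogen = self.element.upper() == "H" or (
                not self.element and self.name.startswith("H")
            )

    def copy(self) -> "Atom":
        a = dataclasses.replace(self)
        a.position = self.position.copy()
        return a


class Structure:
    """Ordered atom collection with chain/residue bookkeeping."""

    def __init__(self, atoms: Iterable[Atom] = (), title: str = "", source: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.title = title
        self.source = source
        #: per-residue protonation variant tags, filled by ``assign_protonation``
        self.protonation_states: dict[tuple[str, int], str] = {}
        self._check_unique()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def _check_unique(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)

    # -- grouping helpers ---------------------------------------------------
    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain_id, res_seq), preserving order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.res_seq), []).append(a)
        return out

    def residue(self, res_seq: int, chain_id: str | None = None) -> list[Atom]:
        atoms = [
            a
            for a in self.atoms
            if a.res_seq == res_seq and (chain_id is None or a.chain_id == chain_id)
        ]
        if not atoms:
            raise StructureError(f"residue {res_seq} (chain {chain_id}) not found")
        return atoms

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def copy(self) -> "Structure":
        s = Structure([a.copy() for a in self.atoms], self.title, self.source)
        s.protonation_states = dict(self.protonation_states)
        return s

    def translated(self, shift) -> "Structure":
        s = self.copy()
        shift = np.asarray(shift, dtype=float)
        for a in s.atoms:
            a.position = a.position + shift
        return s

    def without_waters(self) -> "Structure":
        s = Structure([a.copy() for a in self.atoms if not a.is_water],
                      self.title, self.source)
        s.protonation_states = dict(self.protonation_states)
        return s


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, keep_waters: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by the alphabetically first altloc id); insertion codes are
    rejected; waters are retained but flagged unless ``keep_waters=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message
        raise StructureError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]  # MODEL 1 only

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise StructureError(
                    f"insertion code {res.seqid.icode!r} at {chain.name} "
                    f"{res.seqid.num} is not supported"
                )
            # resolve altlocs per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                else:
                    if (at.occ, -ord(at.altloc or "~")) > (
                        prev.occ,
                        -ord(prev.altloc or "~"),
                    ):
                        by_name[at.name] = at
            is_water = res.name in WATER_NAMES
            for at in by_name.values():
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_water=is_water,
                    )
                )
    s = Structure(atoms, title=st.name or path.stem, source=str(path))
    if not keep_waters:
        s = s.without_waters()
    return s


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (single model, no altlocs)."""
    st = gemmi.Structure()
    st.name = structure.title or "cupredox"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            model.add_chain(ch)
            ch = model[-1]
            chains[a.chain_id] = ch
        res = None
        if len(ch) and ch[-1].seqid.num == a.res_seq and ch[-1].name == a.res_name:
            res = ch[-1]
        if res is None:
            r = gemmi.Residue()
            r.name = a.res_name
            r.seqid = gemmi.SeqId(a.res_seq, " ")
            r.het_flag = "H" if a.is_water or a.res_name == "CU" else "A"
            ch.add_residue(r)
            res = ch[-1]
        g = gemmi.Atom()
        g.name = a.name
        g.element = gemmi.Element(a.element or a.name[0])
        g.pos = gemmi.Position(*a.position)
        g.occ = 1.0
        g.b_iso = 0.0
        res.add_atom(g)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_pqr(structure: Structure, path: str | Path) -> None:
    """Write a whitespace-separated PQR file (charge and radius columns).

    All atoms must carry a charge and radius.
    """
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        if a.charge is None or a.radius is None:
            raise StructureError(f"atom {a.name} has no charge/radius; parameterize first")
        x, y, z = a.position
        lines.append(
            f"ATOM {i:6d} {a.name:<4s} {a.res_name:<4s} {a.chain_id:1s} "
            f"{a.res_seq:5d} {x:10.4f} {y:10.4f} {z:10.4f} "
            f"{a.charge:8.4f} {a.radius:7.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# chain extraction and copper geometry
# ---------------------------------------------------------------------------

def extract_chain(structure: Structure, chain_id: str) -> Structure:
    """Return only the atoms of one chain; residue numbering is preserved."""
    if chain_id not in structure.chains:
        raise StructureError(
            f"chain {chain_id!r} not in structure (has {sorted(structure.chains)})"
        )
    s = Structure(
        [a.copy() for a in structure.atoms if a.chain_id == chain_id],
        structure.title,
        structure.source,
    )
    s.protonation_states = {
        k: v for k, v in structure.protonation_states.items() if k[0] == chain_id
    }
    return s


def find_copper(structure: Structure) -> Atom:
    for a in structure.atoms:
        if a.element.upper() == "CU" or a.name.upper() == "CU":
            return a
    raise StructureError("no copper atom in structure")


def distance_to_copper(structure: Structure, res_seq: int,
                       chain_id: str | None = None) -> float:
    """Minimum Cu-to-heavy-atom distance (A) for the given residue.

    The reference is the minimum over the residue's heavy atoms; this is a
    convention choice and is recorded with screen output so alternatives can
    be compared.
    """
    cu = find_copper(structure)
    heavy = [a for a in structure.residue(res_seq, chain_id)
             if not a.is_hydrogen and a is not cu]
    if not heavy:
        raise StructureError(f"residue {res_seq} has no heavy atoms")
    return float(min(np.linalg.norm(a.position - cu.position) for a in heavy))


# ---------------------------------------------------------------------------
# mutation specifications
# ---------------------------------------------------------------------------

_POINT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclasses.dataclass(frozen=True)
class PointMutation:
    res_seq: int
    wt_res: str  # 3-letter
    new_res: str  # 3-letter

    @property
    def label(self) -> str:
        return f"{THREE_TO_ONE[self.wt_res]}{self.res_seq}{THREE_TO_ONE[self.new_res]}"


@dataclasses.dataclass(frozen=True)
class MutationSpec:
    """One mutant, possibly multi-point, e.g. ``M121L/N47S``."""

    points: tuple[PointMutation, ...]

    def __post_init__(self) -> None:
        seqs = [p.res_seq for p in self.points]
        if len(seqs) != len(set(seqs)):
            raise StructureError(f"duplicate positions in mutation {self.label}")

    @property
    def label(self) -> str:
        return "/".join(p.label for p in self.points)

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        points = []
        for part in text.strip().split("/"):
            m = _POINT_RE.match(part.strip().upper())
            if not m:
                raise StructureError(f"cannot parse point mutation {part!r}")
            wt1, seq, new1 = m.groups()
            if wt1 not in ONE_TO_THREE or new1 not in ONE_TO_THREE:
                raise StructureError(f"unknown residue code in {part!r}")
            points.append(PointMutation(int(seq), ONE_TO_THREE[wt1], ONE_TO_THREE[new1]))
        return cls(tuple(points))

    def validate(self, structure: Structure, chain_id: str | None = None) -> None:
        """Check every point against the structure's residue identities."""
        for p in self.points:
            atoms = structure.residue(p.res_seq, chain_id)
            found = atoms[0].res_name
            if found != p.wt_res:
                one = THREE_TO_ONE.get(found, found)
                raise StructureError(
                    f"expected {THREE_TO_ONE[p.wt_res]} at {p.res_seq}, found {one}"
                )
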