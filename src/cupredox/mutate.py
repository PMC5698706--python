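"""In-silico point mutagenesis with a backbone-independent rotamer search.

Side chains are rebuilt from ideal internal-coordinate templates; the rotamer
(set of chi torsions from the bundled library) minimizing a pairwise
soft-sphere clash score against all atoms within a cutoff is kept, with ties
broken by library rank.  Backbone atoms, and the beta carbon where both
residues share one, are never moved.  Crystal structures of azurin mutants
show minimal backbone perturbation, which is what this procedure assumes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import place_atom
from .structure import Atom, MutationSpec, Structure, StructureError
from .templates import N_CHI, SIDECHAIN_TEMPLATES

_DATA = resources.files("cupredox") / "data"

#: element vdW radii for the clash score, A
CLASH_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.00, "CU": 1.40}
CLASH_CUTOFF = 8.0  # environment atoms considered, A

BACKBONE_KEEP = {"N", "CA", "C", "O", "OXT"}


class RotamerLibrary:
    """Backbone-independent chi-angle library keyed by residue type."""

    def __init__(self, rotamers: dict[str, list[tuple[float, ...]]]):
        self.rotamers = rotamers

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RotamerLibrary":
        if path is None:
            path = _DATA / "rotamers.tsv"
        frame = pd.read_csv(path, sep="\t", comment="#")
        rot: dict[str, list[tuple[float, ...]]] = {}
        for row in frame.sort_values(["res_name", "rank"]).itertuples(index=False):
            chis = tuple(
                float(v) for v in (row.chi1, row.chi2, row.chi3, row.chi4)
                if not pd.isna(v)
            )
            rot.setdefault(str(row.res_name), []).append(chis)
        return cls(rot)

    def for_residue(self, res_name: str) -> list[tuple[float, ...]]:
        n = N_CHI.get(res_name)
        if n is None:
            raise StructureError(f"no rotamer/template support for {res_name}")
        if n == 0:
            return [()]
        return self.rotamers[res_name]


def build_sidechain(res_name: str, frame: dict[str, np.ndarray],
                    chis: tuple[float, ...]) -> list[tuple[str, np.ndarray]]:
    """Heavy side-chain atoms for ``res_name`` given backbone frame atoms.

    ``frame`` must contain N, CA, C (and optionally an existing CB, which is
    then reused instead of rebuilt).
    """
    if res_name not in SIDECHAIN_TEMPLATES:
        raise StructureError(f"no side-chain template for {res_name}")
    placed = dict(frame)
    new: list[tuple[str, np.ndarray]] = []
    for name, (ra, rb, rc), bond, ang, tors in SIDECHAIN_TEMPLATES[res_name]:
        if name == "CB" and "CB" in frame:
            continue
        if isinstance(tors, tuple):
            _tag, k, offset = tors
            tval = chis[k - 1] + offset
        else:
            tval = tors
        p = place_atom(placed[ra], placed[rb], placed[rc], bond, ang, tval)
        placed[name] = p
        new.append((name, p))
    return new


def clash_score(candidate: list[tuple[str, np.ndarray]],
                env_positions: np.ndarray, env_radii: np.ndarray) -> float:
    """Soft-sphere overlap score: sum of squared vdW overlaps."""
    if len(env_positions) == 0 or not candidate:
        return 0.0
    score = 0.0
    for name, p in candidate:
        r = CLASH_RADII.get(_element_of(name), 1.7)
        d = np.linalg.norm(env_positions - p, axis=1)
        near = d < CLASH_CUTOFF
        overlap = np.maximum(0.0, (env_radii[near] + r) - d[near])
        score += float(np.sum(overlap**2))
    return score


def _element_of(atom_name: str) -> str:
    if atom_name.startswith("S"):
        return "S"
    if atom_name.startswith("O"):
        return "O"
    if atom_name.startswith("N"):
        return "N"
    if atom_name.startswith("H"):
        return "H"
    if atom_name.upper().startswith("CU"):
        return "CU"
    return "C"


def build_mutant(
    structure: Structure,
    spec: MutationSpec | str,
    rotamer_library: RotamerLibrary | None = None,
    seed: int = 0,
    chain_id: str | None = None,
) -> Structure:
    """Apply every point of a mutation spec to the structure.

    The search is exhaustive over the library and fully deterministic; the
    ``seed`` argument is part of the interface for reproducibility metadata
    but introduces no randomness.
    """
    del seed  # exhaustive deterministic search
    if isinstance(spec, str):
        spec = MutationSpec.parse(spec)
    spec.validate(structure, chain_id)
    if rotamer_library is None:
        rotamer_library = RotamerLibrary.load()

    result = structure.copy()
    for point in spec.points:
        if point.wt_res == point.new_res:
            continue
        chains = sorted({a.chain_id for a in result.atoms
                         if a.res_seq == point.res_seq
                         and a.res_name == point.wt_res
                         and (chain_id is None or a.chain_id == chain_id)})
        for ch in chains:
            result = _mutate_residue(result, ch, point.res_seq, point.new_res,
                                     rotamer_library)
        result.protonation_states.pop((chains[0] if chains else "", point.res_seq), None)
    return result


def _mutate_residue(structure: Structure, chain: str, res_seq: int,
                    new_res: str, library: RotamerLibrary) -> Structure:
    res_atoms = [a for a in structure.atoms
                 if a.chain_id == chain and a.res_seq == res_seq]
    keep_cb = new_res not in ("GLY",) and any(a.name == "CB" for a in res_atoms)

    kept: list[Atom] = []
    frame: dict[str, np.ndarray] = {}
    for a in structure.atoms:
        mine = a.chain_id == chain and a.res_seq == res_seq
        if not mine:
            kept.append(a.copy())
            continue
        if a.name in BACKBONE_KEEP or (a.name == "CB" and keep_cb):
            na = a.copy()
            na.res_name = new_res
            kept.append(na)
            frame[a.name] = a.position
        elif a.name == "H" and new_res != "PRO":
            na = a.copy()
            na.res_name = new_res
            kept.append(na)
    if not {"N", "CA", "C"} <= set(frame):
        raise StructureError(
            f"residue {chain}/{res_seq} is missing backbone atoms; refusing to guess"
        )

    env = [a for a in kept if not (a.chain_id == chain and a.res_seq == res_seq)]
    env_pos = np.array([a.position for a in env]) if env else np.zeros((0, 3))
    env_rad = np.array([CLASH_RADII.get(_element_of(a.name), 1.7) for a in env])

    best: tuple[float, int, list[tuple[str, np.ndarray]]] | None = None
    for rank, chis in enumerate(library.for_residue(new_res)):
        candidate = build_sidechain(new_res, frame, chis)
        score = clash_score(candidate, env_pos, env_rad)
        if best is None or score < best[0] - 1e-12:
            best = (score, rank, candidate)
    assert best is not None

    insert_at = max(
        i for i, a in enumerate(kept)
        if a.chain_id == chain and a.res_seq == res_seq
    ) + 1 if any(a.chain_id == chain and a.res_seq == res_seq for a in kept) else len(kept)
    new_atoms = [
        Atom(0, name, _element_of(name), new_res, res_seq, chain, p)
        for name, p in best[2]
    ]
    atoms = kept[:insert_at] + new_atoms + kept[insert_at:]
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    out = Structure(atoms, structure.title, structure.source)
    out.protonation_states = {
        k: v for k, v in structure.protonation_states.items()
        if k != (chain, res_seq)
    }
    return out
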