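"""Synthetic structure generator for testing and calibration.

Kinds:

``born_ion``
    a single spherical pseudo-ion with explicit charge and radius,
``charge_pair``
    two pseudo-ions at a fixed separation,
``mini_protein``
    a short ideal alpha-helical peptide with real residue types,
``toy_copper_site``
    Cu plus truncated His/His/Cys ligands (and an axial Met121) with a
    two-state charge set whose totals differ by exactly one electron,
``multi_chain``
    n rigidly translated copies of a base fixture as chains A, B, C, ...

All fixtures are deterministic for a given seed.
"""

from __future__ import annotations

import string

import numpy as np

from .forcefield import CopperSiteChargeSet
from .geometry import place_atom
from .mutate import RotamerLibrary, build_sidechain
from .structure import Atom, ONE_TO_THREE, Structure, StructureError

HELIX_PHI, HELIX_PSI, OMEGA = -57.0, -47.0, 180.0


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a synthetic fixture; returns a Structure (plus a charge set for
    ``toy_copper_site``)."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    builders = {
        "born_ion": _born_ion,
        "charge_pair": _charge_pair,
        "mini_protein": _mini_protein,
        "toy_copper_site": _toy_copper_site,
        "multi_chain": _multi_chain,
    }
    if kind not in builders:
        raise StructureError(f"unknown fixture kind {kind!r}")
    return builders[kind](params, rng)


def _pseudo_atom(name: str, res_seq: int, position, charge: float,
                 radius: float, chain: str = "A") -> Atom:
    if radius <= 0:
        raise StructureError("pseudo-atom radius must be positive")
    return Atom(0, name, "X", "ION", res_seq, chain, np.asarray(position, float),
                charge=float(charge), radius=float(radius))


def _born_ion(params: dict, rng) -> Structure:
    q = float(params.get("q", 1.0))
    radius = float(params.get("radius", 2.0))
    center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), float)
    s = Structure([_pseudo_atom("Q", 1, center, q, radius)], title="born_ion")
    return s


def _charge_pair(params: dict, rng) -> Structure:
    q1 = float(params.get("q1", 1.0))
    q2 = float(params.get("q2", -1.0))
    sep = float(params.get("separation", 5.0))
    radius = float(params.get("radius", 1.5))
    if sep <= 0:
        raise StructureError("separation must be positive")
    half = sep / 2.0
    return Structure(
        [
            _pseudo_atom("Q1", 1, (-half, 0.0, 0.0), q1, radius),
            _pseudo_atom("Q2", 2, (+half, 0.0, 0.0), q2, radius),
        ],
        title="charge_pair",
    )


def _helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone (N, CA, C, O per residue)."""
    frames: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    c = place_atom(dummy, n, ca, 1.525, 111.0, HELIX_PHI)
    for i in range(n_res):
        o = place_atom(n, ca, c, 1.231, 120.5, HELIX_PSI + 180.0)
        frames.append({"N": n, "CA": ca, "C": c, "O": o})
        if i + 1 < n_res:
            n_next = place_atom(n, ca, c, 1.329, 116.6, HELIX_PSI)
            ca_next = place_atom(ca, c, n_next, 1.458, 121.7, OMEGA)
            c_next = place_atom(c, n_next, ca_next, 1.525, 111.0, HELIX_PHI)
            n, ca, c = n_next, ca_next, c_next
    return frames


def _mini_protein(params: dict, rng) -> Structure:
    sequence = str(params.get("sequence", "ADKLS")).upper()
    chain = str(params.get("chain_id", "A"))
    start = int(params.get("start_res", 1))
    jitter = float(params.get("jitter", 0.0))
    library = RotamerLibrary.load()
    frames = _helix_backbone(len(sequence))
    atoms: list[Atom] = []
    for i, (one, frame) in enumerate(zip(sequence, frames)):
        if one not in ONE_TO_THREE:
            raise StructureError(f"unknown residue code {one!r}")
        res = ONE_TO_THREE[one]
        seq = start + i
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(0, name, name[0], res, seq, chain, frame[name].copy()))
        chis = library.for_residue(res)[0]
        for name, p in build_sidechain(res, frame, chis):
            atoms.append(Atom(0, name, name[0] if not name.startswith("S") else "S",
                              res, seq, chain, p))
    if jitter > 0:
        for a in atoms:
            a.position = a.position + rng.normal(0.0, jitter, 3)
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms, title="mini_protein")


def _residue_stub(res_name: str, chis: tuple[float, ...]) -> dict[str, np.ndarray]:
    """One residue (backbone + side chain) in a local frame."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    c = place_atom(dummy, n, ca, 1.525, 111.0, -60.0)
    o = place_atom(n, ca, c, 1.231, 120.5, 130.0)
    frame = {"N": n, "CA": ca, "C": c, "O": o}
    for name, p in build_sidechain(res_name, frame, chis):
        frame[name] = p
    return frame


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    cosab = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if cosab > 0:
            return np.eye(3)
        # 180 degree flip about any perpendicular axis
        p = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-8:
            p = np.cross(a, [0.0, 1.0, 0.0])
        p /= np.linalg.norm(p)
        return 2.0 * np.outer(p, p) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + cosab)


def _toy_copper_site(params: dict, rng):
    """Cu(II/I) site: two His (via NE2), one Cys thiolate, axial Met."""
    chain = str(params.get("chain_id", "A"))
    ligands = [
        # res_name, res_seq, coordinating atom, direction from Cu, distance A
        ("HIS", 46, "NE2", np.array([1.0, 0.0, 0.15]), 2.00),
        ("CYS", 112, "SG", np.array([-0.5, 0.866, 0.15]), 2.25),
        ("HIS", 117, "NE2", np.array([-0.5, -0.866, 0.15]), 2.00),
        ("MET", 121, "SD", np.array([0.0, 0.0, -1.0]), 3.20),
    ]
    library = RotamerLibrary.load()
    atoms: list[Atom] = [
        Atom(0, "CU", "CU", "CU", 200, chain, np.zeros(3))
    ]
    for res, seq, coord_name, direction, dist in ligands:
        chis = library.for_residue(res)[0]
        stub = _residue_stub(res, chis)
        coord = stub[coord_name]
        ca = stub["CA"]
        u = direction / np.linalg.norm(direction)
        rot = _rotation_between(ca - coord, u)
        target = dist * u
        for name, p in stub.items():
            newp = target + rot @ (p - coord)
            el = "S" if name.startswith("S") else ("N" if name.startswith("N")
                 else ("O" if name.startswith("O") else "C"))
            atoms.append(Atom(0, name, el, res, seq, chain, newp))
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    structure = Structure(atoms, title="toy_copper_site")
    cu_set = CopperSiteChargeSet.load(params.get("charge_set_path"))
    return structure, cu_set


def _multi_chain(params: dict, rng) -> Structure:
    n = int(params.get("n", 2))
    base_kind = str(params.get("base", "mini_protein"))
    base_params = dict(params.get("base_params", {}))
    offset = np.asarray(params.get("offset", (25.0, 0.0, 0.0)), float)
    if n < 1 or n > 26:
        raise StructureError("multi_chain needs 1 <= n <= 26 chains")
    base = make_fixture(base_kind, base_params, seed=int(params.get("seed", 0)))
    if isinstance(base, tuple):
        base = base[0]
    atoms: list[Atom] = []
    for i in range(n):
        cid = string.ascii_uppercase[i]
        for a in base.atoms:
            na = a.copy()
            na.chain_id = cid
            na.position = a.position + i * offset
            atoms.append(na)
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms, title=f"multi_chain_{n}")
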