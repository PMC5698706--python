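"""Ideal-geometry side-chain templates.

Each heavy side-chain atom is described by internal coordinates relative to
three previously placed atoms: ``(name, (a, b, c), bond, angle, torsion)``.
The torsion is either a fixed value in degrees or ``("chi", k, offset)``
meaning rotamer angle chi_k plus a fixed branch offset.  The beta carbon is
placed off the backbone with the standard L-amino-acid improper torsion.

Tryptophan carries no template here: its fused ring is never a mutation
target in the copper-site workflows and requests for it raise a clear error.
"""

from __future__ import annotations

Chi = tuple[str, int, float]
Entry = tuple[str, tuple[str, str, str], float, float, "float | Chi"]

#: CB off the backbone: torsion N-C-CA-CB fixed by L chirality.
CB_ENTRY: Entry = ("CB", ("N", "C", "CA"), 1.532, 110.5, 122.5)

SIDECHAIN_TEMPLATES: dict[str, list[Entry]] = {
    "GLY": [],
    "ALA": [CB_ENTRY],
    "SER": [CB_ENTRY, ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [CB_ENTRY, ("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        CB_ENTRY,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        CB_ENTRY,
        ("CG1", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, 122.0)),
    ],
    "LEU": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.0)),
    ],
    "ILE": [
        CB_ENTRY,
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "ASP": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "MET": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "LYS": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.5, ("chi", 4, 0.0)),
    ],
    "ARG": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.461, 111.8, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "HIS": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.356, 131.2, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
        ("NE2", ("CG", "ND1", "CE1"), 1.321, 108.4, 0.0),
    ],
    "PHE": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.391, 120.3, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.391, 120.3, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
    ],
    "TYR": [
        CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.391, 120.3, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.391, 120.3, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 120.0, 180.0),
    ],
    # proline ring is built with fixed torsions (no rotamer search)
    "PRO": [
        ("CB", ("N", "C", "CA"), 1.530, 103.2, 115.0),
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, -35.0),
    ],
}

#: number of rotamer torsions per residue type
N_CHI: dict[str, int] = {
    "GLY": 0, "ALA": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "ASP": 2, "ASN": 2, "HIS": 2, "PHE": 2, "TYR": 2,
    "GLU": 3, "GLN": 3, "MET": 3,
    "LYS": 4, "ARG": 4,
}
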