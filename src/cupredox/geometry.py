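"""Internal-coordinate geometry: torsion placement and ideal-geometry helpers."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom *d* bonded to *c* using NeRF internal coordinates.

    ``bond`` is |c-d|, ``angle_deg`` the b-c-d angle and ``torsion_deg`` the
    a-b-c-d torsion about the b-c axis.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms for torsion placement")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = np.asarray(p0, float) - np.asarray(p1, float)
    v = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def bisector_h(center, n1, n2, bond: float = 1.0) -> np.ndarray:
    """H position on *center*, anti to the bisector of center->n1 / center->n2."""
    center = np.asarray(center, float)
    u1 = np.asarray(n1, float) - center
    u2 = np.asarray(n2, float) - center
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    nd = np.linalg.norm(d)
    if nd < 1e-8:
        # opposite neighbours: any perpendicular direction
        d = np.cross(u1, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(d) < 1e-8:
            d = np.cross(u1, np.array([0.0, 1.0, 0.0]))
        nd = np.linalg.norm(d)
    return center + bond * d / nd
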