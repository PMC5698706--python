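"""Cubic lattice, dielectric/screening/charge maps and B-spline discretization.

The dielectric map assigns the interior constant to grid nodes inside the
molecular (solvent-excluded) surface traced by a spherical probe and the
solvent constant outside, with 9-point harmonic smoothing across the
boundary.  Mobile-ion screening is zeroed inside the solute plus a Stern
ion-exclusion layer.  Point charges are spread onto the lattice with cubic
B-spline weights (exact partition of unity), and potentials are read back
with the same stencil.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import constants as K
from .forcefield import ParameterizedStructure


class GridError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Cubic grid: ``n_points`` nodes per edge spanning ``length`` angstrom."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    length: float = 57.8
    spacing: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        n = round(self.length / self.spacing) + 1
        if n < 33:
            raise GridError(f"grid too coarse: {n} points per edge (need >= 33)")
        object.__setattr__(self, "_n", int(n))
        # store the exact spacing implied by the node count
        object.__setattr__(self, "spacing", self.length / (n - 1))

    @property
    def n_points(self) -> int:
        return self._n

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self._n,) * 3

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center, float) - self.length / 2.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        ax = tuple(o[i] + self.spacing * np.arange(self._n) for i in range(3))
        return ax  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return self.spacing**3


@dataclasses.dataclass
class ScalarField:
    """Values on the grid nodes; ``kind`` records the physical meaning."""

    grid: GridSpec
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def write_dx(self, path: str | Path) -> None:
        """Export in OpenDX scalar format (APBS-compatible)."""
        g = self.grid
        o = g.origin
        h = g.spacing
        n = g.n_points
        lines = [
            f"object 1 class gridpositions counts {n} {n} {n}",
            f"origin {o[0]:.6e} {o[1]:.6e} {o[2]:.6e}",
            f"delta {h:.6e} 0.0 0.0",
            f"delta 0.0 {h:.6e} 0.0",
            f"delta 0.0 0.0 {h:.6e}",
            f"object 2 class gridconnections counts {n} {n} {n}",
            f"object 3 class array type double rank 0 items {n**3} data follows",
        ]
        flat = self.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
        lines.append('attribute "dep" string "positions"')
        lines.append('object "regular positions regular connections" class field')
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# solute masks
# ---------------------------------------------------------------------------

def _ball_mask(grid: GridSpec, positions: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Union of spheres rendered on the lattice (True inside any sphere)."""
    n = grid.n_points
    h = grid.spacing
    o = grid.origin
    mask = np.zeros(grid.shape, dtype=bool)
    for p, r in zip(positions, radii):
        if r <= 0:
            continue
        lo = np.maximum(np.floor((p - r - o) / h).astype(int), 0)
        hi = np.minimum(np.ceil((p + r - o) / h).astype(int) + 1, n)
        if np.any(lo >= hi):
            raise GridError("structure extends beyond the grid")
        ax = [o[d] + h * np.arange(lo[d], hi[d]) - p[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= r * r
    return mask


def _check_inside(grid: GridSpec, positions: np.ndarray, margin: float) -> None:
    o = grid.origin
    top = o + grid.length
    if positions.size and (
        np.any(positions - margin < o) or np.any(positions + margin > top)
    ):
        raise GridError("structure (plus margin) extends beyond the grid")


def solvent_excluded_mask(pstructure: ParameterizedStructure, grid: GridSpec,
                          probe: float = K.DEFAULT_PROBE_RADIUS) -> np.ndarray:
    """Molecular-surface interior on the lattice.

    Two-pass probe construction: nodes within ``r_i + probe`` of any atom are
    probe-excluded; of those, nodes farther than ``probe`` from the nearest
    probe-accessible node are inside the solvent-excluded surface (this keeps
    re-entrant regions between atoms interior, unlike an accessible-surface
    test).
    """
    pos = pstructure.positions()
    rad = pstructure.radii()
    if pos.size == 0:
        return np.zeros(grid.shape, dtype=bool)
    if np.any(rad < 0) or np.any(~np.isfinite(rad)):
        raise GridError("all atoms need finite non-negative radii")
    _check_inside(grid, pos, margin=float(np.max(rad)) + probe)
    inflated = _ball_mask(grid, pos, rad + probe)
    if not inflated.any():
        return inflated
    h = grid.spacing
    # distance from each probe-excluded node to the nearest accessible node
    dist = ndimage.distance_transform_edt(inflated, sampling=h)
    inside = inflated & (dist > probe)
    # van der Waals cores are always interior
    inside |= _ball_mask(grid, pos, rad)
    return inside


# ---------------------------------------------------------------------------
# field builders
# ---------------------------------------------------------------------------

def _harmonic9(eps: np.ndarray) -> np.ndarray:
    """9-point harmonic smoothing: harmonic mean over the node (weight 3)
    and its six face neighbours (weight 1 each), borders replicated."""
    inv = 1.0 / np.pad(eps, 1, mode="edge")
    core = inv[1:-1, 1:-1, 1:-1]
    acc = 3.0 * core
    acc = acc + inv[2:, 1:-1, 1:-1] + inv[:-2, 1:-1, 1:-1]
    acc = acc + inv[1:-1, 2:, 1:-1] + inv[1:-1, :-2, 1:-1]
    acc = acc + inv[1:-1, 1:-1, 2:] + inv[1:-1, 1:-1, :-2]
    return 9.0 / acc


def build_dielectric_map(
    pstructure: ParameterizedStructure,
    grid: GridSpec,
    eps_in: float = K.DEFAULT_EPS_IN,
    eps_out: float = K.DEFAULT_EPS_OUT,
    probe: float = K.DEFAULT_PROBE_RADIUS,
    smoothing: str = "harmonic9",
) -> ScalarField:
    """Dielectric constant per node: ``eps_in`` inside the molecular surface,
    ``eps_out`` outside, smoothed across the boundary."""
    inside = solvent_excluded_mask(pstructure, grid, probe)
    eps = np.where(inside, float(eps_in), float(eps_out))
    if smoothing == "harmonic9":
        eps = _harmonic9(eps)
    elif smoothing == "arithmetic9":
        pad = np.pad(eps, 1, mode="edge")
        acc = 3.0 * pad[1:-1, 1:-1, 1:-1]
        acc += pad[2:, 1:-1, 1:-1] + pad[:-2, 1:-1, 1:-1]
        acc += pad[1:-1, 2:, 1:-1] + pad[1:-1, :-2, 1:-1]
        acc += pad[1:-1, 1:-1, 2:] + pad[1:-1, 1:-1, :-2]
        eps = acc / 9.0
    elif smoothing != "none":
        raise GridError(f"unknown smoothing scheme {smoothing!r}")
    return ScalarField(grid, eps, kind="dielectric")


def build_screening_map(
    pstructure: ParameterizedStructure,
    grid: GridSpec,
    ionic_strength: float = K.DEFAULT_IONIC_STRENGTH,
    temperature: float = K.DEFAULT_TEMPERATURE,
    eps_out: float = K.DEFAULT_EPS_OUT,
    stern: float = K.DEFAULT_STERN_LAYER,
) -> ScalarField:
    """Modified screening coefficient kappa-bar^2 (A^-2) per node.

    ``kappa_bar^2 = eps_out / lambda_D^2`` at ion-accessible nodes (so the
    screened Coulomb potential solves the LPBE in bulk solvent) and zero
    inside the solute plus the Stern layer.
    """
    if ionic_strength == 0:
        return ScalarField(grid, np.zeros(grid.shape), kind="screening")
    lam = K.debye_length(ionic_strength, eps_out, temperature)
    kbar2 = eps_out / lam**2
    values = np.full(grid.shape, kbar2)
    pos = pstructure.positions()
    if pos.size:
        rad = pstructure.radii()
        excluded = _ball_mask(grid, pos, rad + stern)
        values[excluded] = 0.0
    return ScalarField(grid, values, kind="screening")


# ---------------------------------------------------------------------------
# cubic B-spline charge spreading / interpolation
# ---------------------------------------------------------------------------

def _bspline_weights(t: float) -> np.ndarray:
    """Cubic B-spline weights for the four nodes floor-1 .. floor+2."""
    return np.array(
        [
            (1.0 - t) ** 3 / 6.0,
            (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0,
            (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0,
            t**3 / 6.0,
        ]
    )


def _stencil(grid: GridSpec, position: np.ndarray):
    g = (np.asarray(position, float) - grid.origin) / grid.spacing
    base = np.floor(g).astype(int)
    frac = g - base
    idx = []
    wts = []
    for d in range(3):
        i0 = base[d] - 1
        if i0 < 0 or i0 + 3 >= grid.n_points:
            raise GridError(
                "atom closer than two grid spacings to the boundary; enlarge the grid"
            )
        idx.append(np.arange(i0, i0 + 4))
        wts.append(_bspline_weights(float(frac[d])))
    return idx, wts


def spread_charges(pstructure: ParameterizedStructure, grid: GridSpec) -> ScalarField:
    """Charge density (e/A^3) from cubic B-spline discretization of the atoms."""
    rho = np.zeros(grid.shape)
    inv_vol = 1.0 / grid.voxel_volume()
    for a in pstructure.atoms:
        if a.charge == 0.0:
            continue
        idx, wts = _stencil(grid, a.position)
        w = np.einsum("i,j,k->ijk", wts[0], wts[1], wts[2])
        rho[np.ix_(idx[0], idx[1], idx[2])] += a.charge * w * inv_vol
    return ScalarField(grid, rho, kind="charge_density")


def interpolate(field: ScalarField, positions: np.ndarray) -> np.ndarray:
    """Field values at arbitrary points via the same cubic B-spline stencil."""
    out = np.empty(len(positions))
    for i, p in enumerate(np.atleast_2d(positions)):
        idx, wts = _stencil(field.grid, p)
        w = np.einsum("i,j,k->ijk", wts[0], wts[1], wts[2])
        out[i] = float(np.sum(field.values[np.ix_(idx[0], idx[1], idx[2])] * w))
    return out
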