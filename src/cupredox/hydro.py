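"""Empirical axial-ligand hydrophobicity correction.

Continuum electrostatics (and tabulated quantum-chemical values) miss the
desolvation effect of replacing the axial methionine of the copper site with
a hydrophobic residue.  The correction is linear in the Kyte-Doolittle
hydropathy change of the axial residue relative to methionine:

    dE_hydro = a * dKD + b            (mV)

with (a, b) calibrated by ordinary least squares against experimental shifts
of the hydrophobic axial series M121X, X in {G, A, L, V, I}.  For a mutant
that combines an axial substitution A with other points M, the predicted
shift is

    ddE(M/A) = ddE_comp(M/A) - ddE_comp(A) + dE_hydro(A)

i.e. the computed axial contribution is replaced by the empirical one; for a
single axial mutant the two computed terms coincide and the prediction
reduces to dE_hydro.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

_DATA = resources.files("cupredox") / "data"

#: published calibration constants (mV/KD and mV)
DEFAULT_SLOPE = 25.8
DEFAULT_INTERCEPT = 64.7


class KDTable:
    """Kyte-Doolittle hydropathy index per one-letter residue code."""

    REFERENCE = "M"  # wildtype axial ligand

    def __init__(self, values: dict[str, float]):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(values)
        if missing:
            raise ValueError(f"KD table misses residues: {sorted(missing)}")
        self.values = dict(values)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "KDTable":
        if path is None:
            path = _DATA / "kyte_doolittle.tsv"
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls({str(r.residue): float(r.kd) for r in frame.itertuples(index=False)})

    def __getitem__(self, code: str) -> float:
        try:
            return self.values[code.upper()]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None


@dataclasses.dataclass
class HydroFit:
    """Slope/intercept of the hydrophobicity correction with provenance."""

    a: float                     # mV per KD unit
    b: float                     # mV
    n_points: int = 0
    rms_residual: float = float("nan")
    provenance: str = "unspecified"

    @classmethod
    def published(cls) -> "HydroFit":
        """The printed calibration constants (a=25.8 mV/KD, b=64.7 mV)."""
        return cls(DEFAULT_SLOPE, DEFAULT_INTERCEPT, provenance="published-calibration")


@dataclasses.dataclass
class CalibrationPoint:
    mutant: str
    delta_kd: float
    ddE_exp: float               # mV
    exp_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.exp_range is not None:
            low, high = self.exp_range
            if not (low <= self.ddE_exp <= high):
                raise ValueError(
                    f"{self.mutant}: value {self.ddE_exp} outside range {self.exp_range}"
                )


def delta_kd(new_res: str, ref_res: str = KDTable.REFERENCE,
             table: KDTable | None = None) -> float:
    """Hydropathy change of the axial residue: KD(new) - KD(reference Met)."""
    table = table or KDTable.load()
    return table[new_res] - table[ref_res]


def hydro_correction(dkd: float, fit: HydroFit | None = None) -> float:
    """dE_hydro = a*dKD + b in mV."""
    fit = fit or HydroFit.published()
    return fit.a * dkd + fit.b


def fit_hydro(points: list[CalibrationPoint],
              use: str = "midpoint") -> HydroFit:
    """Unweighted OLS line through the calibration points.

    ``use`` selects which experimental value enters the fit when a range is
    present: ``midpoint`` (default; the stored value), ``low`` or ``high``.
    """
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    x = np.array([p.delta_kd for p in points])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all delta-KD values identical")

    def y_of(p: CalibrationPoint) -> float:
        if p.exp_range is None or use == "midpoint":
            return p.ddE_exp
        return p.exp_range[0] if use == "low" else p.exp_range[1]

    y = np.array([y_of(p) for p in points])
    design = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (a * x + b)
    return HydroFit(float(a), float(b), len(points),
                    float(np.sqrt(np.mean(resid**2))), provenance=f"ols-{use}")


def load_calibration(path: str | Path | None = None) -> list[CalibrationPoint]:
    """Bundled axial-series calibration set (see data file header for how the
    unpublished members were reconstructed)."""
    if path is None:
        path = _DATA / "hydro_calibration.tsv"
    frame = pd.read_csv(path, sep="\t", comment="#")
    points = []
    for r in frame.itertuples(index=False):
        rng = None
        if not (pd.isna(r.low_mV) or pd.isna(r.high_mV)):
            rng = (float(r.low_mV), float(r.high_mV))
        points.append(CalibrationPoint(str(r.mutant), float(r.delta_kd),
                                       float(r.ddE_mV), rng))
    return points


def combine_axial(ddE_ma_comp: float, ddE_a_comp: float, de_hydro: float) -> float:
    """Predicted shift for a mutant containing an axial substitution."""
    return ddE_ma_comp - ddE_a_comp + de_hydro
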