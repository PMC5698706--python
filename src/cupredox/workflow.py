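"""Method-selection workflow for mutant reduction-potential prediction.

Each point mutation is classified by how it perturbs the copper site:

``SECONDARY_SPHERE``
    long-range electrostatic perturbation; continuum electrostatics (CE).
``HBOND_PERTURBING``
    creates/deletes a hydrogen bond to a copper ligand (curated positions
    47/114); covalent redistribution that CE cannot capture, so the bundled
    quantum-chemical (DFT) table value is used.
``HYDROPHOBIC_AXIAL``
    axial Met121 replaced by G/A/V/L/I; desolvation-dominated, handled by
    the empirical hydrophobicity correction.
``NONHYDROPHOBIC_AXIAL``
    axial Met121 replaced by a polar residue; CE reproduces these well.

Multi-point mutants are combined by resolving the DFT-covered subset from
the table first and treating the remaining points as one joint CE mutant
(with the axial correction applied when the remainder contains a
hydrophobic axial point); the prediction is the sum of its components.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Callable, Mapping
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .hydro import HydroFit, KDTable, combine_axial, delta_kd, hydro_correction
from .structure import MutationSpec, PointMutation, StructureError, THREE_TO_ONE

_DATA = resources.files("cupredox") / "data"


class MutantClass(enum.Enum):
    SECONDARY_SPHERE = "secondary_sphere"
    HBOND_PERTURBING = "hbond_perturbing"
    HYDROPHOBIC_AXIAL = "hydrophobic_axial"
    NONHYDROPHOBIC_AXIAL = "nonhydrophobic_axial"


@dataclasses.dataclass(frozen=True)
class ClassificationRules:
    """Curated routing table (geometric H-bond detection is a non-goal)."""

    first_sphere: tuple[int, ...] = (46, 112, 117)
    axial_position: int = 121
    hydrophobic_axial: tuple[str, ...] = ("GLY", "ALA", "VAL", "LEU", "ILE")
    #: (position, new residue) pairs that create/delete an H-bond to a ligand:
    #: any Pro at 47/114 deletes the backbone NH to Cys112 S-gamma; Asn at 114
    #: introduces new side-chain H-bond partners near Gly45/His117.
    hbond_rules: tuple[tuple[int, str], ...] = (
        (47, "PRO"),
        (114, "PRO"),
        (114, "ASN"),
    )


def classify_point(point: PointMutation,
                   rules: ClassificationRules | None = None) -> MutantClass:
    rules = rules or ClassificationRules()
    if point.res_seq in rules.first_sphere:
        raise StructureError(
            f"mutation at first-sphere copper ligand {point.res_seq} is unsupported"
        )
    if point.res_seq == rules.axial_position:
        if point.new_res in rules.hydrophobic_axial:
            return MutantClass.HYDROPHOBIC_AXIAL
        return MutantClass.NONHYDROPHOBIC_AXIAL
    if (point.res_seq, point.new_res) in rules.hbond_rules:
        return MutantClass.HBOND_PERTURBING
    return MutantClass.SECONDARY_SPHERE


def classify(spec: MutationSpec | str,
             rules: ClassificationRules | None = None
             ) -> dict[PointMutation, MutantClass]:
    """Class per point mutation; every point receives exactly one class."""
    if isinstance(spec, str):
        spec = MutationSpec.parse(spec)
    return {p: classify_point(p, rules) for p in spec.points}


# ---------------------------------------------------------------------------
# bundled DFT value table
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DFTEntry:
    label: str
    ddE_mV: float
    source: str
    exp_range: tuple[float, float] | None
    note: str = ""


class DFTValueTable:
    """Tabulated quantum-chemical shifts (mV, water-like dielectric).

    Entries are looked up by the set of point-mutation labels so that
    ``M121Q/F114N`` and ``F114N/M121Q`` are the same model.
    """

    def __init__(self, entries: list[DFTEntry]):
        self.entries = {frozenset(e.label.split("/")): e for e in entries}

    @classmethod
    def load(cls, path: str | Path | None = None) -> "DFTValueTable":
        if path is None:
            path = _DATA / "dft_table.tsv"
        frame = pd.read_csv(path, sep="\t", comment="#")
        entries = []
        for r in frame.itertuples(index=False):
            rng = None
            if not (pd.isna(r.exp_low_mV) or pd.isna(r.exp_high_mV)):
                rng = (float(r.exp_low_mV), float(r.exp_high_mV))
            entries.append(DFTEntry(str(r.label), float(r.ddE_mV), str(r.source),
                                    rng, "" if pd.isna(r.note) else str(r.note)))
        return cls(entries)

    def get(self, labels: frozenset[str]) -> DFTEntry | None:
        return self.entries.get(labels)

    def covering(self, spec_labels: frozenset[str],
                 required: frozenset[str]) -> DFTEntry | None:
        """Largest entry whose points are within the spec and cover all
        required points; ties broken by label."""
        best = None
        for key, entry in self.entries.items():
            if key <= spec_labels and required <= key:
                if best is None or (len(key), entry.label) > (
                        len(frozenset(best.label.split("/"))), best.label):
                    best = entry
        return best


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Component:
    sub_mutant: str
    method: str                  # CE | DFT_TABLE | HYDRO
    value_mV: float


@dataclasses.dataclass
class Prediction:
    mutant: str
    ddE_mV: float
    components: list[Component]
    notes: str = ""

    def __post_init__(self) -> None:
        total = sum(c.value_mV for c in self.components)
        assert abs(total - self.ddE_mV) < 1e-9, "prediction != sum of components"


def predict(
    spec: MutationSpec | str,
    ce_engine: Callable[[str], float] | None = None,
    dft_table: DFTValueTable | None = None,
    hydro_fit: HydroFit | None = None,
    kd_table: KDTable | None = None,
    rules: ClassificationRules | None = None,
) -> Prediction:
    """Route a mutant through the decision flow and combine components."""
    if isinstance(spec, str):
        spec = MutationSpec.parse(spec)
    rules = rules or ClassificationRules()
    hydro_fit = hydro_fit or HydroFit.published()
    classes = classify(spec, rules)

    hbond = [p for p, c in classes.items() if c is MutantClass.HBOND_PERTURBING]
    components: list[Component] = []
    notes: list[str] = []
    remaining = list(spec.points)

    if hbond:
        if dft_table is None:
            dft_table = DFTValueTable.load()
        required = frozenset(p.label for p in hbond)
        entry = dft_table.covering(frozenset(p.label for p in spec.points), required)
        if entry is None:
            raise StructureError(
                "no tabulated quantum-chemical value covers the hydrogen-bond-"
                f"perturbing point(s) {'/'.join(sorted(required))}; a DFT model "
                "of that sub-mutant is needed"
            )
        covered = frozenset(entry.label.split("/"))
        components.append(Component(entry.label, "DFT_TABLE", entry.ddE_mV))
        remaining = [p for p in remaining if p.label not in covered]

    axial = [p for p in remaining
             if classes[p] is MutantClass.HYDROPHOBIC_AXIAL]
    if axial:
        if len(axial) > 1:
            raise StructureError("more than one axial point mutation")
        a = axial[0]
        dkd = delta_kd(THREE_TO_ONE[a.new_res], table=kd_table)
        de_hydro = hydro_correction(dkd, hydro_fit)
        others = [p for p in remaining if p is not a]
        if others:
            joint = MutationSpec(tuple(remaining))
            if ce_engine is None:
                raise StructureError("continuum-electrostatics engine required")
            dd_ma = float(ce_engine(joint.label))
            dd_a = float(ce_engine(a.label))
            components.append(Component(joint.label, "CE", dd_ma))
            components.append(Component(a.label, "CE", -dd_a))
            components.append(Component(a.label, "HYDRO", de_hydro))
            assert abs(combine_axial(dd_ma, dd_a, de_hydro)
                       - sum(c.value_mV for c in components[-3:])) < 1e-9
        else:
            # single axial mutant: the two computed terms of the combination
            # rule cancel identically, leaving the empirical correction
            components.append(Component(a.label, "HYDRO", de_hydro))
            notes.append("axial-only: computed terms cancel")
    elif remaining:
        joint = MutationSpec(tuple(remaining))
        if ce_engine is None:
            raise StructureError("continuum-electrostatics engine required")
        components.append(Component(joint.label, "CE", float(ce_engine(joint.label))))

    total = float(sum(c.value_mV for c in components))
    return Prediction(spec.label, total, components, "; ".join(notes))


# ---------------------------------------------------------------------------
# evaluation against experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationRow:
    mutant: str
    predicted_mV: float
    experimental: float | tuple[float, float]
    deviation_mV: float


@dataclasses.dataclass
class EvaluationReport:
    rows: list[EvaluationRow]
    mad_mV: float
    n_within_window: int
    window_mV: float
    outliers: list[EvaluationRow]


def _deviation(predicted: float,
               experimental: float | tuple[float, float]) -> float:
    """Distance to the experimental value, 0 anywhere inside a range."""
    if isinstance(experimental, tuple):
        low, high = experimental
        if low > high:
            low, high = high, low
        if low <= predicted <= high:
            return 0.0
        return predicted - high if predicted > high else predicted - low
    return predicted - experimental


def evaluate(
    predictions: list[Prediction] | Mapping[str, float],
    experimental: Mapping[str, float | tuple[float, float]],
    window: float = 25.0,
) -> EvaluationReport:
    """Range-aware comparison: MAD and the count within the +/-window band."""
    if isinstance(predictions, Mapping):
        pred_map = dict(predictions)
    else:
        pred_map = {p.mutant: p.ddE_mV for p in predictions}
    labels = [m for m in pred_map if m in experimental]
    if not labels:
        raise ValueError("no overlap between predicted and experimental mutants")
    rows = []
    for label in labels:
        dev = _deviation(pred_map[label], experimental[label])
        rows.append(EvaluationRow(label, pred_map[label], experimental[label], dev))
    devs = np.array([abs(r.deviation_mV) for r in rows])
    outliers = sorted((r for r in rows if abs(r.deviation_mV) > window),
                      key=lambda r: -abs(r.deviation_mV))
    return EvaluationReport(
        rows=rows,
        mad_mV=float(np.mean(devs)),
        n_within_window=int(np.sum(devs <= window)),
        window_mV=window,
        outliers=outliers,
    )
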