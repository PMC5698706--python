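"""Decision-flow routing, DFT table lookups, range-aware evaluation."""

from __future__ import annotations

import pytest

from cupredox.hydro import hydro_correction
from cupredox.structure import StructureError
from cupredox.workflow import (
    Component,
    DFTEntry,
    DFTValueTable,
    MutantClass,
    Prediction,
    classify,
    evaluate,
    predict,
)


class TestClassify:
    @pytest.mark.parametrize("label,expected", [
        ("M121L", MutantClass.HYDROPHOBIC_AXIAL),
        ("M121G", MutantClass.HYDROPHOBIC_AXIAL),
        ("M121Q", MutantClass.NONHYDROPHOBIC_AXIAL),
        ("M121K", MutantClass.NONHYDROPHOBIC_AXIAL),
        ("F114P", MutantClass.HBOND_PERTURBING),
        ("N47P", MutantClass.HBOND_PERTURBING),
        ("F114N", MutantClass.HBOND_PERTURBING),
        ("N47S", MutantClass.SECONDARY_SPHERE),
        ("D11K", MutantClass.SECONDARY_SPHERE),
        ("F114S", MutantClass.SECONDARY_SPHERE),
    ])
    def test_single_point_routing(self, label, expected):
        (cls,) = classify(label).values()
        assert cls is expected

    def test_first_sphere_always_errors(self):
        for label in ("H46A", "C112S", "H117F"):
            with pytest.raises(StructureError, match="first-sphere"):
                classify(label)

    def test_every_point_classified_in_multipoint(self):
        classes = classify("M121L/N47S")
        assert len(classes) == 2
        assert set(classes.values()) == {
            MutantClass.HYDROPHOBIC_AXIAL, MutantClass.SECONDARY_SPHERE}


class TestDFTTable:
    def test_bundled_entries_match_printed_values(self):
        table = DFTValueTable.load()
        expected = {"F114N": 170.0, "N47S": 65.0, "N47P": -81.0, "F114P": -80.0,
                    "M121V": 89.0, "M121L": 129.0, "M121G": 88.0, "M121N": 88.0,
                    "M121Q": -124.0}
        for label, value in expected.items():
            entry = table.get(frozenset([label]))
            assert entry is not None and entry.ddE_mV == value

    def test_ambiguous_experimental_range_excluded(self):
        entry = DFTValueTable.load().get(frozenset(["M121Q"]))
        assert entry.exp_range is None
        assert "ambiguous" in entry.note


class TestPredict:
    def test_secondary_sphere_routes_to_ce(self):
        pred = predict("D11K", ce_engine=lambda m: 96.0)
        assert pred.ddE_mV == 96.0
        assert [c.method for c in pred.components] == ["CE"]

    def test_single_axial_equals_hydro_correction(self):
        called = []
        pred = predict("M121L", ce_engine=lambda m: called.append(m) or 0.0)
        assert not called  # the two computed terms cancel identically
        assert pred.ddE_mV == pytest.approx(hydro_correction(3.8 - 1.9))
        assert [c.method for c in pred.components] == ["HYDRO"]

    def test_nonhydrophobic_axial_routes_to_ce(self):
        pred = predict("M121Q", ce_engine=lambda m: -50.0)
        assert [c.method for c in pred.components] == ["CE"]

    def test_hbond_point_uses_dft_table(self):
        pred = predict("F114P", ce_engine=None)
        assert [c.method for c in pred.components] == ["DFT_TABLE"]
        assert pred.ddE_mV == -80.0

    def test_triple_mutant_worked_example(self):
        """The DFT-covered pair resolves from the table, the remaining
        secondary-sphere point is one CE mutant; prediction is their sum."""
        table = DFTValueTable([
            DFTEntry("M121Q/F114N", -36.0, "synthetic-test", None),
            DFTEntry("F114N", 170.0, "T1", None),
        ])
        calls = []

        def engine(label):
            calls.append(label)
            return 65.0

        pred = predict("M121Q/F114N/N47S", engine, table)
        assert calls == ["N47S"]
        methods = {(c.sub_mutant, c.method) for c in pred.components}
        assert methods == {("M121Q/F114N", "DFT_TABLE"), ("N47S", "CE")}
        assert pred.ddE_mV == pytest.approx(-36.0 + 65.0)

    def test_missing_dft_entry_names_needed_model(self):
        table = DFTValueTable([])
        with pytest.raises(StructureError, match="F114P"):
            predict("F114P", dft_table=table)

    def test_axial_plus_secondary_combination(self):
        values = {"M121L/N47S": 80.0, "M121L": -15.0}
        pred = predict("M121L/N47S", ce_engine=lambda m: values[m])
        expect = 80.0 - (-15.0) + hydro_correction(1.9)
        assert pred.ddE_mV == pytest.approx(expect)
        assert [c.method for c in pred.components] == ["CE", "CE", "HYDRO"]

    def test_prediction_sum_invariant(self):
        with pytest.raises(AssertionError):
            Prediction("X", 1.0, [Component("X", "CE", 2.0)])


class TestEvaluate:
    def test_perfect_predictions(self):
        report = evaluate({"A": 10.0, "B": -5.0}, {"A": 10.0, "B": -5.0})
        assert report.mad_mV == 0.0
        assert report.n_within_window == 2
        assert report.outliers == []

    def test_single_outlier(self):
        report = evaluate({"A": 40.0}, {"A": 10.0})
        assert report.mad_mV == 30.0
        assert report.n_within_window == 0
        assert report.outliers[0].mutant == "A"

    def test_inside_range_is_zero_deviation(self):
        report = evaluate({"A": 100.0}, {"A": (86.0, 115.0)})
        assert report.rows[0].deviation_mV == 0.0

    def test_outside_range_distance_to_nearest_endpoint(self):
        report = evaluate({"A": 120.0, "B": 80.0}, {"A": (86.0, 115.0),
                                                    "B": (86.0, 115.0)})
        devs = {r.mutant: r.deviation_mV for r in report.rows}
        assert devs == {"A": pytest.approx(5.0), "B": pytest.approx(-6.0)}

    def test_permutation_invariance_of_mad(self):
        preds = {"A": 1.0, "B": 2.0, "C": 33.0}
        exps = {"A": 0.0, "B": 0.0, "C": 0.0}
        r1 = evaluate(preds, exps)
        r2 = evaluate(dict(reversed(list(preds.items()))), exps)
        assert r1.mad_mV == r2.mad_mV

    def test_uniform_shift_bounds_mad_change(self):
        preds = {"A": 10.0, "B": -20.0}
        exps = {"A": 0.0, "B": 0.0}
        base = evaluate(preds, exps).mad_mV
        shifted = evaluate({k: v + 7.0 for k, v in preds.items()}, exps).mad_mV
        assert abs(shifted - base) <= 7.0 + 1e-12

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            evaluate({"A": 1.0}, {"B": 2.0})
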