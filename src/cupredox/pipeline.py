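"""Config-driven pipeline: deterministic file artifacts for each command.

The YAML config schema (version 1):

.. code-block:: yaml

    version: 1
    pdb: path/to/structure.pdb      # or fixture: {kind: ..., params: {...}}
    chains: [A, B, C, D]            # default: all chains
    grid: {length: 57.8, spacing: 0.2}
    solver: {tolerance: 1.e-6, ionic_strength: 0.15}
    threshold_mV: 20.0
    mutants: [M121L, D11A]
    positions: [11, 13]             # screen positions; default: auto-derived
    seed: 1
    output_dir: out/

Identical configs produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .forcefield import parameterize
from .hydro import fit_hydro, load_calibration
from .mutate import build_mutant
from .protonate import assign_protonation
from .redox import CEEngine, candidate_positions, screen
from .solver import SolverOptions
from .structure import Structure, read_pdb, write_pdb, write_pqr
from .workflow import DFTValueTable, evaluate, predict
from .fixtures import make_fixture

_ALLOWED_KEYS = {
    "version", "pdb", "fixture", "chains", "grid", "solver", "threshold_mV",
    "mutants", "positions", "seed", "output_dir", "experimental_csv",
    "calibration_csv",
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("config: top level must be a mapping")
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"config: unknown key(s) {sorted(unknown)}")
    if cfg.get("version", 1) != 1:
        raise ConfigError("config.version: only version 1 is supported")
    if "pdb" not in cfg and "fixture" not in cfg:
        raise ConfigError("config: one of 'pdb' or 'fixture' is required")
    for key, typ in (("grid", dict), ("solver", dict), ("mutants", list),
                     ("positions", list), ("chains", list)):
        if key in cfg and not isinstance(cfg[key], typ):
            raise ConfigError(f"config.{key}: expected {typ.__name__}")
    return cfg


def _load_structure(cfg: dict) -> Structure:
    if "pdb" in cfg:
        return read_pdb(cfg["pdb"])
    fx = cfg["fixture"]
    if not isinstance(fx, dict) or "kind" not in fx:
        raise ConfigError("config.fixture: needs a 'kind'")
    out = make_fixture(fx["kind"], fx.get("params"), int(cfg.get("seed", 0)))
    return out[0] if isinstance(out, tuple) else out


def _engine(cfg: dict, structure: Structure) -> CEEngine:
    grid = cfg.get("grid", {})
    solver = dict(cfg.get("solver", {}))
    return CEEngine(
        structure,
        chains=cfg.get("chains"),
        grid_length=float(grid.get("length", 57.8)),
        grid_spacing=float(grid.get("spacing", 0.2)),
        options=SolverOptions(**solver),
    )


def _outdir(cfg: dict) -> Path:
    out = Path(cfg.get("output_dir", "cupredox_out"))
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_pipeline(config, command: str) -> list[Path]:
    """Execute one pipeline command; returns the paths written."""
    cfg = load_config(config)
    out = _outdir(cfg)
    structure = _load_structure(cfg)
    written: list[Path] = []

    if command == "prepare":
        prot = assign_protonation(structure.without_waters())
        ps = parameterize(prot, oxidation_state=None, cu_set=None)
        path = out / "prepared.pqr"
        write_pqr(ps.structure, path)
        written.append(path)

    elif command == "mutate":
        for label in cfg.get("mutants", []):
            mutant = build_mutant(structure.without_waters(), label)
            path = out / f"mutant_{label.replace('/', '_')}.pdb"
            write_pdb(mutant, path)
            written.append(path)

    elif command == "redox":
        engine = _engine(cfg, structure)
        records = []
        wt = engine.wildtype()
        records.append({"label": wt.label, "mean_mV": wt.mean, "sd_mV": wt.sd,
                        **{f"chain_{c}": v for c, v in wt.per_chain.items()}})
        for label in cfg.get("mutants", []):
            res = engine.mutant(label)
            records.append({"label": res.label, "mean_mV": res.mean,
                            "sd_mV": res.sd,
                            **{f"chain_{c}": v for c, v in res.per_chain.items()}})
        path = out / "redox.csv"
        pd.DataFrame.from_records(records).to_csv(path, index=False,
                                                  float_format="%.3f")
        written.append(path)

    elif command == "screen":
        engine = _engine(cfg, structure)
        positions = cfg.get("positions") or candidate_positions(structure)
        rows = screen(structure, positions, engine,
                      threshold=float(cfg.get("threshold_mV", 20.0)))
        frame = pd.DataFrame(
            [dataclasses.asdict(r) for r in rows]
        ).rename(columns={"ddE_mV": "ddE_mV", "distance_A": "distance_A"})
        frame["positions_used"] = ",".join(map(str, positions))
        path = out / "screen.csv"
        frame.to_csv(path, index=False, float_format="%.3f")
        written.append(path)

    elif command == "calibrate-hydro":
        points = load_calibration(cfg.get("calibration_csv"))
        fit = fit_hydro(points)
        path = out / "hydro_fit.csv"
        pd.DataFrame([{
            "a_mV_per_KD": fit.a, "b_mV": fit.b, "n_points": fit.n_points,
            "rms_residual_mV": fit.rms_residual, "provenance": fit.provenance,
        }]).to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    elif command == "predict":
        engine = _engine(cfg, structure)
        dft = DFTValueTable.load()
        records = []
        for label in cfg.get("mutants", []):
            pred = predict(label, engine, dft)
            records.append({
                "mutant": pred.mutant,
                "ddE_mV": pred.ddE_mV,
                "components": ";".join(
                    f"{c.sub_mutant}:{c.method}:{c.value_mV:.3f}"
                    for c in pred.components),
                "notes": pred.notes,
            })
        path = out / "predictions.csv"
        pd.DataFrame.from_records(records).to_csv(path, index=False,
                                                  float_format="%.3f")
        written.append(path)

    elif command == "evaluate":
        pred_csv = out / "predictions.csv"
        if not pred_csv.exists():
            raise ConfigError("evaluate: run 'predict' first (predictions.csv missing)")
        preds = pd.read_csv(pred_csv)
        exp_path = cfg.get("experimental_csv")
        if exp_path is None:
            raise ConfigError("config.experimental_csv: required for 'evaluate'")
        exp_frame = pd.read_csv(exp_path)
        experimental: dict[str, float | tuple[float, float]] = {}
        for r in exp_frame.itertuples(index=False):
            if hasattr(r, "low_mV") and not pd.isna(r.low_mV):
                experimental[str(r.mutant)] = (float(r.low_mV), float(r.high_mV))
            else:
                experimental[str(r.mutant)] = float(r.ddE_mV)
        report = evaluate(dict(zip(preds.mutant, preds.ddE_mV)), experimental)
        path = out / "evaluation.csv"
        pd.DataFrame([
            {"mutant": r.mutant, "predicted_mV": r.predicted_mV,
             "experimental": str(r.experimental), "deviation_mV": r.deviation_mV}
            for r in report.rows
        ]).to_csv(path, index=False, float_format="%.3f")
        summary = out / "evaluation_summary.txt"
        summary.write_text(
            f"mutants evaluated: {len(report.rows)}\n"
            f"mean absolute deviation: {report.mad_mV:.1f} mV\n"
            f"within +/-{report.window_mV:.0f} mV: {report.n_within_window}"
            f"/{len(report.rows)}\n"
            "outliers: "
            + (", ".join(f"{r.mutant} ({r.deviation_mV:+.0f} mV)"
                         for r in report.outliers) or "none")
            + "\n"
        )
        written.extend([path, summary])

    else:
        raise ConfigError(f"unknown command {command!r}")

    return written
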