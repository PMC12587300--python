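"""Pipeline orchestration: simulate → quantify → exceed → report.

A single YAML (or in-memory) configuration drives the whole audit: column
description, the set of simulated columns (scenario name + per-column
overrides), quantification choices, and exceedance thresholds.  Outputs are
plain CSV files plus a human-readable summary, every file carrying the
configuration hash and the master seed in its comment header so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .column import ColumnSpec, HydraulicsResult, column_hydraulics
from .exceedance import ExceedanceReport, ThresholdSet, exceedance_matrix
from .quantify import (
    MassBalanceReport,
    conservative_inflow,
    flux_mass,
    integrate_dissolved_flux,
    integrate_solid_fe,
    mass_balance,
)
from .simulate import (
    SimulationResult,
    apply_measurement_model,
    make_scenario,
    simulate_column,
)
from .stoichiometry import toluene_equivalent, toluene_mass_concentration
from .tables import config_hash, write_monitoring_csv, write_solid_profile_csv

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "DEFAULT_COLUMNS"]

DEFAULT_COLUMNS = (
    {"scenario": "treatment", "column_id": "T1"},
    {"scenario": "treatment", "column_id": "T2"},
    {"scenario": "control", "column_id": "C1"},
    {"scenario": "control", "column_id": "C2"},
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class QuantifyOptions(BaseModel):
    model_config = {"extra": "forbid"}
    #: solid-profile integration: 'trapezoid' or 'fit_then_integrate'
    method: str = "trapezoid"
    #: censored handling in flux integrals: 'zero' (conservative) or 'half'
    censored_as: str = "zero"
    #: dissolved-flux port selection: 'peak' or a fixed port distance (m)
    flux_mode: str = "peak"
    flux_port: Optional[float] = None
    #: inflow estimate: 'constant' (feed concentration) or 'conservative'
    #: (sterile-control equilibrium effluent over the late window)
    inflow_mode: str = "constant"
    late_window: tuple[float, float] = (33.0, 43.0)


class PipelineConfig(BaseModel):
    model_config = {"extra": "forbid"}

    column: ColumnSpec = Field(default_factory=ColumnSpec)
    #: shared SimulationConfig overrides applied to every column
    scenario: dict = Field(default_factory=dict)
    #: the simulated columns: scenario name, column_id, extra overrides
    columns: tuple[dict, ...] = DEFAULT_COLUMNS
    quantify: QuantifyOptions = Field(default_factory=QuantifyOptions)
    #: analyte → threshold, monitoring units
    thresholds: dict[str, float] = Field(
        default_factory=lambda: {"toluene": 700.0, "fe2_dissolved": 0.3}
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        return config_hash(self.model_dump())


@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: Path
    hydraulics: HydraulicsResult
    runs: dict[str, SimulationResult]
    measured: dict[str, pd.DataFrame]
    balances: dict[str, MassBalanceReport]
    exceedance: ExceedanceReport
    files: list[Path]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapper
    return deco


def _write_kv_csv(path: Path, rows: dict[str, float], header: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("quantity,value\n")
        for key, value in rows.items():
            fh.write(f"{key},{value!r}\n")


def run_pipeline(
    config: Union[PipelineConfig, str, Path],
    out_dir: Union[str, Path] = "fecolumn_out",
    seed: Optional[int] = None,
) -> PipelineResult:
    """Execute the full audit and write the report bundle to ``out_dir``.

    Returns the in-memory results; the written bundle holds hydraulics,
    per-column measured monitoring CSVs and solid profiles, the mass-balance
    table, the classified exceedance table, and a plain-text summary.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [f"config: {config.hash()}", f"seed: {config.seed}"]
    files: list[Path] = []

    hyd = _stage("hydraulics")(column_hydraulics)(config.column)
    path = out_dir / "hydraulics.csv"
    _write_kv_csv(path, hyd.as_dict(), header)
    files.append(path)

    # --- simulate every configured column; child seeds derive from the master
    @_stage("simulate")
    def _simulate() -> tuple[dict, dict]:
        child_seeds = [
            int(s) % (2**31)
            for s in np.random.SeedSequence(config.seed).generate_state(
                len(config.columns)
            )
        ]
        runs, measured = {}, {}
        for spec, child in zip(config.columns, child_seeds):
            spec = dict(spec)
            name = spec.pop("scenario")
            cid = spec.get("column_id", name)
            overrides = {**config.scenario, **spec,
                         "column": config.column, "seed": child}
            sim_config = make_scenario(name, **overrides)
            run = simulate_column(sim_config)
            runs[cid] = run
            measured[cid] = apply_measurement_model(run)
        return runs, measured

    runs, measured = _simulate()

    for cid, table in measured.items():
        path = out_dir / f"monitoring_{cid}.csv"
        write_monitoring_csv(
            table, path,
            metadata={"config": config.hash(), "seed": config.seed, "column": cid},
        )
        files.append(path)
    for cid, run in runs.items():
        path = out_dir / f"solid_fe_{cid}.csv"
        write_solid_profile_csv(
            run.solid_fe_profile, path,
            metadata={"config": config.hash(), "seed": config.seed, "column": cid},
        )
        files.append(path)

    # --- quantification per column
    @_stage("quantify")
    def _quantify() -> dict[str, MassBalanceReport]:
        opts = config.quantify
        q_ml_min = hyd.pumping_rate
        duration = runs[next(iter(runs))].config.duration
        control_ids = [c for c, r in runs.items() if not r.config.biotic]
        balances: dict[str, MassBalanceReport] = {}
        for cid, run in runs.items():
            solid = integrate_solid_fe(run.solid_fe_profile, config.column, opts.method)
            table = measured[cid]
            fe_rows = table[table["analyte"] == "fe2_dissolved"]
            if opts.flux_mode == "peak":
                dissolved_mg, _ = integrate_dissolved_flux(
                    fe_rows, q_ml_min, mode="peak", censored_as=opts.censored_as
                )
            else:
                dissolved_mg, _ = integrate_dissolved_flux(
                    fe_rows, q_ml_min, mode="port", port=opts.flux_port,
                    censored_as=opts.censored_as,
                )
            if opts.inflow_mode == "conservative":
                if not control_ids:
                    raise ValueError("conservative inflow requires a sterile control column")
                ctrl = measured[control_ids[0]]
                far = ctrl[(ctrl["analyte"] == "toluene")]
                far = far[far["distance_m"] == far["distance_m"].max()].copy()
                far["value"] = far["value"] / 1000.0  # µg/L → mg/L
                inflow = conservative_inflow(
                    far.sort_values("day"), q_ml_min, duration, opts.late_window
                )
            else:
                inflow = (
                    toluene_mass_concentration(run.config.influent_toluene)
                    * q_ml_min * 1.44 * duration
                )
            tol_rows = table[table["analyte"] == "toluene"]
            far_tol = tol_rows[tol_rows["distance_m"] == tol_rows["distance_m"].max()].copy()
            far_tol["value"] = far_tol["value"] / 1000.0
            outflow = flux_mass(
                far_tol.sort_values("day"), q_ml_min, censored_as=opts.censored_as
            )
            balances[cid] = mass_balance(
                inflow_mg=inflow,
                outflow_mg=outflow,
                degraded_solid_mg=toluene_equivalent(solid.mass_mg),
                degraded_dissolved_mg=toluene_equivalent(dissolved_mg),
            )
        return balances

    balances = _quantify()

    path = out_dir / "mass_balance.csv"
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        rows = pd.DataFrame(
            [{"column_id": cid, **rep.as_dict()} for cid, rep in balances.items()]
        )
        rows.to_csv(fh, index=False, lineterminator="\n")
    files.append(path)

    # --- exceedance over the pooled measured tables
    @_stage("exceedance")
    def _exceed() -> ExceedanceReport:
        pooled = pd.concat(measured.values(), ignore_index=True)
        return exceedance_matrix(pooled, ThresholdSet(config.thresholds))

    report = _exceed()
    path = out_dir / "exceedance.csv"
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        report.data.to_csv(fh, index=False, lineterminator="\n")
    files.append(path)

    path = out_dir / "summary.txt"
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("hydraulics\n")
        for key, value in hyd.as_dict().items():
            fh.write(f"  {key:32s} {value:.6g}\n")
        fh.write("mass balance (mg)\n")
        for cid, rep in balances.items():
            r = rep.rounded()
            fh.write(
                f"  {cid}: inflow {r['inflow_mass']}, outflow {r['outflow_mass']}, "
                f"degraded(solid) {r['degraded_solid_method']}, "
                f"degraded(dissolved) {r['degraded_dissolved_method']}, "
                f"discrepancy {r['discrepancy']}\n"
            )
        final_day = max(r.config.duration for r in runs.values())
        for analyte in sorted(config.thresholds):
            frac = report.fraction_exceeding(day=final_day, analyte=analyte)
            fh.write(
                f"exceedance {analyte}: {frac:.1f}% of monitoring points "
                f"on day {final_day:g}\n"
            )
    files.append(path)

    return PipelineResult(
        config=config, out_dir=out_dir, hydraulics=hyd, runs=runs,
        measured=measured, balances=balances, exceedance=report, files=files,
    )
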