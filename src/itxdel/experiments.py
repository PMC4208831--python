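"""Named computational experiments with logged, reproducible outputs.

Each scenario reproduces one of the model's standard in-silico
experiments as tidy CSV tables plus a JSON manifest that captures every
number needed to rerun it (fully resolved parameters, schedule, solver
settings, package version, and a content hash).  Rerunning the same
configuration reproduces the outputs exactly.

Scenarios
---------
``fig2_scan``
    steady-state shed-antigen levels in ECS and blood across tumor
    volumes.
``fig3_treatment``
    treated and control tumor-volume time courses under the standard
    three-bolus schedule.
``fig4_toggles``
    shedding off / shedding with complex back-permeation / shedding
    without it, under identical dosing.
``fig4_compare``
    SS1P vs LMB-2 volume profiles under matched growth parameters, dose,
    and initial volume.
``fig5_sweep``
    endpoint tumor volume versus surface antigen number R*, for shedding
    and non-shedding cases and two endocytosis rates.
``custom``
    a plain run of the simulator with the given schedule.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ParameterError, build_preset, with_overrides
from .simulator import (SolverOptions, compare_shedding_scenarios,
                        run_simulation, simulate_untreated_growth,
                        steady_state_shed_antigen, sweep_antigen_density)

__all__ = ["ScenarioConfig", "ScenarioError", "run_scenario",
           "summarize_sweep", "SCENARIOS"]

SCENARIOS = ("fig2_scan", "fig3_treatment", "fig4_toggles", "fig4_compare",
             "fig5_sweep", "custom")


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class ScenarioConfig:
    """Configuration of one named experiment."""

    scenario: str
    preset: str = "SS1P"
    overrides: dict[str, Any] = field(default_factory=dict)
    schedule: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 62.0), (48.0, 62.0), (96.0, 62.0)])
    V0_mm3: float = 110.0
    t_end_hr: float = 144.0
    volumes: list[float] = field(
        default_factory=lambda: list(np.geomspace(10, 1000, 15)))
    r_star_grid: list[float] = field(
        default_factory=lambda: [1e3, 1e4, 1e5, 2e5, 5e5, 1e6, 1e7])
    k_e_values: list[float] = field(default_factory=lambda: [0.08, 0.22])
    solver: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "scenario_out"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ScenarioError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        self.schedule = sorted((float(t), float(d)) for t, d in self.schedule)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ScenarioError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _options(cfg: ScenarioConfig) -> SolverOptions:
    try:
        return SolverOptions(**cfg.solver)
    except TypeError as exc:
        raise ScenarioError(f"bad solver option: {exc}") from exc


def _manifest(cfg: ScenarioConfig, params, options: SolverOptions,
              tables: dict[str, str]) -> dict[str, Any]:
    body = {
        "scenario": cfg.scenario,
        "config": dataclasses.asdict(cfg),
        "resolved_parameters": params.to_dict(),
        "solver_options": dataclasses.asdict(options),
        "outputs": tables,
        "package_version": __version__,
    }
    # the hash covers the scientific content only, not output locations
    hashed = {k: v for k, v in body.items() if k != "outputs"}
    hashed["config"] = {k: v for k, v in hashed["config"].items()
                        if k != "out_dir"}
    digest = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()
    body["run_hash"] = digest
    return body


def run_scenario(cfg: ScenarioConfig) -> dict[str, Any]:
    """Execute a scenario; write CSV outputs and a JSON manifest.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        params = with_overrides(build_preset(cfg.preset), cfg.overrides)
    except ParameterError as exc:
        raise ScenarioError(str(exc)) from exc
    options = _options(cfg)
    tables: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        tables[name] = str(path)

    if cfg.scenario == "fig2_scan":
        rows = []
        for v in cfg.volumes:
            ss = steady_state_shed_antigen(params, float(v), options.n_shells)
            rows.append({"volume_mm3": v, "ecs_avg_nM": ss.ecs_avg_nM,
                         "ecs_wall_nM": ss.ecs_wall_nM,
                         "blood_nM": ss.blood_nM})
        save("shed_scan", pd.DataFrame(rows))

    elif cfg.scenario == "fig3_treatment":
        treated = run_simulation(params, cfg.schedule, cfg.V0_mm3,
                                 cfg.t_end_hr, options)
        control = simulate_untreated_growth(params, cfg.V0_mm3, cfg.t_end_hr)
        df_t = treated.to_frame()
        df_t["arm"] = "treated"
        df_c = control.to_frame()
        df_c["arm"] = "control"
        save("tumor_course", pd.concat([df_t, df_c], ignore_index=True))

    elif cfg.scenario == "fig4_toggles":
        trajs = compare_shedding_scenarios(params, cfg.schedule, cfg.V0_mm3,
                                           cfg.t_end_hr, options)
        frames = []
        for label, tr in trajs.items():
            df = tr.to_frame()
            df["case"] = label
            frames.append(df)
        save("toggles", pd.concat(frames, ignore_index=True))
        endpoints = {k: float(tr.volumes[-1]) for k, tr in trajs.items()}
        order = sorted(endpoints, key=endpoints.get, reverse=True)
        save("toggle_endpoints", pd.DataFrame(
            [{"case": k, "endpoint_volume_mm3": v,
              "rank_largest_first": order.index(k)}
             for k, v in endpoints.items()]))

    elif cfg.scenario == "fig4_compare":
        rows = []
        growth = {"cells.Gamma_0": params.cells.Gamma_0,
                  "cells.alpha": params.cells.alpha}
        for name in ("SS1P", "LMB2"):
            p = with_overrides(build_preset(name), {**growth, **cfg.overrides})
            tr = run_simulation(p, cfg.schedule, cfg.V0_mm3, cfg.t_end_hr,
                                options)
            df = tr.to_frame()
            df["system"] = name
            rows.append(df)
        save("matched_growth_courses", pd.concat(rows, ignore_index=True))

    elif cfg.scenario == "fig5_sweep":
        table = sweep_antigen_density(
            params, cfg.schedule, cfg.r_star_grid, cfg.k_e_values,
            k_s_values=(0.0, None), V0_mm3=cfg.V0_mm3,
            t_end_hr=cfg.t_end_hr, options=options)
        save("sweep", table)
        save("sweep_summary", summarize_sweep(table))

    else:  # custom
        tr = run_simulation(params, cfg.schedule, cfg.V0_mm3, cfg.t_end_hr,
                            options)
        save("trajectory", tr.to_frame())
        save("final_profile", tr.profile_frame(cfg.t_end_hr))

    manifest = _manifest(cfg, params, options, tables)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Optimum-R* region and shedding-benefit crossover per (k_e, dose).

    For each endocytosis rate and dose, reports the R* minimizing the
    endpoint volume in the non-shedding case (flagged degenerate when it
    sits on the grid boundary), and the smallest grid R* at which
    shedding lowers the endpoint (the harmful-to-beneficial crossover;
    none when the comparison never flips or the cases are identical).
    """
    if table.empty:
        raise ScenarioError("sweep table is empty")
    rows = []
    for (ke, dose), grp in table.groupby(["k_e", "dose_nM"]):
        shed = grp[grp.k_s > 0].set_index("R_star")["endpoint_volume_mm3"]
        noshed = grp[grp.k_s == 0].set_index("R_star")["endpoint_volume_mm3"]
        base = noshed if not noshed.empty else shed
        argmin = float(base.idxmin())
        grid = np.sort(base.index.to_numpy())
        row = {"k_e": ke, "dose_nM": dose, "argmin_R_star": argmin,
               "argmin_on_boundary": argmin in (grid[0], grid[-1]),
               "crossover_R_star": np.nan}
        if not shed.empty and not noshed.empty:
            common = shed.index.intersection(noshed.index).sort_values()
            benefit = shed.loc[common] < noshed.loc[common]
            if (shed.loc[common] == noshed.loc[common]).all():
                pass  # identical inputs: crossover undefined
            elif benefit.any():
                row["crossover_R_star"] = float(common[benefit.argmax()])
        rows.append(row)
    return pd.DataFrame(rows)
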