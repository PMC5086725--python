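"""Run configuration, serialization of results, and the run drivers.

A run configuration (YAML or JSON) names a scenario — a preset, a
synthetic recipe, or a layout CSV — together with the integration grid,
seed and output paths, and optionally a sensitivity block.  The drivers
:func:`run_simulate` and :func:`run_sensitivity` tie the modules
together and write tidy CSV plus a JSON summary; every run is
reproducible from the config echo embedded in its summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import scenario as scen
from .model import (
    CommunityLayout,
    ModelParameters,
    Trajectory,
    aggregate,
    initial_state,
    integrate,
)
from .sensitivity import SensitivityConfig, sensitivity_scan

__all__ = [
    "ScenarioBlock",
    "SensitivityBlock",
    "OutputBlock",
    "RunConfig",
    "load_config",
    "save_config",
    "build_scenario",
    "run_simulate",
    "run_sensitivity",
    "trajectory_to_frame",
]

log = logging.getLogger("evacsi")


class ScenarioBlock(BaseModel):
    """Where the community layout and parameters come from."""

    model_config = ConfigDict(extra="forbid")

    preset: Literal["tianjin", "synthetic"] = "tianjin"
    layout_csv: str | None = None
    params_preset: Literal["table1", "table3"] = "table1"
    n: int = 61
    total_population: float = 115_350.0
    dist_range: tuple[float, float] = (0.67, 6.10)
    equal_populations: bool = True
    anchor: tuple[int, int, float] = (1, 1, 150.0)
    init_power: int = 3


class SensitivityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameter: str = "lambda0"
    range: tuple[float, float] = (0.01, 1.0)
    grid: int = Field(default=25, ge=2)
    output_times: tuple[float, float, float, float, float] = (24, 48, 72, 96, 120)
    rel_step: float = 1e-3
    scheme: Literal["forward", "central"] = "forward"


class OutputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trajectory_csv: str = "trajectory.csv"
    summary_json: str = "summary.json"
    sensitivity_csv: str = "sensitivity.csv"
    plot: str | None = None


class RunConfig(BaseModel):
    """Fully validated run description with explicit defaults."""

    model_config = ConfigDict(extra="forbid")

    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    dt: float = 1.0
    horizon: float = 120.0
    seed: int = 0
    output: OutputBlock = Field(default_factory=OutputBlock)
    sensitivity: SensitivityBlock | None = None

    @model_validator(mode="after")
    def _check_grid(self) -> "RunConfig":
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.horizon < self.dt:
            raise ValueError("horizon must be >= dt")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Defaults are filled in explicitly and echoed at INFO level; schema
    violations are reported with their field paths by pydantic.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    cfg = RunConfig.model_validate(raw)
    if cfg.scenario.layout_csv is not None:
        csv = Path(cfg.scenario.layout_csv)
        if not csv.is_absolute():
            csv = Path(path).parent / csv
        if not csv.exists():
            raise FileNotFoundError(f"layout_csv not found: {csv}")
    log.info("loaded config: %s", cfg.model_dump())
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)


def build_scenario(
    cfg: RunConfig,
) -> tuple[CommunityLayout, ModelParameters, tuple[int, int, float]]:
    """Materialize the layout, parameters and anchor a config describes."""
    sc = cfg.scenario
    params = scen.params_table1() if sc.params_preset == "table1" else scen.params_table3()
    anchor0 = (sc.anchor[0] - 1, sc.anchor[1] - 1, sc.anchor[2])
    if sc.layout_csv is not None:
        layout = scen.read_layout_csv(sc.layout_csv)
        return layout, params, anchor0
    if sc.preset == "tianjin":
        layout, params_t, anchor0 = scen.tianjin_like_scenario(seed=cfg.seed)
        if sc.params_preset == "table3":
            params_t = scen.params_table3()
        return layout, params_t, anchor0
    spec = scen.ScenarioSpec(
        n=sc.n,
        total_population=sc.total_population,
        dist_range=tuple(sc.dist_range),
        anchor=sc.anchor,
        seed=cfg.seed,
        equal_populations=sc.equal_populations,
    )
    return scen.synthetic_layout(spec), params, anchor0


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy long-format view: one row per (t, community, type)."""
    T, K, n = traj.I.shape
    t = np.repeat(traj.times, K * n)
    # order: for each time, for each type, all communities
    typ = np.tile(np.repeat(np.arange(1, K + 1), n), T)
    comm = np.tile(np.arange(1, n + 1), T * K)
    I = traj.I.reshape(T * K * n)
    Q = np.tile(traj.layout.populations.reshape(K * n), T)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Q > 0, I / np.where(Q > 0, Q, 1.0), 0.0)
    return pd.DataFrame(
        {
            "t": t,
            "community": comm,
            "type": typ,
            "I": I,
            "S": Q - I,
            "fraction": frac,
        }
    )


def _summary_dict(cfg: RunConfig, traj: Trajectory) -> dict:
    curves = aggregate(traj)
    conserved = bool(
        np.allclose(traj.I + (traj.layout.populations - traj.I), traj.layout.populations)
    )
    log.info("conservation check: %s", conserved)
    return {
        "config": cfg.model_dump(mode="json"),
        "seed": cfg.seed,
        "times": curves.times.tolist(),
        "total": curves.total.tolist(),
        "frac_total": curves.frac_total.tolist(),
        "frac_by_type_final": curves.frac_by_type[-1].tolist(),
        "frac_by_community_final": curves.frac_by_community[-1].tolist(),
        "hours": curves.hours.tolist(),
        "hourly_increments": curves.hourly_increments.tolist(),
        "conservation_ok": conserved,
    }


def run_simulate(cfg: RunConfig, out_dir: str | Path = ".") -> dict[str, Path]:
    """Simulate per config; write trajectory CSV, summary JSON, optional plot.

    Returns the paths written.  Identical config + seed gives
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout, params, anchor = build_scenario(cfg)
    init = initial_state(layout, params, anchor, power=cfg.scenario.init_power)
    traj = integrate(layout, params, init, dt=cfg.dt, horizon=cfg.horizon, seed=cfg.seed)

    paths: dict[str, Path] = {}
    csv_path = out_dir / cfg.output.trajectory_csv
    trajectory_to_frame(traj).to_csv(csv_path, index=False, float_format="%.10g")
    paths["trajectory_csv"] = csv_path

    json_path = out_dir / cfg.output.summary_json
    with open(json_path, "w") as fh:
        json.dump(_summary_dict(cfg, traj), fh, indent=1)
    paths["summary_json"] = json_path

    if cfg.output.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curves = aggregate(traj)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curves.times, curves.frac_total, label="total")
        for k in range(3):
            ax.plot(
                curves.times,
                curves.frac_by_type[:, k],
                label=f"type {k + 1}",
                alpha=0.7,
            )
        ax.set_xlabel("time since first order (h)")
        ax.set_ylabel("cumulative evacuated fraction")
        ax.legend()
        fig.tight_layout()
        plot_path = out_dir / cfg.output.plot
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path
    return paths


def run_sensitivity(cfg: RunConfig, out_dir: str | Path = ".") -> dict[str, Path]:
    """Scan one parameter per the config's sensitivity block.

    Writes a CSV of (value, SF) pairs and a JSON summary with the max
    and average SF over the range.
    """
    if cfg.sensitivity is None:
        raise ValueError("config has no sensitivity block")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout, params, anchor = build_scenario(cfg)
    init = initial_state(layout, params, anchor, power=cfg.scenario.init_power)
    sb = cfg.sensitivity
    scfg = SensitivityConfig(
        output_times=sb.output_times, rel_step=sb.rel_step, dt=cfg.dt, scheme=sb.scheme
    )
    result = sensitivity_scan(
        sb.parameter, tuple(sb.range), sb.grid, layout, init, scfg, params
    )
    csv_path = out_dir / cfg.output.sensitivity_csv
    pd.DataFrame({"value": result.values, "SF": result.sf}).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    json_path = out_dir / cfg.output.summary_json
    with open(json_path, "w") as fh:
        json.dump(
            {
                "config": cfg.model_dump(mode="json"),
                "parameter": result.parameter,
                "max_sensitivity": result.maximum,
                "average_sensitivity": result.average,
            },
            fh,
            indent=1,
        )
    return {"sensitivity_csv": csv_path, "summary_json": json_path}
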