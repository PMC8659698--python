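"""Confluence tables, the nine-scenario registry, and synthetic data.

The experimental design emulated here: three initial glucose media (2, 5 and
10 mM, normalized by the highest to 0.2/0.5/1.0) crossed with three seeding
densities (3.5e4, 5.0e4 and 6.0e4 cells/well), four replicate wells each,
imaged every 3 h for 96 h (33 time points).  Scenario names follow the
"<glucose mM>-<L|M|H>" convention.  Measured per-scenario initial confluences
were not published, so the registry derives the live value geometrically from
the seeding density and single-cell area (overridable), and uses the
published average dead-cell confluence for the dead value.

The synthetic generator runs independent simulator realizations per scenario
and replicate at a known parameter vector and adds Gaussian measurement noise
— the stand-in for the unpublished experimental tables, and the ground truth
for parameter-recovery studies.  A manifest records everything needed to
regenerate a table exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .microenvironment import build_disc_mesh
from .params import (SINGLE_CELL_RADIUS, SimulationConfig, WELL_RADIUS,
                     in_prior_support)
from .simulator import ScenarioSpec, Trajectory, run

__all__ = ["ConfluenceTable", "read_confluence_csv", "write_confluence_csv",
           "scenario_registry", "generate_synthetic_dataset"]

COLUMNS = ("scenario_name", "replicate_id", "time_h", "live_confluence",
           "dead_confluence")

#: published average initial dead-cell confluence
DEFAULT_DEAD_CONFLUENCE = 0.029

SEEDING_DENSITIES = {"L": 3.5e4, "M": 5.0e4, "H": 6.0e4}
GLUCOSE_LEVELS = {"2": 0.2, "5": 0.5, "10": 1.0}


@dataclass
class ConfluenceTable:
    """Long-format live/dead confluence time series per scenario replicate."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("empty confluence table")
        for col in ("live_confluence", "dead_confluence"):
            bad = df.index[(df[col] < 0) | (df[col] > 1)]
            if len(bad):
                raise ValueError(
                    f"{col} outside [0, 1] at rows {bad.tolist()[:10]}")
        # every (scenario, replicate) must share one complete uniform grid
        grids = {}
        for (scen, rep), g in df.groupby(["scenario_name", "replicate_id"]):
            t = np.sort(g["time_h"].to_numpy(dtype=float))
            if t.size > 1:
                dt = np.diff(t)
                if not np.allclose(dt, dt[0]):
                    raise ValueError(f"ragged time grid for ({scen}, {rep})")
            grids.setdefault(scen, []).append((rep, t))
        for scen, reps in grids.items():
            ref = reps[0][1]
            for rep, t in reps[1:]:
                if t.shape != ref.shape or not np.allclose(t, ref):
                    raise ValueError(
                        f"replicate {rep} of {scen} is on a different grid")

    def scenarios(self) -> list[str]:
        return sorted(self.frame["scenario_name"].unique())

    def replicates(self, scenario_name: str) -> list[Trajectory]:
        """Trajectories of every replicate of one scenario."""
        sub = self.frame[self.frame["scenario_name"] == scenario_name]
        if len(sub) == 0:
            raise KeyError(scenario_name)
        out = []
        for rep, g in sub.groupby("replicate_id"):
            g = g.sort_values("time_h")
            out.append(Trajectory(
                times=g["time_h"].to_numpy(dtype=float),
                live_confluence=g["live_confluence"].to_numpy(dtype=float),
                dead_confluence=g["dead_confluence"].to_numpy(dtype=float)))
        return out


def read_confluence_csv(path) -> ConfluenceTable:
    """Read and validate a comma-separated confluence table."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"empty confluence file: {path}")
    return ConfluenceTable(frame=df)


def write_confluence_csv(table: ConfluenceTable, path) -> None:
    table.frame.to_csv(path, index=False)


def derived_live_confluence(seeding_density: float,
                            cell_radius: float = SINGLE_CELL_RADIUS,
                            well_radius: float = WELL_RADIUS) -> float:
    """Initial live confluence implied by the seeding density: n (R/W)^2."""
    return float(seeding_density * (cell_radius / well_radius) ** 2)


def scenario_registry(well_radius: float = WELL_RADIUS,
                      dead_confluence: float = DEFAULT_DEAD_CONFLUENCE,
                      live_overrides: dict[str, float] | None = None,
                      horizon: float = 96.0,
                      sample_interval: float = 3.0) -> dict[str, ScenarioSpec]:
    """The nine experimental scenarios, keyed by their standard names."""
    live_overrides = live_overrides or {}
    registry = {}
    for gname, glucose0 in GLUCOSE_LEVELS.items():
        for cname, density in SEEDING_DENSITIES.items():
            name = f"{gname}-{cname}"
            live = live_overrides.get(
                name, derived_live_confluence(density, well_radius=well_radius))
            registry[name] = ScenarioSpec(
                name=name, glucose0=glucose0, seeding_density=density,
                init_live_confluence=live, init_dead_confluence=dead_confluence,
                well_radius=well_radius, horizon=horizon,
                sample_interval=sample_interval)
    return registry


def generate_synthetic_dataset(theta_true: dict[str, float],
                               registry: dict[str, ScenarioSpec],
                               n_replicates: int = 4,
                               noise_sd: float = 0.01,
                               m: int = 100,
                               rng: np.random.Generator | int | None = None,
                               config: SimulationConfig | None = None,
                               heteroscedastic: bool = False,
                               manifest_path=None
                               ) -> tuple[ConfluenceTable, dict]:
    """Simulated confluence tables emulating the experimental design.

    One independent simulator realization per scenario and replicate at
    ``theta_true``, plus additive zero-mean Gaussian measurement noise of
    standard deviation ``noise_sd`` (optionally scaled by the local
    confluence), clipped to [0, 1].  Returns the table and a manifest from
    which the table is exactly regenerable.
    """
    if not in_prior_support(theta_true):
        raise ValueError("theta_true lies outside the prior support")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = np.random.default_rng(rng)
    sim_seed, noise_seed = (int(s) for s in master.integers(0, 2**31 - 1, 2))
    if config is None:
        config = SimulationConfig(m=m)
    else:
        config = replace(config, m=m)
    config = config.with_theta(theta_true)

    sim_rng = np.random.default_rng(sim_seed)
    noise_rng = np.random.default_rng(noise_seed)
    meshes: dict[float, object] = {}
    rows = []
    rep_seeds: dict[str, list[int]] = {}
    for name in sorted(registry):
        scenario = registry[name]
        W = scenario.well_radius
        if W not in meshes:
            meshes[W] = build_disc_mesh(W, config.mesh_target_elements,
                                        seed=config.mesh_seed)
        rep_seeds[name] = [int(s) for s in
                           sim_rng.integers(0, 2**31 - 1, n_replicates)]
        for rep, s in enumerate(rep_seeds[name]):
            tr = run(scenario, config, s, mesh=meshes[W])
            for out in ("live", "dead"):
                vals = getattr(tr, f"{out}_confluence")
                if noise_sd > 0:
                    scale = noise_sd * (vals if heteroscedastic else 1.0)
                    vals = vals + scale * noise_rng.standard_normal(vals.shape)
                if out == "live":
                    live = np.clip(vals, 0.0, 1.0)
                else:
                    dead = np.clip(vals, 0.0, 1.0)
            for t, lv, dv in zip(tr.times, live, dead):
                rows.append((name, rep, float(t), float(lv), float(dv)))

    table = ConfluenceTable(frame=pd.DataFrame(rows, columns=COLUMNS))
    manifest = {
        "theta_true": {k: float(v) for k, v in theta_true.items()},
        "n_replicates": n_replicates,
        "noise_sd": noise_sd,
        "heteroscedastic": heteroscedastic,
        "m": config.m,
        "sim_seed": sim_seed,
        "noise_seed": noise_seed,
        "replicate_seeds": rep_seeds,
        "scenarios": {
            name: {"glucose0": registry[name].glucose0,
                   "seeding_density": registry[name].seeding_density,
                   "init_live_confluence": registry[name].init_live_confluence,
                   "init_dead_confluence": registry[name].init_dead_confluence,
                   "well_radius": registry[name].well_radius,
                   "horizon": registry[name].horizon,
                   "sample_interval": registry[name].sample_interval}
            for name in sorted(registry)},
        "mesh_target_elements": config.mesh_target_elements,
        "mesh_seed": config.mesh_seed,
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return table, manifest
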