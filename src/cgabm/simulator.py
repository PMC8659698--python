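"""The hybrid two-scale simulation loop and its observables.

One simulated hour consists of (1) a reaction-diffusion step of the glucose
field with the current live-cell occupancy as sink, (2) a phenotype update of
every agent using the glucose interpolated at its center, and (3) mechanical
relaxation of positions at one-minute substeps (or until equilibrium,
whichever comes first).  Live and dead confluences — summed agent area over
well area, overlap deliberately not subtracted — are recorded on a fixed
sampling grid (every 3 h over 96 h by default, 33 points).

Coarse-graining: one agent stands for ``m`` cells of identical phenotype; the
cell, nuclear and action radii all scale with sqrt(m), so total area (hence
confluence) is preserved while the agent count drops m-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import phenotype as phen
from .mechanics import relax_positions
from .microenvironment import (DiscMesh, NutrientField, build_disc_mesh,
                               diffusion_step, live_fraction_field)
from .params import WELL_RADIUS, SimulationConfig
from .population import DEAD, P_PRE, Q, Population

__all__ = ["ScenarioSpec", "Trajectory", "coarse_grain_geometry", "initialize",
           "confluence", "tumor_radius", "run", "resolution_error"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One experimental condition: initial glucose and seeding confluences."""

    name: str
    glucose0: float                 # normalized initial glucose (1.0 == 10 mM)
    seeding_density: float          # cells/well (bookkeeping)
    init_live_confluence: float
    init_dead_confluence: float
    well_radius: float = WELL_RADIUS  # um
    horizon: float = 96.0             # h
    sample_interval: float = 3.0      # h

    def __post_init__(self) -> None:
        if not 0.0 < self.glucose0 <= 1.0:
            raise ValueError("glucose0 must lie in (0, 1]")
        for c in (self.init_live_confluence, self.init_dead_confluence):
            if not 0.0 <= c <= 1.0:
                raise ValueError("initial confluences must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.horizon / self.sample_interval))
        return np.linspace(0.0, self.horizon, n + 1)


@dataclass
class Trajectory:
    """Sampled observables of one realization."""

    times: np.ndarray
    live_confluence: np.ndarray
    dead_confluence: np.ndarray
    tumor_radius_um: np.ndarray | None = None
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times, "live_confluence": self.live_confluence,
                "dead_confluence": self.dead_confluence}
        if self.tumor_radius_um is not None:
            data["tumor_radius_um"] = self.tumor_radius_um
        if self.seed is not None:
            data["seed"] = self.seed
        return pd.DataFrame(data)


def coarse_grain_geometry(base_radii: tuple[float, float, float],
                          m: int) -> tuple[float, float, float]:
    """Scale (R, R_N, R_A) by sqrt(m): agent area equals m single-cell areas."""
    if int(m) != m or m < 1:
        raise ValueError("m must be an integer >= 1")
    s = float(np.sqrt(m))
    r, rn, ra = base_radii
    return (r * s, rn * s, ra * s)


def _seed_positions(n: int, well_radius: float, rng: np.random.Generator) -> np.ndarray:
    r = well_radius * np.sqrt(rng.random(n))
    t = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def initialize(scenario: ScenarioSpec, config: SimulationConfig,
               rng: np.random.Generator,
               mesh: DiscMesh | None = None) -> tuple[Population, NutrientField]:
    """Seed the initial population and the uniform glucose field.

    Agent counts round the requested confluences to the nearest whole agent;
    positions are uniform over the disc.  Live agents start proliferative with
    the glucose-ramp probability (all quiescent if the config says so), dead
    agents are inert from the outset.
    """
    pparams = config.phenotype_params()
    agent_r = config.cell_radius * np.sqrt(config.m)
    agent_area = np.pi * agent_r**2
    well_area = np.pi * scenario.well_radius**2
    n_live = int(round(scenario.init_live_confluence * well_area / agent_area))
    n_dead = int(round(scenario.init_dead_confluence * well_area / agent_area))
    n = n_live + n_dead

    x = _seed_positions(n, scenario.well_radius, rng)
    phenotypes = np.full(n, DEAD, dtype=np.int8)
    if n_live:
        if config.all_quiescent_init:
            p0 = 0.0
        else:
            p0 = phen.initial_proliferative_fraction(scenario.glucose0, pparams)
        # the proliferative FRACTION is fixed by the glucose ramp; which agents
        # carry it is random
        n_p = int(round(p0 * n_live))
        prolif = rng.permutation(n_live) < n_p
        phenotypes[:n_live] = np.where(prolif, P_PRE, Q).astype(np.int8)
    pop = Population(x=x, radius=np.full(n, agent_r), phenotype=phenotypes,
                     clock=np.zeros(n), target_area=np.full(n, agent_area),
                     m=config.m, nuclear_factor=config.nuclear_factor,
                     action_factor=config.action_factor)

    if mesh is None:
        mesh = build_disc_mesh(scenario.well_radius, config.mesh_target_elements,
                               seed=config.mesh_seed)
    nutrient = NutrientField.uniform(mesh, scenario.glucose0, config.D,
                                     config.theta["lambda"])
    return pop, nutrient


def confluence(population: Population, well_radius: float) -> tuple[float, float]:
    """(live, dead) summed-area fractions of the well; overlap not subtracted."""
    well_area = np.pi * well_radius**2
    area = population.area
    live = float(area[population.alive].sum() / well_area)
    dead = float(area[~population.alive].sum() / well_area)
    return live, dead


def tumor_radius(population: Population, q: float = 0.95) -> float:
    """Centroid-based reach: distance to the q-quantile agent plus its radius."""
    n = len(population)
    if n == 0:
        raise ValueError("tumor_radius of an empty population")
    centroid = population.x.mean(axis=0)
    r = np.hypot(*(population.x - centroid).T)
    k = min(n - 1, max(0, int(np.ceil(q * n)) - 1))
    idx = np.argsort(r)[k]
    return float(r[idx] + population.radius[idx])


def run(scenario: ScenarioSpec, config: SimulationConfig,
        rng: np.random.Generator | int | None = None,
        mesh: DiscMesh | None = None,
        record_radius: bool = False) -> Trajectory:
    """Run one stochastic realization of the hybrid model.

    A pre-built ``mesh`` may be passed to amortize mesh generation across
    replicates.  Identical (scenario, config, seed) give identical output.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    pparams = config.phenotype_params()
    mech = config.mechanics
    dt = config.dt

    pop, nutrient = initialize(scenario, config, rng, mesh=mesh)
    mesh = nutrient.mesh

    times = scenario.times
    live = np.zeros(times.size)
    dead = np.zeros(times.size)
    radius = np.zeros(times.size) if record_radius else None

    def record(k: int) -> None:
        live[k], dead[k] = confluence(pop, scenario.well_radius)
        if record_radius:
            radius[k] = tumor_radius(pop) if len(pop) else 0.0

    record(0)
    next_sample = 1
    n_hours = int(round(scenario.horizon / dt))
    for step in range(1, n_hours + 1):
        if len(pop):
            rho = live_fraction_field(pop, mesh)
            diffusion_step(nutrient, rho, dt)
            sigma_agents = nutrient.sample_at(pop.x)
            phen.transition_step(pop, sigma_agents, pparams, rng)
            relax_positions(pop, 60.0 * dt, scenario.well_radius, mech, rng)
        else:
            diffusion_step(nutrient, np.zeros(mesh.n_elements), dt)
        t = step * dt
        while next_sample < times.size and t >= times[next_sample] - 1e-9:
            record(next_sample)
            next_sample += 1

    return Trajectory(times=times, live_confluence=live, dead_confluence=dead,
                      tumor_radius_um=radius, seed=seed)


def _pair_error(reference: np.ndarray, candidate: np.ndarray) -> tuple[float, int]:
    """Mean relative absolute error over time points; zero references skipped."""
    ok = reference != 0.0
    skipped = int((~ok).sum())
    if not ok.any():
        return np.nan, skipped
    err = np.abs(candidate[ok] - reference[ok]) / reference[ok]
    return float(err.mean()), skipped


def resolution_error(scenario: ScenarioSpec, config: SimulationConfig,
                     m_list: list[int], n_reps: int,
                     rng: np.random.Generator | int | None = None,
                     record_radius: bool = True) -> dict:
    """ABM-vs-cgABM error for each coarse-graining level in ``m_list``.

    For every m, runs ``n_reps`` paired (reference m=1, coarse m) replicates
    and reports the mean relative absolute error of live confluence, dead
    confluence and (optionally) tumor radius against the single-cell reference,
    with a 95% normal interval over replicate pairs.
    """
    if 1 not in m_list:
        raise ValueError("m_list must include the m=1 reference")
    rng = np.random.default_rng(rng)
    mesh = build_disc_mesh(scenario.well_radius, config.mesh_target_elements,
                           seed=config.mesh_seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_reps, len(m_list)))
    ref_idx = m_list.index(1)

    refs = [run(scenario, replace(config, m=1), int(seeds[r, ref_idx]), mesh=mesh,
                record_radius=record_radius) for r in range(n_reps)]

    out = {}
    for j, m in enumerate(m_list):
        errs = {"live": [], "dead": [], "radius": []}
        skipped = 0
        for r in range(n_reps):
            if m == 1:
                cand = refs[r]
            else:
                cand = run(scenario, replace(config, m=m), int(seeds[r, j]),
                           mesh=mesh, record_radius=record_radius)
            e, s = _pair_error(refs[r].live_confluence, cand.live_confluence)
            errs["live"].append(e)
            skipped += s
            e, s = _pair_error(refs[r].dead_confluence, cand.dead_confluence)
            errs["dead"].append(e)
            skipped += s
            if record_radius:
                e, s = _pair_error(refs[r].tumor_radius_um, cand.tumor_radius_um)
                errs["radius"].append(e)
                skipped += s
        entry = {"skipped_zero_reference": skipped}
        for key, vals in errs.items():
            if not vals:
                continue
            vals = np.asarray(vals)
            mean = float(np.nanmean(vals))
            half = 1.96 * float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals))) \
                if len(vals) > 1 else 0.0
            entry[key] = {"mean": mean, "ci95": (mean - half, mean + half),
                          "per_replicate": vals.tolist()}
        out[m] = entry
    return out
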