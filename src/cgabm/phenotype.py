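"""Stochastic and deterministic phenotype transitions.

Quiescent agents (Q) can die (Q->D) or commit to division (Q->P) in each
one-hour step, with Poisson-style probabilities ``1 - exp(-rate * dt)``.  The
death intensity rises smoothly by ``gamma_D`` once glucose falls below the
threshold ``sigma_H``; the proliferation intensity ramps linearly with glucose
above the threshold and is zero below it.  Committed agents count down
``tau_P - tau_G1`` hours, split into two half-area daughters, and the
daughters grow linearly in area back to the parent area over ``tau_G1`` hours
before returning to quiescence.  Dead agents are permanent and inert but keep
occupying area and exerting contact forces.

Within a step, the death draw is evaluated before the proliferation draw; at
the calibrated rate magnitudes and dt = 1 h the probability that both fire is
below 1e-3, so the ordering bias is negligible.
"""

from __future__ import annotations

import numpy as np

from .params import PhenotypeParams
from .population import DEAD, P_GROW, P_PRE, Q, Agent, Population

__all__ = [
    "alpha_D",
    "alpha_P",
    "transition_probability",
    "transition_step",
    "divide",
    "grow_daughter",
]


def alpha_D(sigma, params: PhenotypeParams):
    """Death intensity (1/h): base rate plus a smooth starvation increment."""
    sigma = np.asarray(sigma, dtype=float)
    out = params.alpha_D_bar + params.gamma_D / (
        1.0 + np.exp(-2.0 * params.k * (params.sigma_H - sigma))
    )
    return out if out.ndim else float(out)


def alpha_P(sigma, params: PhenotypeParams):
    """Proliferation intensity (1/h): linear glucose ramp above the threshold."""
    if params.sigma_H >= 1.0:
        raise ValueError("sigma_H must be < 1 for the proliferation ramp")
    sigma = np.asarray(sigma, dtype=float)
    out = np.maximum(
        params.alpha_P_bar * (sigma - params.sigma_H) / (1.0 - params.sigma_H), 0.0
    )
    return out if out.ndim else float(out)


def transition_probability(rate, dt: float):
    """Per-step transition probability 1 - exp(-rate * dt), in [0, 1)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0) or dt < 0:
        raise ValueError("rate and dt must be non-negative")
    out = -np.expm1(-rate * dt)
    return out if out.ndim else float(out)


def initial_proliferative_fraction(sigma0: float, params: PhenotypeParams) -> float:
    """Fraction of live cells seeded proliferative.

    The proliferation intensity at the seeding glucose level, clipped to
    [0, 1]: ``min(alpha_P_bar * (sigma0 - sigma_H)/(1 - sigma_H), 1)`` above
    the threshold, zero below.  The base rate enters, so a slowly cycling
    population also starts with few committed cells.
    """
    return float(np.clip(alpha_P(sigma0, params), 0.0, 1.0))


def divide(agent: Agent, rng: np.random.Generator) -> tuple[Agent, Agent]:
    """Split a committed agent into two half-area daughters.

    Daughters are placed symmetrically about the parent center along a random
    direction, separated by half the sum of their radii; the subsequent
    mechanical relaxation restores the equilibrium spacing.  Total area is
    conserved by construction.
    """
    if agent.phenotype != P_PRE:
        raise ValueError("divide() requires a pre-mitotic agent")
    r_d = agent.radius / np.sqrt(2.0)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])
    offset = 0.5 * (2.0 * r_d) / 2.0 * u  # separation = 0.5 * (r_d + r_d)
    kw = dict(radius=r_d, phenotype=P_GROW, clock=0.0, target_area=agent.area,
              nuclear_factor=agent.nuclear_factor, action_factor=agent.action_factor)
    return (Agent(x=agent.x - offset, **kw), Agent(x=agent.x + offset, **kw))


def grow_daughter(agent: Agent, dt: float, tau_G1: float = 9.0) -> Agent:
    """Advance a growing daughter: area rises linearly to the parent area.

    Area is ``target_area * (1/2 + clock / (2 tau_G1))``, i.e. half the parent
    area at birth and the full parent area once ``clock`` reaches ``tau_G1``.
    """
    if agent.phenotype != P_GROW:
        raise ValueError("grow_daughter() requires a growing daughter")
    clock = agent.clock + dt
    area = float(_daughter_area(agent.target_area, clock, tau_G1))
    return Agent(x=agent.x.copy(), radius=float(np.sqrt(area / np.pi)),
                 phenotype=P_GROW, clock=clock, target_area=agent.target_area,
                 nuclear_factor=agent.nuclear_factor,
                 action_factor=agent.action_factor)


def _daughter_area(target_area, clock, tau_G1: float):
    """Linear-in-area growth from target/2 at clock 0 to target at tau_G1."""
    frac = np.clip(np.asarray(clock, dtype=float) / tau_G1, 0.0, 1.0)
    return np.asarray(target_area, dtype=float) * (0.5 + 0.5 * frac)


def transition_step(population: Population, sigma_at_agents: np.ndarray,
                    params: PhenotypeParams, rng: np.random.Generator) -> Population:
    """Advance every agent's phenotype by one step of ``params.dt`` hours.

    Mutates and returns ``population``.  Newly created daughters are appended;
    the dividing parent is replaced in place by its first daughter.
    """
    n = len(population)
    sigma_at_agents = np.asarray(sigma_at_agents, dtype=float)
    if sigma_at_agents.shape != (n,):
        raise ValueError(
            f"need one concentration per agent: got {sigma_at_agents.shape}, n={n}"
        )
    dt = params.dt
    if dt == 0.0 or n == 0:
        return population

    phen = population.phenotype
    q_mask = phen == Q
    pre_mask = phen == P_PRE
    grow_mask = phen == P_GROW

    # --- stochastic Q transitions: death first, then proliferation
    if q_mask.any():
        sig_q = sigma_at_agents[q_mask]
        p_die = transition_probability(alpha_D(sig_q, params), dt)
        dies = rng.random(p_die.shape) < p_die
        p_prol = transition_probability(alpha_P(sig_q, params), dt)
        commits = (~dies) & (rng.random(p_prol.shape) < p_prol)
        idx_q = np.nonzero(q_mask)[0]
        population.phenotype[idx_q[dies]] = DEAD
        population.clock[idx_q[dies]] = 0.0
        population.phenotype[idx_q[commits]] = P_PRE
        population.clock[idx_q[commits]] = 0.0

    # --- deterministic clocks (pre-existing P agents only)
    population.clock[pre_mask] += dt
    population.clock[grow_mask] += dt

    # daughters that finished growing return to quiescence at full size
    done = grow_mask & (population.clock >= params.tau_G1)
    if done.any():
        population.radius[done] = np.sqrt(population.target_area[done] / np.pi)
        population.phenotype[done] = Q
        population.clock[done] = 0.0
    still_growing = grow_mask & ~done
    if still_growing.any():
        area = _daughter_area(population.target_area[still_growing],
                              population.clock[still_growing], params.tau_G1)
        population.radius[still_growing] = np.sqrt(area / np.pi)

    # mitosis after the pre-mitotic countdown (tau_P - tau_G1)
    ready = pre_mask & (population.clock >= params.tau_P - params.tau_G1)
    if ready.any():
        new_agents = []
        for i in np.nonzero(ready)[0]:
            d1, d2 = divide(population.agent(i), rng)
            population.x[i] = d1.x
            population.radius[i] = d1.radius
            population.phenotype[i] = d1.phenotype
            population.clock[i] = 0.0
            population.target_area[i] = d1.target_area
            new_agents.append(d2)
        population.append(new_agents)

    return population
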