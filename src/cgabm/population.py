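"""Agent population container.

Agents are stored struct-of-arrays for speed; :class:`Agent` is a scalar
record view used by the single-agent operations (division, growth).  Nuclear
and action radii are tied to the cell radius by fixed factors, so only the
cell radius is stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ACTION_RADIUS_FACTOR, NUCLEAR_RADIUS_FACTOR

# phenotype codes
Q = 0        # quiescent
P_PRE = 1    # proliferative, pre-mitotic (S/G2/M countdown)
P_GROW = 2   # proliferative daughter, growing through G1
DEAD = 3     # dead, inert and permanent

LIVE_CODES = (Q, P_PRE, P_GROW)


@dataclass
class Agent:
    """Scalar view of one agent (positions in um, areas in um^2)."""

    x: np.ndarray          # shape (2,)
    radius: float
    phenotype: int
    clock: float           # h in current phase
    target_area: float     # um^2, parent area a daughter grows back to
    nuclear_factor: float = NUCLEAR_RADIUS_FACTOR
    action_factor: float = ACTION_RADIUS_FACTOR

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    @property
    def nuclear_radius(self) -> float:
        return self.radius * self.nuclear_factor

    @property
    def action_radius(self) -> float:
        return self.radius * self.action_factor


class Population:
    """Struct-of-arrays collection of agents sharing one coarse-graining level."""

    def __init__(self, x, radius, phenotype, clock, target_area, m: int = 1,
                 nuclear_factor: float = NUCLEAR_RADIUS_FACTOR,
                 action_factor: float = ACTION_RADIUS_FACTOR):
        self.x = np.atleast_2d(np.asarray(x, dtype=float)).reshape(-1, 2).copy()
        n = self.x.shape[0]
        self.radius = np.broadcast_to(np.asarray(radius, float), (n,)).astype(float).copy()
        self.phenotype = np.broadcast_to(np.asarray(phenotype, np.int8), (n,)).astype(np.int8).copy()
        self.clock = np.broadcast_to(np.asarray(clock, float), (n,)).astype(float).copy()
        self.target_area = np.broadcast_to(np.asarray(target_area, float), (n,)).astype(float).copy()
        self.m = int(m)
        self.nuclear_factor = float(nuclear_factor)
        self.action_factor = float(action_factor)

    @classmethod
    def empty(cls, m: int = 1, **kw) -> "Population":
        return cls(np.empty((0, 2)), np.empty(0), np.empty(0, np.int8),
                   np.empty(0), np.empty(0), m=m, **kw)

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def area(self) -> np.ndarray:
        return np.pi * self.radius**2

    @property
    def nuclear_radius(self) -> np.ndarray:
        return self.radius * self.nuclear_factor

    @property
    def action_radius(self) -> np.ndarray:
        return self.radius * self.action_factor

    @property
    def alive(self) -> np.ndarray:
        return self.phenotype != DEAD

    def agent(self, i: int) -> Agent:
        return Agent(
            x=self.x[i].copy(),
            radius=float(self.radius[i]),
            phenotype=int(self.phenotype[i]),
            clock=float(self.clock[i]),
            target_area=float(self.target_area[i]),
            nuclear_factor=self.nuclear_factor,
            action_factor=self.action_factor,
        )

    def append(self, agents: list[Agent]) -> None:
        if not agents:
            return
        self.x = np.vstack([self.x, [a.x for a in agents]])
        self.radius = np.append(self.radius, [a.radius for a in agents])
        self.phenotype = np.append(self.phenotype,
                                   np.array([a.phenotype for a in agents], np.int8))
        self.clock = np.append(self.clock, [a.clock for a in agents])
        self.target_area = np.append(self.target_area, [a.target_area for a in agents])

    def copy(self) -> "Population":
        return Population(self.x, self.radius, self.phenotype, self.clock,
                          self.target_area, m=self.m,
                          nuclear_factor=self.nuclear_factor,
                          action_factor=self.action_factor)
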