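"""Model parameters and configuration containers.

The model describes BT-474 breast cancer cells growing in a circular culture
well.  Each agent is a circular (super-)cell with an incompressible nucleus of
radius ``R_N``, a cell radius ``R`` and an action radius ``R_A`` bounding
short-range adhesion.  Glucose is the single limiting nutrient; its normalized
concentration (1.0 == 10 mM) drives the stochastic quiescent->proliferative and
quiescent->dead transitions.

``DEFAULT_THETA`` holds the deterministic parameter values used in the
coarse-graining studies, ``PRIOR_BOUNDS`` the uniform ranges used for
sensitivity analysis and as calibration priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: names of the five calibrated parameters, in canonical order
THETA_NAMES = ("alpha_P_bar", "alpha_D_bar", "lambda", "gamma_D", "sigma_H")

#: names of the seven parameters screened by the sensitivity analysis
GSA_NAMES = ("alpha_P_bar", "alpha_D_bar", "D", "lambda", "gamma_D", "k", "sigma_H")

#: deterministic parameter values (coarse-graining studies)
DEFAULT_THETA: Mapping[str, float] = {
    "alpha_P_bar": 0.0493,   # 1/h, Q->P transition rate
    "alpha_D_bar": 0.000408, # 1/h, Q->D transition rate
    "D": 50.0,               # um^2/h, glucose diffusion coefficient
    "lambda": 0.0483,        # 1/h, glucose uptake rate by live cells
    "gamma_D": 0.0245,       # 1/h, death-rate increase under glucose starvation
    "k": 50.0,               # dimensionless, sharpness of the starvation switch
    "sigma_H": 0.0538,       # normalized glucose threshold
}

#: uniform prior / sensitivity ranges
PRIOR_BOUNDS: Mapping[str, tuple[float, float]] = {
    "alpha_P_bar": (0.0, 1.0),
    "alpha_D_bar": (0.0, 0.02),
    "D": (0.0, 100.0),
    "lambda": (0.0, 1.0),
    "gamma_D": (0.0, 0.05),
    "k": (0.0, 100.0),
    "sigma_H": (0.0, 1.0),
}

#: single-cell geometry (um)
SINGLE_CELL_RADIUS = 9.953
SINGLE_CELL_NUCLEAR_RADIUS = 5.295
ACTION_RADIUS_FACTOR = 1.214  # R_A = 1.214 R
NUCLEAR_RADIUS_FACTOR = SINGLE_CELL_NUCLEAR_RADIUS / SINGLE_CELL_RADIUS

#: default well radius (um) of one well of a 96-well plate
WELL_RADIUS = 3192.0


@dataclass(frozen=True)
class MechanicsParams:
    """Force-law coefficients and relaxation controls.

    Force scales carry units of um/min (velocity contributed at unit potential
    gradient).  The drag coefficient ``nu`` is dimensionless: the published
    force scales already absorb the fluid drag, so ``nu`` defaults to 1 and is
    exposed only for completeness.  Boundary coefficients default to the
    cell-cell values since no separate values are published.
    """

    c_cca: float = 0.0489   # cell-cell adhesion scale, um/min
    c_ccr: float = 10.0     # cell-cell repulsion scale, um/min
    c_ct: float = 0.0489    # cell-boundary adhesion scale, um/min
    c_rct: float = 10.0     # cell-boundary repulsion scale, um/min
    nu: float = 1.0         # drag coefficient (dimensionless scale)
    relax_substep: float = 1.0   # min, forward-Euler substep
    relax_tol: float = 1e-3      # um, equilibrium displacement criterion

    def __post_init__(self) -> None:
        if min(self.c_cca, self.c_ccr, self.c_ct, self.c_rct) < 0:
            raise ValueError("force scales must be non-negative")
        if self.relax_substep <= 0 or self.relax_tol <= 0:
            raise ValueError("relax_substep and relax_tol must be positive")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


@dataclass(frozen=True)
class PhenotypeParams:
    """Rates and clocks of the Q/P/D phenotype machinery.

    ``tau_A`` (apoptosis time) is carried through from the published parameter
    table but unused: dead agents persist for the whole simulation and their
    confluence only accumulates.
    """

    alpha_P_bar: float = DEFAULT_THETA["alpha_P_bar"]  # 1/h
    alpha_D_bar: float = DEFAULT_THETA["alpha_D_bar"]  # 1/h
    gamma_D: float = DEFAULT_THETA["gamma_D"]          # 1/h
    k: float = DEFAULT_THETA["k"]                      # dimensionless
    sigma_H: float = DEFAULT_THETA["sigma_H"]          # normalized glucose
    tau_P: float = 18.0    # h, full cell-cycle time
    tau_G1: float = 9.0    # h, daughter growth (G1) time
    tau_A: float = 8.6     # h, apoptosis time (parsed, unused)
    dt: float = 1.0        # h, phenotype/nutrient timestep

    def __post_init__(self) -> None:
        if min(self.alpha_P_bar, self.alpha_D_bar, self.gamma_D) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.sigma_H <= 1.0:
            raise ValueError("sigma_H must lie in [0, 1]")
        if not 0.0 < self.tau_G1 < self.tau_P:
            raise ValueError("need 0 < tau_G1 < tau_P")
        if self.dt < 0:
            raise ValueError("dt must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one hybrid simulation besides the scenario.

    ``theta`` is the calibrated subset (alpha_P_bar, alpha_D_bar, lambda,
    gamma_D, sigma_H); diffusion ``D`` and switch sharpness ``k`` are held
    fixed.  ``m`` is the coarse-graining factor (cells per agent); agent radii
    scale with sqrt(m).
    """

    theta: Mapping[str, float] = field(
        default_factory=lambda: {n: DEFAULT_THETA[n] for n in THETA_NAMES}
    )
    D: float = DEFAULT_THETA["D"]          # um^2/h
    k: float = DEFAULT_THETA["k"]
    m: int = 100                           # cells per agent
    cell_radius: float = SINGLE_CELL_RADIUS
    nuclear_factor: float = NUCLEAR_RADIUS_FACTOR
    action_factor: float = ACTION_RADIUS_FACTOR
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    tau_P: float = 18.0
    tau_G1: float = 9.0
    tau_A: float = 8.6
    dt: float = 1.0                        # h
    mesh_target_elements: int = 2413
    mesh_seed: int = 0
    all_quiescent_init: bool = False       # start with zero proliferative cells

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("m must be an integer >= 1")
        for name in THETA_NAMES:
            if name not in self.theta:
                raise ValueError(f"theta is missing parameter {name!r}")

    def phenotype_params(self) -> PhenotypeParams:
        t = self.theta
        return PhenotypeParams(
            alpha_P_bar=t["alpha_P_bar"],
            alpha_D_bar=t["alpha_D_bar"],
            gamma_D=t["gamma_D"],
            k=self.k,
            sigma_H=t["sigma_H"],
            tau_P=self.tau_P,
            tau_G1=self.tau_G1,
            tau_A=self.tau_A,
            dt=self.dt,
        )

    def with_theta(self, theta: Mapping[str, float], D: float | None = None,
                   k: float | None = None) -> "SimulationConfig":
        """Return a copy with a new calibrated-parameter vector."""
        kw = {"theta": dict(theta)}
        if D is not None:
            kw["D"] = D
        if k is not None:
            kw["k"] = k
        return replace(self, **kw)


def theta_array(theta: Mapping[str, float]) -> np.ndarray:
    """Pack a theta mapping into the canonical 5-vector."""
    return np.array([theta[n] for n in THETA_NAMES], dtype=float)


def theta_dict(values) -> dict[str, float]:
    """Unpack a canonical 5-vector into a theta mapping."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(THETA_NAMES),):
        raise ValueError(f"expected {len(THETA_NAMES)} values, got {values.shape}")
    return {n: float(v) for n, v in zip(THETA_NAMES, values)}


def in_prior_support(theta: Mapping[str, float]) -> bool:
    """True when every calibrated parameter lies inside its uniform prior box."""
    return all(
        PRIOR_BOUNDS[n][0] <= theta[n] <= PRIOR_BOUNDS[n][1] for n in THETA_NAMES
    )
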