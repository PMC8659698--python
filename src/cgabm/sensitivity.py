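"""Time-resolved variance-based (Sobol) sensitivity analysis.

Total-effect indices are estimated with the Saltelli two-matrix scheme: two
independent N x K uniform sample matrices A and B, plus K hybrid matrices
AB^(k) equal to A with column k taken from B, for a budget of N(K+1) model
evaluations.  The Jansen estimator

    S_Tk(t) = [ 1/(2N) sum_j (Y_A,j(t) - Y_AB(k),j(t))^2 ] / V(t)

is normalized by the pooled ddof=1 variance of the 2N outputs {Y_A, Y_B},
so indices of an additive model recover a_k^2 / sum a_i^2.  Because the
simulator is stochastic, each design row is evaluated as the mean of N_r
seeded realizations; negative index estimates (sampling noise) are reported
as-is.  Time points with zero pooled variance yield NaN and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import GSA_NAMES, PRIOR_BOUNDS, SimulationConfig, THETA_NAMES
from .simulator import ScenarioSpec, run
from .microenvironment import build_disc_mesh

__all__ = ["SobolDesign", "SobolResult", "build_design", "total_effect",
           "run_sobol"]


@dataclass
class SobolDesign:
    """Saltelli A/B/AB sample matrices over a uniform box."""

    A: np.ndarray                  # (N, K)
    B: np.ndarray                  # (N, K)
    names: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def K(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        """Model-evaluation budget N(K+1) (rows of A plus all AB matrices)."""
        return self.N * (self.K + 1)

    def AB(self, k: int) -> np.ndarray:
        out = self.A.copy()
        out[:, k] = self.B[:, k]
        return out


@dataclass
class SobolResult:
    """Total-effect indices per parameter, output and time point."""

    times: np.ndarray
    names: tuple[str, ...]
    S_T: dict[str, np.ndarray]        # output -> (K, N_t)
    variance: dict[str, np.ndarray]   # output -> (N_t,) pooled V(t)
    N: int
    N_r: int

    def degenerate(self, output: str) -> np.ndarray:
        """Mask of time points where the pooled variance vanishes."""
        return self.variance[output] == 0.0


def build_design(ranges: dict[str, tuple[float, float]], N: int,
                 rng: np.random.Generator | int | None = None) -> SobolDesign:
    """Draw the A and B matrices from independent uniforms over ``ranges``."""
    if N < 2:
        raise ValueError("N must be at least 2")
    names = tuple(ranges)
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"degenerate range for {name!r}: [{lo}, {hi}]")
    rng = np.random.default_rng(rng)
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    K = len(names)
    A = lo + (hi - lo) * rng.random((N, K))
    B = lo + (hi - lo) * rng.random((N, K))
    return SobolDesign(A=A, B=B, names=names, ranges=dict(ranges))


def total_effect(Y_A: np.ndarray, Y_AB_k: np.ndarray,
                 V: np.ndarray) -> np.ndarray:
    """Normalized Jansen total-effect estimator along the last sample axis.

    ``Y_A`` and ``Y_AB_k`` have shape (N, N_t); ``V`` is the pooled per-time
    variance.  Returns an (N_t,) series, NaN where ``V`` is zero.
    """
    Y_A = np.asarray(Y_A, dtype=float)
    Y_AB_k = np.asarray(Y_AB_k, dtype=float)
    if Y_A.shape != Y_AB_k.shape:
        raise ValueError("Y_A and Y_AB_k must have matching shapes")
    V = np.asarray(V, dtype=float)
    num = 0.5 * np.mean((Y_A - Y_AB_k) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(V > 0.0, num / np.where(V > 0.0, V, 1.0), np.nan)
    return out


def _mean_outputs(theta_row: np.ndarray, names, scenario, config, mesh,
                  seeds: np.ndarray) -> dict[str, np.ndarray]:
    """Mean live/dead trajectory over the replicate seeds for one design row."""
    theta = {n: config.theta[n] for n in THETA_NAMES}
    D = config.D
    k_val = config.k
    for name, val in zip(names, theta_row):
        if name == "D":
            D = float(val)
        elif name == "k":
            k_val = float(val)
        else:
            theta[name] = float(val)
    cfg = config.with_theta(theta, D=D, k=k_val)
    live = dead = None
    for s in seeds:
        tr = run(scenario, cfg, int(s), mesh=mesh)
        if live is None:
            live = tr.live_confluence.copy()
            dead = tr.dead_confluence.copy()
        else:
            live += tr.live_confluence
            dead += tr.dead_confluence
    return {"live": live / len(seeds), "dead": dead / len(seeds)}


def run_sobol(scenario: ScenarioSpec, ranges: dict[str, tuple[float, float]],
              N: int, N_r: int,
              rng: np.random.Generator | int | None = None,
              config: SimulationConfig | None = None,
              checkpoint: str | Path | None = None) -> SobolResult:
    """Time-resolved total-effect indices of the stochastic simulator.

    Each of the N(K+1) design rows is evaluated as the mean over ``N_r``
    seeded realizations.  With ``checkpoint`` set, partial evaluations are
    saved to an ``.npz`` after each matrix and reloaded on restart.
    """
    rng = np.random.default_rng(rng)
    design = build_design(ranges, N, rng)
    if config is None:
        config = SimulationConfig()
    mesh = build_disc_mesh(scenario.well_radius, config.mesh_target_elements,
                           seed=config.mesh_seed)
    n_t = scenario.times.size
    K = design.K
    # one replicate-seed set shared by every design row (common random
    # numbers): identical parameter rows give identical outputs, so the
    # Jansen numerator measures parameter effects, not replicate noise
    rep_seeds = rng.integers(0, 2**31 - 1, size=N_r)

    outputs = ("live", "dead")
    Y = {o: np.full((K + 1, N, n_t), np.nan) for o in outputs}
    start_block = 0
    if checkpoint is not None and Path(checkpoint).exists():
        saved = np.load(checkpoint)
        for o in outputs:
            Y[o] = saved[o]
        start_block = int(saved["next_block"])

    def eval_matrix(block: int, rows: np.ndarray) -> None:
        for j in range(N):
            out = _mean_outputs(rows[j], design.names, scenario, config, mesh,
                                rep_seeds)
            for o in outputs:
                Y[o][block, j] = out[o]
        if checkpoint is not None:
            np.savez(checkpoint, next_block=block + 1, **Y)

    for block in range(start_block, K + 1):
        rows = design.A if block == 0 else design.AB(block - 1)
        eval_matrix(block, rows)

    # pooled variance needs Y_B as well
    YB = {o: np.empty((N, n_t)) for o in outputs}
    for j in range(N):
        out = _mean_outputs(design.B[j], design.names, scenario, config, mesh,
                            rep_seeds)
        for o in outputs:
            YB[o][j] = out[o]

    S_T = {}
    variance = {}
    for o in outputs:
        pooled = np.vstack([Y[o][0], YB[o]])
        V = pooled.var(axis=0, ddof=1)
        variance[o] = V
        st = np.empty((K, n_t))
        for k in range(K):
            st[k] = total_effect(Y[o][0], Y[o][k + 1], V)
        S_T[o] = st
    return SobolResult(times=scenario.times, names=design.names, S_T=S_T,
                       variance=variance, N=N, N_r=N_r)


def default_gsa_ranges() -> dict[str, tuple[float, float]]:
    """The seven screened parameters with their published uniform ranges."""
    return {n: PRIOR_BOUNDS[n] for n in GSA_NAMES}
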