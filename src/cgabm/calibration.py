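"""Moment-based Bayesian calibration of the stochastic simulator.

The simulator is stochastic, so the likelihood compares replicate means: for
each time point and output the model mean over N_r seeded realizations is
matched to the data mean over the experimental replicates under a Gaussian
whose variance combines the data spread and the model spread,

    sigma_i^2 = (sigma_i^D)^2 + (sigma_i^d)^2 ,
    ln L = sum_i [ -1/2 ln(2 pi) - ln(sigma_i) - 1/2 ((mu_i^d - mu_i^D)/sigma_i)^2 ] ,

summed over time points and over the live and dead outputs.  Priors are the
published uniform boxes on (alpha_P_bar, alpha_D_bar, lambda, gamma_D,
sigma_H); the diffusion coefficient and switch sharpness are held fixed.
Replicate seeds are drawn once per problem and shared by every likelihood
evaluation (common random numbers), making the log posterior a deterministic
function of theta.  Sampling uses the affine-invariant ensemble sampler with
one walker per chain; the point estimate is the posterior mode of a kernel
density estimate over the pooled post-burn-in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.optimize import minimize
from scipy.stats import gaussian_kde

from .microenvironment import DiscMesh, build_disc_mesh
from .params import PRIOR_BOUNDS, SimulationConfig, THETA_NAMES, theta_dict
from .simulator import ScenarioSpec, Trajectory, run

__all__ = ["MomentSummary", "CalibrationProblem", "Posterior", "model_moments",
           "data_moments", "log_likelihood", "log_posterior", "run_mcmc",
           "map_estimate"]

SIGMA_FLOOR = 1e-4  # confluence units; keeps sigma_i^2 > 0 at quiet time points


@dataclass
class MomentSummary:
    """Per-time replicate means and standard deviations for live/dead outputs.

    Either side (model or data) of the likelihood; arrays are (N_t,) per
    output key.
    """

    mu: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_replicates: int
    times: np.ndarray

    @property
    def outputs(self) -> tuple[str, ...]:
        return tuple(self.mu)


@dataclass
class CalibrationProblem:
    """Scenarios, data, priors and replication settings for one calibration."""

    scenarios: list[tuple[ScenarioSpec, MomentSummary]]
    config: SimulationConfig
    N_r: int = 16
    seed: int = 0
    output_weights: dict[str, float] = field(
        default_factory=lambda: {"live": 1.0, "dead": 1.0})
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {n: PRIOR_BOUNDS[n] for n in THETA_NAMES})
    _meshes: dict = field(default_factory=dict, repr=False)
    _rep_seeds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.N_r < 2:
            raise ValueError("N_r must be at least 2")

    def replicate_seeds(self) -> np.ndarray:
        """Common-random-number seeds shared by every likelihood evaluation."""
        if self._rep_seeds is None:
            self._rep_seeds = np.random.default_rng(self.seed).integers(
                0, 2**31 - 1, size=self.N_r)
        return self._rep_seeds

    def mesh_for(self, scenario: ScenarioSpec) -> DiscMesh:
        key = (scenario.well_radius, self.config.mesh_target_elements)
        if key not in self._meshes:
            self._meshes[key] = build_disc_mesh(
                scenario.well_radius, self.config.mesh_target_elements,
                seed=self.config.mesh_seed)
        return self._meshes[key]


def model_moments(theta, scenario: ScenarioSpec, N_r: int,
                  config: SimulationConfig,
                  seeds: np.ndarray | None = None,
                  mesh: DiscMesh | None = None,
                  rng: np.random.Generator | int | None = None) -> MomentSummary:
    """Replicate mean and ddof=1 std of the simulator at ``theta``."""
    if N_r < 2:
        raise ValueError("N_r must be at least 2")
    if seeds is None:
        seeds = np.random.default_rng(rng).integers(0, 2**31 - 1, size=N_r)
    cfg = config.with_theta(theta if isinstance(theta, dict) else theta_dict(theta))
    live = np.empty((N_r, scenario.times.size))
    dead = np.empty_like(live)
    for j, s in enumerate(seeds):
        tr = run(scenario, cfg, int(s), mesh=mesh)
        live[j] = tr.live_confluence
        dead[j] = tr.dead_confluence
    return MomentSummary(
        mu={"live": live.mean(0), "dead": dead.mean(0)},
        sd={"live": live.std(0, ddof=1), "dead": dead.std(0, ddof=1)},
        n_replicates=N_r, times=scenario.times)


def data_moments(replicates: list[Trajectory]) -> MomentSummary:
    """Per-time mean and ddof=1 std across experimental replicates."""
    if len(replicates) < 2:
        raise ValueError("need at least two replicates on a common grid")
    times = replicates[0].times
    for tr in replicates[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError("replicates are not on a common time grid")
    live = np.vstack([tr.live_confluence for tr in replicates])
    dead = np.vstack([tr.dead_confluence for tr in replicates])
    return MomentSummary(
        mu={"live": live.mean(0), "dead": dead.mean(0)},
        sd={"live": live.std(0, ddof=1), "dead": dead.std(0, ddof=1)},
        n_replicates=len(replicates), times=times)


def log_likelihood(model: MomentSummary, data: MomentSummary,
                   output_weights: dict[str, float] | None = None,
                   half_log_2pi_sign: int = -1) -> float:
    """Gaussian moment-matching log likelihood, summed over times and outputs.

    ``half_log_2pi_sign`` exposes the sign of the 1/2 ln(2 pi) constant; it
    shifts the value by a constant and has no effect on sampling or the MAP.
    """
    if model.times.shape != data.times.shape or not np.allclose(model.times,
                                                                data.times):
        raise ValueError("model and data summaries are on different grids")
    total = 0.0
    for out in data.outputs:
        if out not in model.mu:
            raise ValueError(f"model summary lacks output {out!r}")
        w = 1.0 if output_weights is None else output_weights.get(out, 1.0)
        if w == 0.0:
            continue
        var = data.sd[out] ** 2 + model.sd[out] ** 2
        sigma = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        resid = (model.mu[out] - data.mu[out]) / sigma
        if not np.all(np.isfinite(resid)):
            raise FloatingPointError("non-finite residual in likelihood")
        total += w * float(np.sum(
            half_log_2pi_sign * 0.5 * np.log(2.0 * np.pi)
            - np.log(sigma) - 0.5 * resid**2))
    return total


def log_posterior(theta, problem: CalibrationProblem) -> float:
    """Uniform-prior log posterior; -inf outside the prior box."""
    theta = np.asarray(theta, dtype=float)
    td = theta_dict(theta)
    for name in THETA_NAMES:
        lo, hi = problem.bounds[name]
        if not lo <= td[name] <= hi:
            return -np.inf
    if td["sigma_H"] >= 1.0:  # proliferation ramp degenerates at the edge
        return -np.inf
    seeds = problem.replicate_seeds()
    total = 0.0
    for scenario, data in problem.scenarios:
        mm = model_moments(td, scenario, problem.N_r, problem.config,
                           seeds=seeds, mesh=problem.mesh_for(scenario))
        total += log_likelihood(mm, data, problem.output_weights)
    return total


@dataclass
class Posterior:
    """MCMC output: per-chain samples, diagnostics and the MAP point."""

    samples: np.ndarray           # (chains, draws, 5) post burn-in
    log_posterior: np.ndarray     # (chains, draws)
    acceptance: np.ndarray        # (chains,)
    r_hat: dict[str, float]
    theta_MAP: dict[str, float]
    kde_bandwidth: float
    names: tuple[str, ...] = THETA_NAMES

    def pooled(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[-1])

    def credible_interval(self, name: str, level: float = 0.95):
        j = self.names.index(name)
        lo = 100 * (1.0 - level) / 2.0
        flat = self.pooled()[:, j]
        return tuple(np.percentile(flat, [lo, 100 - lo]))


def _split_r_hat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter for (n_chains, n_draws, dim) samples."""
    n_c, n_d, dim = chains.shape
    half = n_d // 2
    parts = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = parts.shape[0], parts.shape[1]
    means = parts.mean(axis=1)
    B = n * means.var(axis=0, ddof=1)
    W = parts.var(axis=1, ddof=1).mean(axis=0)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(W > 0, np.sqrt(var_hat / np.maximum(W, 1e-300)), 1.0)


def maximize_posterior(problem: CalibrationProblem, n_random: int = 200,
                       n_refine: int = 150,
                       rng: np.random.Generator | int | None = None,
                       log_prob=None, extra_starts=()) -> np.ndarray:
    """Approximate posterior mode: prior random search plus local refinement.

    With common random numbers the log posterior is deterministic in theta,
    so Nelder-Mead refinement of the best search draws is meaningful.  The
    rate parameters live orders of magnitude below their prior widths, so
    half the search draws each coordinate log-uniformly over three decades;
    refinement is multi-start (the posterior of a mechanistic model often
    has competing ridges).  ``extra_starts`` adds caller-supplied start
    points, e.g. a mode found on a cheaper sub-problem.
    """
    rng = np.random.default_rng(rng)
    if log_prob is None:
        def log_prob(th):  # noqa: ANN001
            return log_posterior(th, problem)
    lo = np.array([problem.bounds[n][0] for n in THETA_NAMES])
    hi = np.array([problem.bounds[n][1] for n in THETA_NAMES])
    n_uni = n_random // 2
    uni = rng.random((n_uni, lo.size))
    logu = 10.0 ** rng.uniform(-3.0, 0.0, (n_random - n_uni, lo.size))
    draws = lo + (hi - lo) * np.vstack([uni, logu])
    vals = np.array([log_prob(d) for d in draws])

    eps = 1e-9 * (hi - lo)

    def neg(th):
        th = np.clip(th, lo, hi - eps)
        v = log_prob(th)
        return np.inf if not np.isfinite(v) else -v

    order = np.argsort(vals)[::-1][:3]
    starts = [np.asarray(s, dtype=float) for s in extra_starts]
    starts += [draws[idx] for idx in order]
    best_x = starts[0]
    best_v = np.inf
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxfev": n_refine, "xatol": 1e-6,
                                "fatol": 1e-3})
        if np.isfinite(res.fun) and res.fun < best_v:
            best_v = res.fun
            best_x = np.clip(res.x, lo, hi - eps)
    return best_x


def run_mcmc(problem: CalibrationProblem, n_chains: int = 16,
             n_steps: int = 2000,
             rng: np.random.Generator | int | None = None,
             burn_fraction: float = 0.5,
             log_prob=None,
             init_theta=None) -> Posterior:
    """Sample the posterior with an affine-invariant ensemble of chains.

    ``log_prob`` may override the target (used by the synthetic-target
    tests); it defaults to :func:`log_posterior` on ``problem``.  Half of the
    steps are discarded as burn-in.  Without ``init_theta`` walkers start
    from prior draws; with it (typically :func:`maximize_posterior` output)
    they start spread around the mode by a tenth of each prior width, which
    converges far faster when the posterior is sharp.
    """
    if n_chains < 2:
        raise ValueError("need at least two chains")
    ndim = len(THETA_NAMES)
    if n_chains < 2 * ndim:
        n_chains = 2 * ndim  # ensemble moves need a wide complement
    rng = np.random.default_rng(rng)
    if log_prob is None:
        def log_prob(th):  # noqa: ANN001
            return log_posterior(th, problem)

    lo = np.array([problem.bounds[n][0] for n in THETA_NAMES])
    hi = np.array([problem.bounds[n][1] for n in THETA_NAMES])
    if init_theta is None:
        # start walkers from the prior itself: weakly identified directions
        # then stay prior-distributed instead of inheriting a cluster
        center = lo + (hi - lo) * rng.random((n_chains, ndim))
    else:
        init_theta = np.asarray(init_theta, dtype=float)
        spread = 0.1 * (hi - lo)
        center = init_theta + spread * rng.standard_normal((n_chains, ndim))
        center = np.clip(center, lo + 1e-12 * (hi - lo),
                         hi - 1e-12 * (hi - lo))
    sampler = emcee.EnsembleSampler(n_chains, ndim, log_prob)
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)).get_state()
    sampler.run_mcmc(center, n_steps, progress=False)

    burn = int(burn_fraction * n_steps)
    chain = np.swapaxes(sampler.get_chain(discard=burn), 0, 1)  # (chains, draws, d)
    logp = np.swapaxes(sampler.get_log_prob(discard=burn), 0, 1)
    if not np.any(np.isfinite(logp)):
        raise RuntimeError("all chains rejected every proposal; check the model")
    rhat = _split_r_hat(chain)
    theta_map, bw = map_estimate_from_samples(chain.reshape(-1, ndim))
    return Posterior(samples=chain, log_posterior=logp,
                     acceptance=sampler.acceptance_fraction.copy(),
                     r_hat={n: float(r) for n, r in zip(THETA_NAMES, rhat)},
                     theta_MAP=theta_dict(theta_map), kde_bandwidth=bw)


def map_estimate_from_samples(flat: np.ndarray,
                              max_eval: int = 2000) -> tuple[np.ndarray, float]:
    """Posterior mode of a Gaussian KDE over pooled samples, with refinement."""
    flat = np.asarray(flat, dtype=float)
    if flat.shape[0] < 100:
        raise ValueError("need at least 100 post-burn-in samples for the MAP")
    spread = flat.std(axis=0)
    if np.all(spread < 1e-12):  # degenerate posterior: a point mass
        return flat[0].copy(), 0.0
    keep = spread > 1e-12
    kde = gaussian_kde(flat[:, keep].T)
    sub = flat[:: max(1, flat.shape[0] // max_eval)]
    dens = kde(sub[:, keep].T)
    best = sub[int(np.argmax(dens))].copy()

    def neg(v):
        return -kde(v)[0]

    res = minimize(neg, best[keep], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    out = best.copy()
    if res.success and np.isfinite(res.fun):
        out[keep] = res.x
    return out, float(kde.factor)


def map_estimate(posterior: Posterior) -> dict[str, float]:
    """MAP point of an existing posterior (KDE argmax over pooled samples)."""
    theta, _ = map_estimate_from_samples(posterior.pooled())
    return theta_dict(theta)


def leave_one_out_problem(problem: CalibrationProblem,
                          hold_out: str) -> CalibrationProblem:
    """The same problem without the named scenario (prediction design)."""
    kept = [(s, d) for s, d in problem.scenarios if s.name != hold_out]
    if len(kept) == len(problem.scenarios):
        raise ValueError(f"scenario {hold_out!r} not present")
    return CalibrationProblem(scenarios=kept, config=problem.config,
                              N_r=problem.N_r, seed=problem.seed,
                              output_weights=dict(problem.output_weights),
                              bounds=dict(problem.bounds))
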