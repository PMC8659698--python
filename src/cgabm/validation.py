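"""CDF-distance error metric and the model validity test.

The error between model and data at one time point is the L1 distance
between the empirical cumulative distribution functions of confluence —
the model distribution taken over simulation realizations, the data
distribution over experimental replicates — normalized by the mean total
confluence of the data, Phi:

    M = integral |Pi^d(phi) - Pi^D(phi)| dphi / Phi .

The integral of the absolute CDF difference equals the 1-Wasserstein
distance between the empirical distributions.  The model is deemed valid
for prediction when the time average of M stays below a stated tolerance
(10% is the working value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .simulator import Trajectory

__all__ = ["ErrorReport", "cdf_l1_distance", "trajectory_error", "mean_total_confluence"]


@dataclass
class ErrorReport:
    """Per-output validity report of a calibrated model against data."""

    output: str
    M_t: np.ndarray          # metric per time point
    M_mean: float            # time average
    M_sd_time: float         # spread of M_t across time points
    Phi: float               # mean total confluence of the data
    eps_tol: float
    valid: bool


def cdf_l1_distance(model_samples, data_samples, Phi: float) -> float:
    """L1 distance between empirical CDFs divided by Phi (a scaled W1)."""
    model_samples = np.asarray(model_samples, dtype=float).ravel()
    data_samples = np.asarray(data_samples, dtype=float).ravel()
    if model_samples.size == 0 or data_samples.size == 0:
        raise ValueError("need at least one sample on each side")
    if Phi <= 0:
        raise ValueError("Phi must be positive")
    return float(wasserstein_distance(model_samples, data_samples)) / Phi


def mean_total_confluence(data_replicates: list[Trajectory]) -> float:
    """Phi: live+dead confluence averaged over data replicates and times."""
    tot = [tr.live_confluence + tr.dead_confluence for tr in data_replicates]
    return float(np.mean(tot))


def trajectory_error(model_realizations: list[Trajectory],
                     data_replicates: list[Trajectory],
                     eps_tol: float = 0.10,
                     Phi: float | None = None) -> dict[str, ErrorReport]:
    """Per-time CDF-distance errors and the validity verdict per output.

    Model realizations are typically simulations at parameter draws from the
    calibration posterior, so their spread carries both parameter and
    simulator uncertainty; data replicates carry measurement variability.
    """
    if not model_realizations or not data_replicates:
        raise ValueError("need model realizations and data replicates")
    times = data_replicates[0].times
    for tr in list(model_realizations) + list(data_replicates):
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError("trajectories are not on a common time grid")
    if Phi is None:
        Phi = mean_total_confluence(data_replicates)

    reports = {}
    for output in ("live", "dead"):
        attr = f"{output}_confluence"
        model = np.vstack([getattr(tr, attr) for tr in model_realizations])
        data = np.vstack([getattr(tr, attr) for tr in data_replicates])
        M_t = np.array([
            cdf_l1_distance(model[:, i], data[:, i], Phi)
            for i in range(times.size)
        ])
        M_mean = float(M_t.mean())
        reports[output] = ErrorReport(
            output=output, M_t=M_t, M_mean=M_mean,
            M_sd_time=float(M_t.std(ddof=1)) if M_t.size > 1 else 0.0,
            Phi=float(Phi), eps_tol=float(eps_tol),
            valid=bool(M_mean <= eps_tol))
    return reports
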