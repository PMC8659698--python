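"""Cell-scale force laws and overdamped motion.

Agents interact through a short-range adhesion potential, active below the
summed action radii, and a repulsion potential, active below the summed cell
radii and stiffening once the incompressible nuclei overlap.  Inertia is
neglected, so each agent moves with velocity ``F / nu`` and positions are
advanced by forward Euler at one-minute substeps until the configuration is
mechanically relaxed.

Sign convention: :func:`adhesion_gradient` points toward the neighbour and
:func:`repulsion_gradient` away from it, so the net pairwise force on agent
``i`` from ``j`` is ``c_cca * adhesion_gradient + c_ccr * repulsion_gradient``
evaluated at ``l = x_j - x_i`` — adhesion attracts, repulsion repels.  The
same potentials, with the agent's own (un-summed) radii and the vector to the
nearest point of the circular wall, give the boundary forces; the wall is
non-permeable, so agents are additionally clamped inside the well.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .params import MechanicsParams
from .population import Population

__all__ = [
    "DegenerateDirectionError",
    "adhesion_gradient",
    "repulsion_gradient",
    "net_velocity",
    "velocities_all_pairs",
    "velocities_grid",
    "relax_positions",
    "equilibrium_distance",
]


class DegenerateDirectionError(ValueError):
    """Raised when a force direction is undefined (zero separation)."""


def _unit(l_vec: np.ndarray) -> tuple[np.ndarray, float]:
    l_vec = np.asarray(l_vec, dtype=float)
    d = float(np.hypot(l_vec[0], l_vec[1]))
    if d == 0.0:
        raise DegenerateDirectionError("zero separation: direction undefined")
    return l_vec / d, d


def adhesion_gradient(l_vec, RA_sum: float) -> np.ndarray:
    """Adhesion potential gradient: (|l|/RA - 1)^2 * l/|l| inside the action range.

    Zero beyond ``RA_sum``; vanishes continuously at the range boundary.
    """
    if RA_sum <= 0:
        raise ValueError("RA_sum must be positive")
    lhat, d = _unit(l_vec)
    if d > RA_sum:
        return np.zeros(2)
    return (d / RA_sum - 1.0) ** 2 * lhat


def repulsion_gradient(l_vec, RN_sum: float, R_sum: float) -> np.ndarray:
    """Repulsion potential gradient, pointing away from the neighbour.

    Quadratic ``-(|l|/R - 1)^2`` between nuclear contact and cell contact,
    continued linearly (bounded) once the incompressible nuclei overlap, zero
    beyond cell contact.  Continuous at ``|l| = RN_sum``.
    """
    if not 0.0 < RN_sum < R_sum:
        raise ValueError("need 0 < RN_sum < R_sum")
    lhat, d = _unit(l_vec)
    if d >= R_sum:
        return np.zeros(2)
    if d <= RN_sum:
        mag = 1.0 - d * (2.0 * R_sum - RN_sum) / R_sum**2
    else:
        mag = (1.0 - d / R_sum) ** 2
    return -mag * lhat


def _repulsion_magnitude(d: float, RN_sum: float, R_sum: float) -> float:
    if d >= R_sum:
        return 0.0
    if d <= RN_sum:
        return 1.0 - d * (2.0 * R_sum - RN_sum) / R_sum**2
    return (1.0 - d / R_sum) ** 2


def velocities_all_pairs(population: Population, well_radius: float,
                         params: MechanicsParams) -> np.ndarray:
    """Reference O(N^2) evaluation of every agent velocity (um/min)."""
    n = len(population)
    x = population.x
    R = population.radius
    RN = population.nuclear_radius
    RA = population.action_radius
    f = np.zeros((n, 2))
    for i in range(n):
        for j in range(i + 1, n):
            l = x[j] - x[i]
            d = float(np.hypot(l[0], l[1]))
            RAs = RA[i] + RA[j]
            if d > RAs:
                continue
            if d == 0.0:
                raise DegenerateDirectionError(
                    f"agents {i} and {j} have coincident centers"
                )
            lhat = l / d
            mag = 0.0
            if d < RAs:
                mag += params.c_cca * (d / RAs - 1.0) ** 2
            mag -= params.c_ccr * _repulsion_magnitude(d, RN[i] + RN[j], R[i] + R[j])
            f[i] += mag * lhat
            f[j] -= mag * lhat
        # boundary: vector from center to the nearest wall point
        r = float(np.hypot(x[i, 0], x[i, 1]))
        dist = well_radius - r
        if r > 1e-12 and (dist < RA[i] or dist < R[i]):
            out = x[i] / r
            mag = 0.0
            if dist < RA[i]:
                mag += params.c_ct * (dist / RA[i] - 1.0) ** 2
            mag -= params.c_rct * _repulsion_magnitude(max(dist, 0.0), RN[i], R[i])
            f[i] += mag * out
    return f / params.nu


def net_velocity(agent_index: int, population: Population, well_radius: float,
                 params: MechanicsParams) -> np.ndarray:
    """Velocity (um/min) of one agent from the full force balance."""
    return velocities_all_pairs(population, well_radius, params)[agent_index]


@njit(cache=True, fastmath=True)
def _forces_grid(x, R, RN, RA, W, c_cca, c_ccr, c_ct, c_rct):
    """Pairwise + boundary forces via a uniform spatial grid (exact).

    Half-stencil iteration: each pair is visited once and applied with
    action-reaction, so the result equals the all-pairs computation.
    """
    n = x.shape[0]
    f = np.zeros((n, 2))
    if n == 0:
        return f
    ra_max = 0.0
    for i in range(n):
        if RA[i] > ra_max:
            ra_max = RA[i]
    cutoff = 2.0 * ra_max
    ncell = int((2.0 * W) / cutoff)
    if ncell < 1:
        ncell = 1
    if ncell > 512:
        ncell = 512
    cs = 2.0 * W / ncell
    # counting sort of agents into grid cells
    cell = np.empty(n, np.int64)
    for i in range(n):
        ix = int((x[i, 0] + W) / cs)
        iy = int((x[i, 1] + W) / cs)
        if ix < 0:
            ix = 0
        elif ix >= ncell:
            ix = ncell - 1
        if iy < 0:
            iy = 0
        elif iy >= ncell:
            iy = ncell - 1
        cell[i] = iy * ncell + ix
    counts = np.zeros(ncell * ncell + 1, np.int64)
    for i in range(n):
        counts[cell[i] + 1] += 1
    for c in range(1, ncell * ncell + 1):
        counts[c] += counts[c - 1]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        order[fill[cell[i]]] = i
        fill[cell[i]] += 1

    # half stencil: same cell (j > i), then E, NW, N, NE neighbour cells
    for cy in range(ncell):
        for cx in range(ncell):
            c = cy * ncell + cx
            p0 = counts[c]
            p1 = counts[c + 1]
            if p0 == p1:
                continue
            for s in range(5):
                if s == 0:
                    nx, ny = cx, cy
                elif s == 1:
                    nx, ny = cx + 1, cy
                elif s == 2:
                    nx, ny = cx - 1, cy + 1
                elif s == 3:
                    nx, ny = cx, cy + 1
                else:
                    nx, ny = cx + 1, cy + 1
                if nx < 0 or nx >= ncell or ny < 0 or ny >= ncell:
                    continue
                d_cell = ny * ncell + nx
                q0 = counts[d_cell]
                q1 = counts[d_cell + 1]
                for a in range(p0, p1):
                    i = order[a]
                    xi = x[i, 0]
                    yi = x[i, 1]
                    Ri = R[i]
                    RNi = RN[i]
                    RAi = RA[i]
                    b0 = a + 1 if s == 0 else q0
                    for b in range(b0, q1):
                        j = order[b]
                        lx = x[j, 0] - xi
                        ly = x[j, 1] - yi
                        RAs = RAi + RA[j]
                        d2 = lx * lx + ly * ly
                        if d2 > RAs * RAs:
                            continue
                        d = np.sqrt(d2)
                        if d < 1e-9:
                            # coincident centers: deterministic seeded-style
                            # 1e-3 um push along a hashed direction
                            ang = 1e-4 * ((i * 2654435761 + j * 40503) % 62832)
                            lx = 1e-3 * np.cos(ang)
                            ly = 1e-3 * np.sin(ang)
                            d = 1e-3
                        mag = 0.0
                        if d < RAs:
                            mag += c_cca * (d / RAs - 1.0) ** 2
                        Rs = Ri + R[j]
                        if d < Rs:
                            RNs = RNi + RN[j]
                            if d <= RNs:
                                mag -= c_ccr * (1.0 - d * (2.0 * Rs - RNs)
                                                / Rs**2)
                            else:
                                mag -= c_ccr * (1.0 - d / Rs) ** 2
                        ux = mag * lx / d
                        uy = mag * ly / d
                        f[i, 0] += ux
                        f[i, 1] += uy
                        f[j, 0] -= ux  # Newton's third law
                        f[j, 1] -= uy

    # boundary forces against the circular wall
    for i in range(n):
        xi = x[i, 0]
        yi = x[i, 1]
        r = np.sqrt(xi * xi + yi * yi)
        if r > 1e-12:
            dist = W - r
            if dist < 0.0:
                dist = 0.0
            if dist < RA[i] or dist < R[i]:
                ox = xi / r
                oy = yi / r
                mag = 0.0
                if dist < RA[i]:
                    mag += c_ct * (dist / RA[i] - 1.0) ** 2
                if dist < R[i]:
                    if dist <= RN[i]:
                        mag -= c_rct * (1.0 - dist * (2.0 * R[i] - RN[i])
                                        / R[i]**2)
                    else:
                        mag -= c_rct * (1.0 - dist / R[i]) ** 2
                f[i, 0] += mag * ox
                f[i, 1] += mag * oy
    return f


@njit(cache=True)
def _relax_kernel(x, R, RN, RA, W, c_cca, c_ccr, c_ct, c_rct, nu,
                  dt, max_steps, tol):
    """Forward-Euler relaxation; stops when max displacement < tol."""
    n = x.shape[0]
    steps = 0
    for _ in range(max_steps):
        f = _forces_grid(x, R, RN, RA, W, c_cca, c_ccr, c_ct, c_rct)
        maxdisp = 0.0
        for i in range(n):
            dx = f[i, 0] / nu * dt
            dy = f[i, 1] / nu * dt
            x[i, 0] += dx
            x[i, 1] += dy
            r = np.sqrt(x[i, 0] ** 2 + x[i, 1] ** 2)
            if r > W:  # non-permeable wall
                x[i, 0] *= W / r
                x[i, 1] *= W / r
            disp = np.sqrt(dx * dx + dy * dy)
            if disp > maxdisp:
                maxdisp = disp
        steps += 1
        if maxdisp < tol:
            break
    return steps


def velocities_grid(population: Population, well_radius: float,
                    params: MechanicsParams) -> np.ndarray:
    """Grid-accelerated velocities; exactly equals :func:`velocities_all_pairs`."""
    f = _forces_grid(population.x, population.radius,
                     population.nuclear_radius, population.action_radius,
                     float(well_radius), params.c_cca, params.c_ccr,
                     params.c_ct, params.c_rct)
    return f / params.nu


def relax_positions(population: Population, duration: float, well_radius: float,
                    params: MechanicsParams, rng=None) -> Population:
    """Relax agent positions for ``duration`` minutes (in place).

    Substeps of ``params.relax_substep`` minutes; terminates early once the
    largest per-substep displacement falls below ``params.relax_tol`` um.
    ``duration`` must be a whole number of substeps.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_steps = duration / params.relax_substep
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("duration must be a multiple of relax_substep")
    n_steps = int(round(n_steps))
    if n_steps == 0 or len(population) == 0:
        return population
    _relax_kernel(population.x, population.radius, population.nuclear_radius,
                  population.action_radius, float(well_radius),
                  params.c_cca, params.c_ccr, params.c_ct, params.c_rct,
                  params.nu, params.relax_substep, n_steps, params.relax_tol)
    return population


def equilibrium_distance(c_adh: float, c_rep: float, R_N: float, R: float,
                         R_A: float, *, xtol: float = 1e-9) -> float | None:
    """Center separation where adhesion and repulsion balance, or ``None``.

    Solves ``c_adh (1 - l/R_A)^2 = c_rep (1 - l/R)^2`` for the smallest root
    on the cell-contact branch ``(R_N, R)`` by bracketing and bisection.
    Rest separations with overlapping nuclei are not physical equilibria and
    are excluded from the search.
    """
    if not 0.0 < R_N < R < R_A:
        raise ValueError("need 0 < R_N < R < R_A")
    if c_adh <= 0 or c_rep <= 0:
        raise ValueError("coefficients must be positive")

    def g(l: float) -> float:
        return c_adh * (1.0 - l / R_A) ** 2 - c_rep * _repulsion_magnitude(l, R_N, R)

    grid = np.linspace(R_N, R, 4001)
    vals = np.array([g(l) for l in grid])
    sign = np.sign(vals)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if crossings.size == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if exact.size and 0 < exact[0] < len(grid) - 1:
            return float(grid[exact[0]])
        return None
    a, b = grid[crossings[0]], grid[crossings[0] + 1]
    return float(brentq(g, a, b, xtol=xtol))
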