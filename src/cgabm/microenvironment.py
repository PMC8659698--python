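"""Tissue-scale glucose transport on the circular well.

Normalized glucose (1.0 == 10 mM) obeys a reaction-diffusion equation,
``d(sigma)/dt = div(D grad sigma) - lambda * rho_t * sigma``, with a no-flux
wall: neither glucose nor cells leave the well.  ``rho_t`` is the local area
fraction occupied by live agents and couples the cell scale into the uptake
sink.

Discretization: linear (P1) triangular finite elements with a lumped mass
matrix and implicit Euler in time.  On Delaunay meshes the stiffness matrix is
an M-matrix, so the scheme preserves positivity and a discrete maximum
principle; with a spatially uniform field and full occupancy the update
reduces exactly to the scalar decay ``sigma / (1 + lambda dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from matplotlib.tri import LinearTriInterpolator, TrapezoidMapTriFinder, Triangulation
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay, cKDTree

from .population import Population

__all__ = ["DiscMesh", "NutrientField", "build_disc_mesh", "live_fraction_field",
           "diffusion_step"]


@dataclass
class DiscMesh:
    """P1 triangulation of the culture-well disc (lengths in um)."""

    nodes: np.ndarray          # (n, 2)
    triangles: np.ndarray      # (nt, 3) CCW
    element_areas: np.ndarray  # (nt,)
    boundary: np.ndarray       # (n,) bool
    well_radius: float
    _tri: Triangulation | None = field(default=None, repr=False)
    _finder: TrapezoidMapTriFinder | None = field(default=None, repr=False)
    _node_tree: cKDTree | None = field(default=None, repr=False)
    _stiffness: sp.csr_matrix | None = field(default=None, repr=False)
    _lumped_mass: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def triangulation(self) -> Triangulation:
        if self._tri is None:
            self._tri = Triangulation(self.nodes[:, 0], self.nodes[:, 1],
                                      self.triangles)
        return self._tri

    @property
    def finder(self) -> TrapezoidMapTriFinder:
        if self._finder is None:
            self._finder = self.triangulation.get_trifinder()
        return self._finder

    def find_elements(self, points: np.ndarray) -> np.ndarray:
        """Element index containing each point; nearest element if outside hull."""
        points = np.atleast_2d(points)
        idx = np.asarray(self.finder(points[:, 0], points[:, 1]))
        missing = idx < 0
        if missing.any():
            # points in the thin sliver between the polygonal hull and the
            # true circle: snap to the element of the nearest mesh node
            if self._node_tree is None:
                self._node_tree = cKDTree(self.nodes)
            _, nearest = self._node_tree.query(points[missing])
            node_elem = np.full(self.n_nodes, -1)
            for e, tri in enumerate(self.triangles):
                for v in tri:
                    if node_elem[v] < 0:
                        node_elem[v] = e
            idx[missing] = node_elem[nearest]
        return idx

    def fem_operators(self) -> tuple[sp.csr_matrix, np.ndarray]:
        """(stiffness with unit diffusivity, lumped mass vector)."""
        if self._stiffness is None:
            n = self.n_nodes
            tris = self.triangles
            p = self.nodes
            rows, cols, vals = [], [], []
            lumped = np.zeros(n)
            for t, area in zip(tris, self.element_areas):
                x = p[t, 0]
                y = p[t, 1]
                b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
                c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
                ke = (np.outer(b, b) + np.outer(c, c)) / (4.0 * area)
                for a_loc in range(3):
                    lumped[t[a_loc]] += area / 3.0
                    for b_loc in range(3):
                        rows.append(t[a_loc])
                        cols.append(t[b_loc])
                        vals.append(ke[a_loc, b_loc])
            K = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
            self._stiffness = K
            self._lumped_mass = lumped
        return self._stiffness, self._lumped_mass


def _ring_points(radius: float, h: float, rng: np.random.Generator):
    """Quasi-uniform disc point cloud: center, jittered rings, boundary ring."""
    n_rings = max(1, int(round(radius / h)))
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        n_k = max(6, int(round(2.0 * np.pi * r / h)))
        offs = np.pi * (k % 2) / n_k
        ang = 2.0 * np.pi * np.arange(n_k) / n_k + offs
        ring = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        if k < n_rings:  # jitter interior rings to break cocircular ties
            ring += 0.05 * h * rng.standard_normal(ring.shape)
            rr = np.hypot(ring[:, 0], ring[:, 1])
            over = rr > 0.995 * radius
            if over.any():
                ring[over] *= (0.995 * radius / rr[over])[:, None]
        pts.append(ring)
    boundary_count = pts[-1].shape[0]
    return np.vstack(pts), boundary_count


def build_disc_mesh(radius: float, target_elements: int, seed: int = 0) -> DiscMesh:
    """Triangulate the disc with approximately ``target_elements`` elements."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if target_elements < 16:
        raise ValueError("target_elements must be at least 16")
    rng = np.random.default_rng(seed)
    # equilateral-triangle spacing for the requested element count
    h = float(np.sqrt(4.0 / np.sqrt(3.0) * np.pi * radius**2 / target_elements))
    mesh = best = None
    for _ in range(4):
        if radius / h < 1.5:
            # coarse fan: center node plus exactly `target` boundary nodes
            ang = 2.0 * np.pi * np.arange(target_elements) / target_elements
            pts = np.vstack([np.zeros((1, 2)),
                             radius * np.column_stack([np.cos(ang), np.sin(ang)])])
        else:
            pts, _ = _ring_points(radius, h, rng)
        tri = Delaunay(pts)
        simplices = tri.simplices
        p = pts[simplices]
        areas = 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )
        keep = areas > 1e-12 * radius**2
        simplices, areas = simplices[keep], areas[keep]
        # enforce CCW orientation
        p = pts[simplices]
        det = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
               - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        flip = det < 0
        simplices[flip] = simplices[flip][:, [0, 2, 1]]
        r_nodes = np.hypot(pts[:, 0], pts[:, 1])
        boundary = r_nodes > radius * (1.0 - 1e-9)
        mesh = DiscMesh(nodes=pts, triangles=simplices, element_areas=areas,
                        boundary=boundary, well_radius=float(radius))
        count = mesh.n_elements
        if best is None or (abs(count - target_elements)
                            < abs(best.n_elements - target_elements)):
            best = mesh
        if abs(count - target_elements) <= 0.15 * target_elements:
            break
        h *= np.sqrt(count / target_elements)
    mesh = best
    if mesh.n_elements > 1.2 * target_elements or mesh.n_elements < 0.8 * target_elements:
        raise ValueError(
            f"could not reach target element count {target_elements} "
            f"(got {mesh.n_elements})"
        )
    return mesh


@dataclass
class NutrientField:
    """Nodal normalized glucose with diffusion and live-cell uptake."""

    mesh: DiscMesh
    sigma: np.ndarray           # per node, dimensionless (1.0 == 10 mM)
    D_coeff: float              # um^2/h
    lambda_uptake: float        # 1/h
    _system_base: sp.csr_matrix | None = field(default=None, repr=False)
    _base_dt: float = field(default=-1.0, repr=False)

    @classmethod
    def uniform(cls, mesh: DiscMesh, sigma0: float, D_coeff: float,
                lambda_uptake: float) -> "NutrientField":
        return cls(mesh=mesh, sigma=np.full(mesh.n_nodes, float(sigma0)),
                   D_coeff=float(D_coeff), lambda_uptake=float(lambda_uptake))

    def sample_at(self, points: np.ndarray) -> np.ndarray:
        """P1 interpolation of sigma at arbitrary points inside the well."""
        points = np.atleast_2d(points)
        interp = LinearTriInterpolator(self.mesh.triangulation, self.sigma,
                                       trifinder=self.mesh.finder)
        vals = interp(points[:, 0], points[:, 1])
        out = np.ma.filled(vals, np.nan)
        missing = ~np.isfinite(out)
        if missing.any():
            if self.mesh._node_tree is None:
                self.mesh._node_tree = cKDTree(self.mesh.nodes)
            _, nearest = self.mesh._node_tree.query(points[missing])
            out[missing] = self.sigma[nearest]
        return out

    def total_mass(self) -> float:
        """Lumped integral of sigma over the well (um^2 * concentration)."""
        _, m = self.mesh.fem_operators()
        return float(m @ self.sigma)


# footprint quadrature for agents wider than an element: center plus a ring
# at 2R/3 (the mean radial position of a uniform disc), equal weights
_RING = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, 7)[:-1]),
                         np.sin(np.linspace(0, 2 * np.pi, 7)[:-1])])


def live_fraction_field(population: Population, mesh: DiscMesh) -> np.ndarray:
    """Per-element area density of live agents (overlap disregarded).

    Dead agents take no glucose and are excluded.  An agent smaller than a
    mesh element contributes its whole area to the element containing its
    center; a coarse agent wider than an element spreads its area over a
    7-point footprint quadrature.  The density is deliberately NOT capped at
    1: overlapping agents make it exceed 1 locally, and truncating that
    excess would make the integrated uptake depend on the coarse-graining
    level (the sink must scale with the total live area at every m).
    """
    rho = np.zeros(mesh.n_elements)
    if len(population) == 0:
        return rho
    live = population.alive
    if not live.any():
        return rho
    x = population.x[live]
    area = population.area[live]
    radius = population.radius[live]
    h_elem = np.sqrt(mesh.element_areas.mean())
    wide = radius > 0.75 * h_elem
    if np.any(~wide):
        elems = mesh.find_elements(x[~wide])
        np.add.at(rho, elems, area[~wide])
    if np.any(wide):
        xw = x[wide]
        pts = np.concatenate(
            [xw] + [xw + (2.0 / 3.0) * radius[wide][:, None] * r[None, :]
                    for r in _RING])
        elems = mesh.find_elements(pts)
        np.add.at(rho, elems, np.tile(area[wide] / 7.0, 7))
    return rho / mesh.element_areas


def diffusion_step(field: NutrientField, rho_t: np.ndarray, dt: float) -> NutrientField:
    """One implicit-Euler step of diffusion plus live-cell uptake (in place)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    mesh = field.mesh
    rho_t = np.asarray(rho_t, dtype=float)
    if rho_t.shape != (mesh.n_elements,):
        raise ValueError("rho_t must have one value per element")
    K, m = mesh.fem_operators()
    if field._system_base is None or field._base_dt != dt:
        field._system_base = (sp.diags(m) + dt * field.D_coeff * K).tocsr()
        field._base_dt = dt
    # lumped uptake: lambda * rho integrated elementwise onto nodes
    uptake = np.zeros(mesh.n_nodes)
    contrib = field.lambda_uptake * rho_t * mesh.element_areas / 3.0
    for v in range(3):
        np.add.at(uptake, mesh.triangles[:, v], contrib)
    A = field._system_base + sp.diags(dt * uptake)
    rhs = m * field.sigma
    sol = spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(sol)):
        raise FloatingPointError("diffusion solve produced non-finite values")
    field.sigma = sol
    return field
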