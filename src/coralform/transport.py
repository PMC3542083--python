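"""Steady nutrient transport and per-polyp absorbed flux.

Dissolved nutrient (think dissolved inorganic carbon) enters from every
far-field boundary at a fixed idealized concentration of 1 mol m^-3 and is
absorbed completely at the colony surface and the substratum (both held at
zero).  The steady advection-diffusion balance on the flow solution
determines how much of that nutrient reaches each simulated polyp.

Absorbed flux is read off by sampling the concentration a small distance l
along each vertex normal and normalizing by the maximum sample c_max,
which makes the flux field independent of the choice of D and l and
bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import splu

from .flow import FlowField, SimulationDomain
from .geometry import TriSurface, vertex_normals


@dataclass
class TransportParams:
    """Diffusivity, boundary concentration and flux-sampling distance."""

    diffusivity: float = 1.0e-3       # D, m^2 s^-1
    boundary_conc: float = 1.0        # c_b, mol m^-3
    sampling_distance: float | None = None  # l, m (default: 1 voxel pitch)
    tol: float = 1.0e-6               # iterative-solver stopping criterion

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.boundary_conc <= 0:
            raise ValueError("boundary concentration must be positive")
        if self.sampling_distance is not None and self.sampling_distance <= 0:
            raise ValueError("sampling distance must be positive")


@dataclass
class ConcField:
    """Cell-centred steady concentration (mol m^-3)."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)


def solve_transport(domain: SimulationDomain, flow: FlowField | None,
                    params: TransportParams) -> ConcField:
    """Steady advection-diffusion with Dirichlet boundaries.

    c = c_b on all far-field faces (inlet, outlet, open), c = 0 on the
    substratum wall and on the colony cells.  Advection uses donor-cell
    upwinding on the staggered face velocities, which keeps the discrete
    operator an M-matrix so the maximum principle 0 <= c <= c_b holds.
    ``flow=None`` solves the pure-diffusion (no-flow) problem.
    """
    nx, ny, nz = domain.shape
    h = domain.pitch
    D = params.diffusivity
    cb = params.boundary_conc
    solid = domain.solid
    fluid = ~solid

    if flow is not None:
        div = flow.divergence(h)
        div = np.where(fluid, div, 0.0)
        if np.abs(div).max() * h > 10.0 * max(np.abs(flow.u).max(), 1e-12):
            raise ValueError("flow field violates the divergence invariant")
        fu, fv, fw = flow.u, flow.v, flow.w
    else:
        fu = np.zeros((nx + 1, ny, nz))
        fv = np.zeros((nx, ny + 1, nz))
        fw = np.zeros((nx, ny, nz + 1))

    idx = -np.ones(domain.shape, dtype=np.int64)
    idx[fluid] = np.arange(fluid.sum())
    n = int(fluid.sum())
    cells = np.argwhere(fluid)
    ids = idx[fluid]

    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows_l, cols_l, vals_l = [], [], []

    # (offset, face key, face-velocity getter, outward sign)
    specs = [((1, 0, 0), "x+", lambda c: fu[c[:, 0] + 1, c[:, 1], c[:, 2]], +1),
             ((-1, 0, 0), "x-", lambda c: fu[c[:, 0], c[:, 1], c[:, 2]], -1),
             ((0, 1, 0), "y+", lambda c: fv[c[:, 0], c[:, 1] + 1, c[:, 2]], +1),
             ((0, -1, 0), "y-", lambda c: fv[c[:, 0], c[:, 1], c[:, 2]], -1),
             ((0, 0, 1), "z+", lambda c: fw[c[:, 0], c[:, 1], c[:, 2] + 1], +1),
             ((0, 0, -1), "z-", lambda c: fw[c[:, 0], c[:, 1], c[:, 2]], -1)]

    inv_h = 1.0 / h
    for (dx, dy, dz), face, vel_get, sign in specs:
        nb = cells + (dx, dy, dz)
        in_dom = ((nb >= 0) & (nb < (nx, ny, nz))).all(axis=1)
        nb_c = np.clip(nb, 0, (nx - 1, ny - 1, nz - 1))
        nb_id = idx[nb_c[:, 0], nb_c[:, 1], nb_c[:, 2]]
        uf = vel_get(cells) * sign      # outward normal velocity at the face
        # per-unit-volume coefficients: diffusive D/h^2, advective uf/h upwind
        a_out = np.maximum(uf, 0.0) * inv_h + D * inv_h ** 2
        a_in = np.maximum(-uf, 0.0) * inv_h + D * inv_h ** 2

        interior = in_dom & (nb_id >= 0)
        diag[ids[interior]] += a_out[interior]
        rows_l.append(ids[interior])
        cols_l.append(nb_id[interior])
        vals_l.append(-a_in[interior])

        solid_nb = in_dom & (nb_id < 0)     # colony: Dirichlet 0 at the face
        diag[ids[solid_nb]] += a_out[solid_nb] + a_in[solid_nb]
        # (c=0 contributes nothing to rhs)

        on_b = ~in_dom
        bc_type = domain.bc[face]
        if bc_type == "symmetry":
            continue                        # zero-flux face
        c_face = 0.0 if bc_type == "wall" else cb  # substratum absorbs
        # half-cell Dirichlet at the face: conductance 2D/h^2
        a_face_diff = 2.0 * D * inv_h ** 2
        diag[ids[on_b]] += a_face_diff + np.maximum(uf[on_b], 0.0) * inv_h
        rhs[ids[on_b]] += (a_face_diff
                           + np.maximum(-uf[on_b], 0.0) * inv_h) * c_face

    rows = np.concatenate(rows_l + [ids])
    cols = np.concatenate(cols_l + [ids])
    vals = np.concatenate(vals_l + [diag])
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    sol = _solve_sparse(A, rhs)

    resid = np.abs(A @ sol - rhs).max() / max(np.abs(rhs).max(), 1e-300)
    if resid > params.tol:
        raise RuntimeError(
            f"transport solve residual {resid:.2e} above tolerance "
            f"{params.tol:.1e}")

    c = np.zeros(domain.shape)
    c[fluid] = sol
    # clip solver-level round-off; the M-matrix guarantees the bounds
    c = np.clip(c, 0.0, cb)
    return ConcField(c=c)


def _solve_sparse(A: sp.csc_matrix, rhs: np.ndarray) -> np.ndarray:
    """Direct solve for small systems, ILU-BiCGStab for large ones."""
    n = A.shape[0]
    if n <= 6000:
        return splu(A).solve(rhs)
    from scipy.sparse.linalg import LinearOperator, bicgstab, spilu
    ilu = spilu(A, drop_tol=1e-4, fill_factor=10)
    M = LinearOperator((n, n), matvec=ilu.solve)
    x, info = bicgstab(A.tocsr(), rhs, M=M, rtol=1e-10, atol=0.0,
                       maxiter=2000)
    if info != 0:
        raise RuntimeError(f"transport linear solve stalled (info={info})")
    return x


def absorbed_flux(surface: TriSurface, conc: ConcField,
                  domain: SimulationDomain,
                  params: TransportParams) -> np.ndarray:
    """Normalized nutrient flux absorbed at each vertex (polyp).

    flux_i = c(v_i + l n_i) / c_max with c_max the maximum over vertices,
    so max flux is exactly 1 and the values do not depend on D or l.
    """
    l = params.sampling_distance
    if l is None:
        l = domain.pitch
    n = vertex_normals(surface)
    pts = surface.vertices + l * n
    coords = (pts / domain.pitch - 0.5).T  # cell-centre index space
    samples = map_coordinates(conc.c, coords, order=1, mode="nearest")
    c_max = float(samples.max())
    if c_max <= 0.0:
        raise RuntimeError(
            "colony is fully screened from nutrient (c_max = 0): "
            "starvation state")
    return samples / c_max


def peclet_number(u_mean: float, length: float, diffusivity: float) -> float:
    """Pe = u L / D: advective over diffusive transport."""
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if length <= 0:
        raise ValueError("characteristic length must be positive")
    if u_mean < 0:
        raise ValueError("mean speed must be non-negative")
    return u_mean * length / diffusivity


def reynolds_number(density: float, u_mean: float, length: float,
                    viscosity: float) -> float:
    """Re = rho u L / mu: inertial over viscous forces."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return density * u_mean * length / viscosity
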