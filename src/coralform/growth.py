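"""Accretive growth driver: nutrient translocation and layer deposition.

Each growth step couples four processes (the simulation loop):

1. steady flow around the voxelized colony (:mod:`coralform.flow`),
2. steady nutrient transport on that flow (:mod:`coralform.transport`),
3. lateral translocation of the absorbed nutrient between neighbouring
   polyps by surface diffusion on the mesh, and
4. conversion of the translocated concentration C_i into the thickness
   l_i of a new skeletal layer through a saturating (sigmoid) growth
   response, followed by accretion along vertex normals and remeshing.

Branching is emergent: no branching rule exists anywhere in the loop;
local differences in absorbed nutrient are amplified because protruding
regions intercept more nutrient.  The model is fully deterministic —
symmetry breaking comes from mesh discreteness alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import geometry as geo
from .flow import FlowField, FluidParams, SimulationDomain, solve_flow, \
    voxelize_colony
from .transport import ConcField, TransportParams, absorbed_flux, \
    solve_transport


@dataclass
class GrowthParams:
    """Growth-response and surface-diffusion constants.

    ``l_max`` (m) is the asymptotic maximum extension per step; ``k``
    (mol m^-3) the half-saturation concentration; ``n`` the kinetic order
    (steepness) of the response; ``d_s`` (m^2 s^-1) the surface diffusion
    coefficient controlling branch spacing.  ``tau_s`` (s) is the
    integration time of the surface-diffusion step; the default makes the
    diffusion length sqrt(d_s tau_s) equal to three mean edge lengths, a
    mid-range choice between minimal translocation (fine branches) and
    strong smearing (bulky branches).
    """

    l_max: float = 1.0e-3
    k: float = 1.0
    n: float = 1.2
    d_s: float = 3.0e-4
    tau_s: float | None = None
    steps: int = 40
    target_edge: float = 4.0e-3

    def __post_init__(self) -> None:
        if self.l_max <= 0 or self.k <= 0 or self.d_s <= 0:
            raise ValueError("l_max, k and d_s must be positive")
        if self.n < 1:
            raise ValueError("growth exponent n must be >= 1")
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be positive")

    def effective_tau(self, mean_edge: float) -> float:
        if self.tau_s is not None:
            return self.tau_s
        return (3.0 * mean_edge) ** 2 / self.d_s


@dataclass
class PolypState:
    """Per-vertex absorbed flux and translocated concentration."""

    flux: np.ndarray
    conc: np.ndarray  # C_i, mol m^-3


# ---------------------------------------------------------------------------
# surface diffusion (cotangent Laplacian, lumped mass)
# ---------------------------------------------------------------------------

def _cotan_laplacian(surface: geo.TriSurface
                     ) -> tuple[sp.csr_matrix, np.ndarray]:
    """(stiffness L, lumped vertex areas M) of the mesh.

    L is the standard cotangent-weight Laplacian (symmetric, zero row
    sums); M the barycentric lumped mass.  Degenerate triangles make the
    cotangents blow up and are reported as errors.
    """
    v, f = surface.vertices, surface.faces
    n = len(v)
    p = v[f]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    if (areas < 1e-18).any():
        bad = int(np.argmin(areas))
        raise ValueError(f"degenerate triangle {bad} (area {areas[bad]:.3e})")

    rows, cols, vals = [], [], []
    for corner in range(3):
        i = f[:, (corner + 1) % 3]
        j = f[:, (corner + 2) % 3]
        o = f[:, corner]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        if not np.isfinite(cot).all():
            bad = int(np.where(~np.isfinite(cot))[0][0])
            raise ValueError(f"non-finite cotangent weight in triangle {bad}")
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-w, -w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())

    M = np.zeros(n)
    for corner in range(3):
        np.add.at(M, f[:, corner], areas / 3.0)
    return L.tocsr(), M


def surface_diffuse(surface: geo.TriSurface, flux: np.ndarray,
                    d_s: float, tau_s: float,
                    substeps: int = 32) -> PolypState:
    """Integrate dC/dt = d_s lap_s C for time tau_s from C = flux.

    Sub-stepped backward Euler; the system matrix is identical in every
    substep, so it is factorized once and back-substituted ``substeps``
    times.  Because L has zero row sums the area-weighted total sum(M C)
    is conserved exactly on closed surfaces.
    """
    flux = np.asarray(flux, dtype=float)
    if len(flux) != surface.n_vertices:
        raise ValueError("flux length does not match vertex count")
    if (flux < 0).any():
        raise ValueError("negative absorbed flux")
    L, M = _cotan_laplacian(surface)
    dt = tau_s / substeps
    lu = splu((sp.diags(M) + dt * d_s * L).tocsc())
    conc = flux
    for _ in range(substeps):
        conc = lu.solve(M * conc)
    return PolypState(flux=flux, conc=conc)


def surface_diffuse_explicit(surface: geo.TriSurface, flux: np.ndarray,
                             d_s: float, tau_s: float,
                             n_steps: int = 2000) -> np.ndarray:
    """Fine-step explicit Euler integration (reference implementation)."""
    L, M = _cotan_laplacian(surface)
    c = np.asarray(flux, dtype=float).copy()
    dt = tau_s / n_steps
    Minv = 1.0 / M
    for _ in range(n_steps):
        c = c - dt * d_s * (Minv * (L @ c))
    return c


# ---------------------------------------------------------------------------
# growth response
# ---------------------------------------------------------------------------

def growth_response(conc, params: GrowthParams) -> np.ndarray:
    """Saturating (Hill-form) conversion of nutrient to layer thickness.

    g(C) = l_max C^n / (k^n + C^n): monotone increasing, g(k) = l_max/2,
    and bounded by l_max as C grows (saturation kinetics).
    """
    c = np.asarray(conc, dtype=float)
    if (c < 0).any():
        raise ValueError("negative concentration")
    cn = c ** params.n
    return params.l_max * cn / (params.k ** params.n + cn)


def growth_response_logistic(conc, params: GrowthParams) -> np.ndarray:
    """Logistic variant of the growth response (config-selectable)."""
    c = np.asarray(conc, dtype=float)
    if (c < 0).any():
        raise ValueError("negative concentration")
    # matched to the Hill form: half-max at c = k, slope set by n
    return params.l_max / (1.0 + np.exp(-2.0 * params.n * (c - params.k)
                                        / params.k))


# ---------------------------------------------------------------------------
# the outer loop
# ---------------------------------------------------------------------------

@dataclass
class GrowthConfig:
    """Full configuration of one growth experiment."""

    domain: SimulationDomain = field(default_factory=SimulationDomain)
    fluid: FluidParams = field(default_factory=FluidParams)
    transport: TransportParams = field(default_factory=TransportParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    initial_diameter: float = 0.06
    center_height: float | None = None
    flow_enabled: bool = True
    flow_update_interval: int = 1
    self_intersection_interval: int = 0  # 0 disables the check
    response: str = "hill"  # or "logistic"
    keep_meshes: bool = True

    def colony_center(self) -> tuple[float, float]:
        return (self.domain.extents[0] / 2.0, self.domain.extents[1] / 2.0)


@dataclass
class StepRecord:
    step: int
    area: float
    volume: float
    extent: float
    flux_cv: float
    mean_layer: float
    flow_iterations: int


@dataclass
class GrowthHistory:
    config: GrowthConfig
    surfaces: list            # per-step TriSurface (initial + each step)
    records: list             # per-step StepRecord
    halted: str | None = None

    @property
    def final(self) -> geo.TriSurface:
        return self.surfaces[-1]


def grow_colony(config: GrowthConfig) -> GrowthHistory:
    """Run the accretive growth loop for the configured number of steps.

    Deterministic: no randomness anywhere.  The Eulerian problem
    (voxelization, flow, concentration) is refreshed every
    ``flow_update_interval`` steps; between refreshes the interface moves
    much less than one voxel, so the frozen fields remain consistent.
    Halts with a structured report when accretion produces a
    self-intersecting surface (the physical analogue of branch fusion,
    which the model cannot represent).
    """
    gp = config.growth
    surf = geo.make_initial_colony(config.initial_diameter, gp.target_edge,
                                   center_height=config.center_height,
                                   center_xy=config.colony_center())
    surfaces = [surf]
    records: list[StepRecord] = []
    halted = None

    flow_field: FlowField | None = None
    conc: ConcField | None = None
    domain: SimulationDomain | None = None
    response = growth_response if config.response == "hill" \
        else growth_response_logistic

    for step in range(gp.steps):
        refresh = (step % max(config.flow_update_interval, 1) == 0
                   or conc is None)
        if refresh:
            domain = voxelize_colony(surf, config.domain)
            if config.flow_enabled:
                flow_field = solve_flow(domain, config.fluid,
                                        warm_start=flow_field)
            conc = solve_transport(domain, flow_field, config.transport)

        flux = absorbed_flux(surf, conc, domain, config.transport)
        mean_edge = float(surf.edge_lengths().mean())
        state = surface_diffuse(surf, flux, gp.d_s, gp.effective_tau(mean_edge))
        lengths = response(np.maximum(state.conc, 0.0), gp)
        lengths = np.where(surf.fixed, 0.0, lengths)

        check = (config.self_intersection_interval > 0
                 and (step + 1) % config.self_intersection_interval == 0)
        surf = geo.accrete(surf, geo.GrowthLayer(lengths),
                           check_self_intersection=check)
        # the substratum is impenetrable: rim-adjacent vertices whose
        # normals dip below the horizon stay on the plane
        surf.vertices[:, 2] = np.maximum(surf.vertices[:, 2], 0.0)
        if surf.metadata.get("self_intersecting"):
            halted = (f"self-intersection detected at step {step}: "
                      "branch fusion (anastomosis) is outside the model")
            records.append(_record(step, surf, flux, lengths, flow_field))
            break
        # register state channels so the remesh interpolates them at splits
        surf.vertex_data["flux"] = flux
        surf.vertex_data["conc"] = state.conc
        surf = geo.remesh(surf, gp.target_edge)
        records.append(_record(step, surf, flux, lengths, flow_field))
        if config.keep_meshes:
            surfaces.append(surf)

    if not config.keep_meshes:
        surfaces.append(surf)
    return GrowthHistory(config=config, surfaces=surfaces, records=records,
                         halted=halted)


def _record(step: int, surf: geo.TriSurface, flux: np.ndarray,
            lengths: np.ndarray, flow_field: FlowField | None) -> StepRecord:
    area, vol = geo.surface_area_volume(surf)
    free = flux[np.abs(flux) > 0] if flux.size else flux
    cv = float(np.std(free) / np.mean(free)) if free.size and \
        np.mean(free) > 0 else 0.0
    return StepRecord(
        step=step, area=area, volume=vol, extent=surf.max_extent(),
        flux_cv=cv, mean_layer=float(np.mean(lengths)),
        flow_iterations=flow_field.iterations if flow_field else 0)


def colony_extension_check(history: GrowthHistory) -> float:
    """Maximum linear extent (m) of the final colony."""
    return history.final.max_extent()
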