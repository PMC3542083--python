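"""Procedural branching solids and analytic reference flows.

These generators make every stage of the pipeline testable without any
scan data: capsule-union "colonies" with known ground truth (tip
positions, radii, orientations) emulate CT volumes of branching corals,
and a set of closed-form flow/transport problems validates the solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import SimulationDomain
from .morphometrics import VoxelVolume


@dataclass
class FixtureSpec:
    """Specification of a procedural branching colony.

    ``orientation_bias`` beta pulls branch azimuths toward ``bias_axis``:
    0 = isotropic azimuths, 1 = fully aligned.  ``elevation_deg`` is the
    branch elevation above the substratum plane (scalar or (lo, hi)
    range).  The random seed fixes the output bit-exactly.
    """

    n_branches: int = 8
    branch_length: float | tuple[float, float] = (0.035, 0.05)   # m
    branch_radius: float | tuple[float, float] = (0.0028, 0.0036)  # m
    elevation_deg: float | tuple[float, float] = 45.0
    orientation_bias: float = 0.0
    bias_axis: tuple[float, float] = (-1.0, 0.0)        # xy unit direction
    azimuth_jitter: float = 0.15  # fraction of the even spacing
    seed: int = 0
    pitch: float = 0.001                                # m
    pad: int = 4                                        # voxels of margin
    slab_voxels: int = 2                                # substratum slab

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValueError("need at least one branch")
        if not 0.0 <= self.orientation_bias <= 1.0:
            raise ValueError("orientation bias must lie in [0, 1]")
        if np.min(self.branch_radius) < 2 * self.pitch:
            raise ValueError("branch radii must exceed 2 voxels")

    def _range(self, v) -> tuple[float, float]:
        if np.isscalar(v):
            return (float(v), float(v))
        return (float(v[0]), float(v[1]))


@dataclass
class FixtureTruth:
    """Ground truth record emitted with each generated volume."""

    base: np.ndarray
    tips: np.ndarray            # (n, 3) m
    radii: np.ndarray           # (n,) m
    directions: np.ndarray      # (n, 3) unit
    spec: FixtureSpec = None

    def to_dict(self) -> dict:
        return {
            "base": self.base.tolist(),
            "tips": self.tips.tolist(),
            "radii": self.radii.tolist(),
            "directions": self.directions.tolist(),
        }


def make_branching_volume(spec: FixtureSpec
                          ) -> tuple[VoxelVolume, FixtureTruth]:
    """Union of capsules radiating from a basal node on a substratum slab.

    Capsules (sphere-swept segments) keep the union smooth so skeleton
    junctions are well defined.  Returns the voxel volume plus the ground
    truth needed by oracle tests.  Warns when branches overlap so much
    the fixture degenerates into a blob.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_branches

    # azimuths: evenly spread with jitter (guarantees tips stay distinct),
    # then pulled toward the bias axis
    jit = spec.azimuth_jitter
    base_az = (2 * np.pi * (np.arange(n) + jit * rng.uniform(-1, 1, n)) / n
               + rng.uniform(0, 2 * np.pi))
    base_az = np.mod(base_az, 2 * np.pi)
    target_az = np.arctan2(spec.bias_axis[1], spec.bias_axis[0])
    dphi = (base_az - target_az + np.pi) % (2 * np.pi) - np.pi
    az = target_az + (1.0 - spec.orientation_bias) * dphi

    lo, hi = spec._range(spec.elevation_deg)
    elev = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    elev_r = np.radians(elev)
    lo, hi = spec._range(spec.branch_length)
    lengths = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    if (not np.isscalar(spec.branch_radius)
            and len(spec.branch_radius) == n and n != 2):
        radii = np.asarray(spec.branch_radius, dtype=float)  # per branch
    else:
        lo, hi = spec._range(spec.branch_radius)
        radii = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)

    dirs = np.column_stack([np.cos(az) * np.cos(elev_r),
                            np.sin(az) * np.cos(elev_r),
                            np.sin(elev_r)])

    h = spec.pitch
    base_z = spec.slab_voxels * h
    # boss radius: absorb the region where adjacent capsules merge, so the
    # only skeleton junction is the basal node itself
    r_base = 1.5 * radii.max()
    for i in range(n):
        j = (i + 1) % n
        sep = np.linalg.norm(dirs[i] - dirs[j])
        if sep > 1e-9:
            r_base = max(r_base, 1.1 * (radii[i] + radii[j]) / sep)
    r_base = min(r_base, 0.45 * np.min(lengths))
    extent = lengths.max() + radii.max() + r_base
    half = extent + spec.pad * h
    # boss tangent to the slab: its medial centre IS the basal node
    base = np.array([half, half, base_z + r_base])
    tips = base + dirs * lengths[:, None]

    nz = int(np.ceil((tips[:, 2].max() + radii.max()) / h)) + spec.pad
    nxy = int(np.ceil(2 * half / h))
    shape = (nxy, nxy, nz)

    x = (np.arange(nxy) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    occ = np.zeros(shape, dtype=bool)
    occ[:, :, :spec.slab_voxels] = True
    # basal boss joining the branches to the slab
    occ |= np.linalg.norm(pts - base, axis=-1) <= r_base

    per_branch = []
    for i in range(n):
        a, b, r = base, tips[i], radii[i]
        ab = b - a
        t = np.clip(np.einsum("xyzc,c->xyz", pts - a, ab) / np.dot(ab, ab),
                    0.0, 1.0)
        closest = a + t[..., None] * ab
        inside = np.linalg.norm(pts - closest, axis=-1) <= r
        per_branch.append(inside)
        occ |= inside

    # overlap diagnostic: voxels claimed by 2+ branches outside the boss
    counts = np.sum(per_branch, axis=0)
    beyond = np.linalg.norm(pts - base, axis=-1) > r_base
    overlap = (float((beyond & (counts > 1)).sum())
               / max(float((beyond & (counts > 0)).sum()), 1.0))
    if overlap > 0.5:
        import warnings
        warnings.warn(f"branch overlap fraction {overlap:.2f}: fixture "
                      "degenerates toward a blob")

    vol = VoxelVolume(occ, (h, h, h), origin=(0.0, 0.0, 0.0),
                      substratum_slices=spec.slab_voxels)
    truth = FixtureTruth(base=base, tips=tips, radii=radii,
                         directions=dirs, spec=spec)
    return vol, truth


# ---------------------------------------------------------------------------
# analytic reference problems
# ---------------------------------------------------------------------------

@dataclass
class AnalyticCase:
    name: str
    domain: SimulationDomain
    params: dict
    solution: callable = None     # callable(coords) -> field values
    description: str = ""


def analytic_flow_cases() -> dict[str, AnalyticCase]:
    """Closed-form validation problems for the flow/transport solvers.

    * ``poiseuille`` — plane channel, no-slip top and bottom: developed
      streamwise profile is parabolic, u(z) = 6 u_mean (z/H)(1 - z/H).
    * ``slab`` — 1-D advection-diffusion between c = 0 and c = 1 walls:
      c(x) = (e^{Ux/D} - 1)/(e^{UL/D} - 1).
    * ``absorber`` — absorbing sphere of radius R in a diffusive far
      field: c(r) = 1 - R/r (up to the uniform finite-domain factor).
    """
    H = 0.1
    nz = 48
    h = H / nz
    poise = AnalyticCase(
        name="poiseuille",
        domain=SimulationDomain(
            extents=(64 * h, 3 * h, H), pitch=h,
            bc={"x-": "inlet", "x+": "outlet", "y-": "symmetry",
                "y+": "symmetry", "z-": "wall", "z+": "wall"}),
        params={"gap": H, "u_mean_key": "inlet_speed"},
        solution=lambda z, u_mean, gap=H: 6.0 * u_mean * (z / gap)
        * (1.0 - z / gap),
        description="plane Poiseuille, parabolic profile")

    L = 0.64
    slab = AnalyticCase(
        name="slab",
        domain=SimulationDomain(
            extents=(0.04, 0.04, L), pitch=0.01,
            bc={"x-": "symmetry", "x+": "symmetry", "y-": "symmetry",
                "y+": "symmetry", "z-": "wall", "z+": "open"}),
        params={"length": L},
        solution=lambda z, U, D, length=L: np.expm1(U * z / D)
        / np.expm1(U * length / D),
        description="1-D advection-diffusion slab, exponential profile")

    R = 0.025
    big = 0.4
    absorber = AnalyticCase(
        name="absorber",
        domain=SimulationDomain(
            extents=(big, big, big), pitch=0.0125,
            bc={k: "open" for k in ("x-", "x+", "y-", "y+", "z-", "z+")}),
        params={"radius": R, "center": (big / 2, big / 2, big / 2)},
        solution=lambda r, R=R: 1.0 - R / r,
        description="spherical absorber, 1 - R/r far field")

    return {c.name: c for c in (poise, slab, absorber)}
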