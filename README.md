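# coralform

Flow-driven accretive growth simulation of branching coral colonies and
skeleton-based 3D morphometrics.

Branching corals such as *Pocillopora verrucosa* show strong phenotypic
plasticity: under unidirectional current they grow asymmetric colonies
with branches developed predominantly upstream, and their compactness
changes with the relative strength of advective versus diffusive nutrient
transport. `coralform` is for researchers who want to simulate that
process mechanistically and quantify the resulting forms — simulated or
CT-scanned — with a common morphometric vocabulary.

The package has two halves:

* **Growth model.** A polyp-based accretive model: each vertex of a
  closed triangulated surface is a polyp; every growth step solves steady
  laminar channel flow (incompressible Navier–Stokes, MAC staggered
  grid), steady advection–diffusion of a nutrient proxy with absorbing
  colony/substratum boundaries, translocates the absorbed flux across the
  surface by surface diffusion (coefficient D_s), and converts the local
  nutrient C into a new layer thickness through the saturating response

      g(C) = L_max · Cⁿ / (Kⁿ + Cⁿ),

  accreted along vertex normals (L_max = 1 mm, K = 1 mol·m⁻³, n = 1.2 by
  default). Branching is emergent — there is no branching rule. The
  transport regime is characterized by the Péclet number Pe = u·dc/D,
  with dc the mean terminal branch thickness, and the flow regime by
  Re = ρ·u·dc/μ; the Pe sweep lowers D by factors of 10 at fixed
  velocity.
* **Morphometrics.** Topology-preserving 3D skeletonization of voxel
  volumes (CT-like, anisotropic pitch supported) or meshes; terminal
  branch thickness dc from inscribed spheres at skeleton tips; symmetry
  angles h_angle/v_angle of every node relative to the substratum plane
  and the flow-normal plane; the streamwise symmetry magnitude sm_mag;
  surface area, volume and the compactness ratio S/V; and distribution
  statistics (95% CI, skewness, excess kurtosis).

A procedural fixture generator (capsule-union branching solids with known
tips, radii and orientation bias, plus closed-form flow/transport
problems) makes every stage testable without scan data.

## Worked example

Grow a colony for a few steps under flow and measure it:

```python
from coralform import desk_scale_config, grow_colony, morph_report

cfg = desk_scale_config(diffusivity=1e-4, steps=40)   # high-Pe conditions
history = grow_colony(cfg)
rep = morph_report(history.final, flow_speed=0.05,
                   diffusivity=1e-4, viscosity=5e-2, density=1000.0)
print(f"Pe_branch      {rep.pe_branch:.1f}")
print(f"S/V            {rep.sv_ratio:.1f} 1/m")
print(f"sm signed mean {rep.sm_signed_mean*1e3:.2f} mm")
```

prints

```
Pe_branch      33.7
S/V            88.4
sm signed mean 3.84 mm
```

The positive signed symmetry magnitude says the colony's mass sits
upstream of its attachment point — the flow-induced asymmetry. The same
run at D = 0.1 m²/s (Pe ≈ 0.03, diffusion-limited) gives a near-zero
signed mean of 1.16 mm: diffusive supply is isotropic, so growth is
symmetric.

Dimensionless worked examples run in microseconds:

```python
from coralform import peclet_number, reynolds_number
peclet_number(0.05, 2.26e-3, 1e-4)          # 1.13
reynolds_number(1000, 0.15, 1.92e-3, 1e-3)  # 288.0
```

## Command line

```bash
coralform grow -c run.yaml                    # full growth simulation
coralform morph scan.nrrd --pitch 0.00035 0.00035 0.0003 --flow-axis x
coralform synth -c fixtures.yaml              # procedural test volume
coralform sweep -c run.yaml --param transport.diffusion_coefficient \
                --values "1e-1 1e-2 1e-3 1e-4"
```

Configs are YAML with SI units throughout (see `docs/methods.md` and the
`coralform.config` docstring for the schema); runs archive their config,
per-step JSON logs, PLY meshes with per-vertex flux, and a morphometrics
CSV.

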