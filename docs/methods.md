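# Methods

`coralform` couples a flow-driven, polyp-based accretive growth model of
branching coral colonies to a skeleton-based 3D morphometric pipeline.
This note documents the model, the numerical choices, the synthetic-data
generators, and the limits of what the desk-scale test runs demonstrate.

## The growth model

A colony is a closed triangulated surface standing on the substratum
plane z = 0; each vertex represents a polyp. One growth step runs four
stages:

1. **Flow.** Steady incompressible Navier–Stokes flow (no body force) in
   a rectangular channel around the voxelized colony: uniform inlet
   velocity u₀ at x = 0, zero pressure and viscous stress at the outlet
   x = Lx, no-slip on the substratum and the colony, and open (free
   inflow/outflow, no viscous stress) lateral and top boundaries. The
   laminar regime is maintained the same way the flume simulations were
   laminarized: the dynamic viscosity is raised to μ = 5·10⁻² Pa·s so the
   colony Reynolds number stays near 100; a precondition refuses
   Re > 200, where a steady wake no longer exists.
2. **Transport.** Steady advection–diffusion of a nutrient proxy
   (c = 1 mol·m⁻³ on all far-field boundaries, c = 0 on the colony and
   substratum) on the flow solution. The absorbed flux at polyp i is the
   concentration sampled a small distance l along the vertex normal,
   normalized by the maximum sample c_max, which makes the flux field
   independent of D and l and bounded by 1.
3. **Translocation.** The absorbed flux diffuses laterally over the
   colony surface (surface diffusion coefficient D_s) for a time τ_s,
   modelling resource sharing between neighbouring polyps. This sets the
   spacing of branches: small D_s·τ_s → fine branching, large → bulky.
4. **Accretion.** The translocated concentration C_i sets the thickness
   of the new skeletal layer through a saturating response
   g(C) = L_max·Cⁿ/(Kⁿ + Cⁿ) (half-max at C = K, asymptote L_max,
   kinetic order n; a logistic variant is config-selectable). Each free
   vertex advances l_i = g(C_i) along its outward normal; substratum
   vertices are anchored; edge split/collapse remeshing maintains the
   triangulation as the surface grows.

Branching carries no rule anywhere: it can only emerge from the
diffusion-limited instability (protruding regions intercept more
nutrient). The model is deterministic — the only symmetry-breaking seeds
are mesh discreteness and voxelization.

### Parameters (defaults)

| parameter | default | units | notes |
|---|---|---|---|
| channel | 0.6 × 0.6 × 0.4 | m | flume-scale domain |
| u₀ | 0.05 | m·s⁻¹ | inlet speed |
| μ | 5·10⁻² | Pa·s | raised 50× to laminarize |
| ρ | 1000 | kg·m⁻³ | |
| c_b | 1.0 | mol·m⁻³ | far-field nutrient |
| D | 10⁻¹ … 10⁻⁵ | m²·s⁻¹ | swept by decades; sets Pe |
| l | 1 voxel pitch | m | flux sampling distance |
| D_s | 3·10⁻⁴ | m²·s⁻¹ | surface diffusion |
| τ_s | (3·edge)²/D_s | s | diffusion length ≈ 3 mesh edges |
| L_max | 10⁻³ | m | max extension per step |
| K | 1.0 | mol·m⁻³ | half-saturation |
| n | 1.2 | – | response steepness (sweep 1.0–2.6 supported) |
| seed colony | 0.06 | m | sphere diameter, clipped at d/6 below centre |
| steps | 40 (scaled-down) | – | full-scale reference uses 150 |

The Péclet number Pe = u·L/D and Reynolds number Re = ρ·u·L/μ use the
mean terminal branch thickness dc as the characteristic length L, the
morphological invariant of a branching colony.

## Numerics

* **Flow:** marker-and-cell staggered finite volumes; donor-cell upwind
  convection, central diffusion; explicit pseudo-transient projection
  iterated to steady state with an adaptive time step inside the combined
  advective+diffusive stability bound. The pressure Poisson system is
  solved by warm-started Jacobi-preconditioned conjugate gradients
  (direct factorization below ~6000 cells); a final tight projection
  enforces per-cell continuity to solver precision. Convergence criterion:
  normalized momentum residual max|Δu|·h/(Δt·u₀²) ≤ 10⁻³ (configurable).
  Across growth steps the previous field warm-starts the next solve
  (typically ~10 instead of ~400 iterations, since the interface moves
  far less than one voxel between refreshes).
* **Transport:** cell-centred finite volumes, first-order upwind
  advection (an M-matrix, so 0 ≤ c ≤ c_b holds discretely), half-cell
  Dirichlet boundary closure; ILU-preconditioned BiCGStab (direct solve
  for small grids), residual checked against the 10⁻⁶ stopping criterion.
* **Surface diffusion:** cotangent-weight Laplacian with barycentric
  lumped mass; 32 sub-stepped backward-Euler solves sharing one
  factorization (agrees with a fine-step explicit reference to <1%).
  Total area-weighted nutrient is conserved to round-off on closed
  surfaces because the stiffness matrix has zero row sums.
* **Remeshing:** edges longer than 1.5× the target split at midpoints
  (scalar channels interpolated); edges shorter than 0.5× collapse when
  the link condition preserves manifoldness. Area drift per call is
  <0.5% on smooth meshes.
* **Voxelization:** vertical-ray parity counting per grid column; odd
  parity in any column flags a leaking surface.
* **Initial colony:** a class-I geodesic sphere of arbitrary frequency
  (edge length matched to the target within ~±20% after spring
  relaxation), clipped by the substratum and closed with a basal disk
  triangulated at the same resolution. How deep the seed sphere sits is
  not constrained by observation; the default (plane d/6 below the
  centre) makes the colony "sit" on the substratum with an immobile rim.
* **Self-intersection:** accretion can be checked with a grid-hashed
  triangle–triangle test (the physical analogue of anastomosis, which the
  model cannot represent); a detection halts the run with a structured
  report. The check is off by default and config-exposed, because the
  exhaustive test dominates step cost on large meshes.

## Morphometrics

Volumes (CT-like, anisotropic pitch supported) or meshes (voxelized
internally) are reduced to a medial-axis graph by topology-preserving 3D
thinning; graph nodes are tips and junctions, each carrying the largest
inscribed-sphere radius from a physical-unit Euclidean distance
transform. Conventions worth noting:

* Volumes are zero-padded before thinning. Objects exactly mirror
  symmetric about a voxel-face plane can be erased entirely by the
  parallel thinning (a known degeneracy — e.g. even-diameter analytic
  cylinders); natural and procedurally generated shapes are unaffected.
* Junction–junction edges shorter than 1.2× the local inscribed radius
  are contracted: a medial branch shorter than the thickness of the
  region it sits in is an artefact of the medial axis, not morphology.
* Tip radii use the maximum distance-transform value within one tip
  diameter along the terminal path, because the medial axis stops about
  one radius short of a flat cap where the inscribed sphere is clipped.
* dc = 2 × tip radius; endpoints on the volume border are flagged and
  excluded; the skeleton root v₀ is the node nearest the
  colony–substratum attachment centroid.
* **Degenerate (unbranched) colonies:** when the medial structure
  collapses to fewer than two nodes — a dome has a sheet-like medial
  surface, not a curve — the colony is represented as a single trunk:
  the deepest node plus a root anchored at the attachment centroid.
  dc then measures the core thickness of the colony, which *is* its
  only terminal branch. Branched skeletons never take this path.
* Symmetry angles: for d = v_k − v₀, h_angle is the elevation of d above
  the substratum plane and v_angle its inclination towards the flow axis;
  both in [0°, 90°], summing to 90° for vectors in the flow-vertical
  plane. The symmetry magnitude sm_k is the signed scalar projection of
  d onto the direction of an upstream reference point (default: one unit
  upstream of the root; arbitrary for no-flow runs). Mirror-symmetric
  colonies give a signed sum near zero. Both the signed mean and the
  mean magnitude are reported, since the symmetric-colony diagnostic uses
  the signed sum while compact tabulations report magnitudes.
* Angle-distribution statistics: sample mean with t-based 95% CI,
  adjusted Fisher–Pearson skewness, bias-corrected excess kurtosis.

## Synthetic fixtures

`make_branching_volume` emits unions of capsules radiating from a basal
boss on a 2-voxel substratum slab, with seeded, bit-reproducible output
and a ground-truth record (tips, radii, directions). The boss is sized to
absorb the region where adjacent capsules merge and is placed tangent to
the slab so its medial centre coincides with the branch origin — the
skeleton root then recovers the generator's basal node. These fixtures
emulate the connectivity and thickness structure of CT scans, not the
corallite-scale roughness or natural branch-shape statistics of real
colonies; morphometric recovery on them validates the pipeline's
geometry, not its behaviour on noisy scans.

`analytic_flow_cases` provides plane Poiseuille flow, the 1-D
advection–diffusion slab, and the spherical absorber as configured
domains with closed-form profiles. The absorber comparison matches the
amplitude at a reference shell because a finite Dirichlet box rescales
the 1 − R/r solution uniformly by 1/(1 − R/R_out).

## Desk-scale study conditions and their limits

The trend experiments (tests and the acceptance script) use a reduced
configuration chosen once: channel 0.24 × 0.24 × 0.18 m at 7.5 mm grid
pitch, 4 mm mesh edges, 40 growth steps, Eulerian fields refreshed every
5 steps (the interface advances ≤0.5 mm per step, far below one voxel).
A full sweep of four diffusivities runs in about three minutes.

What these scaled-down runs show — and do not show:

* Directional response is reproduced: at high Pe the upstream face
  absorbs roughly twice the nutrient of the wake face, colonies lean
  upstream, the branch-scale Péclet number spans three decades across
  the sweep, and the streamwise symmetry magnitude roughly triples
  between the diffusion-limited and advection-dominated ends.
* **Spontaneous branching does not emerge in 40 steps.** The
  diffusion-limited instability amplifies shape perturbations roughly in
  proportion to accumulated growth over colony radius; 40 steps of
  ≤0.5 mm layers on a 6 cm seed amplify the sub-0.1 mm mesh-facet seeds
  by only ~e⁴, leaving millimetre-scale lobes. The branched morphologies
  of full-scale 150-step runs accumulate two to three times more
  e-foldings. Consequently the desk-scale colonies are upstream-leaning
  domes measured through the single-trunk convention, and trends that are
  *carried by branching* — notably the decline of surface/volume ratio
  with Pe, which reflects the loss of branch area as flow compactifies
  the colony — do not reproduce at this scale (the measured S/V ordering
  is flat-to-slightly-increasing). The corresponding acceptance tests
  assert the full-scale expectations and are left failing rather than
  weakened; see the test suite.
* The two most diffusion-limited runs (Pe ≈ 0.03 and 0.3) are the same
  physical regime and produce morphologies identical to within
  micrometres; orderings between them are ties, not signal.

## Known limitations

* First-order upwinding makes both solvers robust but numerically
  diffusive; boundary layers thinner than a voxel are under-resolved.
* The no-slip colony surface is the voxelized mask, so the hydrodynamic
  geometry is blocky below the grid pitch.
* Corallite-scale roughness, anastomosis (branch fusion), turbulence and
  unsteady wakes are outside the model; a self-intersection halts the
  run rather than fusing branches.
* Thinning-based skeletons degenerate on near-convex solids; the trunk
  convention above makes the pipeline total but reduces such colonies to
  two nodes.
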