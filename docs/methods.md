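# Methods

This note records the models, numerical choices and limitations behind
`canopyflow`, in the order the pipeline runs.

## Virtual plant

The plant is parameterized by `PlantSpec`. The printed phenotype
constants — 130 cm height, 20 stem segments, fruiting branches on nodes
5–20 simplified to straight cylinders with equal internode spacing,
leaf-class fractions 20/55/25% and per-class windward areas 4206.25 /
7859.10 / 9823.00 mm² — are defaults; everything else (petiole length
distribution, branch taper, insertion angles, phyllotactic azimuth
137.5° with seedable jitter) is not published for this system and is
exposed as configurable parameters with documented defaults.

Leaf blades are star-shaped polar curves, r(φ) = R(1 + a cos kφ) with
(k, a) = (1, 0.55) for the ovate egg shape, (3, 0.40) and (5, 0.35) for
the lobed classes; the basal sinus at φ = π is the petiole attachment.
Star-shapedness makes the fan triangulation from the origin provably
valid, and uniform scaling sets the polygon area exactly to the target.
Leaf kinds are allocated by largest-remainder rounding (realized counts
within 1 of n·fraction, e.g. 4/11/5 at n = 20) and shuffled with the
seeded generator. Branches insert at mid-segment heights so the stem tip
defines the bounding box. Layers are assigned by attachment height with
half-open [lo, hi) intervals, top interval closed.

## Lattice-Boltzmann fluid

D3Q27, BGK single relaxation time, standard second-order equilibrium
(weights 8/27, 2/27, 1/54, 1/216), Guo forcing with the half-force
velocity correction, uniform Cartesian lattice (no octree refinement —
unnecessary at desk scale). Unit mapping: the user picks the grid N;
dx = 1.5 m / N and dt is chosen so the inlet speed maps to 0.05 lattice
units (Mach ≈ 0.09). Boundaries: prescribed-velocity inlet on the top
face via non-equilibrium extrapolation, zero-gradient outflow on the
bottom and side faces, half-way bounce-back for interior obstacles.
Validation: Poiseuille profile error < 1% at 64 nodes (wall planes half
a spacing beyond the last fluid node), Taylor–Green kinetic-energy decay
within 2% of the Stokes rate, mass conservation to 1e-10 over 10³
periodic steps.

**WALE closure.** ν_t is computed from the finite-difference velocity
gradient (second-order central, one-sided at boundaries) because the
traceless symmetric square of the gradient needs the full tensor g,
which the non-equilibrium second moment cannot supply; the moment-based
strain remains available as a diagnostic (it matches the FD strain to a
few percent in the channel benchmark). The effective relaxation time is
τ_eff = τ_mol + ν_t/c_s² per node, recomputed every step. One property
worth stating plainly: WALE vanishes identically in pure shear (g
nilpotent ⇒ g² = 0), but **not** in solid-body rotation — for
antisymmetric g the deviatoric part of g² is diag(−ω²/3, −ω²/3, 2ω²/3),
giving ν_t = (B_wΔ)²(S^d:S^d)^{1/4} > 0. That is a known trait of this
closure, not an implementation artifact.

**Numerical background viscosity.** At N = 40 the molecular relaxation
time is τ = 0.500012 — within 1e-5 of the BGK stability bound — and the
resolved-gradient ν_t cannot damp the non-hydrodynamic modes that grow
in the under-resolved shear layers behind leaves; coupled runs at
5 m s⁻¹ were observed to blow up from the fluid side after ≈0.25 s.
Coupled runs therefore clamp τ_eff from below
(`CouplingConfig.tau_floor`, default 0.505, i.e. ν ≈ 1.7·10⁻³ lattice
units, cell Reynolds ≈ 30) — an implicit-LES-style regularization that
caps the effective Reynolds number at a few hundred. The quantities the
canopy runs report (deflection ordering between layers, band-mean speed
attenuation, porosity dynamics) are insensitive to this cap; benchmark
runs (Poiseuille, Taylor–Green) use no floor. Fluid gravity is recorded
in the configuration but enters as a hydrostatically balanced body
force: for a uniform-density isothermal fluid a constant body force is
absorbed entirely by the hydrostatic pressure, so applying it raw in an
open domain would merely accelerate the whole box (an option
`unbalanced_gravity` exposes that behaviour). Gravity does act on the
shell. Temperature (289.35 K) and molar mass (28.996 g mol⁻¹) are
configuration metadata; the solver is isothermal.

## Thin-shell structure

Leaves are ~0.5 mm thin at ~100 mm span, so solid elements are replaced
by triangle shells:

- **Membrane**: constant-strain triangles with a St. Venant–Kirchhoff
  plane-stress law (rotation-invariant through the Green strain);
  forces are the exact energy gradient.
- **Bending**: hinge stencils on interior edges with coefficient
  c_e = D |e|² / (2 (A₁+A₂)), D = E t³/12(1−ν²). For hinges whose rest
  stencil is flat the energy uses the *linearized* dihedral angle
  (c_e |Σ_k s_k x_k|² with s_k the rest-state angle gradients projected
  on the stencil normal) — exactly invariant under rigid motions of the
  flat stencil; non-flat hinges (the petiole–blade welds) keep the
  nonlinear dihedral form.

A finding that shaped this design: minimizers of hinge bending energies
on one-diagonal structured grids undershoot the Kirchhoff plate
stiffness by 25–70% depending on cell aspect (verified by direct sparse
static solves) — the discretization is nonconforming and admits soft
zig-zag modes. On **crossed-diagonal (union-jack) meshes with square
cells** the calibrated coefficient converges to the plate limit (static
tip-deflection ratios 1.10 / 1.02 / 0.99 at 10×1 / 20×2 / 40×4), so
strips (petioles, benchmarks) are meshed that way; `strip_mesh`
documents the aspect sensitivity. Leaf-blade fan meshes retain a
bending-stiffness discretization error of order tens of percent, which
is within the uncertainty of the unprinted leaf thickness (a first-order
sensitivity: D ∝ t³; default t = 0.5 mm, configurable).

Time integration is damped symplectic Euler; the stable step is the
minimum of the membrane limit (0.4 h/c, c = √(E/ρ(1−ν²))) and a
flexural-wave limit (0.2 h² √(12ρ(1−ν²)/E)/t). Mass-proportional
damping defaults to 5 s⁻¹ for coupled runs (light, to tame explicit
ringing; reported in the run log); the cantilever benchmark uses
near-critical damping computed from the first beam mode. The cantilever
against q L⁴/(8EI) settles to 2.4% at nx = 20 and 1.0% at nx = 40
(ν = 0 so the beam and plate formulas coincide).

Petioles are flat strips of 4× blade thickness welded onto the blade's
basal edge (built in the edge's own frame so the welded quad stays well
shaped) and clamped at the branch; stem and branches are rigid. The
paper-style full fixity of the stem is therefore represented by the
clamps at the petiole bases. Leaf–leaf contact is not modelled.

## Two-way coupling

Explicit partitioned loop per fluid step: interpolate fluid velocity to
Lagrangian markers (triangle centroids after subdividing to the lattice
spacing — prevents leakage through coarse grids), apply direct forcing
(the momentum correction that drives the local fluid toward the shell
velocity, spread through the kernel), hand the exact opposite impulse to
the shell nodes in newtons via barycentric weights (action–reaction
holds to round-off by construction), then sub-cycle the shell
(`substeps` ≈ dt_fluid / dt_shell, typically 100–400). Leaves couple as
zero-thickness interfaces. The interpolation/spreading kernel is the
trilinear hat by default (partition of unity; a marker on a node takes
the full weight there); the smoothed 3-point kernel is available as
`kernel="peskin3"`. Loose explicit coupling is acceptable here because
the leaf's areal mass (ρ_s t ≈ 0.35 kg m⁻²) is several times the
engaged fluid mass per step (ρ_f dx ≈ 0.05 kg m⁻²); structural damping
and sub-cycling absorb the residual added-mass ringing. The frame
cadence is exact: duration/output_interval frames (200 for 1 s at
5 ms), with the undeformed no-wind state kept separately as the
porosity baseline. The loop draws no random numbers, so records are
bitwise reproducible.

## Porosity imaging

Rendering is an orthographic rasterization of leaf triangles (top view
for downward airflow; front view available) on a white background at a
recorded mm-per-pixel scale; bands select triangles by current centroid
height — fixed layer bounds in cm, or N canopy-relative-height bands
over the initial leaf extent. Processing is 3×3 median denoise,
grayscale, Otsu threshold (polarity flag for inverted input). The outer
contour is the convex hull of foreground pixel centres, offset outward
by half a pixel with mitred joins so a full k×k block measures exactly
k² pixels (an alpha-shape-like concave option exists for strongly
concave canopies). Windward area is the foreground pixel count times
the pixel area; rendering at 384–512 px keeps both measures within
0.5% under resolution doubling.

Porosity conventions: the verbal definition of optical porosity is the
void/contour ratio, while the printed per-layer formula divides the
*leaf* area by the contour area. Both are computed for every band and
frame (`P_optical = 1 − A/S`, `P_literal = A/S`; they sum to 1);
`optical` is the default and the output tables carry both columns plus
the dynamic variation dP against the no-wind baseline. Empty bands
yield NaN with a warning rather than aborting.

## Metrics

Probe speeds are trilinear interpolations of |u|; probe coordinates
must be user-supplied in real validations (a 3-layer × 3-point default
grid exists for smoke tests). NMAE is mean(|S−M|)/mean(M)·100 (the
commonest convention; a per-point normalization is selectable), and the
regression is of measured on simulated values with R² = 1 − SS_res/SS_tot.
Per-layer NMAE aggregates all point×time samples of a layer. CRH
profiles report per-band windward area and porosity from the imaging
pipeline plus slab-mean speed and vorticity from the recorded per-layer
fluid profiles.

## Scaled-down study conditions

The full scenario (a 48-leaf plant, 1 s horizon, production lattice
resolutions) is more than validating the implementation requires, so
the shipped canopy tests use a 6-leaf mini-plant spread over all three layers, a 40³ lattice (dx = 3.75 cm)
and a 0.3 s horizon at 5 m s⁻¹ — sizes chosen so the qualitative
structure the method predicts (upper layer deflects first; band-mean
speed decays monotonically with canopy depth) is resolved. Mini-plant
blades use 40-point outlines so the welded petiole strips keep a usable
explicit time step; the plant-generator default remains 128.

## Known limitations

- BGK + τ-floor regularization caps the effective Reynolds number; the
  solver resolves jet-scale structures, not atmospheric turbulence.
- Hinge bending on unstructured blade fans carries O(10%) stiffness
  discretization error (see above); leaf thickness itself is the
  dominant uncertainty.
- Loose coupling is first-order in time; no iterative FSI.
- No leaf–leaf contact, no spray droplets, no moving nozzle.
- The printed field-validation numbers (NMAE, R², absolute porosities)
  depend on unpublished hot-wire data and unspecified leaf placement;
  the package reproduces the constructive geometry and the method's
  qualitative predictions, not those measurement-specific values.
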