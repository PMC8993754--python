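# Methods

## Model and assumptions

The embryonic sheet is modeled as a 2D continuum, a flattened lateral
projection of the post-neurulation body.  Its constitutive behaviour is
viscous on the time scale of morphogenesis: stress is proportional to
strain *rate*, `sigma = H : d(eps)/dt`, with `H` assembled like a
plane-stress Hooke matrix whose entries are viscosities.  Two parameters
define it:

- `E*` (stiffness-analog, default **2.0**): sets the overall
  stress/velocity scale.  With the body height of order 0.4–1 model units,
  redimensioning by a real embryo (~500 µm, ~1000 Pa, strain rates
  ~1e-3 s^-1) lands in the physiological range; the solver itself never
  uses physical units (`mechanics.UnitSystem` converts for presentation
  only).
- `nu*` (Poisson-analog, default **0.45**): the ratio of bulk to shear
  viscous response.  The tissue has a bulk viscosity in addition to shear,
  i.e. it is compressible but resists dilation; 0.45 is near-incompressible
  while keeping the system well conditioned.  Whether the original
  plane-reduction should be plane stress or plane strain is not decidable
  from the biology; we fix the plane-stress analog and expose `nu*` as
  config.

Mechanics is quasi-static: at each instant `div sigma = 0` with the
actuator tractions as boundary data, solved for the velocity field; inertia
is absent.  The mesh is then advected explicitly (`x <- x + v dt`) and
becomes the new reference configuration.  Because every actuator is
re-evaluated on the deformed boundary, a contraction transported with the
flow shrinks its own source term.  That feedback is the load-bearing
mechanism of the model: a constant tension on a shrinking rim keeps total
force constant (linear closure), while a constant line-force on a shrinking
segment loses total force in proportion to the segment, giving
`dL/dt ∝ -L` and exponential self-arrest.

Per-region softness factors `f ∈ (0, 1]` scale `E*` inside placode
territories ("very soft" tissue); `f = 0` removes the territory from the
mesh entirely (absent tissue), leaving its footprint on the boundary.

## Discretisation

- **Elements**: linear (P1) triangles; direct sparse factorisation
  (relative residual checked against 1e-10).  The patch test reproduces a
  uniform strain-rate field to solver roundoff (~1e-12 relative), and a
  manufactured smooth solution converges in L2 at order ~2.
- **Tractions** are forces per unit boundary length sampled at chain
  vertices and converted to nodal loads by edge lumping (half of each
  adjacent edge length).  For uniform stress states an exact per-edge rule
  (`stress_boundary_loads`) is provided; it is what makes the patch test
  exact.
- **Rigid modes**: each scenario pins a boundary chain (the outer rim for
  wound rings, the neck edge for body scenarios).  For self-equilibrated
  loads a Lagrange-multiplier filter of the three rigid modes is available
  instead.
- **Time stepping**: explicit forward Euler with
  `dt = min(dt_max, c * h_min / max|v|)`, `c = 0.2` by default.  A step
  that would invert an element is rejected and retried at half `dt` (up to
  six times).  Area drift of a rigid rotation is O(dt^2), which bounds the
  geometric error of the explicit update.
- **Curvature** at boundary vertices comes from the circumscribed circle of
  three consecutive chain vertices, signed by the cross product of the
  adjacent edge vectors.  Chains are oriented with the material on their
  left, so a convex outer boundary has `kappa = +1/R` and a hole rim
  `kappa = -1/R`; the Laplace traction `-T kappa n` is then contractile on
  both without case analysis.  Open-chain endpoints use a one-sided
  three-vertex stencil and are flagged.  On a closed convex contour the
  discrete total turning `sum(kappa ds)` reproduces 2 pi within 2%.
- **Meshing**: structured quad-split meshes (each quad cut into four
  triangles about its centroid, which preserves mirror symmetries exactly)
  for the annulus and the rectangular body; a conforming-Delaunay mesher
  (hex-grid interior points, centroid-in-polygon filtering, midpoint
  splitting of unrecovered segments, guarded Laplacian smoothing) for
  rounded-corner outlines and for remeshing arbitrary deformed boundaries.
- **Remeshing** triggers when any element quality (2 r_in / R_circ) falls
  below 0.12.  Boundary vertex positions, labels and internal constraint
  chains are preserved exactly; region tags are re-assigned by centroid
  location.  When clustered boundary vertices make the requested quality
  unreachable, the effective threshold backs off (anti-thrash) instead of
  re-triangulating every step.
- **Self-intersection** of the boundary polygon halts the simulation with
  the offending segment pair; runs whose physical endpoint is a collapse
  (slit flanks touching) use an observable stop criterion to end just
  before it.

## Actuators: conventions and defaults

Positive magnitudes are contractile (tension, pressure, shear pairs) or
outward-growing (negative surface tension).  Two conventions deserve
mention:

- `normal_pressure` is *centripetal with respect to the enclosed void*: on
  a hole rim (total turning -2 pi) it points into the hole so that a wound
  closes, on a convex outer contour it points into the material.  A
  negative `P` grows the contour outward (used by the free-morphing
  scenario).
- `neg_surface_tension` applies `gamma * kappa^m * n` (m = 1 or 2) only
  where the contour is convex; concave stretches are clamped to zero by
  default (growth is a property of ridges, not folds), with an unclamped
  option.  It is restricted to external contours.  The "surface shear
  proportional to the curvature gradient" that would accompany a
  curvature-dependent tension is *not* auto-derived; instead the
  free-morphing scenario exposes independent normal and tangential
  magnitudes.
- `shear_pair` splits its target chain at the arclength midpoint and
  applies `+-F t`; `asymmetry` scales the second half (in chain order), and
  the mouth actuator carries tangential forces only — the normal
  (straightening) component of a flexing tension profile is of higher
  order in the deflection and is deliberately omitted (a flag can restore
  it for exploration).

## Scenario presets

No force magnitudes are published for the original experiments, so preset
magnitudes are order-unity values chosen once to express each qualitative
regime; they live in the config, not in code.  Notable choices:

- Wound rings: `T = 1` and `P = T/r0` so both closure experiments start
  from the same total force 2 pi T; runs stop at radius 0.1 (a third of the
  initial hole), mesh ~2.3k triangles (edge 0.07).
- Crenel family: a 0.3 x 0.3 crenel centered on a 2 x 1 body, base pull
  `F = 2`, run to t = 3 (about one decade of decay).  The square placode
  makes "elongation vs circularisation" monotone in the principal-axis
  aspect ratio.  The asymmetric variant uses a 2:1 split; the gradient
  variant adds a tangential pull of 0.15 toward the dorsal axis.
- Slit: absent tissue (`f = 0`); the base contraction then digs a boundary
  invagination whose depth/width ratio is the slit aspect.  The run stops
  at half the initial base length, before the flanks touch.  (Very soft but
  present tissue, e.g. `f = 0.01`, is also supported; its collapse endpoint
  is the same self-intersection.)
- Nasal processes: rounded head corner of radius 0.15 (corner smoothing is
  mandatory because curvature is undefined at a sharp corner; the default
  radius elsewhere is five target edge lengths), `gamma_2 = gamma_1 * r` so
  both growth laws start from the same tip traction.
- Buckling: kappa-proportional growth (`gamma = 0.3`) on the initially flat
  dorsal line plus a small placode winding (`F = 0.3`); without the
  winding the dorsal line has no curvature and nothing grows, so the bulge
  is genuinely nucleated by the placode.

Presets serialise to YAML bit-exactly; all meshing is deterministic, so a
config (with its seed field) reproduces observable CSVs byte-for-byte.

## What the generated geometries do and do not emulate

The generators produce idealised reference configurations: a perfect
annulus, a rectangle with crenel/trapeze notches, circular-arc corner
smoothing.  They emulate the *topology and force-carrying structure* of the
embryonic projection (labeled dorso-ventral line, placode territories with
their own material tag, head contour), not real embryo outlines: no
imaging-derived shapes, no left-right asymmetry of the real body, no
out-of-plane invagination (the third dimension is absent by construction).
Passing tests therefore demonstrate the mechanics of the force pattern —
closure laws, self-arrest, regime orderings — and say nothing quantitative
about any particular embryo.

## Diagnostics

`fit_closure_law` fits a linear law and a log-linear exponential to an
observable L(t) after discarding a burn-in fraction (default 0.2, covering
the initial-deformation transient), evaluates both residual sums on the
original scale and selects by AIC (k = 2 each; ties go to linear).  The
exponential's `R^2` on log L is reported for the log-linearity check, and
`tau > 0` is only reported when the log-slope is negative.

Self-arrest is asserted on the source term itself: the contraction speed
|dL/dt| of the ear base decays after the transient and log L is linear in
t.  The raw maximum velocity over the mesh is *not* monotone during ear
formation — the winding placode transiently accelerates even as the total
pull decays — so it is recorded but not used as the self-arrest criterion.

Shape metrics: region area/perimeter/centroid from the tagged triangles,
principal-axis aspect ratio from exact second area moments, isoperimetric
ratio 4 pi A / P^2; open boundary chains get chord-based deflection depths
(inward = invagination, outward = tip extension).

## Known limitations

- Strictly 2D and quasi-static: no inertia, no contact; flanks that touch
  end the run rather than fuse.
- No bulk growth forces; all drivers are boundary tractions.
- The kappa^2 growth law is genuinely runaway: the quadratic nasal-process
  run is stopped by step count as the tip sharpens, which is the expected
  behaviour of the feedback, not an artifact.
- Remeshing preserves boundary vertices exactly, so extreme boundary
  vertex clustering (late-stage contractions) bounds the reachable element
  quality; the anti-thrash backoff accepts that flatter quality floor.
- The exponential time constant of the ear contraction varies by a few
  percent between mesh resolutions (7% between edge lengths 0.06 and
  0.05), dominated by discrete remesh events and the coarse representation
  of the winding crenel.
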