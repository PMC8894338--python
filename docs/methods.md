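# Methods

## Scope and model

`stomamech` computes the small-strain linear-elastic response of a
multi-material abdominal-wall model to intraabdominal pressure (IAP)
and post-processes the deformation of a circular stoma incision
(trephine).  The constitutive law is isotropic Hooke elasticity per
material region; the kinematics are geometrically linear; the pressure
is a dead load on the reference-configuration surface normals.  These
three choices are deliberate and coupled: a linear constitutive
statement admits a single deterministic solve per geometry, makes the
pressure sweep exact by scaling, and keeps every reported number a
reproducible function of the mesh and the material table.  The
trade-off is discussed under Limitations.

The discretization is the P1 (linear, 4-node) tetrahedron.  Strain and
stress are element-constant; the von Mises scalar
`σ_v = sqrt(3/2 s:s)` (s = stress deviator) is reported per element,
with an optional volume-weighted nodal average for visualization only.
Maximum deformation is the largest nodal displacement magnitude;
`σ_v^max` is the largest *element* value (conservative relative to
nodal averaging).

Units: mm, MPa, N pipeline-wide, so 20 kPa enters as 0.02 MPa;
centimetre conversions happen only in reporting.

## Materials

| region | tissue analogue        | E (MPa) | ν   |
|--------|------------------------|---------|-----|
| EO     | external oblique       | 1.0     | 0.3 |
| IO     | internal oblique       | 0.65    | 0.3 |
| RA     | rectus abdominis       | 0.52    | 0.3 |
| TR     | transverse abdominis   | 1.03    | 0.3 |
| LA     | linea alba (tendinous) | 72      | 0.3 |

Skin and subcutaneous fat are an order of magnitude softer than muscle
and are not modelled.  The incompressible limit ν → 0.5 is rejected by
the constitutive routine (the standard displacement formulation locks
there).

## The wall phantom

Patient-derived abdominal meshes are not shipped; the synthetic phantom
reproduces the *mechanical structure* of the wall instead: four soft
muscle strata in series through the thickness (TR innermost, then RA,
IO, EO), joined in parallel by a stiff midline strip (the linea alba
analogue) that spans the full height and touches both halves, the
whole slab bent onto a cylinder, clamped on all four lateral edges, and
pressurized on the concave (inner) face.

Default dimensions: 300 × 400 mm wall, four 3 mm layers (12 mm total),
20 mm strip width, 200 mm curvature radius — adult-abdomen orders of
magnitude; every value is overridable through `PhantomSpec`.  The
seventeen stoma positions follow the labelling scheme `s0` (on the
strip, mid-height) and `s{i}{j}` with lateral offset growing with
i (columns at 40/80/120 mm on the default wall, i.e. width × 2i/15) and
height growing with j (rows at 100..300 mm in 40 mm steps, i.e.
height/4 + (j−1)·height/10); j runs 1–6 for i = 1, 2 and 1–4 for
i = 3.  The grid spacing is a free modelling parameter — no anatomical
coordinates exist for it — and lives in `column_offsets`/`row_heights`.

Construction runs in a developable parameter plane (arc length s,
height y, thickness t):

1. a graded tensor grid with target edge `resolution` (default 6 mm)
   far away and a fine band around the hole sized so the circle carries
   at least `hole_segments` (default 64) nodes — about 1 mm; growth
   rate 0.3 toward the far field; mandatory grid lines at the strip
   edges;
2. hole cutting: every cell touching a node strictly inside the circle
   is deleted; the nodes on the kept/deleted interface are projected
   radially onto the circle; 30 constrained Laplace sweeps relax the
   surrounding annulus while boundary nodes slide along the circle.
   The trephine boundary loops therefore lie *exactly* on the requested
   circle, so the undeformed baseline (perimeter 2πr, area πr²) is
   reproduced up to the inscribed-polygon deficit, below 0.2% at 64
   segments — that is why 64 is the default;
3. each quad is split into two triangles choosing the diagonal that
   maximizes the minimum triangle area (the snapped boundary can make
   quads concave; the fixed-diagonal split would fold there), the
   triangles are extruded through the thickness into prisms, and each
   prism is split into three tetrahedra with diagonals through each
   quad face's smallest global node id — a choice that conforms between
   arbitrary neighbours;
4. the plane is bent onto the cylinder (the inner surface is mapped
   isometrically, so in-plane lengths, including the trephine
   circumference, are preserved exactly).

Region tags come from the through-thickness layer index, overridden to
`LA` where the cell centre lies inside the strip.  `fixed_edges`
collects all nodes of the four lateral boundaries through the
thickness.  An optional jitter (`seed`, amplitude `jitter`, default
off) perturbs interior nodes for mesh-sensitivity studies; generation
is bit-reproducible for a fixed spec including the seed.

What the phantom does *not* emulate: partial muscle overlaps and
aponeurotic sheets of real anatomy, fibre anisotropy, fat/skin, and a
thin (rather than full-thickness) linea alba.  Passing tests therefore
demonstrate correctness of the mechanics pipeline and the *direction*
of position effects on a controlled geometry, not patient-level values.

## Verification fixtures

* `build_unit_cube` — uniform Kuhn-split cube with per-face facet and
  node groups for roller boundary conditions.  The patch test (uniform
  pressure on one face, rollers on the three opposite faces) must
  reproduce the homogeneous state to 1e-8 for every material in the
  table; P1 elements are exact there, so the check isolates assembly
  and constraint errors.
* `build_hollow_sphere` — icosphere-based shell for the pressurized
  thick-walled-sphere closed form.  The radial direction is sampled at
  half the surface edge length because the solution varies as 1/r²;
  at the oracle's default 2 mm resolution the inner-surface radial
  displacement is within 2% of the closed form, and the error falls
  monotonically over the 8/4/2 mm ladder.  The sphere has no Dirichlet
  boundary; the solver projects out the six rigid-body modes and uses
  conjugate gradients on the consistent singular system.

## Solving

Assembly is vectorized per region; the global operator is symmetric
(checked to round-off in tests) with the six rigid modes as kernel
before constraints.  Dirichlet conditions are imposed by reduction;
the default solver is SuperLU (COLAMD ordering) — deterministic, which
matters for the bit-identical-rerun contract — with a
Jacobi-preconditioned CG fallback for larger meshes (tolerance 1e-10).
A relative residual above 1e-8 raises rather than returning a degraded
field.  Consistent pressure loads put p·A/3 on each facet node along
the inward normal; facet orientation consistency is checked via
directed-edge uniqueness.  Reactions (K u − f on constrained dofs) must
balance the applied resultant to 1e-6 relative.

The experiment runner solves each geometry once at the largest pressure
and scales the other levels (exact in this model); a self-check
re-solves one low level per sweep and requires agreement to 1e-6
relative.  `--no-linearity-shortcut` disables the optimization.

## Trephine morphometry

Measurements are taken on the trephine boundary loop at the innermost
wall surface (the outer loop is also available via configuration).  The
deformed loop is non-planar, so its area is the magnitude of the Newell
vector area `½‖Σ rᵢ × rᵢ₊₁‖`, which is rotation/translation invariant,
reduces to the enclosed area for planar loops, and needs no plane fit.
Axial and sagittal diameters are loop extents along configurable global
axes (defaults: x — the horizontal body axis — and z — the
antero-posterior protrusion direction); no CT measurement plane is
defined for a phantom, so an explicit global convention was preferred
over a local-surface one.  Percent enlargements are kept at full
precision and rounded (2-decimal cm/cm², integer %) only in formatted
tables.  Position groups average the percent fields per lateral column
(i = 1, 2, 3); `s0` is reported alone.

## Problem sizes and runtimes

Default-resolution phantoms have ≈ 17k nodes (no hole) to ≈ 35k nodes
(with the refined hole band, ≈ 100k dofs); a hole case solves in about
half a minute on one CPU and the full 18-geometry × 5-level sweep in
about nine minutes.  The verification oracles use a 0.25 mm unit cube
(patch test, machine precision) and spheres up to ≈ 15k nodes.  The
unit-test fixtures run a 160 × 200 mm coarse wall so the suite
iterates quickly; the acceptance-style checks rerun everything at the
default sizes.

## Known limitations

* **Linear kinematics at large deflection.**  With soft muscle
  (≈ 0.5–1 MPa) under 20 kPa the predicted deflections reach tens of
  millimetres — far beyond small-strain validity.  The linear model is
  retained as the faithful reading of the constitutive statement
  σ = Eε; absolute displacements should be read as extrapolations,
  comparisons between positions as the meaningful output.  A
  geometrically nonlinear solve with follower pressure is the natural
  extension point and would reduce all absolute magnitudes.
* **Inner-surface closure of the through-strip stoma.**  On the
  phantom, the `s0` trephine severs the full-thickness stiff strip;
  each severed half rotates outward under pressure and the rotation
  (arm = half the wall thickness) moves the halves' innermost fibres
  toward each other.  The innermost loop can therefore *contract*
  vertically while the outermost loop enlarges.  This is a genuine
  prediction of the stated model on this geometry — a thin tendinous
  sheet, as in real anatomy, has a much smaller rotation arm — and is
  surfaced (not suppressed) by the test suite.
* **Element order.**  P1 tetrahedra are stiff in bending; through
  -thickness resolution (one element per 3 mm layer by default) bounds
  the bending accuracy of thin-wall response.  All cross-position
  comparisons use the same discretization policy, so the comparative
  findings are consistent within the model.
* **No irreversibility.**  Enlargements are elastic and fully
  reversible; permanent trephine defect (fatigue, tissue adaptation)
  is outside the model.
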