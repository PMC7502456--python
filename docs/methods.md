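# Methods

`needlefem` simulates the deep, quasi-static insertion of a steerable
bevel-tip needle into a soft elastic block in plane strain.  The cut is
not prescribed: it emerges from a cohesive-zone fracture model, a
crack-tip-opening-displacement (CTOD) propagation condition, a
minimum-strain-energy-density (MSED) kinking condition, and iterative
remeshing.  This note records the model, its numerical realisation, the
deliberate design choices, and what the shipped problem sizes do and do
not demonstrate.

## Model

**Substrate and needle.**  Both bodies are discretised with linear
(constant-strain) triangles under plane strain.  The material input is
linear elastic (gelatine phantom: E = 14.8 kPa, nu = 0.475; needle:
E between 117 and 940 kPa, nu = 0.475), with geometric nonlinearity
retained.  The default finite-strain realisation is compressible
neo-Hookean with the same Lame constants,

    P = mu (F - F^{-T}) + lambda ln(J) F^{-T},

which coincides with Hooke's law at small strain and whose energy grows
without bound as J -> 0.  That compressive barrier is essential here:
the material under the blunt needle tip is transiently compressed to
J ~ 0.3 during indentation, where a Saint-Venant-Kirchhoff realisation
(also provided, as `model="svk"`) loses ellipticity and the implicit
solve fails on inverted elements.  A linearised-kinematics switch
(`model="small"`) exists for debugging.

**Cohesive interface.**  The fracture process zone is lumped into
zero-thickness four-node interface elements along the crack path with a
bilinear traction–separation law: stiffness K = sigma_max/delta_max up
to the strength sigma_max, then linear softening to zero traction at
delta_c, with

    G_c = (1/2) sigma_max delta_c,      delta_max = 2 rho_tip,
    delta_max < delta_c < b.

The same uncoupled law acts in the normal and tangential directions;
damage is irreversible (per-integration-point historical maximum,
secant unloading to the origin).  Gelatine values: G_c = 1.1 J/m^2;
sigma_max defaults to 550 Pa, the centre of the admissible window
(275, 2200) Pa implied by the two calibration inequalities — the
strength is not independently measurable from the data the model is
built on, so every quantity that depends on it is parameter-sensitive.
Normal interpenetration of closed faces is resisted with a separate
stiffness at the contact-penalty scale (the law's K, designed for a
soft solid, is orders of magnitude too compliant to act as an
impenetrability constraint).  The ten notch-seeded starter elements
(one for the PBN, along the bevel bisector) have their strength scaled
by 1e-2 with delta_c rescaled so G_c is unchanged.

**Propagation condition.**  The crack advances when the normal opening
at a characteristic distance behind the equivalent crack tip reaches
the peak-traction opening:

    delta_n(L_bar) = delta_max,   L_bar = rho_tip / tan(alpha)
                                       = delta_max / (2 tan alpha)
                                       = sigma_max / (2 K tan alpha).

The three expressions agree to machine precision for a calibrated law
(asserted).  The probe walks the two sides of the *deformed* cavity —
cohesive faces plus the traction-free notch walls, which are part of
the same equivalent crack — because during deep indentation the
reference-frame pair openings underestimate the separation badly (the
slit is dragged bodily with the deformation bulb).  When the cavity is
shorter than L_bar the probe clamps to the notch mouth.

**Kinking condition.**  At criticality, strain energy densities are
sampled at the centroids (the single Gauss point of a CST) of the ring
elements around the tip in the deformed configuration, interpolated
with a periodic cubic spline over the angle relative to the current tip
direction, and minimised over an admissible range of +-75 degrees (the
pure-shear MSED kink for nu near 0.5 is ~80 degrees; the bound is
configurable).  One guard applies: while the tip-adjacent faces are
still pressed shut (deformed pair separation below 5% of delta_max) the
SED distribution reflects the compressive indentation bulb rather than
a crack-tip field, and the crack continues straight.  Once the tip zone
is crack-like, MSED governs.

**Outer algorithm.**  Each iteration replays the insertion from
D_e = 0 (the new interface changes the stiffness, so history cannot be
continued), drives the needle in displacement increments until the
CTOD condition fires, computes the kink angle, appends one cohesive
element of tip-element length h along the kinked direction, and
remeshes the inner region.  Reported results (force curve, tip path,
energies) come from the last iteration.  A warm-path replay uses
triple-length steps below 85% of the previous iteration's critical
displacement.

**Contact.**  Node-to-segment contact couples the substrate cavity
boundary (notch walls, crack faces, nearby top surface) to the needle
outline: augmented-Lagrangian normal enforcement (penalty
30 E_gel / h_tip by default; multipliers updated until the worst
penetration falls below 1e-3 h_tip or stops improving), smoothed vertex
normals so the force direction is continuous across the facets of the
curved tip cap, and a rule that a penetrated follower can never
deactivate regardless of projection distance.  Friction is Coulomb
f = 0.3 with a tanh-saturated regularisation,

    t_t = f p tanh(eps_t (s_ref - s) / (f p)),

exactly on the cone at finite slip but smooth at the stick/slip
transition (a hard return mapping makes plain Newton cycle around the
cone vertex).  Frictional dissipation accumulates per converged
increment from the traction times the irreversible slip.  The trocar is
a pair of rigid frictionless vertical walls at x = +-b/2 acting on
needle boundary nodes above the surface.

**Meshing.**  DistMesh-style: graded point seeding from a sizing field
h(x) = clip(h_min + 0.35 dist, h_min, h_max) around the crack, tip ring
and notch; spring relaxation; Delaunay; removal of triangles outside
the region polygon.  Crack-path segments, boundary chains and the
forward tip-ring spoke are protected by seed-exclusion zones and their
presence is verified (missing edges raise, with seed-perturbed
retries).  The outer substrate region is meshed once and cached; every
crack extension rebuilds only the inner region, preserving stored
crack-path coordinates bitwise and keeping two element edges collinear
with the propagation direction (the forward spoke and the last path
segment).  Crack faces are duplicated node pairs (plus face = +x side
of a downward path); the tip ring defaults to 16 sectors at radius
2 h_tip.  Mesh quality is enforced at a 20-degree minimum interior
angle for the substrate; the slender needle wedge is allowed slightly
thinner triangles.

**Needle geometry and the starter notch.**  A tangent fillet of radius
rho_tip on a 10-degree half-angle wedge truncates the theoretical apex
by rho_tip (1/sin(alpha_w) - 1) — about 2.4 mm for the standard
symmetric tip — so the *material* tip is a blunt circular cap roughly
1 mm wide.  All positioning is by the material bottom, and the starter
notch is the needle profile itself clipped to the surface: flank walls
along the wedge faces and the fillet cap at the bottom.  The notch
depth defaults to 3 mm (factor 6 on rho_tip) in the run presets: a
shallower congruent notch leaves the blunt cap plowing a wrap-around
field that no fixed mesh resolution survives, while the paper-style
observation that the notch affects only the earliest force response
holds here too (the notch region is fully traversed within the first
millimetres).  The needle starts with a standoff (half the notch depth)
so flank wedging opens the seeded crack before the cap reaches intact
material.

## Numerics

- Newton with a monotone backtracking line search (least-bad fallback
  when no scale reduces the residual, which happens while crossing a
  contact-state corner); convergence at a relative residual of 1e-6.
  A solve that stalls on nonsmooth switches is accepted once its best
  residual is below 1% of the force scale — the dominant equilibrium
  error of the method, and the reason the energy-balance closure is
  checked at the 2% level.
- Load steps of 0.5 h_tip (0.1 h_tip once the probed CTOD exceeds 75%
  of delta_max), halved on failure down to 0.002 h_tip.  Two rescue
  layers act before a step is abandoned: adaptive stabilization
  (springs to the last converged state, factor 2e-3..2e-1 of the
  tangent diagonal, used as a predictor whose result must re-converge
  without springs) for snap-throughs with no nearby static equilibrium,
  and, bounded at 25 per iteration, acceptance of a quasi-equilibrium
  at an 8% residual.  If a deep state admits no acceptable equilibrium
  at all (at desk scale this happens at the PBN tip-shaft transition),
  the insertion terminates early and reports the history up to that
  point.
- The needle interior mesh is left deliberately (mildly) asymmetric
  even for the symmetric tip: exactly mirror-symmetric discretisations
  make left/right contact events simultaneous and the associated
  snap-throughs degenerate, which stalls the solver.

## Problem sizes and what they show

The shipped presets:

- `symmetric` / `pbn-c22` / `pbn-c32` / `pbn-c47`: the standard bench
  scale (235 x 245 mm block, b = 8 mm, h_tip = rho_tip/2 = 0.25 mm,
  insertion depths of tens of mm).  Hours-scale runs.
- `coarse-*`: block shrunk 4x, h_tip doubled.
- `micro-*`: the desk-scale study used by the test suite and
  `scripts/acceptance.py`: identical needle tip geometry, materials and
  cohesive calibration, an 80 x 60 mm block, h_tip = 0.25 mm, target
  depths of 4–8 mm (PBN offset c = 6 mm).

At micro scale the algorithm demonstrably produces straight symmetric
cuts (every kink angle exactly zero; established path deviation at
round-off), closes the energy balance to within a few per cent
(1.5-5% across seeds and depths; the absolute residual, dominated by
contact work during the engagement transient, is roughly fixed while
the work integral grows with depth), and reproduces the qualitative
force-curve structure up to the PBN tip-shaft transition.
Three things the micro scale does *not* probe: (i) steering curvature —
the paper-scale radii (hundreds of mm) imply lateral deflections of
tens of micrometres at these depths, below the elastic lean induced by
the unstructured discretisation (~0.5 mm); (ii) the post-transition
relaxation of the PBN force peak, where the withdrawn segment's blunt
entry currently exceeds the solver's robustness at this resolution; and
(iii) cohesive dissipation U_G as a major energy term, because at a few
millimetres of depth friction and stored energy dominate.

## Known limitations

- Displacement-based elements at nu = 0.475 carry a mild volumetric
  locking risk; the patch and cantilever oracles plus mesh-convergence
  checks are the guard, not a mixed formulation.
- One-way contact (substrate followers against the needle outline)
  assumes the substrate mesh is at least as fine as the needle surface.
- Crack-face self-contact without the needle between the faces is
  carried by the compressive branch of the cohesive elements only.
- The initial transient (blunt indentation before the first genuine
  propagation event) is regularised by the seeded weak elements, the
  congruent notch and the straight-continuation guard; quantities read
  during that transient are initialisation artifacts, which is why
  results are taken from the final iteration at depth.
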