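# Methods

`ocufsi` is a desk-scale re-implementation of an image-based
fluid–structure-interaction (FSI) workflow for the juxtacanalicular tissue
(JCT) and the Schlemm's canal (SC) inner-wall endothelium with its basement
membrane (BM): synthetic segmented-micrograph generation, binary
segmentation, pixel-to-element meshing, an explicit weakly-compressible FSI
solve, and postprocessing of tensile stress/strain, wall shear and
giant-vacuole morphometry.  This note records the model, the parameters that
matter and why they have the defaults they do, the numerical choices, and
the limits of what the synthetic fixture can show.

## The physical model

**Solid.** The JCT matrix, SC inner-wall cells and BM are a single nearly
incompressible linear elastic material (E = 3.05 kPa, ν = 0.495,
ρ = 700 kg/m³ — the high-flow-region value after 24 h perfusion); the
scleral tether is elastic with E = 2.54 MPa, ν = 0.495, ρ = 1000 kg/m³.  No
failure, viscoelasticity or anisotropy: at large tensile load elements
stretch without breaking, so regions of very high first-principal strain
should be read as candidate failure sites, not as converged material
response.

**Fluid.** Aqueous humor is Newtonian (ρ₀ = 1000 kg/m³,
μ = 0.7185 × 10⁻³ Pa·s) and weakly compressible with a Mie–Gruneisen
equation of state with cubic shock-velocity/particle-velocity Hugoniot
(C = 1480 m/s, S₁ = 2.56, S₂ = −1.98, S₃ = 0.226, γ₀ = 0.5, a = 0).  The
published form of the pressure equation is typographically corrupted; the
standard hydrocode form consistent with those constants is implemented:
compression branch

p = ρ₀C²μ·[1 + (1 − γ₀/2)μ − (a/2)μ²] / [1 − (S₁−1)μ − S₂μ²/(μ+1) − S₃μ³/(μ+1)²]² + (γ₀ + aμ)E

with μ = 1/V − 1, and a linear branch p = ρ₀C²μ + (γ₀ + aμ)E in expansion
(μ < 0).  The two branches join with continuous value and slope, giving the
acoustic limit p ≈ ρ₀C²μ (sound speed C) at the reference state V = 1.

**Coupling.** The tissue is immersed in a fixed Eulerian fluid grid ("sunk
in the aqueous humor"): fluid occupies every cell, and coupling points
distributed along the Lagrangian solid boundary (spacing ≈ half a fluid
cell) carry penalty springs on the accumulated fluid–solid relative
displacement, normal *and* tangential ("tension and compression" coupling;
the tangential spring is the no-slip condition for a viscous fluid).  Forces
are spread to the staggered fluid faces by the adjoint of bilinear
interpolation and applied equal-and-opposite to the solid nodes, so the pair
adds zero net momentum to machine precision.  The spring constant is the
penalty factor (default 0.1) times an interface stiffness estimated from the
fluid bulk modulus and face geometry, capped at the explicit stability limit
of the lighter coupled mass.  Fluid trapped inside solid parts simply rides
along; it adds only volumetric stiffness, minor because the tissue is itself
nearly incompressible.

**Boundary conditions.** The inlet (anterior-chamber side, the bottom of the
domain) is a pressure reservoir ramped linearly 0 → 7 mmHg
(933.25 Pa; 1 mmHg = 133.322 Pa); a flow-controlled variant instead
prescribes the inlet face velocity (used when the run must carry a stated
flow, e.g. one pore's share of 2.5 µL/min).  The outlet (SC side, top) is
non-reflecting: an impedance ρ₀c per unit area acts on the *deviation* of
the outlet face velocity from its slow running mean.  A plain impedance on
the full velocity would add a large spurious back-pressure to the steady
outflow at the reduced desk-scale sound speed; acting on the fluctuation
absorbs acoustic transients (< 5% reflected amplitude in the pulse test)
while the mean outflow sees the 0-gauge reference.  Lateral walls are slip
walls; the scleral strips are fixed on their lateral faces (the tether);
tissue self-contact is a node–segment penalty between non-adjacent boundary
segments.  The 2-D plane-strain configuration is the desk-scale default and
is exactly the one-element-thick slab with z-fixity on the slab faces.

**Model #1 / #2.** Fluid elements are tagged FLUID_AC (anterior-chamber
component) or FLUID_ZERO (0-gauge component; near-wall spaces in model #1,
plus intertrabecular spaces 3–5 µm below the BM in model #2).  The tag is an
initial-condition bookkeeping device; because the inlet ramp itself starts
at 0 gauge, the entire fluid starts unpressurized and the two models evolve
identically here.  The tag is retained in the mesh and output for region
bookkeeping and for protocols whose ramp starts above zero.

## The synthetic microstructure

The native tissue images are not deposited, so a generator emulates a
segmented cross-section with full ground truth.  Layered construction, from
the inlet: anterior-chamber fluid band (2 µm); JCT band (20 µm deep — the
depth the flow traverses); BM (0.5 µm); inner-wall cell layer (1.5 µm); SC
lumen (9 µm).  On this skeleton:

- **Intertrabecular spaces**: the JCT band is open aqueous space crossed by
  elliptical trabecular beams (≈5 × 1.6 µm, random orientation) added until
  the void fraction reaches 0.55.  The spaces are capacious and
  interconnected, so the upstream flow is slow.  Beams thinner than 0.8 µm
  and beams not connected to the wall complex or sclera are removed (they
  would be mechanically meaningless or drift freely).
- **Dense subendothelial layer**: the deepest 2 µm of the JCT against the
  BM is solid matrix, perforated only by a 2 µm funnel under each vacuole.
  This is where the outflow literature (and the reference workflow's own
  discussion) localizes the resistance; mechanically it also gives the wall
  assembly its realistic effective thickness.  Without it the 3 kPa wall
  carries the full pressure drop over an unsupported span, strains run away
  and the vacuole membrane tears open at the pore — elastically modeled
  rupture, which is outside the model's stated scope.
- **Giant vacuole**: an elliptical cavity (default 7 µm wide, 4.5 µm
  wall-normal) rooted at the cell-layer base, bulging into SC under a
  uniform 1.5 µm membrane shell; its basal side opens to the JCT through a
  0.6 µm discontinuity in the BM (the low end of reported BM discontinuity
  sizes, so that the basal path — not the dome pore — dominates the series
  resistance and the dome stays below its elastic stability limit).  A
  stated fraction of vacuoles (default: all) carries an open pore — a
  1.3 µm channel through the shell apex connecting the cavity to SC.
- **SC lumen**: 7 µm tall, so the inflated dome locally constricts the
  canal as giant vacuoles do in situ; the squeeze flow around the dome is
  what keeps the SC shear average above the JCT-space average.
- **Sclera**: 1.5 µm strips on both lateral sides spanning 12 µm from the
  wall top downward.  The 15 µm domain width leaves a 12 µm tissue span
  between the tethers, the tether length scale of the reference workflow;
  with E ≈ 3 kPa, spans much longer than this deflect by many micrometres
  under 933 Pa and the cross-section stops being meaningful.
- **Pore density**: printed per mm² of inner wall (292/mm²); the expected
  pore count over a 2-D slab is density × wall length × slab thickness
  (≪ 1 for one cross-section), so fixture pores come from the
  open-pore-fraction parameter, not from areal sampling.

Grayscale rendering maps labels to representative gray levels, adds Gaussian
noise, and sprinkles dark speckle on the fluid side of tissue boundaries —
the "black dot" shading artifacts the segmentation stage must remove.

What the generator does **not** emulate: nucleus/cytoplasm contrast,
3-D interconnection of pores across slices, low-flow-region morphology,
electron-optics physics.  Passing tests therefore demonstrate that the
*workflow* recovers known ground truth and reproduces the reported
magnitudes on a morphologically plausible stand-in — not that it reproduces
any particular eye.

## Numerics

- **Meshing**: structured parent grid (default edge 0.25 µm) with
  majority-vote part assignment per element and a tissue-wins tie-break
  (conservative toward retaining the flow-resisting solid).  Validation by
  boundary overlay at 5 cross-sections and mesh-density (refinement)
  analysis.
- **Solid**: one-point-integrated plane-strain quadrilaterals,
  updated-Lagrangian hypoelastic stress rate with Jaumann rotation,
  Flanagan–Belytschko stiffness hourglass control (coefficient 0.1), lumped
  mass, central-difference update with unconditionally stable
  mass-proportional damping.
- **Fluid**: staggered (MAC) finite-volume grid; velocity update from
  pressure (EOS) + linear bulk artificial viscosity (0.15) + viscous + 
  coupling forces, then conservative donor-cell transport of mass and
  first-order upwind transport of momentum/energy.  Closed domains conserve
  mass to round-off.  Empirical acoustic stability bound 0.5·dx/(c+|u|).
- **Desk scaling**: the reference protocol (0.5 s ramp, 500 output steps,
  ≈10⁻¹⁰ s stable step at C = 1480 m/s) is far beyond desk budgets.  The
  package runs the same ramp shape quasi-statically: effective sound speed
  reduced to 20 m/s (flow Mach number stays ≪ 1, so the incompressible
  limit is preserved), ramp compressed to 0.2 ms plus a 30% hold, mass
  damping 2×10⁵ s⁻¹ (structural settling time ≪ ramp), 60 output snapshots.
  The stiff sclera is selectively mass-scaled so it does not control the
  global step — standard quasi-static explicit practice; its inertia is
  immaterial at these rates.  Problem size of the standard run: 60 × 124
  fluid cells / ≈3,500 solid elements at 0.25 µm over a 15 × 31 µm section.
  The per-point coupling loop is JIT-compiled when numba is available, with
  an equivalent vectorized numpy path otherwise (verified identical).
- **Energy bookkeeping**: external (coupling + contact) work, internal,
  kinetic, hourglass and damping energies are integrated with midpoint
  velocities; a run aborts if kinetic + internal energy exceeds 10× the
  external work (instability guard).

## Postprocessing definitions

- First-principal stress/strain: largest eigenvalue per element.
- Fluid shear stress magnitude: √(½ τ:τ) with τ = 2μ·dev(sym ∇u) (equals
  μ·du/dy in simple shear); "volumetric average shear stress" is its
  volume-weighted mean over a region.  This volume-based reading is the
  primary one; per-face wall shear stress (one-sided gradient with no-slip)
  is computed as the secondary route since the phrase admits both.
- Regions: JCT spaces = intertrabecular spaces + vacuole interiors; SC
  lumen; both exclude cells within 2 µm of the sclera (the tether's
  artifact zone, distance configurable) and cells mostly covered by solid at
  the evaluated state.  Membrane peak stress/strain likewise exclude the
  near-sclera zone.
- Vacuole morphometry: the Lagrangian boundary nodes lining each cavity are
  identified in the reference configuration and tracked; width = max
  wall-parallel extent, length = max wall-normal extent, per state; a
  least-squares (Kasa) circle fit gives the diameter whose sphere
  (π/6)d³ reconstructs a volume.
- Trans-pore velocity: mean speed over the open cells of the mid-height
  cross-section of the displaced pore throat (the pore moves with the
  membrane).  It is measured in the pressure-driven 7 mmHg state — the
  condition under which the reference velocity was obtained.  A 2-D slot
  cannot carry the full 3-D per-pore velocity: the slot's per-depth
  resistance would impose a trans-dome differential (σ ≈ r·v·12µ/w²,
  independent of wall thickness) beyond the elastic dome's stability limit,
  so the stable-dome ceiling here is a few cm/s and the reported value sits
  below the 3-D figure by design of the dimensional reduction, not by
  physics of the wall.
- Recirculation: contiguous regions of positive 2-D swirling strength
  (complex velocity-gradient eigenvalues) above 10% of the field maximum;
  parallel shear has zero swirling strength, so channel flow reports none.
- Analytic pore velocity V = Q/(Nπ(d/2)²) and Reynolds number ρvL/μ are
  direct arithmetic with exact unit conversion.

## Known limitations

- Linear elasticity at 30–60% strain: the hypoelastic rate form is the
  hydrocode convention, but strain magnitudes near the reported peaks are at
  the edge of the model's validity — as in the reference workflow itself.
- The immersed-boundary wall is diffuse at the ~1-cell scale, so narrow-gap
  resistances carry an O(dx/h) geometric uncertainty.
- One 2-D cross-section cannot carry the 3-D pore network; the fluid bathes
  the tissue as a single connected component instead.
- Model #1 vs #2 differ only in initial-condition tags under a 0-starting
  ramp (see above).
- The synthetic geometry is a stand-in: field-level agreement with the
  reported values is expected only at the order-of-magnitude / factor-2
  level.  The peak measures (membrane stress and strain) sit at the
  compliant end of that band because an isolated 2-D section concentrates
  the full pressure drop on a single tethered wall span; the JCT-space
  shear average sits at the high end because the throttling jets through
  the funnel and basal openings lie inside the averaged region; and the
  trans-pore velocity sits below the 3-D value for the slot-resistance
  reason above.
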