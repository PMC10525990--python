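# ocufsi

Image-based fluid–structure interaction (FSI) of the human aqueous outflow
tissue: the juxtacanalicular tissue (JCT) and the inner-wall endothelium of
Schlemm's canal (SC) with its basement membrane (BM).  Most aqueous humor
leaves the eye through this few-micrometre-thick interface, and its
mechanics — tissue deformation, giant-vacuole inflation, funneling of flow
into sparse inner-wall pores — sets the outflow resistance that regulates
intraocular pressure.  `ocufsi` is for researchers in ocular biomechanics
who want a desk-scale, fully scripted version of the segmented-micrograph →
finite-element → coupled-FSI → morphometry workflow, with synthetic
ground-truth microstructure standing in for (non-deposited) serial
block-face SEM data.

## What is inside

1. **`ocufsi.microstructure`** — generator for labeled cross-sections of the
   JCT/SC complex (capacious intertrabecular spaces with trabecular beams,
   BM, inner-wall cell layer, giant vacuoles with optional open pores of
   diameter 1.3 µm, scleral tether strips) plus noisy grayscale renderings
   and per-vacuole ground truth.
2. **`ocufsi.segmentation`** — thresholding (manual/Otsu), removal of dark
   boundary-shading artifacts, pixel-edge boundary polylines.
3. **`ocufsi.mesh`** — structured parent mesh (4-node quads, default edge
   0.25 µm; one-element slab of 8-node hexahedra available), majority-vote
   part assignment (tissue / sclera / fluid at anterior-chamber pressure /
   fluid initialized at 0), boundary-overlay validation, mesh-density
   analysis.
4. **`ocufsi.constitutive`** — nearly incompressible linear elasticity
   (tissue E = 3.05 kPa, ν = 0.495; sclera E = 2.54 MPa) and the aqueous
   humor as a Newtonian fluid (µ = 0.7185 mPa·s) with a Mie–Gruneisen
   equation of state with cubic shock-velocity/particle-velocity Hugoniot,

   p = ρ₀C²µ [1 + (1 − γ₀/2)µ − (a/2)µ²] /
       [1 − (S₁−1)µ − S₂µ²/(µ+1) − S₃µ³/(µ+1)²]² + (γ₀ + aµ)E,
   µ = 1/V − 1.

5. **`ocufsi.solver`** — explicit central-difference Lagrangian solid
   (one-point quadrature with hourglass control) immersed in a staggered-grid
   weakly compressible Eulerian fluid, penalty-coupled (factor 0.1), with a
   0 → 7 mmHg inlet ramp, an impedance-matched non-reflecting outlet,
   scleral tethering and tissue self-contact.
6. **`ocufsi.postprocess`** — first-principal stress/strain fields, fluid
   shear-stress magnitude and wall shear stress, region-restricted
   volumetric averages, swirl-based recirculation detection, giant-vacuole
   morphometry (width/length, circle-fit diameter, sphere volume), and the
   analytic trans-pore velocity V = Q/(Nπ(d/2)²).
7. **`ocufsi.pipeline` / `ocufsi` CLI** — one-config orchestration of all
   stages with caching and a run manifest.

See `docs/methods.md` for the model, its assumptions and the desk-scale
numerical choices.

## Worked example

```bash
python examples/04_materials_and_pore_flow.py
```

prints (abridged):

```
aqueous humor Gruneisen EOS (C=1480 m/s, S1=2.56, S2=-1.98, S3=0.226):
  V= 1.000 -> compression  0.00e+00 -> p =  0.000e+00 Pa
  V= 0.999 -> compression  1.00e-03 -> p =  2.201e+06 Pa
  V= 0.990 -> compression  1.01e-02 -> p =  2.300e+07 Pa
tissue (E=3.05 kPa, nu=0.495): 1% uniaxial strain -> sigma_xx = 1030.27 Pa

trans-pore velocity V = Q/(N pi (d/2)^2) at Q = 2.5 uL/min, d = 1.3 um:
  N =  33 pores -> V = 0.951 m/s  (Re = 1.721)
  N =  62 pores -> V = 0.506 m/s  (Re = 0.916)
  N = 292 pores -> V = 0.108 m/s  (Re = 0.195)
```

The EOS pressures show the stiff acoustic response of water (≈ ρ₀C²µ); the
uniaxial stress reflects the near-incompressible plane-strain tangent; the
three velocities are the classic Q = VA estimates of trans-pore speed for
published pore counts, with creeping-flow Reynolds numbers.

The coupled run itself:

```bash
python examples/06_standard_fixture_pipeline.py   # a few minutes
```

generates the standard fixture (one giant vacuole with an open pore over a
20-µm JCT), ramps the inlet to 7 mmHg and writes `runs/<hash>/summary.json`
with peak membrane tensile stress [kPa] and strain [%], volumetric average
shear stress in the JCT spaces and SC lumen [Pa], the mean trans-pore
velocity [m/s], the recirculation count on the SC side, and the vacuole
width/length increases [%] between 0 and 7 mmHg.

Other examples: `01` generator + census, `02` segmentation round trip,
`03` meshing + overlay + refinement, `05` a small coupled run checked
against the Laplace law.

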