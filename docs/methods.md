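# Methods

## Scope and model chain

`atriasim` simulates the chain from single atrial myocyte to body-surface
P-wave in four stages:

1. **cell** — a human atrial myocyte ionic model with eight regional
   phenotypes;
2. **tissue** — anisotropic monodomain reaction–diffusion on hexahedral
   meshes;
3. **forward** — extracellular potentials, either in an infinite
   homogeneous medium (pseudo-ECG) or through a heterogeneous torso volume
   conductor;
4. **analysis** — LAT/APD maps, B-RMS surface maps, P-wave features and
   per-region source decomposition.

## Ionic model

The membrane model is the Maleckar et al. human atrial myocyte model: the
Nygren cell architecture (GHK-type fast Na⁺ current; L-type Ca²⁺ current
with Ca²⁺-dependent/-independent inactivation; compartmental intracellular,
cleft, diadic, SR-uptake and SR-release spaces; Na⁺/K⁺ pump, NCX, SERCA,
RyR with two-state adaptation; calmodulin/troponin/calsequestrin buffers)
with the transient outward current I_t and ultra-rapid delayed rectifier
I_Kur refit to human atrial data, plus an ACh-gated K⁺ current that is
zero at the default ACh ≈ 0. The complete constant set and initial state
live in `src/atriasim/cell/maleckar_constants.json` (units s, mV, pA, nS,
pF, mM, nL); that file is the single source of truth for the model
parameters. The stimulus current is booked against intracellular K⁺ so
that long pacing trains conserve charge and the concentrations can reach a
true periodic steady state.

**Regional phenotypes.** Eight regional variants scale three maximum
conductances (g_to, g_CaL, g_Kr) of the baseline model:

| region | g_to | g_CaL | g_Kr |
|---|---|---|---|
| RA/PM (baseline) | 1.00 | 1.00 | 1.00 |
| CT/BB | 0.50 | 1.00 | 0.50 |
| RAA | 1.35 | 1.00 | 1.00 |
| TV | 1.35 | 0.80 | 2.00 |
| LA | 1.00 | 0.67 | 1.60 |
| PV | 1.35 | 0.67 | 3.20 |
| LAA | 1.35 | 0.67 | 1.60 |
| MV | 1.35 | 0.53 | 3.20 |

Only these three currents are scaled; nothing else differs between
regions.

**Integration.** Forward Euler at dt = 0.02 ms with Rush–Larsen
(exponential) updates for the twelve Hodgkin–Huxley gates. Halving dt
changes APD90 by < 0.05 ms. The model is not defensive against
non-physiological overdrive: stimuli much stronger than ~52 pA/pF × 2 ms
push the state out of its stable basin and the integrator reports the
blow-up rather than clamping.

**Stabilization protocol.** The reference protocol is 3600 one-hertz
beats (1 ms, 52 pA/pF). Because the model approaches its limit cycle in
roughly the first ten minutes of pacing, `pace_to_steady_state` monitors
APD90 every 20 beats and stops once the drift per 20 beats falls below
0.2 ms (minimum 200, cap 1200 beats; typically 200–350 beats). APD90
values obtained this way agree with the full-protocol values to within
about 1 ms, well inside the ±3 ms acceptance band used in the tests.

**APD measurement.** Onset = time of maximum dV/dt in the beat; APD_x =
time from onset until Vm first repolarizes past peak − x·(peak −
pre-stimulus diastolic Vm), linearly interpolated. Steady state is
quantified as the relative change of pre-stimulus [Na⁺]ᵢ, [K⁺]ᵢ, [Ca²⁺]ᵢ
between the first and last of the final 60 beats ("2%" is read as 2%
relative change per species — the only unit-consistent reading).

## Tissue model

Monodomain with an equivalent conductivity tensor
D = σ_T I + (σ_L − σ_T) f fᵀ per element, no-flux boundaries. σ values are
"equivalent" conductivities in mS/cm: they absorb the surface-to-volume
ratio and are converted to diffusivity (cm²/ms) through a fixed membrane
factor χC_m = 1400 µF/cm³. The factor itself is immaterial because σ_L is
pinned by conduction-velocity calibration, exactly as in the source
modelling tradition.

Discretization: trilinear FEM stiffness on hexahedra (2×2×2 Gauss),
lumped mass, Godunov operator splitting — reaction step per node with its
regional ionic model (numba-compiled), diffusion step by backward Euler
with a sparse LU factorization computed once per run. dt = 0.02 ms,
output sampling 1 ms (0.5 ms in the CV rigs).

**Fibres.** The longitudinal fibre direction of each element is
normalize(p(region) × n(element)) where p is the region's principal
defining vector and n the outward surface normal (radial mid-surface
normal on shells, +z on slabs). The rule makes fibres exactly tangential
to the shell; degenerate cross products are an error, so principal
vectors must not be parallel to any normal within their region's patch.

**CV calibration.** Conduction velocities are the physiological inputs;
σ_L is the output. The rig is the 50×50×3-element, 300 µm slab with
fibres along x and a planar stimulus band of fixed 0.8 mm depth (a single
stimulated node plane cannot capture at high σ — diffusive loading).
Probes sit at 30%/70% of slab length on the mid-depth line. Root finding
exploits the near-exact CV ∝ √σ_L law (σ ← σ(target/cv)², bisection on
log σ as a bracketed fallback); convergence to 1% in CV takes 3–5 slab
runs. Targets: RA/LA 63.3; IST 75.0; PV 76.6; CS/LFO 99.5; PM 107.0;
CT/BB 116.0 cm/s (the mapping of individual bundles onto the fast range
is a surrogate choice). Anisotropy ratios σ_T/σ_L: 0.15 bundles, 0.35
general tissue, 0.5 PV/CS, 1.0 IST/SAN/FO.

At 300 µm the transverse wavefront of general tissue is under-resolved
and the measured CV_T falls ~10% below the continuum √ratio prediction —
ordinary grid-induced CV slowdown, which the calibrated σ values absorb.
Properties that compare against continuum monodomain theory (√σ scaling,
CV_T/CV_L = √(σ_T/σ_L)) are therefore tested on a 150 µm slab, where the
residual error is ~1–2%.

## Forward problem

**Pseudo-ECG.** V(r) = −(γ/4π)(σᵢ/σₑ) Σ_e ∇Vm(e)·∇′(1/|r′−r|) vol(e),
with constant-per-element trilinear gradients at centroids and the
analytic kernel gradient. γ = 1 and σᵢ/σₑ = 1 by default: they only scale
amplitude, so every amplitude-bearing test is ratio- or sign-based. The
integral is linear in Vm and in the element set, which makes per-region
masking an exact decomposition (traces over a partition sum to the total
at machine precision). Observation points inside or touching the source
mesh are rejected (singular kernel).

**Torso volume conductor.** Quasi-static: each output step solves
∇·(D_T∇V_T) = 0 with organ-wise isotropic conductivities (myocardium
4.589, bone 0.200, liver 0.277, lung 0.389, chest 2.390, blood 7.0
mS/cm), Dirichlet data on an inner source layer offset 0.8 mm outside the
atrial boundary — fed by the infinite-medium integral — and zero flux on
the skin. P1 tetrahedral FEM; the interior block is factorized once and
reused for all time steps.

The desk-scale torso is a structured box (default 24×18×30 cm, 1–1.5 cm
spacing, Kuhn 6-tet decomposition) with simplified organs: two lung
ellipsoids, a spine column, a liver block, and a blood sphere wrapped in
a myocardial shell at the heart centre. The source layer is the set of
mesh nodes nearest the offset sphere, i.e. at 0.8 mm ± one element
spacing — the layer concept is preserved, its geometric sharpness is
limited by the mesh. On the structured Kuhn mesh the discrete maximum
principle holds and is tested.

## Synthetic geometry

The idealized bi-atrial surrogate is two voxelized ellipsoidal shells
(500 µm voxels, 1 mm wall) joined at the septum, with the 21 anatomical
region labels painted by angular sectors: caval/valve rings as polar
caps and bands, crista terminalis as a meridian strip with the sinoatrial
node carved from its top (guaranteeing shared faces), pectinate and
appendage patches on the free wall, and the Bachmann-bundle labels on the
upper septal contact so the right and left limbs are face-adjacent. The
principal fibre vectors per region are surrogates chosen to be
non-parallel to every normal in their patch.

What this surrogate shares with real atria: topology (two chambers,
interatrial connection through BB and septum), regional heterogeneity,
fibre anisotropy, wall thinness. What it does not: true anatomy, bundle
geometry, wall-thickness variation, realistic inter-region distances.
Consequently the full-organ activation/P-wave numbers of the source
study are *not* reproduced here; tests assert orderings and directions
(SAN activates first, LA is entered through the septal bundle labels
after the RA, isotropy shortens total activation, torso heterogeneity
changes lead amplitude, region-contribution ranking is stable across
mesh resolution) rather than absolute times or amplitudes.

The sinus stimulus in tissue is 52 pA/pF × 2 ms on a 0.25 cm ball around
the SAN centroid: at surrogate resolution, the bare SAN patch is too
small a source to drive the fast bundles (source–sink mismatch).

## Signal analysis

Activation threshold −40 mV, upward crossing, linear interpolation.
B-RMS is the per-point RMS of the potential trace over the analysis
window, without baseline subtraction. P-wave features: duration = span
where |V| > 5% of max |V|; amplitude = max − min; morphology by signed
lobe analysis with a 25% secondary-lobe/notch gate (both gates are module
constants). Region contribution shares are each region's summed RMS over
all surface points, normalized to 100%.

## Numerical and design choices

- Backward-Euler diffusion is unconditionally stable; at dt = 0.02 ms the
  splitting error is negligible next to spatial discretization error.
- Node-level regional parameters take the label of the lowest-index
  incident element (deterministic tie-break at region interfaces).
- All stages are deterministic: identical configs give byte-identical
  artifacts; the only admissible randomness is explicit fixture jitter
  under a caller-provided seed.
- Problem sizes used by the shipped tests and the acceptance script:
  single-cell runs of 200–1200 beats (convergence-stopped), the 7500-
  element calibration slab, surrogate atria of ~6×10³ elements at 500 µm
  (and 600 µm for refinement checks), torso boxes of ~2–8×10⁴ tetrahedra.

## Known limitations

- No bidomain, mechanics, or adaptive time stepping.
- The ionic model diverges under non-physiological overdrive (reported,
  not clamped).
- The 53-sub-region fibre refinement is supported as a label vocabulary
  but no sub-region fixture ships, since the per-sub-region principal
  vectors are not published at this level.
- Pseudo-ECG amplitudes are arbitrary up to γσᵢ/σₑ; only ratios, signs
  and morphologies are meaningful.
- The torso surrogate's source layer tolerance equals its element
  spacing; a sub-millimetre-sharp layer requires local refinement that
  the structured generator does not provide.
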