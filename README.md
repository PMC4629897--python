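# atriasim

Multi-scale simulation of human atrial electrical activation and its
body-surface signature: regionally heterogeneous atrial myocyte models,
anisotropic monodomain tissue propagation on hexahedral meshes, forward
computation of extracellular potentials, and P-wave / body-surface-map
analysis.

It is written for computational cardiac electrophysiologists who want a
desk-scale, fully scripted version of the classic sinus-rhythm modelling
chain: tune a cell model, calibrate tissue conduction velocities on a slab,
activate an atrial geometry from the sinoatrial node, and ask which atrial
regions the P-wave actually comes from.

## Model core

* **Cell.** The Maleckar human atrial myocyte model (Nygren-lineage
  compartmental Na⁺/K⁺/Ca²⁺ handling, refit I_t and I_Kur). Eight regional
  phenotypes scale (g_to, g_CaL, g_Kr) — e.g. crista terminalis / Bachmann
  bundle (0.50, 1.00, 0.50) for long plateaus, pulmonary veins
  (1.35, 0.67, 3.20) for early repolarization.
* **Tissue.** Monodomain, C_m ∂V_m/∂t = ∇·(D∇V_m) − I_ion, with
  D = σ_T I + (σ_L−σ_T) f fᵀ per element and no-flux boundaries. Fibres
  follow the cross-product rule f = normalize(p_region × n̂_surface).
  Longitudinal conductivities are calibrated so a planar wave on a
  50×50×3-element, 300 µm slab runs at the target conduction velocity
  (63.3 cm/s general tissue … 116.0 cm/s bundles).
* **Forward.** Infinite-medium pseudo-ECG,
  V(r) = −(γ/4π)(σᵢ/σₑ) Σ_e ∇V_m·∇′(1/|r′−r|) vol(e), and a quasi-static
  heterogeneous torso (organ-wise Laplace solve with Dirichlet data on a
  source layer 0.8 mm outside the atrial wall).
* **Analysis.** LAT and APD₉₀ maps, B-RMS surface maps, P-wave
  duration/amplitude/morphology classes, and exact per-region contribution
  decomposition by masking the linear source integral.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Stabilize two regional cells and calibrate general atrial tissue:

```python
from atriasim.cell import make_regional_cell, pace_to_steady_state
from atriasim.calibration import tune_sigma_longitudinal, simulate_slab_cv

for region in ("RA/PM", "CT/BB", "PV"):
    trace, apds = pace_to_steady_state(make_regional_cell(region))
    print(f"{region:6s} APD90 = {apds[-1]:6.2f} ms "
          f"({trace.metadata['beats_run']} beats)")

sigma, cv = tune_sigma_longitudinal(63.3, 0.35, make_regional_cell("RA/PM"))
print(f"sigma_L = {sigma:.3f} mS/cm, verified CV = {cv:.2f} cm/s")
```

prints

```
RA/PM  APD90 = 200.04 ms (200 beats)
CT/BB  APD90 = 227.34 ms (260 beats)
PV     APD90 = 160.31 ms (260 beats)
sigma_L = 3.742 mS/cm, verified CV = 63.29 cm/s
```

i.e. the crista/Bachmann phenotype prolongs the action potential by ~14%
over baseline right-atrial tissue and the pulmonary-vein phenotype shortens
it by ~20%, while a longitudinal conductivity of 3.74 mS/cm (anisotropy
ratio 0.35) carries a planar wave at 63.3 cm/s on the reference slab.

A full sinus-rhythm activation of the idealized bi-atrial surrogate, with
forward P-waves and region decomposition:

```bash
atriasim make-geometry atria --out atria.vtk
atriasim run-pipeline --config examples/slab_cv.yaml --out run_out
```

Library-level drivers for the same chain live in `atriasim.presets`
(regional conductivities, cell assignments, SAN stimulus) and are exercised
end-to-end in `tests/test_acceptance.py`.

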