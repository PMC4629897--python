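# Planar-wave CV verification on the reference calibration slab.
geometry:
  kind: slab
  nx: 50
  ny: 50
  nz: 3
  spacing_um: 300.0
protocol:
  sim_ms: 40.0
  amplitude: 52.0
  duration: 2.0
tissue:
  sigma_l: 3.742
  anisotropy_ratio: 0.35
  default_cell: RA/PM
forward:
  gamma: 1.0
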