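# Demo 4-concentration experiment: one treatment well per administered
# LC-Dox-PoP concentration (1, 3, 6, 9 μg/mL), a drug-free control and a
# cell-free drug-only blank, imaged in the doxorubicin (~590 nm emission)
# and porphyrin (~720 nm emission) channels with matched-OD ND references.
#
# Well ROIs are positions on the plate canvas (half-open [r0, r1, c0, c1],
# 0-based row-major); each well is acquired as its own 128×128 frame.
plate_shape: [256, 384]
frame_shape: [128, 128]
seed: 7
archetype: compact
cell_model: SCC2095sc
bleach_factor: 0.9
k_sigma: 3.0
channels:
  - {name: dox, excitation_nm: 490, emission_filter: "593/40", nd_reference: true}
  - {name: pop, excitation_nm: 656, emission_filter: "750/50", nd_reference: true}
wells:
  W1:    {roi: [0, 128, 0, 128],     concentration: 1.0, role: treatment}
  W2:    {roi: [0, 128, 128, 256],   concentration: 3.0, role: treatment}
  W3:    {roi: [0, 128, 256, 384],   concentration: 6.0, role: treatment}
  W4:    {roi: [128, 256, 0, 128],   concentration: 9.0, role: treatment}
  CTRL:  {roi: [128, 256, 128, 256], concentration: 0.0, role: control}
  BLANK: {roi: [128, 256, 256, 384], concentration: 9.0, role: blank}
optics:
  gain: 100.0
  leakage_fraction: 0.91
  dark_level: 100.0
noise:
  shot_noise_enabled: true
  read_noise_sd: 5.0
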