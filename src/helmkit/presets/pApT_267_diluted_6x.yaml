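# Polymeric duplex, 267 nm excitation, buffer diluted six-fold. The
# dilution experiment was reported with 285 nm excitation; this preset
# mirrors the same relative increase in long-lived amplitude onto the
# 267 nm condition (generator ground-truth choices, no printed values).
system: pApT
excitation_nm: 267
buffer: diluted_6x
quantum_yield: 3.0e-4
background_rate: 2.0
irf_fwhm_ps: 80.0

decays:
  305:
    tail_lifetime_ns: 2.6
    fraction_after_1ns: 0.38
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.18], [0.30, 0.12]]
    long: [[2.6, 1.0]]
  330:
    fraction_after_1ns: 0.14
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.13], [0.30, 0.17]]
    long: [[2.6, 1.0]]
  420:
    fraction_after_1ns: 0.26
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.12], [0.30, 0.18]]
    long: [[1.2, 0.5], [3.0, 0.5]]

anisotropy:
  305: {r_inf: 0.02, components: [[0.1814, 0.3]]}
  420: {r_inf: 0.02, components: [[-0.01, 0.5]]}

spectrum:
  main_center_nm: 327.0
  main_asymmetry: 1.2
  visible_center_nm: 430.0
  visible_fwhm_cm1: 3500.0
  visible_asymmetry: 1.0
  fwhm_cm1: 5400.0
  ss_ratio_305_420: 3.9

melting:
  tm: 65.0
  width: 2.0
  a_folded_ref: 1.0
  slope_folded: 0.0004
  slope_melted: 0.0008
  hyperchromicity_pct: 60.0
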