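# Polymeric duplex, 285 nm excitation, standard buffer. The 305 and 330 nm
# fractions-after-1-ns are measured constraints; the 420 nm fraction is the
# measured value quoted alongside the R statistic of this condition.
system: pApT
excitation_nm: 285
buffer: standard
quantum_yield: 3.0e-4
background_rate: 2.0
irf_fwhm_ps: 80.0

decays:
  305:
    tail_lifetime_ns: 2.2
    fraction_after_1ns: 0.275
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.18], [0.30, 0.12]]
    long: [[2.2, 1.0]]
  330:
    fraction_after_1ns: 0.125
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.13], [0.30, 0.17]]
    long: [[2.2, 1.0]]
  420:
    fraction_after_1ns: 0.28
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
  tm: 72.0
  width: 1.5
  a_folded_ref: 1.0
  slope_folded: 0.0004
  slope_melted: 0.0008
  hyperchromicity_pct: 70.0
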