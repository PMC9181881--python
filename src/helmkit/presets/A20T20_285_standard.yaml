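# Oligomeric duplex (20 bp), 285 nm excitation, standard buffer. The
# steady-state 305/420 intensity ratio is back-computed from R = 3.7 and
# the measured fractions (0.36 * 3.7 / 0.501); it is a derived quantity,
# not a directly measured one.
system: A20T20
excitation_nm: 285
buffer: standard
quantum_yield: 3.0e-4
background_rate: 2.0
irf_fwhm_ps: 80.0

decays:
  305:
    tail_lifetime_ns: 2.7
    fraction_after_1ns: 0.501
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.18], [0.30, 0.12]]
    long: [[2.7, 1.0]]
  330:
    fraction_after_1ns: 0.306
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.13], [0.30, 0.17]]
    long: [[2.7, 1.0]]
  420:
    fraction_after_1ns: 0.36
    group: fixed
    short: [[0.01, 0.70], [0.10, 0.12], [0.30, 0.18]]
    long: [[1.2, 0.5], [3.0, 0.5]]

anisotropy:
  305: {r_inf: 0.04, components: [[0.1535, 0.3]]}
  420: {r_inf: 0.01, components: [[-0.025, 0.8]]}

spectrum:
  main_center_nm: 327.0
  main_asymmetry: 1.2
  visible_center_nm: 430.0
  visible_fwhm_cm1: 3500.0
  visible_asymmetry: 1.0
  fwhm_cm1: 6900.0
  ss_ratio_305_420: 2.658683

melting:
  tm: 63.0
  width: 3.0
  a_folded_ref: 1.0
  slope_folded: 0.0004
  slope_melted: 0.0008
  hyperchromicity_pct: 40.0
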