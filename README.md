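# helmkit

Time-correlated single photon counting (TCSPC) analysis of the long-lived
fluorescence of adenine–thymine DNA duplexes.

Double-stranded DNA is almost non-fluorescent (quantum yields ~1e-4), yet a
small population of excited states survives into the nanosecond regime. In
homopolymeric A·T duplexes this nanosecond emission is dominated by a
*high-energy* band peaking below 305 nm with a ~2.2–2.7 ns lifetime and an
anomalously low anisotropy plateau (~0.02–0.04) — the signature of
high-energy long-lived mixed (HELM) excitons: collective ππ*/charge-transfer
states sensitive to base stacking, duplex size and ionic strength.

`helmkit` is a library for scientists working with such data. It covers the
complete analysis chain and a matched synthetic-data generator, so every
stage can be exercised and validated without access to instrument data:

- **decay simulation** — multi-exponential models convolved with a Gaussian
  instrument response function (IRF, 80 ps FWHM by default), bin-wise
  Poisson counting noise, seeded and fully reproducible;
- **tail lifetime fits** — mono-exponential weighted least squares on the
  1.5–10.5 ns window (no reconvolution needed that far past the pulse);
- **photon fractions and budgets** — the fraction of photons emitted after
  1 ns per wavelength, and the share of all photons per time interval;
- **time-resolved emission spectra (TRES)** — window integration, detector
  response correction, peak normalisation;
- **fluorescence anisotropy** — r(t) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥) with
  propagated Poisson errors, magic-angle reconstruction, and the analytic
  limits r(θ) = (3cos²θ − 1)/5 and the in-plane random-dipole floor r = 0.1;
- **the R statistic** — the relative importance of high- vs low-energy
  nanosecond emission,

  ```
  R = (f₃₀₅ · Iₛₛ(305)) / (f₄₂₀ · Iₛₛ(420))
  ```

  where f_λ is the fraction of photons at wavelength λ emitted after 1 ns
  and Iₛₛ the steady-state intensity; R > 1 means the nanosecond emission
  is dominated by the high-energy band;
- **melting curves** — two-state logistic fits of A₂₆₀(T) with linear
  baselines, melting temperature Tm and hyperchromicity
  100·(A(96 °C) − A(20 °C))/A(20 °C).

Named presets (`pApT` ≈ 1000 bp polymer, `A20T20` 20 bp oligomer; 267 or
285 nm excitation; standard phosphate buffer, six-fold diluted buffer, or a
KCl control at matched ionic strength) encode the reference values of each
condition as generator ground truth, calibrated deterministically at load
time.

## Worked example

```python
from helmkit import simulate_decay, tail_fit, fraction_after
from helmkit.presets import get_preset

preset = get_preset("pApT", 267, "standard")
decay = simulate_decay(preset.decay_models[305.0], preset.irf,
                       n_photons=1_000_000, seed=1)
fit = tail_fit(decay)                 # 1.5-10.5 ns window
frac = fraction_after(decay, t_cut=1.0)
print(f"{fit.tau:.3f} +- {fit.tau_stderr:.3f} ns, {100*frac:.1f}% after 1 ns")
```

prints

```
2.599 +- 0.014 ns, 33.0% after 1 ns
```

i.e. the tail fit recovers the encoded 2.6 ns lifetime of the polymer's
305 nm emission, and a third of its photons arrive on the nanosecond
timescale. The `examples/` directory has one short script per capability
(TRES + photon budget, R statistic, anisotropy, melting analysis, and the
full multi-preset reproduction run); each prints the numbers it computes
and what they mean. A thin CLI mirrors the same operations
(`helmkit --help`).

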