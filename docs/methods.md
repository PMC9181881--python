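# Methods

This note documents the models behind `helmkit`, the choices made where the
design was genuinely open, and what the synthetic data do and do not
emulate.

## Time axis and instrument response

All decays live on a uniform grid from −1 to 10.5 ns in 25 ps bins
(460 bins). The pre-pulse span exists so that dark counts can be estimated
from data: the background estimator averages all bins lying entirely before
−0.5 ns, ~14 IRF widths before the pulse. 25 ps sampling covers the 80 ps
FWHM Gaussian IRF more than three times. IRF values are stored as
probability mass per bin (Gaussian CDF differences), exact for any bin
width; `fwhm_ps = 0` degenerates to a one-hot delta.

Repetition-period wrap-around is ignored: at the 4.75 MHz pulse-picked
rate the period is ~210 ns, and exp(−210/2.7) is numerically zero for
every lifetime in play.

## Forward decay model

The emission impulse response is a finite multi-exponential
I(t) = Σᵢ aᵢ·exp(−t/τᵢ) for t ≥ 0; the photon share of component i is
proportional to aᵢτᵢ. For Gaussian IRFs the convolution uses the
exponentially-modified-Gaussian closed form per component,

    ½·exp(σ²/2τ² − t′/τ)·erfc((σ/τ − t′/σ)/√2),  t′ = t − t₀,

evaluated stably by switching to the scaled complement erfcx on the early
side. Tabulated IRFs use discrete convolution with a bin-averaged
exponential kernel; that path is exact in total photon number and agrees
with the closed form to better than 1e−3 past four IRF widths, but is
limited by the piecewise-constant IRF representation on the steep rising
edge — acceptable because no analysis quantity here reads the rise.

Sub-10-ps kinetics (the dominant ππ* decay, mean lifetimes ~1–2 ps) are
unresolvable under an 80 ps IRF and are collapsed into a single effective
"prompt" component with τ = 10 ps. All integrated-fraction quantities are
insensitive to this choice by construction.

## Poisson photon counting

`simulate_decay` scales the noise-free expectation so the expected number
of *signal* photons over the grid equals `n_photons`, adds the dark-count
rate (default 2 counts per bin), and draws bin-wise Poisson counts. This is
the exact statistics of a TCSPC histogram in the low-pile-up regime;
afterpulsing, dead time and TAC nonlinearity are deliberately out of scope.
Every simulator is a pure function of (parameters, seed). Multi-decay
datasets expand one integer seed as (seed, k) with k the wavelength index,
so subsets regenerate identically.

## Tail fits

The 1.5–10.5 ns window opens ≥ 18 IRF widths after the pulse, so the tail
fit is a plain (non-reconvolved) weighted least squares of
A·exp(−(t − t_lo)/τ) + b. Weights follow the Neyman convention
1/max(counts, 1); no convention is canonical for these data and at ≥10⁵
tail photons the difference from Pearson weighting is far below the quoted
uncertainties. The background is a free parameter bounded at zero,
initialised from the pre-pulse estimate. Optimisation uses a trust-region
reflective solver: the classic MINPACK route can stall at a bounded
starting point when τ is initialised above the optimum. These fits are
phenomenological summaries of a multi-exponential reality — the model is
deliberately *not* the truth, which is why the suite checks them against a
brute-force grid-search oracle rather than against algebra.

A full multi-exponential reconvolution fit (fixed lifetimes, non-negative
amplitudes by NNLS) is provided for completeness but no headline quantity
uses it.

## Fractions, budgets and TRES

`fraction_after` integrates background-subtracted counts in [t_cut, 10.5]
over those in [−1, 10.5]; it is scale-invariant and, for single
exponentials, strictly increasing in τ. Whether the reference percentages
were background-corrected is not documented; at the encoded dark-count
level the difference is ~0.1 percentage point, far inside the 1-point
closure tolerance.

Photon budgets partition the full range (default boundaries at 0.1, 1 and
10 ns) and report percentages of total background-subtracted photons; the
partition is validated (disjoint, covering) and percentages sum to exactly
100. TRES spectra are window integrals per wavelength, divided by the
detector sensitivity (linear interpolation), and peak-normalised. Peak
positions are refined by a quadratic through the three points around the
argmax — necessary because spectra are sampled every 5–15 nm; edge maxima
and exact ties are flagged rather than interpolated.

## Anisotropy

r(t) is computed on background-subtracted, *non-normalised* counts
(normalising either channel would corrupt the ratio), with first-order
Poisson error propagation and a G factor defaulting to 1 (matched
excitation energies). Bins with non-positive denominator or |r| > 1 are
flagged undefined. Values inside the first ~100 ps are IRF-limited and
should not be interpreted; plateau readouts use an inverse-variance mean
over 2–9 ns. Polarized pairs are generated by splitting the population
decay as I∥ = I(1+2r)/3, I⊥ = I(1−r)/3 *before* IRF convolution; because
products of exponentials are exponentials, both channels stay in closed
form, and I∥ + 2I⊥ reconstructs the population decay exactly. Rotational
diffusion is not modelled: these duplexes are too large to rotate on the
nanosecond timescale.

## Steady-state spectra

Band shapes are sums of bifurcated Gaussians in wavenumber (asymmetry =
red/blue half-width ratio; 1 gives a plain Gaussian). Each preset's
spectrum is assembled from a main UV band at 327 nm (asymmetry 1.2, red
tailed) plus a weak visible band at 430 nm. Two parameters are solved at
load time: the visible band height in closed form so I(305)/I(420) matches
the encoded ratio, and the main band width by a bracketing root find so
the assembled spectrum's FWHM in wavenumber matches the encoded width
(5400 cm⁻¹ polymer, 6900 cm⁻¹ oligomer). The oligomer's intensity ratio is
not a measured quantity: it is back-computed from R = 3.7 and the measured
fractions (0.36·3.7/0.501 ≈ 2.66) and flagged as derived.

Note that the oligomer band is wide enough that its blue half-maximum
crossing lies below 300 nm; width measurements need a wavelength grid
reaching ~280 nm. The water Raman line that contaminates the region below
~305 nm in real measurements is not simulated.

## Preset calibration

Raw preset files store measured target quantities plus a decay template
per wavelength: fixed lifetimes (prompt 10 ps; intermediates 100 and
300 ps; a long component at the tail lifetime, or a 1.2/3.0 ns pair in the
visible where the decay is distinctly non-mono-exponential) and photon
shares within the short group. Loading solves, deterministically and
without any random numbers:

1. the long-group amplitude per wavelength, in closed form against the
   IRF-convolved template, so the noise-free fraction after 1 ns equals its
   target exactly;
2. for the 267 nm polymer dataset, two scale factors on the
   free-wavelength fractions (UV and visible groups) by a 2-D root find,
   so the aggregate 1–10 ns photon share is 15% and the visible/UV ratio
   of the late TRES window is 20% — both under the same detected-intensity
   weighting the simulated dataset uses;
3. the melted-baseline anchor of the melting model, in closed form, so the
   noise-free hyperchromicity is exact.

Per-wavelength values nobody measured (fractions at 320–440 nm for the
267 nm dataset, the diluted-buffer visible fraction, Tm values) are
generator choices fixed once; the budget solve pushes the 440 nm fraction
to ~0.47, higher than at 420 nm — a known artefact of reconciling the 15%
budget with the 20% visible/UV ratio under this template, harmless because
no headline quantity reads 440 nm alone. The KCl control preset reuses the
standard-buffer parameters by construction, which is the point of that
control. Calibration closure (noise-free analysis reproduces every encoded
value within 1% relative) is asserted in the test suite for all presets.

## Melting curves

A(T) = B_f(T)·f(T) + B_m(T)·(1 − f(T)) with logistic
f(T) = 1/(1 + exp((T − tm)/w)) and linear baselines — a phenomenological
two-state form, not a van't Hoff bimolecular model: only Tm and the
hyperchromicity feed the downstream comparisons, no ΔH/ΔS is extracted.
Hyperchromicity is referenced at 20 and 96 °C. The fit initialises Tm from
the smoothed derivative maximum (falling back to the range midpoint),
baselines from the outer 20% of the range, and declares "no transition"
when the fitted baseline separation at Tm does not exceed three times the
residual noise. The model-free readout interpolates the curve directly;
on a single 1 °C-step curve at 0.5% absorbance noise it carries ~1-point
standard deviation, so recovery comparisons at the ±2-point level use the
fitted model (which averages the whole curve) or multi-seed means.

## Problem sizes

Default validation runs use 10⁶ photons per decay (typical of a merged
TCSPC acquisition), 2×10⁶ per polarized pair, 77-point melting curves at
0.5% noise, and 10 seeds where spread matters. At these sizes the entire
reproduction pipeline runs in seconds on one CPU.

## What passing tests do and do not show

The generator emulates multi-exponential kinetics under a Gaussian IRF,
Poisson counting, smooth band shapes, logistic melting and
single-correlation-time depolarisation. It does not emulate IRF asymmetry
or drift, scattered-light and Raman contamination, photodegradation,
detector colour shift, wavelength-dependent time zero, or model
misspecification beyond the prompt-collapse described above. Closure of
the pipeline on synthetic data therefore validates the *analysis
implementation* — estimator correctness, windowing, weighting, error
propagation — not the adequacy of these models for any particular
instrument's raw data.
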