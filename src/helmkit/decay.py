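"""Core decay computations.

The forward model is a multi-exponential convolved with the IRF. For a
Gaussian IRF of standard deviation sigma centred at t0, each component has
the exponentially-modified-Gaussian closed form

    (exp(-t'/tau) * H) (*) G_sigma
        = 1/2 exp(sigma^2 / 2 tau^2 - t'/tau) erfc((sigma/tau - t'/sigma)/sqrt 2)

with t' = t - t0. The closed form is used whenever the IRF was built as a
Gaussian; tabulated IRFs go through discrete convolution. The tail fit on
the 1.5-10.5 ns window is a plain (non-reconvolved) weighted least squares:
the window opens more than eighteen IRF widths after the pulse, so the
convolution correction there is numerically irrelevant, which is also why
such fits are phenomenological rather than a full kinetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy.special import erfc, erfcx

from .errors import (
    AlignmentError,
    DegenerateSignalError,
    FitFailureError,
    InsufficientBaselineError,
    WindowRangeError,
)
from .grids import InstrumentResponse, TimeGrid
from .models import DecayCurve, DecayModel, TimeWindow

#: Pre-rise bins end here; everything before is treated as pure background.
BASELINE_EDGE_NS = -0.5

TAIL_WINDOW = TimeWindow(1.5, 10.5)
TOTAL_WINDOW = TimeWindow(-1.0, 10.5)


def exgauss(t: np.ndarray, tau: float, sigma: float, t0: float = 0.0) -> np.ndarray:
    """Closed-form convolution of ``H(t) exp(-t/tau)`` with a unit-area Gaussian.

    Evaluated stably across the whole grid: the late-time branch (where the
    erfc argument is large and negative) switches to the scaled complement
    ``erfcx`` so no overflow occurs.
    """
    t = np.asarray(t, dtype=float)
    tp = t - t0
    if sigma <= 0:
        return np.where(tp >= 0, np.exp(-np.clip(tp, 0, None) / tau), 0.0)
    x = (sigma / tau - tp / sigma) / np.sqrt(2.0)
    out = np.empty_like(tp)
    # Early times (x >= 0): exp(k) can overflow for tiny tau, but
    # erfcx(x) <= 1 and exp(-tp^2/2 sigma^2) <= 1 are both safe.
    early = x >= 0
    out[early] = 0.5 * erfcx(x[early]) * np.exp(-(tp[early] ** 2) / (2.0 * sigma**2))
    # Late times (x < 0): erfc(x) is bounded by 2 and k decays with t.
    k = sigma**2 / (2.0 * tau**2) - tp[~early] / tau
    out[~early] = 0.5 * np.exp(k) * erfc(x[~early])
    return out


def _expected_components(
    components: Sequence[tuple[float, float]],
    irf: InstrumentResponse,
    grid: TimeGrid,
) -> np.ndarray:
    """Expected (noise-free) signal for signed-amplitude components.

    Internal: polarized channels produce multi-exponential expansions with
    negative coefficients, which :class:`DecayModel` deliberately rejects.
    """
    if irf.grid != grid:
        raise AlignmentError("IRF and decay grids differ")
    t = grid.centers()
    out = np.zeros(grid.n_bins)
    if irf.shape == "gaussian" and irf.sigma_ns > 0:
        for a, tau in components:
            out += a * exgauss(t, tau, irf.sigma_ns, irf.t0)
    else:
        # Discrete convolution. The IRF values are bin probabilities. For a
        # single-bin (delta) IRF the kernel is point-sampled, so the result
        # is the bare multi-exponential on bins at/after t0. For extended
        # IRFs the kernel is bin-averaged (exact integral over each bin
        # divided by the width): this removes the half-bin bias the
        # Heaviside discontinuity would otherwise introduce on the rise.
        n = grid.n_bins
        bw = grid.bin_width
        offsets = bw * np.arange(n)
        kernel = np.zeros(n)
        if np.count_nonzero(irf.values) == 1:
            for a, tau in components:
                kernel += a * np.exp(-offsets / tau)
        else:
            lo = np.clip(offsets - bw / 2.0, 0.0, None)
            hi = offsets + bw / 2.0
            for a, tau in components:
                kernel += a * (tau / bw) * (np.exp(-lo / tau) - np.exp(-hi / tau))
        out = np.convolve(irf.values, kernel)[:n]
    return out


def expected_counts(
    model: DecayModel,
    irf: InstrumentResponse,
    grid: TimeGrid | None = None,
    include_background: bool = True,
) -> np.ndarray:
    """Noise-free expected counts per bin for ``model`` under ``irf``.

    For a Gaussian IRF the result agrees with the exponential-Gaussian
    closed form; for a delta IRF it reduces to the bare multi-exponential
    on bins at or after t0.
    """
    if grid is None:
        grid = irf.grid
    out = _expected_components(model.components, irf, grid)
    if include_background:
        out = out + model.background_rate
    return out


def estimate_background(decay: DecayCurve) -> float:
    """Mean counts per bin over the pre-rise region (bins entirely < -0.5 ns)."""
    edges = decay.grid.edges()
    mask = edges[1:] <= BASELINE_EDGE_NS
    if not mask.any():
        raise InsufficientBaselineError(
            f"no bins entirely before {BASELINE_EDGE_NS} ns; grid starts at "
            f"{decay.grid.start} ns"
        )
    return float(decay.counts[mask].mean())


def normalize_decay(decay: DecayCurve, background: float | None = None) -> np.ndarray:
    """Background-subtracted counts scaled so the peak is exactly 1."""
    if background is None:
        background = estimate_background(decay)
    signal = decay.counts - background
    peak = signal.max()
    if not peak > 0:
        raise DegenerateSignalError("no counts above background to normalise")
    return signal / peak


def _window_mask(grid: TimeGrid, t_lo: float, t_hi: float) -> np.ndarray:
    centers = grid.centers()
    return (centers >= t_lo) & (centers <= t_hi)


def fraction_after(
    decay: DecayCurve,
    t_cut: float = 1.0,
    total_window: TimeWindow = TOTAL_WINDOW,
    background: float | None = None,
) -> float:
    """Fraction of signal photons emitted after ``t_cut``.

    Background-subtracted counts in [t_cut, t_hi] divided by those in the
    total window (-1 to 10.5 ns by default). Because both integrals share
    the same scale the result is invariant under rescaling of the counts.
    """
    if not total_window.t_lo <= t_cut <= total_window.t_hi:
        raise WindowRangeError(
            f"t_cut {t_cut} outside total window {total_window}"
        )
    if background is None:
        background = estimate_background(decay)
    signal = decay.counts - background
    total = signal[_window_mask(decay.grid, total_window.t_lo, total_window.t_hi)].sum()
    if not total > 0:
        raise DegenerateSignalError("zero total signal in the total window")
    after = signal[_window_mask(decay.grid, t_cut, total_window.t_hi)].sum()
    return float(after / total)


@dataclass(frozen=True)
class TailFitResult:
    """Mono-exponential tail fit A exp(-(t - t_lo)/tau) + b.

    ``amplitude`` is the fitted signal level at the window start, ``tau`` the
    lifetime in ns with its standard error, ``background`` the fitted flat
    offset (counts per bin) and ``chi2_reduced`` the reduced chi-square under
    Neyman weighting (1 / max(counts, 1)).
    """

    tau: float
    amplitude: float
    background: float
    chi2_reduced: float
    tau_stderr: float
    window: TimeWindow


def tail_fit(decay: DecayCurve, window: TimeWindow = TAIL_WINDOW) -> TailFitResult:
    """Weighted mono-exponential fit of the decay tail.

    The default 1.5-10.5 ns window starts far enough after the excitation
    pulse that IRF reconvolution is unnecessary. Weights follow the Neyman
    convention 1/max(counts, 1) appropriate for Poisson counting data.
    """
    t_all = decay.grid.centers()
    mask = _window_mask(decay.grid, window.t_lo, window.t_hi)
    if mask.sum() < 20:
        raise WindowRangeError(
            f"tail window {window} holds only {int(mask.sum())} bins (< 20)"
        )
    t = t_all[mask]
    y = decay.counts[mask]
    try:
        bg0 = estimate_background(decay)
    except InsufficientBaselineError:
        bg0 = 0.0
    if not (y.sum() - bg0 * y.size) > 0:
        raise DegenerateSignalError("no signal above background in the tail window")
    weights = 1.0 / np.sqrt(np.maximum(y, 1.0))

    # Log-slope initial guess from the two window halves.
    half = y.size // 2
    m1, m2 = y[:half].mean(), y[half:].mean()
    c1, c2 = t[:half].mean(), t[half:].mean()
    if m1 - bg0 > 0 and m2 - bg0 > 0 and m1 > m2:
        tau0 = (c2 - c1) / np.log((m1 - bg0) / (m2 - bg0))
    else:
        tau0 = window.span / 4.0
    tau0 = float(np.clip(tau0, 0.05, 50.0))

    params = Parameters()
    params.add("amplitude", value=max(y[0] - bg0, 1.0), min=0.0)
    params.add("tau", value=tau0, min=1e-3, max=1e3)
    params.add("background", value=max(bg0, 0.0), min=0.0)

    def residual(p):
        model = p["amplitude"] * np.exp(-(t - window.t_lo) / p["tau"]) + p["background"]
        return (model - y) * weights

    # Trust-region reflective handles the bounded parameters robustly from
    # any initial tau (MINPACK's bound transform can stall at the start).
    result = minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitFailureError("tail fit did not converge", diagnostics=result)
    tau = float(result.params["tau"].value)
    if not tau > 0:
        raise FitFailureError(f"fitted tau {tau} is not positive", diagnostics=result)
    stderr = result.params["tau"].stderr
    return TailFitResult(
        tau=tau,
        amplitude=float(result.params["amplitude"].value),
        background=float(result.params["background"].value),
        chi2_reduced=float(result.redchi),
        tau_stderr=float(stderr) if stderr is not None else float("nan"),
        window=window,
    )


def reconvolution_fit(
    decay: DecayCurve,
    irf: InstrumentResponse,
    lifetimes: Sequence[float],
) -> dict:
    """Full multi-exponential reconvolution fit with fixed lifetimes.

    Amplitudes and background are solved by non-negative weighted linear
    least squares against the IRF-convolved basis. Provided for completeness;
    none of the headline numbers depend on it.
    """
    from scipy.optimize import nnls

    t = decay.grid.centers()
    basis = [
        _expected_components([(1.0, tau)], irf, decay.grid) for tau in lifetimes
    ]
    basis.append(np.ones_like(t))
    A = np.column_stack(basis)
    w = 1.0 / np.sqrt(np.maximum(decay.counts, 1.0))
    coef, _ = nnls(A * w[:, None], decay.counts * w)
    fitted = A @ coef
    resid = (decay.counts - fitted) * w
    dof = max(t.size - coef.size, 1)
    return {
        "lifetimes": tuple(float(x) for x in lifetimes),
        "amplitudes": tuple(float(c) for c in coef[:-1]),
        "background": float(coef[-1]),
        "chi2_reduced": float(resid @ resid / dof),
    }
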