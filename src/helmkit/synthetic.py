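"""Synthetic data generation: photon-counting decays, polarized pairs,
steady-state spectra, detector response curves and melting curves.

Every simulator is a pure function of its parameters and an integer seed:
identical inputs give identical outputs. Counting noise is bin-wise Poisson,
which is exact for TCSPC histograms at the repetition rates used here
(pile-up, afterpulsing and dead-time effects are out of scope).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .decay import _expected_components, expected_counts
from .errors import CoverageError, InvalidModelError
from .grids import InstrumentResponse, TimeGrid, make_irf
from .models import (
    AnisotropyModel,
    DecayCurve,
    DecayModel,
    MeltingCurve,
    MeltModelParams,
    ResponseCurve,
    SteadyStateSpectrum,
)
from .spectra import evaluate_bands

__all__ = [
    "simulate_decay",
    "expected_polarized_pair",
    "simulate_polarized_pair",
    "simulate_steady_state_spectrum",
    "simulate_melting_curve",
    "simulate_wavelength_series",
    "default_response_curve",
    "calibrate_melt_params",
]


def simulate_decay(
    model: DecayModel,
    irf: InstrumentResponse,
    n_photons: int,
    seed,
    emission_wavelength: float = 305.0,
    excitation_wavelength: float = 267.0,
    polarization: str = "magic",
) -> DecayCurve:
    """Simulate one TCSPC histogram.

    The noise-free expectation (model convolved with the IRF) is scaled so
    the expected number of *signal* photons over the grid equals
    ``n_photons``; the model's dark-count rate is then added per bin and
    counts are drawn bin-wise Poisson.

    ``seed`` may be an int or a sequence of ints (used by the wavelength
    series to derive independent per-decay streams).
    """
    if not n_photons > 0:
        raise InvalidModelError(f"n_photons must be > 0, got {n_photons}")
    signal = expected_counts(model, irf, include_background=False)
    signal = np.clip(signal, 0.0, None)
    total = signal.sum()
    if not total > 0:
        raise InvalidModelError("decay model has zero expected signal on the grid")
    lam = signal * (n_photons / total) + model.background_rate
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(float)
    return DecayCurve(
        grid=irf.grid,
        counts=counts,
        emission_wavelength=emission_wavelength,
        excitation_wavelength=excitation_wavelength,
        polarization=polarization,
        seed=seed if isinstance(seed, int) else None,
    )


def _polarized_components(
    model: DecayModel, aniso: AnisotropyModel, channel: str
) -> list[tuple[float, float]]:
    """Multi-exponential expansion of I(t) (1 + 2 r(t))/3 or I(t)(1 - r(t))/3.

    Products of exponentials are exponentials (rates add), so each polarized
    channel is again a finite multi-exponential and keeps its closed-form
    IRF convolution.
    """
    sign = 2.0 if channel == "parallel" else -1.0
    comps: list[tuple[float, float]] = []
    for a, tau in model.components:
        comps.append((a * (1.0 + sign * aniso.r_inf) / 3.0, tau))
        for c, theta in aniso.components:
            tau_combined = 1.0 / (1.0 / tau + 1.0 / theta)
            comps.append((a * sign * c / 3.0, tau_combined))
    return comps


def expected_polarized_pair(
    model: DecayModel,
    aniso: AnisotropyModel,
    irf: InstrumentResponse,
    n_photons: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expectations of the parallel and perpendicular channels.

    The isotropic (magic-angle) decay carrying ``n_photons`` expected signal
    photons is split as I_par = I (1 + 2 r)/3 and I_perp = I (1 - r)/3
    *before* IRF convolution, so I_par + 2 I_perp recovers the population
    decay exactly in expectation. Background is not included.
    """
    aniso.validate_on(irf.grid)
    magic = expected_counts(model, irf, include_background=False)
    scale = n_photons / magic.sum()
    par = _expected_components(_polarized_components(model, aniso, "parallel"), irf, irf.grid)
    perp = _expected_components(_polarized_components(model, aniso, "perpendicular"), irf, irf.grid)
    return np.clip(par * scale, 0, None), np.clip(perp * scale, 0, None)


def simulate_polarized_pair(
    model: DecayModel,
    aniso: AnisotropyModel,
    irf: InstrumentResponse,
    n_photons: int,
    seed,
    emission_wavelength: float = 305.0,
    excitation_wavelength: float = 285.0,
) -> tuple[DecayCurve, DecayCurve]:
    """Simulate matched parallel / perpendicular decay histograms."""
    if not n_photons > 0:
        raise InvalidModelError(f"n_photons must be > 0, got {n_photons}")
    par_exp, perp_exp = expected_polarized_pair(model, aniso, irf, float(n_photons))
    rng = np.random.default_rng(seed)
    curves = []
    for name, lam in (("parallel", par_exp), ("perpendicular", perp_exp)):
        counts = rng.poisson(lam + model.background_rate).astype(float)
        curves.append(
            DecayCurve(
                grid=irf.grid,
                counts=counts,
                emission_wavelength=emission_wavelength,
                excitation_wavelength=excitation_wavelength,
                polarization=name,
                seed=seed if isinstance(seed, int) else None,
            )
        )
    return curves[0], curves[1]


def simulate_steady_state_spectrum(preset, wavelengths) -> SteadyStateSpectrum:
    """Steady-state emission spectrum of a preset, peak-normalised to 1.

    ``wavelengths`` must cover 300-460 nm so both the 305 nm readout and the
    420 nm readout used by the R statistic are available.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.min() > 305.0 or wavelengths.max() < 420.0:
        raise CoverageError(
            "wavelength grid must contain both 305 and 420 nm readout points"
        )
    inten = evaluate_bands(preset.spectrum_bands, wavelengths)
    return SteadyStateSpectrum(wavelengths=wavelengths, intensities=inten / inten.max())


def default_response_curve(
    wavelengths: Sequence[float] | None = None,
) -> ResponseCurve:
    """Synthetic detector spectral sensitivity, rising linearly to the red.

    Photocathode quantum efficiency typically drops toward the UV; a linear
    ramp from 0.5 at 300 nm to 1.0 at 440 nm is a serviceable stand-in and is
    strictly positive everywhere (division-safe).
    """
    if wavelengths is None:
        wavelengths = np.arange(280.0, 501.0, 5.0)
    wl = np.asarray(wavelengths, dtype=float)
    sens = 0.5 + 0.5 * (wl - 300.0) / 140.0
    return ResponseCurve(wavelengths=wl, sensitivity=np.clip(sens, 0.05, None))


def calibrate_melt_params(params: MeltModelParams) -> MeltModelParams:
    """Solve the melted-baseline anchor so the noise-free model reproduces
    the encoded hyperchromicity exactly.

    The requirement A(96) = (1 + H/100) A(20) is linear in ``a_melted_96``,
    so the solve is closed-form and deterministic.
    """
    h = params.hyperchromicity_pct / 100.0
    f20 = float(params.folded_fraction(np.array([20.0]))[0])
    f96 = float(params.folded_fraction(np.array([96.0]))[0])
    bf20 = params.a_folded_ref
    bf96 = params.a_folded_ref + params.slope_folded * 76.0
    # A(20) = bf20 f20 + (a96 - 76 s_m)(1 - f20);  A(96) = bf96 f96 + a96 (1 - f96)
    coef = (1.0 - f96) - (1.0 + h) * (1.0 - f20)
    rhs = (1.0 + h) * (bf20 * f20 - 76.0 * params.slope_melted * (1.0 - f20)) - bf96 * f96
    if abs(coef) < 1e-12:
        raise InvalidModelError("melting model degenerate: cannot solve baseline")
    a96 = rhs / coef
    return MeltModelParams(
        tm=params.tm,
        width=params.width,
        a_folded_ref=params.a_folded_ref,
        hyperchromicity_pct=params.hyperchromicity_pct,
        slope_folded=params.slope_folded,
        slope_melted=params.slope_melted,
        a_melted_96=a96,
    )


def simulate_melting_curve(
    params: MeltModelParams,
    temperatures: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltingCurve:
    """Absorbance-vs-temperature curve with additive Gaussian noise.

    ``noise_sd = 0`` returns the exact model values. Temperatures must be
    ascending within [0, 100] C.
    """
    T = np.asarray(temperatures, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise InvalidModelError("temperatures must be strictly ascending")
    if T.min() < 0.0 or T.max() > 100.0:
        raise InvalidModelError("temperatures must lie within [0, 100] C")
    if params.a_melted_96 is None:
        params = calibrate_melt_params(params)
    A = params.absorbance(T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return MeltingCurve(temperatures=T, absorbance=np.clip(A, 1e-9, None))


def simulate_wavelength_series(
    preset,
    n_photons: int = 1_000_000,
    seed: int = 0,
    weighted: bool = True,
) -> dict[float, DecayCurve]:
    """Simulate magic-angle decays at every wavelength of a preset.

    With ``weighted=True`` (the default) the expected photon number at each
    wavelength is ``n_photons`` scaled by the detected relative intensity
    (emission spectrum times detector sensitivity, normalised to 1 at its
    maximum), emulating equal acquisition time per wavelength. The global
    seed is expanded as ``(seed, k)`` with k the index of the wavelength in
    ascending order, so any subset is reproducible independently.
    """
    decays: dict[float, DecayCurve] = {}
    weights = preset.weights
    wmax = max(weights.values())
    for k, wl in enumerate(sorted(preset.decay_models)):
        n = n_photons * (weights[wl] / wmax) if weighted else n_photons
        decays[wl] = simulate_decay(
            preset.decay_models[wl],
            preset.irf,
            max(int(round(n)), 1),
            seed=(seed, k),
            emission_wavelength=wl,
            excitation_wavelength=preset.excitation,
        )
    return decays
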