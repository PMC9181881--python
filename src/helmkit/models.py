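"""Domain types shared across the analysis modules.

All times are ns, wavelengths nm, temperatures degrees Celsius. Spectral
widths are quoted in wavenumber (cm^-1) because emission band shapes are
close to symmetric on an energy axis, not on a wavelength axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, InvalidGridError, InvalidModelError
from .grids import TimeGrid

POLARIZATIONS = ("magic", "parallel", "perpendicular")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open-by-convention time interval [t_lo, t_hi] in ns."""

    t_lo: float
    t_hi: float

    def __post_init__(self) -> None:
        if not self.t_hi > self.t_lo:
            raise InvalidGridError(
                f"time window requires t_hi > t_lo, got ({self.t_lo}, {self.t_hi})"
            )

    @property
    def span(self) -> float:
        return self.t_hi - self.t_lo


@dataclass(frozen=True)
class DecayModel:
    """Multi-exponential emission model.

    ``components`` is a sequence of (amplitude, lifetime) pairs describing
    the impulse response  I(t) = sum_i a_i exp(-t / tau_i)  for t >= 0.
    Amplitudes are intensity amplitudes (counts at t = 0 per unit scale);
    the photon share of component i is proportional to a_i * tau_i.
    ``background_rate`` is the expected dark-count level in counts per bin.
    """

    components: tuple[tuple[float, float], ...]
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(tau)) for a, tau in self.components)
        if len(comps) < 1:
            raise InvalidModelError("at least one decay component is required")
        for a, tau in comps:
            if not tau > 0:
                raise InvalidModelError(f"lifetimes must be > 0, got {tau}")
            if a < 0:
                raise InvalidModelError(f"amplitudes must be >= 0, got {a}")
        if not any(a > 0 for a, _ in comps):
            raise InvalidModelError("amplitudes must not all be zero")
        if self.background_rate < 0:
            raise InvalidModelError("background_rate must be >= 0")
        object.__setattr__(self, "components", comps)

    def intensity(self, t: np.ndarray) -> np.ndarray:
        """Impulse-response intensity (no IRF, no background), zero for t < 0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0
        for a, tau in self.components:
            out[pos] += a * np.exp(-t[pos] / tau)
        return out

    def photon_shares(self) -> np.ndarray:
        """Fraction of emitted photons per component (a_i tau_i normalised)."""
        w = np.array([a * tau for a, tau in self.components])
        return w / w.sum()


@dataclass(frozen=True)
class AnisotropyModel:
    """Time-resolved anisotropy r(t) = r_inf + sum_i a_i exp(-t / theta_i).

    The initial value r(0) = r_inf + sum(a_i) must lie in the photoselection
    range [-0.2, 0.4]; so must the whole trace, which is checked against a
    grid by :meth:`validate_on`.
    """

    r_inf: float
    components: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(theta)) for a, theta in self.components)
        for _, theta in comps:
            if not theta > 0:
                raise InvalidModelError(f"correlation times must be > 0, got {theta}")
        object.__setattr__(self, "components", comps)
        for value, name in ((self.r0, "r(0)"), (self.r_inf, "r_inf")):
            if not -0.2 - 1e-12 <= value <= 0.4 + 1e-12:
                raise InvalidModelError(
                    f"{name} = {value:.4f} outside the physical range [-0.2, 0.4]"
                )

    @property
    def r0(self) -> float:
        return self.r_inf + sum(a for a, _ in self.components)

    def r(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.r_inf)
        for a, theta in self.components:
            out += a * np.exp(-np.clip(t, 0.0, None) / theta)
        return out

    def validate_on(self, grid: TimeGrid) -> None:
        t = grid.centers()
        r = self.r(t[t >= 0])
        if r.size and (r.min() < -0.2 - 1e-9 or r.max() > 0.4 + 1e-9):
            raise InvalidModelError(
                f"r(t) leaves [-0.2, 0.4] on the grid (range {r.min():.3f}..{r.max():.3f})"
            )


@dataclass(frozen=True)
class DecayCurve:
    """A TCSPC histogram with its acquisition metadata.

    ``counts`` are non-negative per-bin photon counts. Simulated and measured
    curves are integer-valued; noise-free model expectations (float-valued)
    are also accepted so analytic checks can run through the same operations.
    """

    grid: TimeGrid
    counts: np.ndarray
    emission_wavelength: float
    excitation_wavelength: float
    polarization: str = "magic"
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.grid.n_bins,):
            raise AlignmentError(
                f"counts length {counts.shape[0]} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise InvalidModelError("counts must be finite and non-negative")
        if self.polarization not in POLARIZATIONS:
            raise InvalidModelError(
                f"polarization must be one of {POLARIZATIONS}, got {self.polarization!r}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def times(self) -> np.ndarray:
        return self.grid.centers()

    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class SteadyStateSpectrum:
    """Steady-state emission spectrum on a strictly ascending wavelength axis."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.shape != inten.shape or wl.ndim != 1:
            raise InvalidModelError("wavelengths and intensities must match 1-D")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise InvalidModelError("wavelengths must be strictly ascending")
        if np.any(inten < 0) or not inten.max() > 0:
            raise InvalidModelError("intensities must be >= 0 with a positive max")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class ResponseCurve:
    """Spectral sensitivity of the detection system (division-safe: > 0)."""

    wavelengths: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.sensitivity, dtype=float)
        if wl.shape != s.shape or wl.ndim != 1:
            raise InvalidModelError("wavelengths and sensitivity must match 1-D")
        if np.any(np.diff(wl) <= 0):
            raise InvalidModelError("wavelengths must be strictly ascending")
        if np.any(s <= 0):
            raise InvalidModelError("sensitivity must be strictly positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivity", s)


@dataclass(frozen=True)
class MeltModelParams:
    """Two-state melting model with linear baselines.

    A(T) = B_folded(T) * f(T) + B_melted(T) * (1 - f(T)),
    f(T) = 1 / (1 + exp((T - tm) / width)).

    Baselines are anchored at the reference temperatures used for the
    hyperchromicity readout: B_folded(20 C) = a_folded_ref and
    B_melted(96 C) = a_melted_96. ``hyperchromicity_pct`` is the noise-free
    percent absorbance increase at 96 C relative to 20 C the model encodes.
    """

    tm: float
    width: float
    a_folded_ref: float
    hyperchromicity_pct: float
    slope_folded: float = 0.0
    slope_melted: float = 0.0
    a_melted_96: float | None = None

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvalidModelError("transition width must be > 0")
        if self.hyperchromicity_pct < 0:
            raise InvalidModelError("hyperchromicity_pct must be >= 0")
        if not self.a_folded_ref > 0:
            raise InvalidModelError("a_folded_ref must be > 0")

    def folded_fraction(self, temperatures: np.ndarray) -> np.ndarray:
        T = np.asarray(temperatures, dtype=float)
        return 1.0 / (1.0 + np.exp((T - self.tm) / self.width))

    def absorbance(self, temperatures: np.ndarray) -> np.ndarray:
        """Noise-free model absorbance; requires a solved ``a_melted_96``."""
        if self.a_melted_96 is None:
            raise InvalidModelError(
                "a_melted_96 is unset; run calibrate_melt_params first"
            )
        T = np.asarray(temperatures, dtype=float)
        f = self.folded_fraction(T)
        b_fold = self.a_folded_ref + self.slope_folded * (T - 20.0)
        b_melt = self.a_melted_96 + self.slope_melted * (T - 96.0)
        return b_fold * f + b_melt * (1.0 - f)


@dataclass(frozen=True)
class MeltingCurve:
    """Absorbance at 260 nm versus temperature."""

    temperatures: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        A = np.asarray(self.absorbance, dtype=float)
        if T.shape != A.shape or T.ndim != 1:
            raise InvalidModelError("temperatures and absorbance must match 1-D")
        if np.any(np.diff(T) <= 0):
            raise InvalidModelError("temperatures must be strictly ascending")
        if np.any(A <= 0):
            raise InvalidModelError("absorbance must be positive")
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "absorbance", A)
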