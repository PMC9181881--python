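"""Polarization algebra for fluorescence anisotropy.

The anisotropy r(t) = (I_par - G I_perp) / (I_par + 2 G I_perp) reports the
angle between absorption and emission transition dipoles. Two analytic
limits anchor the interpretation: r = (3 cos^2 theta - 1)/5 for a single
angle theta between the dipoles (0.4 parallel, -0.2 perpendicular), and
r = 0.1 for an emission dipole uniformly distributed within the molecular
plane containing the absorption dipole — the floor for purely in-plane
pi-pi* emission in B-form duplexes. Plateaus below 0.1 indicate
out-of-plane character, i.e. mixing with charge-transfer transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .decay import estimate_background
from .errors import AlignmentError, InsufficientDataError
from .grids import TimeGrid
from .models import DecayCurve, TimeWindow

__all__ = [
    "AnisotropyTrace",
    "compute_r_trace",
    "magic_from_pair",
    "theta_anisotropy",
    "in_plane_limit",
    "plateau_r",
]


@dataclass(frozen=True)
class AnisotropyTrace:
    """Per-bin anisotropy with propagated Poisson standard errors.

    ``defined`` flags bins where the denominator is positive and the value
    physical (|r| <= 1); everything else holds NaN.
    """

    grid: TimeGrid
    r_values: np.ndarray
    r_stderr: np.ndarray
    defined: np.ndarray
    g_factor: float = 1.0

    @property
    def times(self) -> np.ndarray:
        return self.grid.centers()


def _check_pair(par: DecayCurve, perp: DecayCurve) -> None:
    if par.grid != perp.grid:
        raise AlignmentError("parallel and perpendicular grids differ")
    if par.emission_wavelength != perp.emission_wavelength:
        raise AlignmentError("pair recorded at different emission wavelengths")


def compute_r_trace(
    par: DecayCurve, perp: DecayCurve, g_factor: float = 1.0
) -> AnisotropyTrace:
    """Bin-wise anisotropy from a parallel/perpendicular pair.

    Counts are background-subtracted (pre-rise estimate per channel) but not
    normalised — normalising either channel would corrupt the ratio. The
    result is invariant under a common positive rescaling of both channels.
    Standard errors come from first-order propagation of Poisson variances
    (variance = raw counts per bin).

    The G factor corrects unequal detection sensitivity of the two
    polarization channels; it is 1.0 when excitation energies are matched.
    """
    _check_pair(par, perp)
    p = par.counts - estimate_background(par)
    q = perp.counts - estimate_background(perp)
    gq = g_factor * q
    denom = p + 2.0 * gq
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (p - gq) / denom
        # d r/d p = 3 G q / D^2 ; d r/d q = -3 G p / D^2
        var = (3.0 * g_factor / denom**2) ** 2 * (
            q**2 * np.maximum(par.counts, 1.0) + p**2 * np.maximum(perp.counts, 1.0)
        )
        stderr = np.sqrt(var)
    defined = (denom > 0) & np.isfinite(r) & (np.abs(r) <= 1.0)
    r = np.where(defined, r, np.nan)
    stderr = np.where(defined, stderr, np.nan)
    return AnisotropyTrace(
        grid=par.grid, r_values=r, r_stderr=stderr, defined=defined, g_factor=g_factor
    )


def magic_from_pair(
    par: DecayCurve, perp: DecayCurve, g_factor: float = 1.0
) -> np.ndarray:
    """Magic-angle (population) decay reconstructed as (I_par + 2 G I_perp)/3.

    Proportional to the polarization-free decay: the anisotropy terms cancel
    exactly in the sum.
    """
    _check_pair(par, perp)
    return (par.counts + 2.0 * g_factor * perp.counts) / 3.0


def theta_anisotropy(theta_degrees: float) -> float:
    """Anisotropy for a fixed angle between absorption and emission dipoles.

    r = (3 cos^2 theta - 1) / 5: 0.4 for parallel dipoles, -0.2 for
    perpendicular ones, 0 at the magic angle (54.7356 deg).
    """
    c = np.cos(np.deg2rad(theta_degrees))
    return float((3.0 * c * c - 1.0) / 5.0)


def in_plane_limit(method: str = "closed_form") -> float:
    """Limiting anisotropy for an emission dipole random within the plane
    containing the absorption dipole.

    Averaging (3 cos^2 theta - 1)/5 over theta uniform on [0, 2 pi) gives
    <cos^2 theta> = 1/2 and hence r = 0.1 — the in-plane floor for pi-pi*
    emission. ``method='quadrature'`` evaluates the same average numerically
    (agrees with the closed form to better than 1e-9).
    """
    if method == "closed_form":
        return (3.0 * 0.5 - 1.0) / 5.0
    if method == "quadrature":
        integral, _ = quad(
            lambda th: (3.0 * np.cos(th) ** 2 - 1.0) / 5.0, 0.0, 2.0 * np.pi
        )
        return integral / (2.0 * np.pi)
    raise ValueError(f"unknown method {method!r}")


def plateau_r(trace: AnisotropyTrace, window: TimeWindow) -> float:
    """Inverse-variance-weighted mean anisotropy over a time window.

    Used to read the long-time plateau (e.g. 2-9 ns) where r(t) has settled.
    Requires at least 10 defined bins in the window.
    """
    t = trace.times
    mask = (t >= window.t_lo) & (t <= window.t_hi) & trace.defined
    if mask.sum() < 10:
        raise InsufficientDataError(
            f"only {int(mask.sum())} defined bins in {window}; need >= 10"
        )
    r = trace.r_values[mask]
    sigma = trace.r_stderr[mask]
    w = 1.0 / np.clip(sigma, 1e-12, None) ** 2
    return float(np.sum(w * r) / np.sum(w))
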