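"""Spectral band shapes and shape measurements.

Emission bands are modelled in wavenumber space (nu = 1e7 / lambda[nm],
cm^-1) as bifurcated Gaussians: independent widths on the high- and
low-energy sides, so an asymmetry factor > 1 gives the red-tailed profile
typical of relaxed emission. With asymmetry 1 the band is a plain Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import MultimodalSpectrumError
from .grids import FWHM_TO_SIGMA
from .models import SteadyStateSpectrum


def nm_to_wavenumber(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Convert wavelength in nm to wavenumber in cm^-1."""
    return 1.0e7 / np.asarray(wavelengths_nm, dtype=float)


@dataclass(frozen=True)
class SpectralBand:
    """One emission band: centre (nm), FWHM (cm^-1), peak height, asymmetry."""

    center_nm: float
    fwhm_cm1: float
    height: float = 1.0
    asymmetry: float = 1.0

    def profile(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        nu = nm_to_wavenumber(wavelengths_nm)
        nu0 = 1.0e7 / self.center_nm
        # Half widths: red (low nu) side is `asymmetry` times the blue side.
        hw_blue = self.fwhm_cm1 / (1.0 + self.asymmetry)
        hw_red = self.fwhm_cm1 - hw_blue
        sigma_blue = 2.0 * hw_blue / FWHM_TO_SIGMA
        sigma_red = 2.0 * hw_red / FWHM_TO_SIGMA
        sigma = np.where(nu < nu0, sigma_red, sigma_blue)
        return self.height * np.exp(-0.5 * ((nu - nu0) / sigma) ** 2)


def evaluate_bands(
    bands: Sequence[SpectralBand], wavelengths_nm: np.ndarray
) -> np.ndarray:
    """Sum of band profiles on a wavelength grid."""
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    out = np.zeros_like(wavelengths_nm)
    for band in bands:
        out += band.profile(wavelengths_nm)
    return out


def spectral_fwhm_wavenumber(spectrum: SteadyStateSpectrum) -> float:
    """Full width at half maximum in cm^-1.

    The spectrum is converted to a wavenumber axis and the two half-maximum
    crossings are located by linear interpolation. More than two crossings
    means the spectrum is not unimodal above half maximum and the width is
    ill-defined.
    """
    nu = nm_to_wavenumber(spectrum.wavelengths)[::-1]
    inten = spectrum.intensities[::-1]
    half = inten.max() / 2.0
    above = inten >= half
    sign_changes = np.nonzero(np.diff(above.astype(int)))[0]
    if len(sign_changes) != 2:
        raise MultimodalSpectrumError(
            f"expected 2 half-maximum crossings, found {len(sign_changes)}"
        )
    crossings = []
    for i in sign_changes:
        y0, y1 = inten[i], inten[i + 1]
        frac = (half - y0) / (y1 - y0)
        crossings.append(nu[i] + frac * (nu[i + 1] - nu[i]))
    return float(abs(crossings[1] - crossings[0]))


class PeakEstimate(NamedTuple):
    """Interpolated peak position with a quality flag ('ok', 'edge' or 'tie')."""

    wavelength_nm: float
    flag: str


def peak_wavelength(spectrum: SteadyStateSpectrum) -> PeakEstimate:
    """Peak position by parabolic interpolation through the 3 bins at the argmax.

    Spectra are typically sampled every 5-15 nm, so the quadratic refinement
    matters. A maximum on the grid boundary cannot be interpolated and is
    returned as-is with flag ``'edge'``; exact ties return the smallest
    wavelength with flag ``'tie'``.
    """
    wl = spectrum.wavelengths
    inten = spectrum.intensities
    peak_val = inten.max()
    idx_all = np.nonzero(inten == peak_val)[0]
    i = int(idx_all[0])
    if len(idx_all) > 1:
        return PeakEstimate(float(wl[i]), "tie")
    if i == 0 or i == wl.size - 1:
        return PeakEstimate(float(wl[i]), "edge")
    # Quadratic through three (possibly unevenly spaced) points.
    coeffs = np.polyfit(wl[i - 1 : i + 2], inten[i - 1 : i + 2], 2)
    if coeffs[0] >= 0:  # degenerate curvature; fall back to the grid point
        return PeakEstimate(float(wl[i]), "ok")
    vertex = -coeffs[1] / (2.0 * coeffs[0])
    vertex = float(np.clip(vertex, wl[i - 1], wl[i + 1]))
    return PeakEstimate(vertex, "ok")
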