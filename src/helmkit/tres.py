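"""Time-resolved emission spectra (TRES) and photon budgets.

A TRES is reconstructed from a series of per-wavelength decays by
integrating the background-subtracted photons of each decay over a time
window, correcting the resulting spectrum for the detector's spectral
response, and peak-normalising. Photon budgets split the total detected
photons (all wavelengths) across a partition of the time range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .decay import estimate_background
from .errors import (
    AlignmentError,
    CoverageError,
    InvalidModelError,
    PartitionError,
    WindowRangeError,
)
from .grids import TimeGrid
from .models import DecayCurve, ResponseCurve, SteadyStateSpectrum, TimeWindow
from .spectra import peak_wavelength, spectral_fwhm_wavenumber  # re-export

__all__ = [
    "TRES",
    "PhotonBudget",
    "integrate_window",
    "correct_response",
    "build_tres",
    "photon_budget",
    "spectral_fwhm_wavenumber",
    "peak_wavelength",
]


def _common_grid(decays: Mapping[float, DecayCurve]) -> TimeGrid:
    grids = {d.grid for d in decays.values()}
    if len(grids) != 1:
        raise AlignmentError("decays in a series must share one time grid")
    return grids.pop()


def integrate_window(
    decays: Mapping[float, DecayCurve], window: TimeWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted photon sums per wavelength over a time window.

    Returns ``(wavelengths, sums)`` with wavelengths ascending. Requires at
    least three wavelengths on a common grid; the window must lie within it.
    """
    if len(decays) < 3:
        raise InvalidModelError(
            f"need >= 3 wavelengths for a spectrum, got {len(decays)}"
        )
    grid = _common_grid(decays)
    if window.t_lo < grid.start - 1e-9 or window.t_hi > grid.stop + 1e-9:
        raise WindowRangeError(f"window {window} outside grid [{grid.start}, {grid.stop}]")
    centers = grid.centers()
    mask = (centers >= window.t_lo) & (centers <= window.t_hi)
    wavelengths = np.array(sorted(decays))
    sums = np.array(
        [
            float((decays[wl].counts - estimate_background(decays[wl]))[mask].sum())
            for wl in wavelengths
        ]
    )
    return wavelengths, sums


def correct_response(
    spectrum: tuple[np.ndarray, np.ndarray], response: ResponseCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Divide a raw spectrum by the detector sensitivity, wavelength-wise.

    The sensitivity is interpolated linearly onto the spectrum wavelengths,
    which must lie inside the response curve's range.
    """
    wavelengths, intensities = spectrum
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.min() < response.wavelengths.min() or wavelengths.max() > (
        response.wavelengths.max()
    ):
        raise CoverageError("response curve does not cover the spectrum wavelengths")
    sens = np.interp(wavelengths, response.wavelengths, response.sensitivity)
    return wavelengths, np.asarray(intensities, dtype=float) / sens


@dataclass(frozen=True)
class TRES:
    """Window-integrated, response-corrected emission spectra.

    ``raw`` holds the uncorrected photon sums, ``corrected`` the
    response-corrected ones and ``normalized`` the corrected spectra scaled
    to peak at exactly 1 (all arrays are windows x wavelengths).
    """

    windows: tuple[TimeWindow, ...]
    wavelengths: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray

    def spectrum(self, i: int, kind: str = "normalized") -> SteadyStateSpectrum:
        """Window ``i`` as a SteadyStateSpectrum (clipping negatives to 0)."""
        values = getattr(self, kind)[i]
        return SteadyStateSpectrum(
            wavelengths=self.wavelengths, intensities=np.clip(values, 0.0, None)
        )


def build_tres(
    decays: Mapping[float, DecayCurve],
    windows: Sequence[TimeWindow],
    response: ResponseCurve,
) -> TRES:
    """Integrate each window, correct for the response, peak-normalise."""
    raw_rows, corr_rows, norm_rows = [], [], []
    wavelengths = None
    for window in windows:
        wl, raw = integrate_window(decays, window)
        _, corr = correct_response((wl, raw), response)
        peak = corr.max()
        if not peak > 0:
            norm = np.zeros_like(corr)
        else:
            norm = corr / peak
        wavelengths = wl
        raw_rows.append(raw)
        corr_rows.append(corr)
        norm_rows.append(norm)
    return TRES(
        windows=tuple(windows),
        wavelengths=wavelengths,
        raw=np.array(raw_rows),
        corrected=np.array(corr_rows),
        normalized=np.array(norm_rows),
    )


@dataclass(frozen=True)
class PhotonBudget:
    """Percentages of total detected photons per time interval (sum = 100)."""

    intervals: tuple[TimeWindow, ...]
    percentages: np.ndarray

    def for_interval(self, t_lo: float, t_hi: float) -> float:
        for window, pct in zip(self.intervals, self.percentages):
            if abs(window.t_lo - t_lo) < 1e-9 and abs(window.t_hi - t_hi) < 1e-9:
                return float(pct)
        raise KeyError(f"no interval ({t_lo}, {t_hi}) in the budget")


#: Successive intervals with boundaries at 0.1 and 1 ns, closing at 10 then
#: the end of the acquisition range.
DEFAULT_BUDGET_INTERVALS = (
    TimeWindow(-1.0, 0.1),
    TimeWindow(0.1, 1.0),
    TimeWindow(1.0, 10.0),
    TimeWindow(10.0, 10.5),
)


def photon_budget(
    decays: Mapping[float, DecayCurve],
    intervals: Sequence[TimeWindow] = DEFAULT_BUDGET_INTERVALS,
) -> PhotonBudget:
    """Share of all detected photons (all wavelengths) per time interval.

    Intervals must be pairwise disjoint and cover the full acquisition
    range. Counts are background-subtracted per decay; per-interval sums are
    clipped at zero before converting to percentages, which therefore sum to
    exactly 100.
    """
    grid = _common_grid(decays)
    ordered = sorted(intervals, key=lambda w: w.t_lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_lo < a.t_hi - 1e-9:
            raise PartitionError(f"intervals {a} and {b} overlap")
        if b.t_lo > a.t_hi + 1e-9:
            raise PartitionError(f"gap between intervals {a} and {b}")
    if abs(ordered[0].t_lo - grid.start) > grid.bin_width + 1e-9 or abs(
        ordered[-1].t_hi - grid.stop
    ) > grid.bin_width + 1e-9:
        raise PartitionError(
            f"intervals cover [{ordered[0].t_lo}, {ordered[-1].t_hi}] but the "
            f"grid spans [{grid.start}, {grid.stop}]"
        )
    centers = grid.centers()
    sums = []
    for window in intervals:
        mask = (centers >= window.t_lo) & (centers < window.t_hi)
        total = 0.0
        for decay in decays.values():
            total += float(
                (decay.counts - estimate_background(decay))[mask].sum()
            )
        sums.append(max(total, 0.0))
    sums = np.array(sums)
    if not sums.sum() > 0:
        raise PartitionError("no signal photons in any interval")
    return PhotonBudget(
        intervals=tuple(intervals), percentages=100.0 * sums / sums.sum()
    )
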