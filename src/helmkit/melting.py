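"""Melting-curve analysis: two-state sigmoid fit and hyperchromicity.

Duplex melting releases hypochromism: the 260 nm absorbance rises as base
stacking is lost. The curve is modelled phenomenologically as a logistic
two-state transition with linear folded/melted baselines,

    A(T) = B_f(T) f(T) + B_m(T) (1 - f(T)),   f(T) = 1/(1 + exp((T - Tm)/w)).

Only Tm and the hyperchromicity (percent absorbance increase at 96 C versus
20 C) feed the downstream comparisons; no thermodynamic parameters are
extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy.ndimage import uniform_filter1d

from .errors import FitFailureError, NoTransitionError, WindowRangeError
from .models import MeltingCurve, TimeWindow

__all__ = ["MeltFitResult", "fit_melting", "hyperchromicity", "melting_temperature"]

T_REF = 20.0
T_HOT = 96.0


@dataclass(frozen=True)
class MeltFitResult:
    """Fitted two-state melting model.

    ``baseline_folded`` / ``baseline_melted`` are (intercept, slope) pairs
    with the intercept at 0 C. ``hyperchromicity_pct`` is evaluated from the
    fitted model at 20 and 96 C, ``rmse`` in absorbance units.
    """

    tm: float
    width: float
    baseline_folded: tuple[float, float]
    baseline_melted: tuple[float, float]
    hyperchromicity_pct: float
    rmse: float

    def model(self, temperatures: np.ndarray) -> np.ndarray:
        T = np.asarray(temperatures, dtype=float)
        f = 1.0 / (1.0 + np.exp((T - self.tm) / self.width))
        bf = self.baseline_folded[0] + self.baseline_folded[1] * T
        bm = self.baseline_melted[0] + self.baseline_melted[1] * T
        return bf * f + bm * (1.0 - f)


def _initial_tm(curve: MeltingCurve) -> float:
    """Tm guess from the maximum of a smoothed numerical derivative."""
    T, A = curve.temperatures, curve.absorbance
    smooth = uniform_filter1d(A, size=max(3, A.size // 10), mode="nearest")
    dA = np.gradient(smooth, T)
    return float(T[int(np.argmax(dA))])


def fit_melting(curve: MeltingCurve) -> MeltFitResult:
    """Nonlinear least squares of the logistic two-state model.

    Initialisation is deterministic: Tm candidates are the smoothed
    derivative maximum and the midpoint of the temperature range (the best
    of the two fits is kept); baselines start from straight-line fits to the
    outer 20% of the range on each side. A curve whose fitted amplitude
    change does not exceed the residual noise has no transition to speak of
    and raises :class:`NoTransitionError`.
    """
    T, A = curve.temperatures, curve.absorbance
    if T.size < 8:
        raise FitFailureError(f"need >= 8 points, got {T.size}")
    n_edge = max(3, T.size // 5)
    lo_fit = np.polyfit(T[:n_edge], A[:n_edge], 1)  # slope, intercept
    hi_fit = np.polyfit(T[-n_edge:], A[-n_edge:], 1)
    span = T[-1] - T[0]

    def run(tm0: float):
        params = Parameters()
        params.add("tm", value=tm0, min=T[0] - 10.0, max=T[-1] + 10.0)
        params.add("width", value=max(span / 25.0, 0.5), min=1e-3, max=span)
        params.add("bf0", value=lo_fit[1])
        params.add("bf1", value=lo_fit[0])
        params.add("bm0", value=hi_fit[1])
        params.add("bm1", value=hi_fit[0])

        def residual(p):
            f = 1.0 / (1.0 + np.exp((T - p["tm"]) / p["width"]))
            bf = p["bf0"] + p["bf1"] * T
            bm = p["bm0"] + p["bm1"] * T
            return bf * f + bm * (1.0 - f) - A

        return minimize(residual, params, method="least_squares")

    results = [run(tm0) for tm0 in (_initial_tm(curve), float(T.mean()))]
    results = [r for r in results if r.success]
    if not results:
        raise FitFailureError("melting fit did not converge", diagnostics=results)
    best = min(results, key=lambda r: r.chisqr)
    p = best.params
    rmse = float(np.sqrt(np.mean(best.residual**2)))
    tm = float(p["tm"].value)
    # Amplitude of the transition at Tm: separation of the two baselines.
    jump = abs(
        (p["bm0"].value + p["bm1"].value * tm) - (p["bf0"].value + p["bf1"].value * tm)
    )
    if jump <= max(3.0 * rmse, 1e-12) or not (T[0] < tm < T[-1]):
        raise NoTransitionError(
            f"no sigmoidal transition: baseline separation {jump:.2e} "
            f"vs noise {rmse:.2e}"
        )
    result = MeltFitResult(
        tm=tm,
        width=float(p["width"].value),
        baseline_folded=(float(p["bf0"].value), float(p["bf1"].value)),
        baseline_melted=(float(p["bm0"].value), float(p["bm1"].value)),
        hyperchromicity_pct=0.0,
        rmse=rmse,
    )
    a_ref = float(result.model(np.array([T_REF]))[0])
    a_hot = float(result.model(np.array([T_HOT]))[0])
    return MeltFitResult(
        tm=result.tm,
        width=result.width,
        baseline_folded=result.baseline_folded,
        baseline_melted=result.baseline_melted,
        hyperchromicity_pct=100.0 * (a_hot - a_ref) / a_ref,
        rmse=rmse,
    )


def hyperchromicity(
    curve: MeltingCurve, t_ref: float = T_REF, t_hot: float = T_HOT
) -> float:
    """Model-free percent absorbance increase at ``t_hot`` vs ``t_ref``.

    Reads the curve directly with linear interpolation; readout points may
    fall at most 2 C outside the measured range (edge value used).
    """
    T, A = curve.temperatures, curve.absorbance
    for t in (t_ref, t_hot):
        if t < T[0] - 2.0 or t > T[-1] + 2.0:
            raise WindowRangeError(
                f"readout at {t} C is > 2 C outside the measured range "
                f"[{T[0]}, {T[-1]}]"
            )
    a_ref = float(np.interp(t_ref, T, A))
    a_hot = float(np.interp(t_hot, T, A))
    return 100.0 * (a_hot - a_ref) / a_ref


def melting_temperature(fit: MeltFitResult) -> float:
    """Melting temperature of a fitted curve (the logistic inflection)."""
    return fit.tm
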