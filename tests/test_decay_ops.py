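"""Decay operations: forward model, background, normalisation, fractions,
tail fits. Expected values come from closed forms or brute-force oracles
independent of the implementation path."""

import numpy as np
import pytest
from scipy.integrate import quad

from helmkit import (
    DecayCurve,
    DecayModel,
    TimeGrid,
    TimeWindow,
    estimate_background,
    expected_counts,
    fraction_after,
    make_irf,
    normalize_decay,
    simulate_decay,
    tail_fit,
)
from helmkit.errors import (
    DegenerateSignalError,
    InsufficientBaselineError,
    WindowRangeError,
)


class TestExpectedCounts:
    def test_delta_irf_reduces_to_bare_exponential(self, grid, irf_delta):
        model = DecayModel(((1.0, 2.0),))
        out = expected_counts(model, irf_delta, include_background=False)
        t = grid.centers()
        t0 = t[int(np.argmax(irf_delta.values))]
        late = t >= t0
        assert np.allclose(out[late], np.exp(-(t[late] - t0) / 2.0), atol=1e-12)
        assert np.all(out[t < t0] == 0)

    def test_matches_exgaussian_closed_form(self, grid, irf80):
        # Spec formula 1/2 exp(s^2/2 tau^2 - t/tau) erfc((s/tau - t/s)/sqrt 2)
        # evaluated independently at five bins.
        from scipy.special import erfc

        tau, s = 2.6, irf80.sigma_ns
        model = DecayModel(((1.0, tau),))
        out = expected_counts(model, irf80, include_background=False)
        t = grid.centers()
        for i in [40, 80, 120, 200, 400]:
            ref = (
                0.5
                * np.exp(s**2 / (2 * tau**2) - t[i] / tau)
                * erfc((s / tau - t[i] / s) / np.sqrt(2))
            )
            assert out[i] == pytest.approx(ref, rel=1e-6)

    def test_matches_numerical_convolution(self, grid, irf80):
        # Independent oracle: direct quadrature of the convolution integral.
        tau, s = 0.3, irf80.sigma_ns
        model = DecayModel(((1.0, tau),))
        out = expected_counts(model, irf80, include_background=False)
        t = grid.centers()
        for i in [38, 45, 60, 150]:
            # finite range with a breakpoint at the Gaussian peak, so the
            # adaptive rule cannot miss the narrow integrand
            ref, _ = quad(
                lambda u: np.exp(-u / tau)
                * np.exp(-((t[i] - u) ** 2) / (2 * s**2))
                / (s * np.sqrt(2 * np.pi)),
                0.0,
                5.0,
                points=[max(t[i], 0.0)],
                limit=200,
            )
            assert out[i] == pytest.approx(ref, rel=1e-6)

    def test_linearity_in_components(self, irf80):
        one = expected_counts(DecayModel(((0.7, 0.4),)), irf80, include_background=False)
        two = expected_counts(DecayModel(((0.3, 2.6),)), irf80, include_background=False)
        both = expected_counts(
            DecayModel(((0.7, 0.4), (0.3, 2.6))), irf80, include_background=False
        )
        assert np.allclose(both, one + two, rtol=1e-12)

    def test_gaussian_and_discrete_convolution_agree(self, grid):
        # The tabulated path is a second, independent route to the same
        # expectation; at 25 ps bins it agrees to discretisation accuracy.
        from helmkit.grids import InstrumentResponse

        irf_g = make_irf(80.0, grid)
        irf_t = InstrumentResponse(
            grid=grid, values=irf_g.values, fwhm_ps=80.0, shape="tabulated"
        )
        model = DecayModel(((1.0, 2.6),))
        a = expected_counts(model, irf_g, include_background=False)
        b = expected_counts(model, irf_t, include_background=False)
        # Past the pulse (4 sigma) the two routes agree to better than 1e-3;
        # on the steep rising edge the piecewise-constant IRF representation
        # limits the tabulated path, but total photon numbers stay exact.
        t = grid.centers()
        late = t > irf_g.t0 + 4 * irf_g.sigma_ns
        assert np.allclose(a[late], b[late], rtol=1e-3)
        assert b.sum() == pytest.approx(a.sum(), rel=1e-6)


class TestBackgroundAndNormalisation:
    def test_constant_baseline_recovered(self, grid):
        counts = np.full(grid.n_bins, 7.0)
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        assert estimate_background(decay) == pytest.approx(7.0)

    def test_poisson_baseline_within_standard_error(self, grid):
        rng = np.random.default_rng(42)
        counts = np.zeros(grid.n_bins)
        pre = grid.edges()[1:] <= -0.5
        counts[pre] = rng.poisson(5.0, pre.sum())
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        assert estimate_background(decay) == pytest.approx(
            5.0, abs=3 * np.sqrt(5.0 / pre.sum())
        )

    def test_grid_without_prerise_rejected(self):
        g = TimeGrid(start=0.0, stop=10.0, bin_width=0.025)
        decay = DecayCurve(g, np.ones(g.n_bins), 305.0, 267.0)
        with pytest.raises(InsufficientBaselineError):
            estimate_background(decay)

    @pytest.mark.parametrize(
        "counts,background,expected",
        [
            ([0.0, 10.0, 5.0], 0.0, [0.0, 1.0, 0.5]),
            ([3.0, 13.0, 8.0], 3.0, [0.0, 1.0, 0.5]),
        ],
    )
    def test_normalisation_arithmetic(self, counts, background, expected):
        g = TimeGrid(start=0.0, stop=0.075, bin_width=0.025)
        decay = DecayCurve(g, np.array(counts), 305.0, 267.0)
        assert np.allclose(normalize_decay(decay, background), expected)

    def test_normalisation_idempotent(self, grid, irf80):
        model = DecayModel(((1.0, 2.0),))
        counts = expected_counts(model, irf80, include_background=False) * 1e4
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        once = normalize_decay(decay, 0.0)
        again = normalize_decay(DecayCurve(grid, once, 305.0, 267.0), 0.0)
        assert np.allclose(once, again)
        assert once.max() == 1.0

    def test_all_background_decay_rejected(self, grid):
        decay = DecayCurve(grid, np.full(grid.n_bins, 4.0), 305.0, 267.0)
        with pytest.raises(DegenerateSignalError):
            normalize_decay(decay, 4.0)


class TestFractionAfter:
    def test_single_exponential_closed_form(self, grid):
        # (e^{-1/tau} - e^{-T/tau}) / (1 - e^{-T/tau}) with tau=2.6, T=10.5
        tau, T = 2.6, 10.5
        oracle = (np.exp(-1 / tau) - np.exp(-T / tau)) / (1 - np.exp(-T / tau))
        t = grid.centers()
        counts = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        assert fraction_after(decay, background=0.0) == pytest.approx(
            oracle, abs=5e-3
        )
        assert oracle == pytest.approx(0.675, abs=2e-3)

    def test_cut_at_window_start_gives_unity(self, grid, irf80):
        counts = expected_counts(
            DecayModel(((1.0, 2.0),)), irf80, include_background=False
        )
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        assert fraction_after(decay, t_cut=-1.0, background=0.0) == pytest.approx(1.0)

    def test_cut_outside_window_rejected(self, grid, irf80):
        counts = expected_counts(
            DecayModel(((1.0, 2.0),)), irf80, include_background=False
        )
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        with pytest.raises(WindowRangeError):
            fraction_after(decay, t_cut=12.0)

    def test_monotone_in_lifetime(self, grid, irf80):
        fractions = []
        for tau in (0.5, 1.0, 2.0, 4.0):
            counts = expected_counts(
                DecayModel(((1.0, tau),)), irf80, include_background=False
            )
            decay = DecayCurve(grid, counts, 305.0, 267.0)
            fractions.append(fraction_after(decay, background=0.0))
        assert np.all(np.diff(fractions) > 0)


def _grid_search_tail_tau(t, y, window, n_grid=4000):
    """Brute-force oracle: scan tau, solving amplitude/background by
    non-negative linear least squares (matching the fit's constraints)."""
    from scipy.optimize import nnls

    best = (np.inf, None)
    w = 1.0 / np.maximum(y, 1.0)
    for tau in np.linspace(0.2, 8.0, n_grid):
        basis = np.column_stack([np.exp(-(t - window.t_lo) / tau), np.ones_like(t)])
        coef, _ = nnls(basis * w[:, None] ** 0.5, y * w**0.5)
        resid = y - basis @ coef
        sse = float(np.sum(w * resid**2))
        if sse < best[0]:
            best = (sse, tau)
    return best[1]


class TestTailFit:
    def test_exact_recovery_in_model_class(self, grid):
        t = grid.centers()
        counts = np.where(t >= 0, 5e4 * np.exp(-np.clip(t, 0, None) / 2.0), 0.0)
        decay = DecayCurve(grid, counts, 305.0, 267.0)
        fit = tail_fit(decay)
        assert fit.tau == pytest.approx(2.0, rel=1e-4)
        assert fit.chi2_reduced < 1e-6

    def test_biexponential_matches_grid_search_oracle(self, grid):
        window = TimeWindow(1.5, 10.5)
        t = grid.centers()
        pos = np.clip(t, 0, None)
        # equal 1-ns amplitudes of a 0.5 and a 2.5 ns component
        y = np.where(
            t >= 0,
            4e4 * (np.exp(1 / 0.5) * np.exp(-pos / 0.5) + np.exp(1 / 2.5) * np.exp(-pos / 2.5)),
            0.0,
        )
        decay = DecayCurve(grid, y, 305.0, 267.0)
        fit = tail_fit(decay, window)
        mask = (t >= window.t_lo) & (t <= window.t_hi)
        oracle = _grid_search_tail_tau(t[mask], y[mask], window)
        assert fit.tau == pytest.approx(oracle, rel=0.01)

    def test_self_consistency_over_seeds(self, grid, irf80, papt267):
        # Refitting data simulated from the fitted parameters recovers them
        # within 2 standard errors (checked over 20 seeds).
        decay = simulate_decay(
            papt267.decay_models[305.0], irf80, 500_000, seed=0
        )
        fit0 = tail_fit(decay)
        model = DecayModel(
            ((fit0.amplitude * np.exp(1.5 / fit0.tau), fit0.tau),),
            background_rate=fit0.background,
        )
        misses = 0
        for seed in range(20):
            sim = simulate_decay(model, irf80, int(decay.total_counts()), seed=seed)
            refit = tail_fit(sim)
            if abs(refit.tau - fit0.tau) > 2 * refit.tau_stderr:
                misses += 1
        assert misses <= 3  # ~5% expected miss rate per seed

    def test_short_window_rejected(self, grid, irf80):
        counts = expected_counts(
            DecayModel(((1.0, 2.0),)), irf80, include_background=False
        )
        decay = DecayCurve(grid, counts * 1e4, 305.0, 267.0)
        with pytest.raises(WindowRangeError):
            tail_fit(decay, TimeWindow(5.0, 5.2))
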