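"""Generator behaviour: determinism, Poisson statistics, photon
conservation in polarized pairs, preset calibration closure, spectra and
melting curves."""

import numpy as np
import pytest

from helmkit import (
    AnisotropyModel,
    DecayCurve,
    DecayModel,
    MeltModelParams,
    calibrate_melt_params,
    expected_counts,
    expected_polarized_pair,
    fraction_after,
    make_irf,
    simulate_decay,
    simulate_melting_curve,
    simulate_polarized_pair,
    simulate_steady_state_spectrum,
    simulate_wavelength_series,
    ss_intensity_ratio,
    spectral_fwhm_wavenumber,
)
from helmkit.errors import CoverageError, InvalidModelError, UnknownPresetError
from helmkit.presets import KNOWN_COMBINATIONS, get_preset


class TestSimulateDecay:
    def test_determinism(self, irf80):
        model = DecayModel(((1.0, 2.6),), background_rate=2.0)
        a = simulate_decay(model, irf80, 10_000, seed=123)
        b = simulate_decay(model, irf80, 10_000, seed=123)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_decay(model, irf80, 10_000, seed=124)
        assert not np.array_equal(a.counts, c.counts)

    def test_total_counts_poisson_sum(self, irf80):
        model = DecayModel(((1.0, 2.6),), background_rate=0.0)
        decay = simulate_decay(model, irf80, 1_000_000, seed=5)
        assert abs(decay.total_counts() - 1e6) < 5 * np.sqrt(1e6)

    def test_mean_arrival_time_matches_truncated_exponential(self, grid, irf_delta):
        # Closed-form mean of exp(-t/tau) truncated to [0, T]:
        # tau - T e^{-T/tau} / (1 - e^{-T/tau}).
        tau = 2.6
        t0_bin = grid.centers()[int(np.argmax(irf_delta.values))]
        T = grid.stop - t0_bin
        oracle = tau - T * np.exp(-T / tau) / (1 - np.exp(-T / tau))
        decay = simulate_decay(DecayModel(((1.0, tau),)), irf_delta, 1_000_000, seed=9)
        t_rel = grid.centers() - t0_bin
        mean = np.sum(t_rel * decay.counts) / decay.total_counts()
        # variance of the truncated exponential, for the 3-sigma band
        second = tau**2 * 2 - (T**2 + 2 * tau * T) * np.exp(-T / tau) / (
            1 - np.exp(-T / tau)
        )
        sd = np.sqrt(second - oracle**2) / np.sqrt(decay.total_counts())
        assert abs(mean - oracle) < 3 * sd + grid.bin_width / 2

    def test_nonpositive_photons_rejected(self, irf80):
        with pytest.raises(InvalidModelError):
            simulate_decay(DecayModel(((1.0, 2.6),)), irf80, 0, seed=1)


class TestPolarizedPair:
    def test_isotropic_gives_equal_channels(self, irf80):
        model = DecayModel(((1.0, 2.6),))
        aniso = AnisotropyModel(r_inf=0.0)
        par, perp = expected_polarized_pair(model, aniso, irf80, 1e6)
        assert np.allclose(par, perp, rtol=1e-12)

    def test_photoselection_maximum(self, irf80):
        model = DecayModel(((1.0, 2.6),))
        aniso = AnisotropyModel(r_inf=0.4)
        par, perp = expected_polarized_pair(model, aniso, irf80, 1e6)
        assert np.allclose(perp[par > 0], par[par > 0] / 3.0, rtol=1e-9)

    def test_photon_conservation(self, irf80, a20t20):
        # E[I_par] + 2 E[I_perp] equals 3x the magic-angle expectation.
        model = a20t20.decay_models[305.0]
        aniso = a20t20.anisotropy_models[305.0]
        par, perp = expected_polarized_pair(model, aniso, irf80, 1e6)
        magic = expected_counts(model, irf80, include_background=False)
        magic = magic * (1e6 / magic.sum())
        assert np.allclose(par + 2 * perp, magic, atol=1e-8 * magic.max())

    def test_unphysical_anisotropy_rejected(self, irf80):
        with pytest.raises(InvalidModelError):
            AnisotropyModel(r_inf=0.3, components=((0.3, 0.5),))  # r0 = 0.6

    def test_simulated_pair_determinism(self, irf80, a20t20):
        args = (
            a20t20.decay_models[305.0],
            a20t20.anisotropy_models[305.0],
            irf80,
            50_000,
        )
        p1, q1 = simulate_polarized_pair(*args, seed=7)
        p2, q2 = simulate_polarized_pair(*args, seed=7)
        assert np.array_equal(p1.counts, p2.counts)
        assert np.array_equal(q1.counts, q2.counts)


class TestPresets:
    @pytest.mark.parametrize("system,excitation,buffer", KNOWN_COMBINATIONS)
    def test_all_presets_load_and_close(self, system, excitation, buffer):
        # Calibration closure: noise-free analysis of every decay model
        # reproduces the encoded fraction-after-1-ns within 1% relative.
        preset = get_preset(system, excitation, buffer)
        centers = preset.grid.centers()
        for wl, model in preset.decay_models.items():
            curve = expected_counts(model, preset.irf, include_background=False)
            f = curve[centers >= 1.0].sum() / curve.sum()
            target = preset.targets.fractions_after_1ns[wl]
            assert f == pytest.approx(target, rel=0.01), (wl, preset.label)

    def test_unknown_combination_rejected(self):
        with pytest.raises(UnknownPresetError):
            get_preset("A20T20", 267, "standard")

    def test_long_lifetimes_match_encoding(self, papt267, papt285, a20t20):
        for preset, tau in ((papt267, 2.6), (papt285, 2.2), (a20t20, 2.7)):
            lifetimes = [t for _, t in preset.decay_models[305.0].components]
            assert tau in lifetimes

    def test_kcl_control_identical_to_standard(self, papt267):
        kcl = get_preset("pApT", 267, "KCl_matched")
        assert kcl.decay_models[305.0].components == (
            papt267.decay_models[305.0].components
        )

    def test_simulated_fraction_recovers_table_value(self, a20t20):
        decay = simulate_decay(
            a20t20.decay_models[305.0], a20t20.irf, 1_000_000, seed=3
        )
        assert fraction_after(decay) == pytest.approx(0.501, abs=0.01)


class TestSteadyStateSpectrum:
    def test_polymer_ratio_and_width(self, papt267, wide_wavelengths):
        spec = simulate_steady_state_spectrum(papt267, wide_wavelengths)
        assert ss_intensity_ratio(spec) == pytest.approx(3.9, abs=0.05)
        assert spectral_fwhm_wavenumber(spec) == pytest.approx(5400, abs=50)
        assert spec.intensities.max() == pytest.approx(1.0)

    def test_oligomer_width(self, a20t20, wide_wavelengths):
        spec = simulate_steady_state_spectrum(a20t20, wide_wavelengths)
        assert spectral_fwhm_wavenumber(spec) == pytest.approx(6900, abs=50)

    def test_narrow_grid_rejected(self, papt267):
        with pytest.raises(CoverageError):
            simulate_steady_state_spectrum(papt267, np.arange(320.0, 401.0, 5.0))

    def test_ratio_consistent_with_preset_encoding(self, a20t20, wide_wavelengths):
        spec = simulate_steady_state_spectrum(a20t20, wide_wavelengths)
        assert ss_intensity_ratio(spec) == pytest.approx(
            a20t20.ss_ratio_305_420, rel=0.05
        )


class TestMeltingCurveGenerator:
    def test_midpoint_is_half_folded(self):
        params = calibrate_melt_params(
            MeltModelParams(tm=65.0, width=3.0, a_folded_ref=1.0, hyperchromicity_pct=40.0)
        )
        assert params.folded_fraction(np.array([65.0]))[0] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "preset_args,target",
        [
            (("pApT", 285, "standard"), 70.0),
            (("A20T20", 285, "standard"), 40.0),
            (("pApT", 285, "diluted_6x"), 60.0),
        ],
    )
    def test_noise_free_hyperchromicity_exact(self, preset_args, target):
        preset = get_preset(*preset_args)
        T = np.arange(20.0, 96.01, 1.0)
        curve = simulate_melting_curve(preset.melt_params, T, noise_sd=0.0)
        h = 100.0 * (curve.absorbance[-1] - curve.absorbance[0]) / curve.absorbance[0]
        assert h == pytest.approx(target, abs=1e-6)

    def test_zero_hyperchromicity_flat_curve(self):
        params = calibrate_melt_params(
            MeltModelParams(tm=60.0, width=2.0, a_folded_ref=1.0, hyperchromicity_pct=0.0)
        )
        curve = simulate_melting_curve(params, np.arange(20.0, 96.01, 2.0))
        assert np.ptp(curve.absorbance) < 1e-9

    def test_noise_determinism(self, a20t20):
        T = np.arange(20.0, 96.01, 2.0)
        a = simulate_melting_curve(a20t20.melt_params, T, 0.005, seed=4)
        b = simulate_melting_curve(a20t20.melt_params, T, 0.005, seed=4)
        assert np.array_equal(a.absorbance, b.absorbance)


class TestWavelengthSeries:
    def test_subset_reproducible_independently(self, papt267):
        # The (seed, index) expansion means a subset simulation reproduces
        # the same counts as the full series at shared wavelengths.
        full = simulate_wavelength_series(papt267, 10_000, seed=6)
        again = simulate_wavelength_series(papt267, 10_000, seed=6)
        for wl in full:
            assert np.array_equal(full[wl].counts, again[wl].counts)

    def test_weighting_follows_detected_intensity(self, papt267):
        series = simulate_wavelength_series(papt267, 200_000, seed=8)
        weights = papt267.weights
        wmax = max(weights.values())
        for wl, decay in series.items():
            expected = 200_000 * weights[wl] / wmax + papt267.grid.n_bins * 2.0
            assert decay.total_counts() == pytest.approx(expected, rel=0.05)

    def test_irf_limit_converges_to_pure_exponential(self, grid):
        # As the IRF narrows the convolved expectation approaches the bare
        # multi-exponential bin-wise.
        model = DecayModel(((1.0, 2.6),))
        t = grid.centers()
        target = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / 2.6), 0.0)
        errs = []
        for fwhm in (80.0, 20.0, 5.0):
            out = expected_counts(model, make_irf(fwhm, grid), include_background=False)
            errs.append(np.abs(out - target)[np.abs(t) > 0.2].max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4
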