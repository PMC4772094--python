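"""Band integration, the ratio statistic and the spectrum Gaussian fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from qdtherm.errors import BandCoverageError, DegenerateSignalError, FitError
from qdtherm.spectral import (
    BandPair,
    EmissionSpectrum,
    TemperatureResponseModel,
    analytic_gaussian_ratio,
    band_integrate,
    band_ratio,
    fit_spectrum_gaussian,
    predict_ratio,
    relative_sensitivity,
    sensitivity_scan,
)


def quad_ratio(mean_nm: float, sigma_nm: float, bands: BandPair) -> float:
    """Independent oracle: adaptive quadrature of the Gaussian density."""

    def g(x):
        return np.exp(-((x - mean_nm) ** 2) / (2 * sigma_nm**2))

    lo = quad(g, *bands.low_band)[0]
    hi = quad(g, *bands.high_band)[0]
    return hi / lo


class TestBandIntegrate:
    def test_flat_spectrum_equal_bands(self, bands):
        wl = np.arange(600.0, 701.0, 1.0)
        spec = EmissionSpectrum(wl, np.full(wl.size, 7.0))
        I_low, I_high = band_integrate(spec, bands)
        assert I_low == pytest.approx(20 * 7.0)
        assert I_high == pytest.approx(20 * 7.0)

    def test_gaussian_centered_on_split_is_symmetric(self, bands, gaussian_spectrum):
        spec = gaussian_spectrum(mean_nm=650.0, sigma_nm=10.0, step_nm=0.1)
        I_low, I_high = band_integrate(spec, bands)
        assert I_high == pytest.approx(I_low, rel=1e-9)

    def test_red_shifted_gaussian_matches_quadrature_oracle(
        self, bands, gaussian_spectrum
    ):
        spec = gaussian_spectrum(mean_nm=651.0, sigma_nm=11.1, step_nm=0.1)
        I_low, I_high = band_integrate(spec, bands)
        ratio = band_ratio(I_low, I_high)
        assert ratio == pytest.approx(quad_ratio(651.0, 11.1, bands), rel=1e-4)
        assert ratio == pytest.approx(1.13, abs=0.005)

    def test_grid_not_covering_bands_raises(self, bands):
        wl = np.arange(640.0, 661.0, 1.0)
        spec = EmissionSpectrum(wl, np.ones(wl.size))
        with pytest.raises(BandCoverageError):
            band_integrate(spec, bands)


class TestBandRatio:
    @pytest.mark.parametrize(
        "I_low, I_high, expected", [(10.0, 10.0, 1.0), (4.0, 5.0, 1.25)]
    )
    def test_arithmetic(self, I_low, I_high, expected):
        assert band_ratio(I_low, I_high) == expected

    def test_nonpositive_denominator_raises(self):
        with pytest.raises(DegenerateSignalError):
            band_ratio(0.0, 5.0)

    def test_scale_invariance_under_global_gain(self, bands, gaussian_spectrum):
        # the photobleaching rationale: a ratio cancels overall intensity
        spec = gaussian_spectrum(mean_nm=653.0, step_nm=0.5)
        r1 = band_ratio(*band_integrate(spec, bands))
        r2 = band_ratio(*band_integrate(spec.scaled(0.37), bands))
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestAnalyticGaussianRatio:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(sigma=st.floats(0.5, 40.0))
    def test_peak_on_split_gives_unity(self, sigma):
        assert analytic_gaussian_ratio(650.0, sigma) == pytest.approx(1.0, rel=1e-12)

    def test_matches_quadrature_oracle(self, bands):
        assert analytic_gaussian_ratio(651.0, 11.1, bands) == pytest.approx(
            quad_ratio(651.0, 11.1, bands), rel=1e-9
        )

    @pytest.mark.parametrize("mu", [640.0, 645.0, 650.0, 655.0, 660.0])
    @pytest.mark.parametrize("sigma", [5.0, 11.1, 20.0])
    def test_fine_grid_quadrature_agreement(self, mu, sigma, bands, gaussian_spectrum):
        spec = gaussian_spectrum(mean_nm=mu, sigma_nm=sigma, step_nm=0.01,
                                 lo_nm=560.0, hi_nm=740.0)
        numeric = band_ratio(*band_integrate(spec, bands))
        assert numeric == pytest.approx(
            analytic_gaussian_ratio(mu, sigma, bands), rel=1e-3
        )

    def test_strictly_increasing_in_peak(self):
        r = [analytic_gaussian_ratio(mu, 11.1) for mu in (650.0, 651.0, 652.0)]
        assert r[0] < r[1] < r[2]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        mu=st.floats(640.0, 660.0),
        eps=st.floats(0.01, 1.0),
        sigma=st.floats(5.0, 20.0),
    )
    def test_monotonicity_within_one_sigma(self, mu, eps, sigma):
        lo, hi = 650.0 - sigma, 650.0 - eps
        mu = min(max(mu, lo), hi)  # mu and mu+eps both within [lm-s, lm+s]
        assert analytic_gaussian_ratio(mu + eps, sigma) > analytic_gaussian_ratio(
            mu, sigma
        )

    def test_far_detuned_low_band_raises(self):
        with pytest.raises(DegenerateSignalError):
            analytic_gaussian_ratio(1200.0, 1.0)


class TestPredictRatio:
    def test_empirical_linear_arithmetic(self, linear_model):
        assert predict_ratio(41.0, linear_model) == pytest.approx(1.62)

    def test_shift_model_peak_displacement(self, shift_model):
        assert shift_model.peak_at(37.0) - shift_model.peak_at(27.0) == pytest.approx(
            1.05
        )

    def test_shift_model_at_reference_equals_analytic(self, shift_model):
        assert predict_ratio(27.0, shift_model, sigma_nm=11.1) == pytest.approx(
            analytic_gaussian_ratio(651.0, 11.1)
        )

    def test_exactly_one_parameterization_enforced(self):
        with pytest.raises(ValueError):
            TemperatureResponseModel(
                kind="shift",
                reference_temp_degC=27.0,
                reference_peak_nm=651.0,
                reference_ratio=1.0,
            )


class TestRelativeSensitivity:
    @pytest.mark.parametrize(
        "Q, dQ, expected", [(1.0, 0.062, 0.062), (2.0, 0.062, 0.031), (1.0, 0.0, 0.0)]
    )
    def test_values(self, Q, dQ, expected):
        assert relative_sensitivity(Q, dQ) == pytest.approx(expected)

    def test_nonpositive_Q_raises(self):
        with pytest.raises(ValueError):
            relative_sensitivity(0.0, 0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), Q=st.floats(0.1, 10.0), dQ=st.floats(-1.0, 1.0))
    def test_homogeneous_of_degree_zero(self, c, Q, dQ):
        assert relative_sensitivity(c * Q, c * dQ) == pytest.approx(
            relative_sensitivity(Q, dQ), rel=1e-9
        )

    def test_scan_reports_max_over_range(self, linear_model):
        reports = sensitivity_scan(linear_model, np.arange(30.0, 43.0))
        s_values = [r.S for r in reports]
        assert all(r.S_m == pytest.approx(max(s_values)) for r in reports)
        # linear model: S = slope / Q, largest where the ratio is smallest
        assert np.argmax(s_values) == 0


class TestFitSpectrumGaussian:
    def test_noiseless_recovery_to_machine_precision(self, gaussian_spectrum):
        fit = fit_spectrum_gaussian(gaussian_spectrum(651.0, 11.1, step_nm=2.0))
        assert fit.mean_nm == pytest.approx(651.0, abs=1e-8)
        assert fit.sigma_nm == pytest.approx(11.1, abs=1e-8)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_within_half_nanometre(self, gaussian_spectrum):
        spec = gaussian_spectrum(651.0, 11.1, step_nm=2.0)
        rng = np.random.default_rng(42)
        noisy = EmissionSpectrum(
            spec.wavelengths_nm,
            np.clip(
                spec.intensities * (1 + 0.02 * rng.standard_normal(len(spec))), 0, None
            ),
        )
        fit = fit_spectrum_gaussian(noisy)
        assert fit.mean_nm == pytest.approx(651.0, abs=0.5)

    def test_constant_spectrum_raises(self):
        wl = np.arange(600.0, 700.0, 2.0)
        with pytest.raises(FitError):
            fit_spectrum_gaussian(EmissionSpectrum(wl, np.full(wl.size, 3.0)))

    def test_baseline_term_recovers_offset_gaussian(self, gaussian_spectrum):
        spec = gaussian_spectrum(651.0, 11.1, step_nm=2.0)
        offset = EmissionSpectrum(spec.wavelengths_nm, spec.intensities + 50.0)
        fit = fit_spectrum_gaussian(offset, baseline=True)
        assert fit.mean_nm == pytest.approx(651.0, abs=1e-6)
        assert fit.baseline == pytest.approx(50.0, abs=1e-4)


class TestEmissionSpectrumInvariants:
    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            EmissionSpectrum(np.arange(4.0), np.array([1.0, -1.0, 1.0, 1.0]))

    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError):
            EmissionSpectrum(np.array([1.0, 2.0, 2.0, 3.0]), np.ones(4))

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            EmissionSpectrum(np.arange(3.0), np.ones(3))
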