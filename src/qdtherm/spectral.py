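"""Emission-spectrum model and the band-intensity ratio statistic.

A quantum dot's emission spectrum is well approximated by a Gaussian in
wavelength whose peak red-shifts with temperature.  The thermometric
parameter used throughout this package is the band-intensity ratio

    R = I(650-670 nm) / I(630-650 nm),

i.e. the integrated intensity above a split wavelength ``lambda_m``
divided by the integrated intensity below it.  Because R is a ratio of
two simultaneously acquired intensities, it is invariant to overall
brightness changes (photobleaching, focus drift, excitation power).

Two temperature-response parameterizations are provided:

* ``shift`` — the physical picture: the Gaussian peak moves at a fixed
  rate (default 0.105 nm/degC) and the ratio follows from band
  integration of the shifted Gaussian.
* ``empirical-linear`` — the ratio itself is linear in temperature with
  a measured slope (default 0.062 per degC).

The two are deliberately kept separate: the shift-only model with a
11.1 nm wide spectrum predicts a ratio slope of only ~0.015/degC, well
below the empirically measured 0.062/degC, so the empirical model is
the default for converting ratio changes into temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .errors import BandCoverageError, DegenerateSignalError, FitError

__all__ = [
    "EmissionSpectrum",
    "GaussianSpectrumFit",
    "BandPair",
    "TemperatureResponseModel",
    "SensitivityReport",
    "band_integrate",
    "band_ratio",
    "analytic_gaussian_ratio",
    "predict_ratio",
    "relative_sensitivity",
    "sensitivity_scan",
    "fit_spectrum_gaussian",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum sampled on a wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing sample wavelengths in nanometres.
    intensities
        Non-negative intensities in arbitrary fluorescence units, one
        per wavelength.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 4:
            raise ValueError("a spectrum needs at least 4 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def scaled(self, gain: float) -> "EmissionSpectrum":
        """Return a copy with all intensities multiplied by ``gain`` (> 0)."""
        if gain <= 0:
            raise ValueError("gain must be positive")
        return EmissionSpectrum(self.wavelengths_nm, self.intensities * gain)


@dataclass(frozen=True)
class GaussianSpectrumFit:
    """Least-squares Gaussian fit of an emission spectrum."""

    mean_nm: float
    sigma_nm: float
    amplitude: float
    residual_rms: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("sigma_nm must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def fwhm_nm(self) -> float:
        return _FWHM_PER_SIGMA * self.sigma_nm

    def predict(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        return self.baseline + self.amplitude * np.exp(
            -((wl - self.mean_nm) ** 2) / (2.0 * self.sigma_nm**2)
        )


@dataclass(frozen=True)
class BandPair:
    """Two contiguous, equal-width spectral bands split at ``lambda_m_nm``.

    The low band is the half-open interval [lambda_m - width, lambda_m)
    and the high band is [lambda_m, lambda_m + width), so the shared
    boundary is counted exactly once.  Defaults reproduce the 630-650 /
    650-670 nm bands.
    """

    lambda_m_nm: float = 650.0
    band_width_nm: float = 20.0

    def __post_init__(self) -> None:
        if self.band_width_nm <= 0:
            raise ValueError("band_width_nm must be positive")

    @property
    def low_band(self) -> tuple[float, float]:
        return (self.lambda_m_nm - self.band_width_nm, self.lambda_m_nm)

    @property
    def high_band(self) -> tuple[float, float]:
        return (self.lambda_m_nm, self.lambda_m_nm + self.band_width_nm)


@dataclass(frozen=True)
class TemperatureResponseModel:
    """How the thermometric ratio responds to temperature.

    Exactly one parameterization is active, selected by ``kind``:

    * ``"shift"``: the spectral peak moves linearly with temperature at
      ``shift_rate_nm_per_degC`` away from ``reference_peak_nm``.
    * ``"empirical-linear"``: the ratio itself is linear in temperature
      with slope ``empirical_slope_per_degC`` away from
      ``reference_ratio``.
    """

    kind: str
    reference_temp_degC: float
    shift_rate_nm_per_degC: float | None = None
    reference_peak_nm: float | None = None
    empirical_slope_per_degC: float | None = None
    reference_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "shift":
            if self.reference_peak_nm is None:
                raise ValueError("shift model requires reference_peak_nm")
            if self.empirical_slope_per_degC is not None or self.reference_ratio is not None:
                raise ValueError("shift model must not carry empirical-linear fields")
            if self.shift_rate_nm_per_degC is None:
                object.__setattr__(self, "shift_rate_nm_per_degC", 0.105)
        elif self.kind == "empirical-linear":
            if self.reference_ratio is None:
                raise ValueError("empirical-linear model requires reference_ratio")
            if self.shift_rate_nm_per_degC is not None or self.reference_peak_nm is not None:
                raise ValueError("empirical-linear model must not carry shift fields")
            if self.empirical_slope_per_degC is None:
                object.__setattr__(self, "empirical_slope_per_degC", 0.062)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @classmethod
    def shift(
        cls,
        reference_temp_degC: float,
        reference_peak_nm: float,
        shift_rate_nm_per_degC: float = 0.105,
    ) -> "TemperatureResponseModel":
        return cls(
            kind="shift",
            reference_temp_degC=reference_temp_degC,
            reference_peak_nm=reference_peak_nm,
            shift_rate_nm_per_degC=shift_rate_nm_per_degC,
        )

    @classmethod
    def linear(
        cls,
        reference_temp_degC: float,
        reference_ratio: float,
        slope_per_degC: float = 0.062,
    ) -> "TemperatureResponseModel":
        return cls(
            kind="empirical-linear",
            reference_temp_degC=reference_temp_degC,
            reference_ratio=reference_ratio,
            empirical_slope_per_degC=slope_per_degC,
        )

    def peak_at(self, temperature_degC: float) -> float:
        """Peak wavelength at a temperature (shift kind only)."""
        if self.kind != "shift":
            raise ValueError("peak_at is only defined for the shift model")
        assert self.reference_peak_nm is not None
        assert self.shift_rate_nm_per_degC is not None
        return self.reference_peak_nm + self.shift_rate_nm_per_degC * (
            temperature_degC - self.reference_temp_degC
        )


@dataclass(frozen=True)
class SensitivityReport:
    """Relative temperature sensitivity of a thermometric parameter Q.

    ``S = |dQ/dT| / Q`` (fraction per kelvin); ``S_m`` is the maximum of
    S over the evaluated temperature range.
    """

    temperature_degC: float
    Q: float
    dQ_dT: float
    S: float
    S_m: float


def _integrate_band(
    wl: np.ndarray, it: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral of a sampled spectrum over [lo, hi]."""
    inside = (wl > lo) & (wl < hi)
    xs = [lo, *wl[inside], hi]
    ys = [
        float(np.interp(lo, wl, it)),
        *it[inside],
        float(np.interp(hi, wl, it)),
    ]
    return float(np.trapezoid(ys, xs))


def band_integrate(
    spectrum: EmissionSpectrum, bands: BandPair = BandPair()
) -> tuple[float, float]:
    """Integrate a spectrum over the low and high bands.

    Uses trapezoidal quadrature on the supplied grid, with the band
    edges added by linear interpolation.  Raises
    :class:`BandCoverageError` if the grid does not span both bands.
    """
    wl = spectrum.wavelengths_nm
    lo_lo, lo_hi = bands.low_band
    hi_lo, hi_hi = bands.high_band
    if wl[0] > lo_lo or wl[-1] < hi_hi:
        raise BandCoverageError(
            f"grid [{wl[0]}, {wl[-1]}] nm does not cover bands "
            f"[{lo_lo}, {hi_hi}] nm"
        )
    I_low = _integrate_band(wl, spectrum.intensities, lo_lo, lo_hi)
    I_high = _integrate_band(wl, spectrum.intensities, hi_lo, hi_hi)
    return I_low, I_high


def band_ratio(I_low: float, I_high: float) -> float:
    """The thermometric ratio: high-band over low-band intensity."""
    if I_low <= 0:
        raise DegenerateSignalError(f"low-band intensity must be positive, got {I_low}")
    return I_high / I_low


def analytic_gaussian_ratio(
    mean_nm: float, sigma_nm: float, bands: BandPair = BandPair()
) -> float:
    """Closed-form band ratio of a Gaussian spectrum.

    With Phi the standard normal CDF, lambda_m the split wavelength and
    w the band width::

        R = [Phi((lambda_m + w - mu)/sigma) - Phi((lambda_m - mu)/sigma)]
            / [Phi((lambda_m - mu)/sigma) - Phi((lambda_m - w - mu)/sigma)]

    Exactly 1 when the peak sits on the split wavelength.
    """
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be positive")
    lo_lo, lo_hi = bands.low_band
    hi_lo, hi_hi = bands.high_band
    z = lambda x: (x - mean_nm) / sigma_nm  # noqa: E731
    mass_low = norm.cdf(z(lo_hi)) - norm.cdf(z(lo_lo))
    mass_high = norm.cdf(z(hi_hi)) - norm.cdf(z(hi_lo))
    if mass_low <= 1e-300:
        raise DegenerateSignalError("low band carries essentially zero Gaussian mass")
    return float(mass_high / mass_low)


def predict_ratio(
    temperature_degC: float,
    model: TemperatureResponseModel,
    sigma_nm: float = 11.1,
    bands: BandPair = BandPair(),
) -> float:
    """Predict the band ratio at a temperature under a response model."""
    if model.kind == "shift":
        mu = model.peak_at(temperature_degC)
        return analytic_gaussian_ratio(mu, sigma_nm, bands)
    assert model.reference_ratio is not None
    assert model.empirical_slope_per_degC is not None
    return model.reference_ratio + model.empirical_slope_per_degC * (
        temperature_degC - model.reference_temp_degC
    )


def relative_sensitivity(Q: float, dQ_dT: float) -> float:
    """Relative temperature sensitivity S = |dQ/dT| / Q (per kelvin)."""
    if Q <= 0:
        raise ValueError(f"Q must be positive, got {Q}")
    return abs(dQ_dT) / Q


def sensitivity_scan(
    model: TemperatureResponseModel,
    temperatures_degC: Sequence[float],
    sigma_nm: float = 11.1,
    bands: BandPair = BandPair(),
) -> list[SensitivityReport]:
    """Evaluate S(T) over a temperature range and report S_m = max S.

    dQ/dT is taken analytically for the empirical-linear model and by
    central finite difference (0.01 degC step) for the shift model.
    """
    temps = np.asarray(list(temperatures_degC), dtype=float)
    if temps.size == 0:
        raise ValueError("temperature range is empty")
    Qs = np.array([predict_ratio(t, model, sigma_nm, bands) for t in temps])
    if model.kind == "empirical-linear":
        dQ = np.full_like(Qs, float(model.empirical_slope_per_degC))
    else:
        h = 0.01
        dQ = np.array(
            [
                (
                    predict_ratio(t + h, model, sigma_nm, bands)
                    - predict_ratio(t - h, model, sigma_nm, bands)
                )
                / (2 * h)
                for t in temps
            ]
        )
    S = np.abs(dQ) / Qs
    S_m = float(S.max())
    return [
        SensitivityReport(
            temperature_degC=float(t), Q=float(q), dQ_dT=float(d), S=float(s), S_m=S_m
        )
        for t, q, d, s in zip(temps, Qs, dQ, S)
    ]


def fit_spectrum_gaussian(
    spectrum: EmissionSpectrum, baseline: bool = False
) -> GaussianSpectrumFit:
    """Least-squares Gaussian fit ``A * exp(-(wl - mu)^2 / (2 sigma^2))``.

    Initialization uses the intensity-weighted mean and standard
    deviation of the wavelength grid and the maximum intensity, which is
    robust for unimodal spectra.  An optional constant baseline term can
    be enabled; it is off by default.
    """
    wl = spectrum.wavelengths_nm
    it = spectrum.intensities
    if wl.size < 5:
        raise FitError("need at least 5 samples to fit a Gaussian")
    if np.ptp(it) == 0:
        raise FitError("cannot fit a Gaussian to a constant spectrum")

    w = it - it.min()
    if w.sum() <= 0:
        raise FitError("spectrum carries no weight above its minimum")
    mu0 = float(np.average(wl, weights=w))
    sig0 = float(np.sqrt(np.average((wl - mu0) ** 2, weights=w)))
    sig0 = max(sig0, np.diff(wl).min())
    amp0 = float(it.max())

    if baseline:
        def model(x, a, mu, sig, b):
            return b + a * np.exp(-((x - mu) ** 2) / (2 * sig**2))

        p0 = [amp0, mu0, sig0, float(it.min())]
    else:
        def model(x, a, mu, sig):
            return a * np.exp(-((x - mu) ** 2) / (2 * sig**2))

        p0 = [amp0, mu0, sig0]

    try:
        popt, _ = optimize.curve_fit(model, wl, it, p0=p0, maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Gaussian spectrum fit did not converge: {exc}") from exc

    amp, mu, sig = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    base = float(popt[3]) if baseline else 0.0
    resid = it - model(wl, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if amp <= 0 or sig <= 0:
        raise FitError(
            f"degenerate fit: amplitude={amp:.3g}, sigma={sig:.3g}"
        )
    if not (wl[0] - 2 * sig <= mu <= wl[-1] + 2 * sig):
        raise FitError(f"fitted mean {mu:.1f} nm lies far outside the grid")
    return GaussianSpectrumFit(
        mean_nm=mu, sigma_nm=sig, amplitude=amp, residual_rms=rms, baseline=base
    )


def read_spectrum_csv(path) -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, intensity) CSV."""
    df = pd.read_csv(path)
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy()
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths_nm,
            "intensity": spectrum.intensities,
        }
    ).to_csv(path, index=False, float_format="%.10g")
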