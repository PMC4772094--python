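import numpy as np
import pytest

from qdtherm.spectral import BandPair, EmissionSpectrum, TemperatureResponseModel


@pytest.fixture
def bands() -> BandPair:
    return BandPair()  # 630-650 / 650-670 nm


@pytest.fixture
def gaussian_spectrum():
    """Factory for noiseless Gaussian spectra on a configurable grid."""

    def make(
        mean_nm: float = 651.0,
        sigma_nm: float = 11.1,
        step_nm: float = 2.0,
        lo_nm: float = 600.0,
        hi_nm: float = 700.0,
        amplitude: float = 1000.0,
    ) -> EmissionSpectrum:
        wl = np.arange(lo_nm, hi_nm + 0.5 * step_nm, step_nm)
        inten = amplitude * np.exp(-((wl - mean_nm) ** 2) / (2 * sigma_nm**2))
        return EmissionSpectrum(wl, inten)

    return make


@pytest.fixture
def shift_model() -> TemperatureResponseModel:
    return TemperatureResponseModel.shift(
        reference_temp_degC=27.0, reference_peak_nm=651.0
    )


@pytest.fixture
def linear_model() -> TemperatureResponseModel:
    return TemperatureResponseModel.linear(
        reference_temp_degC=31.0, reference_ratio=1.0, slope_per_degC=0.062
    )
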