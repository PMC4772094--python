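"""Spot detection, Gaussian fitting, photometry and QC gates."""

import numpy as np
import pandas as pd
import pytest

from qdtherm.errors import DegenerateSignalError, FitError, GatingError
from qdtherm.photometry import (
    DiameterFilter,
    SpotRecord,
    detect_spots,
    diameter_filter,
    estimate_diameter,
    extract_ratio,
    fit_spot,
    measure_spots,
    z_gate,
)
from qdtherm.synthetic import SimulationConfig, SpotSpec, gen_two_channel_stack, gen_z_profile

PIX = 0.05  # um / pixel

FIVE_SPOTS = [
    SpotSpec(1.2, 1.3, 0.36, 1.74, 2e5),
    SpotSpec(3.1, 1.1, 0.36, 1.64, 2e5),
    SpotSpec(5.0, 3.3, 0.36, 1.20, 2e5),
    SpotSpec(1.4, 4.8, 0.36, 1.00, 2e5),
    SpotSpec(4.2, 5.5, 0.36, 2.00, 2e5),
]


def noiseless_stack(spots=FIVE_SPOTS, background=5.0):
    cfg = SimulationConfig(noise_model="none", background_level=background,
                           pixel_size_um=PIX)
    return gen_two_channel_stack(spots, cfg)


class TestDetectSpots:
    def test_five_well_separated_spots_found_at_true_positions(self):
        low, high, truth = noiseless_stack()
        cands = detect_spots(low, high, PIX, min_separation_um=0.5)
        assert len(cands) == 5
        found = sorted((c.x_um, c.y_um) for c in cands)
        expected = sorted((t.x_um, t.y_um) for t in truth.spots)
        for (fx, fy), (tx, ty) in zip(found, expected):
            assert abs(fx - tx) <= PIX and abs(fy - ty) <= PIX

    def test_blank_image_with_background_noise_yields_nothing(self):
        cfg = SimulationConfig(seed=1, pixel_size_um=PIX)  # poisson+gaussian noise
        low, high, _ = gen_two_channel_stack([], cfg, shape_px=(64, 64))
        assert detect_spots(low, high, PIX) == []

    def test_close_pair_collapses_to_one_flagged_detection(self):
        # resolvable as two maxima, but closer than the single-dot gate
        spots = [SpotSpec(2.0, 2.0, 0.36, 1.5, 2e5), SpotSpec(2.5, 2.0, 0.36, 1.5, 1e5)]
        low, high, _ = noiseless_stack(spots)
        cands = detect_spots(low, high, PIX, min_separation_um=0.7)
        assert len(cands) == 1
        assert cands[0].overlapping

    def test_deterministic_row_major_ordering(self):
        low, high, _ = noiseless_stack()
        c1 = detect_spots(low, high, PIX)
        c2 = detect_spots(low, high, PIX)
        assert c1 == c2
        ys = [c.y_um for c in c1]
        assert ys == sorted(ys)


class TestFitSpot:
    def test_noiseless_centroid_within_a_tenth_of_a_pixel(self):
        low, high, truth = noiseless_stack([SpotSpec(2.02, 2.51, 0.36, 1.5, 2e5)])
        fit = fit_spot(low + high, (2.0, 2.5), PIX)
        assert fit.x_um == pytest.approx(2.02, abs=0.1 * PIX)
        assert fit.y_um == pytest.approx(2.51, abs=0.1 * PIX)
        assert fit.fit_rms == pytest.approx(0.0, abs=1e-6)

    def test_flat_window_raises(self):
        img = np.full((64, 64), 5.0)
        with pytest.raises(FitError):
            fit_spot(img, (1.6, 1.6), PIX)

    def test_recovers_combined_psf_and_size_width(self):
        cfg = SimulationConfig(noise_model="none", background_level=0.0,
                               pixel_size_um=PIX, psf_sigma_um=0.1)
        low, high, _ = gen_two_channel_stack([SpotSpec(2.0, 2.0, 0.36, 1.5, 2e5)], cfg)
        fit = fit_spot(low + high, (2.0, 2.0), PIX)
        expected = np.sqrt(0.1**2 + (0.36 / 2.3548) ** 2)
        assert fit.sigma_um == pytest.approx(expected, rel=0.01)


class TestEstimateDiameter:
    def test_fwhm_arithmetic(self):
        assert estimate_diameter(0.15) == pytest.approx(0.3532, abs=2e-4)

    def test_degenerate_sigma_raises(self):
        with pytest.raises(ValueError):
            estimate_diameter(0.0)

    def test_cohort_mean_fwhm_lands_between_printed_thresholds(self):
        # sigma chosen so the mean FWHM is (0.314 + 0.413) / 2
        sigma = 0.3635 / 2.3548
        assert 0.314 < estimate_diameter(sigma) < 0.413


class TestExtractRatio:
    def test_unity_ratio_round_trip_noise_free(self):
        low, high, _ = noiseless_stack([SpotSpec(2.0, 2.0, 0.36, 1.0, 2e5)])
        _, _, ratio = extract_ratio(low, high, 2.0, 2.0, 0.4, PIX)
        assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_high_count_ratio_within_one_percent(self):
        cfg = SimulationConfig(seed=2, pixel_size_um=PIX)
        low, high, _ = gen_two_channel_stack([SpotSpec(2.0, 2.0, 0.36, 1.64, 5e5)], cfg)
        _, _, ratio = extract_ratio(low, high, 2.0, 2.0, 0.4, PIX)
        assert ratio == pytest.approx(1.64, rel=0.01)

    def test_aperture_missing_the_spot_raises(self):
        low, high, _ = noiseless_stack([SpotSpec(2.0, 2.0, 0.36, 1.5, 2e5)])
        with pytest.raises(DegenerateSignalError):
            extract_ratio(low, high, 5.5, 5.5, 0.3, PIX)

    def test_invariant_to_global_gain_on_both_channels(self):
        low, high, _ = noiseless_stack([SpotSpec(2.0, 2.0, 0.36, 1.74, 2e5)])
        _, _, r1 = extract_ratio(low, high, 2.0, 2.0, 0.4, PIX)
        _, _, r2 = extract_ratio(3.7 * low, 3.7 * high, 2.0, 2.0, 0.4, PIX)
        assert r2 == pytest.approx(r1, rel=1e-12)


def _records(diams):
    return [
        SpotRecord(
            x_um=float(i), y_um=0.0, diameter_um=d, I_low=1.0, I_high=1.5,
            ratio=1.5, gaussian_fit_rms=0.0,
        )
        for i, d in enumerate(diams)
    ]


class TestDiameterFilter:
    def test_mean_pm_sd_thresholds_and_retention(self):
        # hand oracle: mean 0.3825, sample s.d. (n-1) 0.08421
        # -> gate (0.29829, 0.46671), strict: keeps 0.30, 0.36, 0.37
        retained, report = diameter_filter(_records([0.30, 0.36, 0.37, 0.50]))
        assert report.lower_um == pytest.approx(0.29829, abs=1e-5)
        assert report.upper_um == pytest.approx(0.46671, abs=1e-5)
        assert sorted(r.diameter_um for r in retained) == [0.30, 0.36, 0.37]
        assert {r.diameter_um for r in report.excluded} == {0.50}
        assert "diameter_out_of_range" in next(iter(report.excluded)).qc_flags

    def test_explicit_printed_thresholds(self):
        policy = DiameterFilter(derivation="explicit", lower_um=0.314, upper_um=0.413)
        retained, report = diameter_filter(_records([0.30, 0.36, 0.37, 0.50]), policy)
        assert sorted(r.diameter_um for r in retained) == [0.36, 0.37]
        assert (report.lower_um, report.upper_um) == (0.314, 0.413)

    def test_all_equal_diameters_degenerate_band_retains_all(self):
        retained, report = diameter_filter(_records([0.36] * 4))
        assert len(retained) == 4
        assert report.degenerate

    def test_retention_is_order_invariant_and_non_mutating(self):
        recs = _records([0.30, 0.36, 0.37, 0.50])
        r1, _ = diameter_filter(recs)
        r2, _ = diameter_filter(list(reversed(recs)))
        assert {r.diameter_um for r in r1} == {r.diameter_um for r in r2}
        assert all(r.qc_flags == frozenset() for r in recs)


class TestZGate:
    def test_quarter_micron_gate_retains_eleven_planes(self):
        prof = gen_z_profile(peak_z_um=0.0)
        result = z_gate(prof, tolerance_um=0.25)
        assert result.peak_z_um == pytest.approx(0.0)
        assert int(result.accepted.sum()) == 11
        accepted_z = prof["z_um"].to_numpy()[result.accepted]
        assert np.all(np.abs(accepted_z) <= 0.25 + 1e-9)

    def test_monotone_profile_raises(self):
        prof = pd.DataFrame(
            {"z_um": np.arange(0, 1.0, 0.05), "intensity": np.arange(20.0)}
        )
        with pytest.raises(GatingError):
            z_gate(prof)


class TestMeasureSpots:
    def test_noise_free_pipeline_recovers_every_true_ratio(self):
        low, high, truth = noiseless_stack()
        records = measure_spots(low, high, PIX)
        assert len(records) == 5
        truth_by_pos = {(t.x_um, t.y_um): t.ratio for t in truth.spots}
        for rec in records:
            key = min(
                truth_by_pos,
                key=lambda p: (p[0] - rec.x_um) ** 2 + (p[1] - rec.y_um) ** 2,
            )
            assert rec.ratio == pytest.approx(truth_by_pos[key], rel=1e-6)
            assert rec.qc_flags == frozenset()

    def test_diameters_recovered_after_psf_deconvolution_are_plausible(self):
        low, high, _ = noiseless_stack()
        records = measure_spots(low, high, PIX)
        # measured FWHM reflects psf (0.1 um) + emitter size in quadrature
        expected = 2.3548 * np.sqrt(0.1**2 + (0.36 / 2.3548) ** 2)
        for rec in records:
            assert rec.diameter_um == pytest.approx(expected, rel=0.02)
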