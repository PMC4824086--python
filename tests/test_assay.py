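"""Assay pipeline: peak readout, quench ratios, SV fits, LOD, specificity."""

import numpy as np
import pytest

from foldlock import (
    AssayError,
    EmissionSpectrum,
    TitrationSeries,
    amount_moles,
    lod_estimate,
    peak_intensity,
    quench_ratio,
    read_spectrum_csv,
    specificity_matrix,
    stern_volmer_fit,
    write_spectrum_csv,
)


def gaussian_spectrum(amplitude=1000.0, center=580.0, sigma=25.0, baseline=0.0):
    w = np.arange(450.0, 751.0, 2.0)
    y = baseline + amplitude * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    return EmissionSpectrum(w, y, excitation_nm=480.0, label="test")


def sv_series(ksv_per_m, concs_m, i0=1000.0):
    intensities = [i0 / (1.0 + ksv_per_m * c) for c in concs_m]
    return TitrationSeries(
        probe="p", concentrations_m=np.array(concs_m),
        intensities=np.array(intensities),
    )


class TestPeakIntensity:
    def test_window_max_hits_peak(self):
        s = gaussian_spectrum(amplitude=1234.0)
        assert peak_intensity(s, (560.0, 600.0)) == pytest.approx(1234.0)

    def test_window_outside_range_rejected(self):
        with pytest.raises(AssayError, match="does not overlap"):
            peak_intensity(gaussian_spectrum(), (900.0, 950.0))

    def test_flat_spectrum_constant(self):
        w = np.arange(500.0, 600.0, 5.0)
        s = EmissionSpectrum(w, np.full(w.size, 7.0))
        assert peak_intensity(s, (520.0, 580.0)) == 7.0

    def test_readout_at_wavelength(self):
        s = gaussian_spectrum()
        assert peak_intensity(s, at_nm=579.9) == s.intensities[
            np.argmin(np.abs(s.wavelengths_nm - 580.0))
        ]

    @pytest.mark.parametrize(
        "w, y, fragment",
        [
            (np.arange(8.0), -np.ones(8), "negative"),
            (np.array([1.0, 2, 3, 4, 5, 6, 7, 7]), np.ones(8), "increasing"),
            (np.arange(5.0), np.ones(5), "points"),
        ],
    )
    def test_invalid_spectra_rejected(self, w, y, fragment):
        with pytest.raises(AssayError, match=fragment):
            EmissionSpectrum(w, y)


class TestQuenchRatio:
    def test_simple_ratio_and_zero_definition(self):
        series = TitrationSeries(
            probe="p", concentrations_m=np.array([0.0, 1e-6]),
            intensities=np.array([100.0, 50.0]),
        )
        assert quench_ratio(series) == [(0.0, 1.0), (1e-6, 2.0)]

    def test_zero_intensity_guarded(self):
        series = TitrationSeries(
            probe="p", concentrations_m=np.array([0.0, 1e-6]),
            intensities=np.array([100.0, 0.0]),
        )
        with pytest.raises(AssayError, match="non-positive intensity"):
            quench_ratio(series)

    def test_series_requires_single_zero(self):
        with pytest.raises(AssayError, match="exactly once"):
            TitrationSeries(probe="p", concentrations_m=np.array([1e-6, 2e-6]),
                            intensities=np.array([1.0, 2.0]))
        with pytest.raises(AssayError, match="exactly once"):
            TitrationSeries(probe="p", concentrations_m=np.array([0.0, 0.0]),
                            intensities=np.array([1.0, 1.0]))


class TestSternVolmer:
    def test_exact_recovery_noise_free(self):
        ksv = 2.0e6  # 2.0 per uM
        series = sv_series(ksv, [0.0, 0.25e-6, 0.5e-6, 1.0e-6])
        fit = stern_volmer_fit(series)
        assert fit.ksv_per_m == pytest.approx(ksv, rel=1e-12)
        assert fit.intercept == 1.0
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_no_quenching_gives_zero_slope(self):
        series = sv_series(0.0, [0.0, 0.25e-6, 0.5e-6, 1.0e-6])
        assert stern_volmer_fit(series).ksv_per_m == pytest.approx(0.0, abs=1e-15)

    def test_free_intercept_recovers_both_parameters(self):
        pairs = [(c, 1.3 + 4.0e6 * c) for c in (0.0, 0.2e-6, 0.5e-6, 1.0e-6)]
        fit = stern_volmer_fit(pairs, fix_intercept=False)
        assert fit.ksv_per_m == pytest.approx(4.0e6, rel=1e-9)
        assert fit.intercept == pytest.approx(1.3, rel=1e-9)

    def test_needs_three_nonzero_points(self):
        with pytest.raises(AssayError, match=">= 3"):
            stern_volmer_fit(sv_series(1e6, [0.0, 0.5e-6, 1.0e-6]))
        with pytest.raises(AssayError, match="degenerate"):
            stern_volmer_fit([(1e-6, 2.0)] * 4)

    def test_unit_invariance(self):
        """Scaling all intensities leaves I0/I and Ksv unchanged."""
        concs = [0.0, 0.2e-6, 0.5e-6, 1.0e-6]
        a = sv_series(3e6, concs, i0=1.0)
        b = sv_series(3e6, concs, i0=8.5e6)
        assert quench_ratio(a) == pytest.approx(quench_ratio(b))
        assert stern_volmer_fit(a).ksv_per_m == pytest.approx(
            stern_volmer_fit(b).ksv_per_m
        )

    def test_median_recovery_under_multiplicative_noise(self):
        """5% CV noise, n=8, 200 replicates: median Ksv within 10%."""
        rng = np.random.default_rng(7_031_502)
        ksv = 5e6
        concs = np.array([0.0, 0.05e-6, 0.1e-6, 0.2e-6, 0.4e-6, 0.6e-6,
                          0.8e-6, 1.0e-6])
        clean = 1000.0 / (1.0 + ksv * concs)
        fitted = []
        for _ in range(200):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(concs.size))
            series = TitrationSeries(probe="p", concentrations_m=concs,
                                     intensities=noisy)
            fitted.append(stern_volmer_fit(series).ksv_per_m)
        assert np.median(fitted) == pytest.approx(ksv, rel=0.10)


class TestLOD:
    def test_amount_arithmetic(self):
        assert amount_moles(20e-9, 500e-6) == pytest.approx(10e-12, rel=1e-12)

    def test_lod_scales_with_blank_cv(self):
        fit = stern_volmer_fit(sv_series(5e6, [0.0, 0.2e-6, 0.5e-6, 1.0e-6]))
        tight = lod_estimate(fit, [1000.0, 1010.0, 990.0])
        loose_blanks = [1000.0 + 2 * (b - 1000.0) for b in (1000.0, 1010.0, 990.0)]
        loose = lod_estimate(fit, loose_blanks)
        assert loose.lod_m == pytest.approx(2 * tight.lod_m, rel=1e-9)
        assert tight.lod_m == pytest.approx(3 * tight.cv_blank / 5e6, rel=1e-12)

    def test_reports_absolute_amount(self):
        fit = stern_volmer_fit(sv_series(5e6, [0.0, 0.2e-6, 0.5e-6, 1.0e-6]))
        res = lod_estimate(fit, [100.0, 101.0, 99.0], volume_l=500e-6)
        assert res.amount_mol == pytest.approx(res.lod_m * 500e-6)

    def test_undefined_without_quenching(self):
        flat = stern_volmer_fit(sv_series(0.0, [0.0, 0.2e-6, 0.5e-6, 1.0e-6]))
        with pytest.raises(AssayError, match="LOD undefined"):
            lod_estimate(flat, [100.0, 101.0, 99.0])
        good = stern_volmer_fit(sv_series(5e6, [0.0, 0.2e-6, 0.5e-6, 1.0e-6]))
        with pytest.raises(AssayError, match="blank replicates"):
            lod_estimate(good, [100.0, 101.0])


class TestSpecificity:
    def test_detection_calls_and_log2(self):
        result = specificity_matrix(
            "6C-miR-18a-11bp",
            {
                "miR-18a": (1400.0, 100.0),   # I0/I = 14
                "miR-21": (1400.0, 1400.0),   # I0/I = 1
                "miR-451": (1400.0, 2800.0),  # I0/I = 0.5: intensity increase
            },
            threshold=2.0,
            cognate="miR-18a",
        )
        t = result.table.set_index("miRNA")
        assert t.loc["miR-18a", "detected"]
        assert not t.loc["miR-21", "detected"]
        assert t.loc["miR-451", "log2_ratio"] == pytest.approx(-1.0)
        assert not t.loc["miR-451", "detected"]
        assert result.detected() == ["miR-18a"]
        # log2 column is exactly log2 of the ratio column
        assert np.array_equal(
            t["log2_ratio"].to_numpy(), np.log2(t["ratio"].to_numpy())
        )

    def test_missing_reference_rejected(self):
        with pytest.raises(AssayError, match="I0"):
            specificity_matrix("p", {"miR-21": (0.0, 10.0)})
        with pytest.raises(AssayError, match="empty"):
            specificity_matrix("p", {})


class TestSpectrumIO:
    def test_roundtrip(self, tmp_path):
        s = gaussian_spectrum(amplitude=321.5)
        path = tmp_path / "spec.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path)
        assert np.allclose(back.wavelengths_nm, s.wavelengths_nm)
        assert np.allclose(back.intensities, s.intensities)

    def test_malformed_csv_diagnostics(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("wl,counts\n500,1\n")
        with pytest.raises(AssayError, match="expected columns"):
            read_spectrum_csv(bad)
        holes = tmp_path / "holes.csv"
        holes.write_text("wavelength_nm,intensity\n" +
                         "\n".join(f"{500+i}," for i in range(10)))
        with pytest.raises(AssayError, match="rows"):
            read_spectrum_csv(holes)
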