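"""Spectrum domain types, tabular IO round-trips, and grid utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluorbind import (
    AbsorptionSpectrum,
    DegenerateSpectrumWarning,
    EmissionSpectrum,
    ExtrapolationError,
    TitrationSeries,
    ValidationError,
    interpolate_to_grid,
    peak_position,
    read_spectrum_table,
    read_titration_table,
    write_spectrum_table,
    write_titration_table,
)
from conftest import gaussian_emission


class TestValidation:
    def test_non_monotone_wavelengths_rejected(self):
        with pytest.raises(ValidationError):
            EmissionSpectrum(wavelength=[300, 300, 310], intensity=[1, 2, 3])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            EmissionSpectrum(wavelength=[300, 310], intensity=[1, -2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            AbsorptionSpectrum(wavelength=[300, 310, 320], absorbance=[0.1, 0.2])

    def test_titration_must_start_at_zero_quencher(self):
        spectra = [
            gaussian_emission(quencher_concentration=c) for c in (4e-6, 8e-6)
        ]
        with pytest.raises(ValidationError):
            TitrationSeries("HSA", 1e-5, 298.0, spectra)

    def test_titration_concentrations_strictly_increase(self):
        spectra = [
            gaussian_emission(quencher_concentration=c) for c in (0.0, 8e-6, 8e-6)
        ]
        with pytest.raises(ValidationError):
            TitrationSeries("HSA", 1e-5, 298.0, spectra)


class TestIO:
    def test_long_format_round_trip(self, tmp_path):
        spec = EmissionSpectrum(
            wavelength=[300.0, 310.5, 320.0, 331.25, 340.0],
            intensity=[1.0, 5.5, 9.25, 4.0, 0.5],
            temperature=310.0,
            quencher_concentration=4e-6,
        )
        path = tmp_path / "spec.csv"
        write_spectrum_table(spec, path)
        back = read_spectrum_table(
            path, kind="emission",
            metadata={"temperature": 310.0, "quencher_concentration": 4e-6},
        )
        np.testing.assert_array_equal(back.wavelength, spec.wavelength)
        np.testing.assert_array_equal(back.intensity, spec.intensity)
        assert back.temperature == 310.0
        assert back.quencher_concentration == 4e-6

    @pytest.mark.parametrize("sep", [",", "\t", ";"])
    def test_delimiter_autodetect(self, tmp_path, sep):
        path = tmp_path / "spec.txt"
        path.write_text(
            "wavelength" + sep + "intensity\n300" + sep + "1.5\n310" + sep + "2.5\n"
        )
        spec = read_spectrum_table(path, kind="emission")
        np.testing.assert_array_equal(spec.intensity, [1.5, 2.5])

    def test_duplicate_wavelength_row_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("wavelength,intensity\n300,1\n300,2\n310,3\n")
        with pytest.raises(ValidationError):
            read_spectrum_table(path, kind="emission")

    def test_wide_titration_round_trip(self, tmp_path):
        spectra = [
            gaussian_emission(peak=1000.0 / (1 + i), quencher_concentration=c)
            for i, c in enumerate([0, 4e-6, 8e-6, 1e-5, 1.6e-5, 2.4e-5, 3.2e-5, 4e-5])
        ]
        series = TitrationSeries("HSA", 1e-5, 298.0, spectra)
        path = tmp_path / "titration.csv"
        write_titration_table(series, path)
        back = read_titration_table(path, protein_id="HSA")
        assert len(back.spectra) == 8
        np.testing.assert_array_equal(back.concentrations, series.concentrations)
        for a, b in zip(back.spectra, series.spectra):
            np.testing.assert_array_equal(a.intensity, b.intensity)


class TestInterpolation:
    def test_identity_on_own_grid(self, emission_band):
        out = interpolate_to_grid(emission_band, emission_band.wavelength)
        np.testing.assert_array_equal(out.intensity, emission_band.intensity)

    def test_linear_midpoint(self):
        spec = EmissionSpectrum(wavelength=[300.0, 310.0], intensity=[600.0, 620.0])
        out = interpolate_to_grid(spec, [305.0])
        assert out.intensity[0] == pytest.approx(610.0)

    def test_extrapolation_rejected(self, emission_band):
        with pytest.raises(ExtrapolationError):
            interpolate_to_grid(emission_band, [200.0, 300.0])

    def test_gaussian_resampling_accuracy(self):
        # 1 nm -> 0.25 nm against the analytic band: < 0.1% of peak
        spec = gaussian_emission(center=335.0, sigma=15.0, peak=1.0)
        fine = np.arange(260.0, 490.0, 0.25)
        out = interpolate_to_grid(spec, fine)
        analytic = np.exp(-0.5 * ((fine - 335.0) / 15.0) ** 2)
        assert np.max(np.abs(out.intensity - analytic)) < 1e-3

    def test_exact_on_piecewise_linear(self):
        wl = np.array([300.0, 310.0, 330.0, 360.0])
        spec = EmissionSpectrum(wavelength=wl, intensity=3 * wl + 7)
        grid = np.linspace(300, 360, 41)
        out = interpolate_to_grid(spec, grid)
        np.testing.assert_allclose(out.intensity, 3 * grid + 7, rtol=1e-14)


class TestPeakPosition:
    def test_symmetric_gaussian_peak(self):
        wl, inten = peak_position(gaussian_emission(center=335.0))
        assert wl == 335.0
        assert inten == pytest.approx(1000.0)

    def test_tie_breaks_to_smaller_wavelength(self):
        spec = EmissionSpectrum(
            wavelength=[320.0, 330.0, 340.0, 350.0], intensity=[1.0, 5.0, 5.0, 1.0]
        )
        assert peak_position(spec)[0] == 330.0

    def test_all_zero_spectrum_warns(self):
        spec = EmissionSpectrum(wavelength=[300.0, 310.0], intensity=[0.0, 0.0])
        with pytest.warns(DegenerateSpectrumWarning):
            wl, inten = peak_position(spec)
        assert wl == 300.0 and inten == 0.0

    def test_noisy_peak_recovered_with_smoothing(self):
        rng = np.random.default_rng(42)
        spec = gaussian_emission(center=335.0, sigma=15.0, peak=1000.0)
        noisy = spec.with_intensity(
            np.clip(spec.intensity + rng.normal(0, 5.0, spec.intensity.size), 0, None)
        )
        wl, _ = peak_position(noisy, smooth_window=5)
        assert abs(wl - 335.0) <= 1.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_positive_scaling(self, scale):
        spec = gaussian_emission(center=340.0, sigma=12.0, peak=1.0)
        scaled = spec.with_intensity(spec.intensity * scale)
        assert peak_position(scaled)[0] == peak_position(spec)[0]
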