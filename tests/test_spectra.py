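"""Spectrum container, grids, resampling, smoothing and file I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aphidvision as av
from aphidvision.errors import ComputationError, RangeError, SpectrumFormatError
from aphidvision.spectra import (Spectrum, make_grid, read_two_column,
                                 shared_grid, write_two_column,
                                 write_spectra_table)


def _ramp(start=400.0, stop=700.0, step=5.0):
    wl = make_grid(start, stop, step)
    return Spectrum(wl, np.linspace(0.1, 0.9, wl.size))


class TestSpectrumValidation:
    def test_rejects_descending_wavelengths(self):
        with pytest.raises(SpectrumFormatError):
            Spectrum(np.array([500.0, 400.0]), np.array([0.1, 0.2]))

    def test_rejects_negative_values(self):
        with pytest.raises(SpectrumFormatError):
            Spectrum(np.array([400.0, 500.0]), np.array([0.1, -0.2]))

    def test_rejects_non_finite(self):
        with pytest.raises(SpectrumFormatError):
            Spectrum(np.array([400.0, 500.0]), np.array([0.1, np.nan]))

    def test_reflectance_above_cap_is_rejected_not_clipped(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.1, 1.6]))
        with pytest.raises(SpectrumFormatError, match="cap"):
            s.validate_reflectance()

    def test_reflectance_slightly_above_one_is_accepted(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.1, 1.1]))
        s.validate_reflectance()


class TestGridsAndResampling:
    def test_interp_is_exact_at_original_nodes(self):
        s = _ramp()
        fine = av.resample(s, 400.0, 700.0, step=1.0)
        on_nodes = fine.interp(s.wavelength_nm)
        assert np.allclose(on_nodes, s.value, atol=1e-12)

    def test_interp_outside_support_raises(self):
        s = _ramp()
        with pytest.raises(RangeError):
            s.interp(np.array([300.0, 500.0]))

    def test_shared_grid_is_step_aligned_overlap(self):
        a = _ramp(402.0, 698.0, 2.0)
        b = _ramp(450.0, 800.0, 5.0)
        grid = shared_grid([a, b])
        assert grid[0] == 450.0 and grid[-1] == 695.0
        assert np.allclose(np.diff(grid), 5.0)

    def test_disjoint_supports_raise(self):
        a = _ramp(400.0, 500.0)
        b = _ramp(600.0, 700.0)
        with pytest.raises(ComputationError):
            shared_grid([a, b])

    @given(st.floats(min_value=0.05, max_value=10.0))
    def test_resampling_commutes_with_scaling(self, k):
        s = _ramp()
        scaled = Spectrum(s.wavelength_nm, k * s.value)
        r1 = av.resample(scaled, 420.0, 680.0, step=2.5)
        r2 = av.resample(s, 420.0, 680.0, step=2.5)
        assert np.allclose(r1.value, k * r2.value, rtol=1e-12)


class TestSmoothing:
    def test_constant_spectrum_unchanged(self):
        wl = make_grid(400.0, 700.0, 1.0)
        s = Spectrum(wl, np.full(wl.size, 0.4))
        out = av.smooth_moving_average(s, window_nm=10.0)
        assert np.allclose(out.value, 0.4)

    def test_window_below_grid_step_is_identity(self):
        s = _ramp(step=5.0)
        out = av.smooth_moving_average(s, window_nm=2.4)
        assert np.allclose(out.value, s.value)

    def test_smoothing_reduces_noise_variance(self):
        wl = make_grid(400.0, 700.0, 1.0)
        rng = np.random.default_rng(0)
        noisy = np.clip(0.5 + 0.05 * rng.standard_normal(wl.size), 0, 1)
        out = av.smooth_moving_average(Spectrum(wl, noisy), window_nm=9.0)
        assert np.var(out.value) < np.var(noisy)


class TestFileIO:
    def test_two_column_round_trip(self, tmp_path):
        s = _ramp()
        path = tmp_path / "one.csv"
        write_two_column(path, s)
        back = read_two_column(path)
        assert np.allclose(back.wavelength_nm, s.wavelength_nm)
        assert np.allclose(back.value, s.value)

    def test_spectra_table_round_trip(self, tmp_path):
        spectra = {"t1": _ramp(), "t2": Spectrum(_ramp().wavelength_nm,
                                                 _ramp().value ** 2)}
        path = tmp_path / "table.csv"
        write_spectra_table(path, spectra)
        back = av.read_spectra_table(path)
        assert set(back) == {"t1", "t2"}
        assert np.allclose(back["t2"].value, spectra["t2"].value)

    def test_bad_cell_is_reported_with_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,t1\n400,0.5\n405,oops\n")
        with pytest.raises(SpectrumFormatError, match="t1"):
            av.read_spectra_table(path)


class TestD65:
    def test_normalized_to_one_at_560(self, d65):
        assert d65.interp(np.array([560.0]))[0] == pytest.approx(1.0)

    def test_photon_over_energy_units_scale_with_wavelength(self):
        ph = av.load_d65(units="photon")
        en = av.load_d65(units="energy")
        ratio = (ph.value / en.value) / ph.wavelength_nm
        assert np.allclose(ratio, ratio[0], rtol=1e-9)
        # photon units weight red wavelengths up relative to blue
        assert (ph.value / en.value)[-1] > (ph.value / en.value)[0]

    def test_support_covers_uv_to_near_ir(self, d65):
        lo, hi = d65.support
        assert lo <= 320.0 and hi >= 700.0
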