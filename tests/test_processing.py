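import numpy as np
import pytest
from hypothesis import given, strategies as st

from thzcornea import (
    SlopeBand,
    Spectrum,
    THzTrace,
    compute_spectrum,
    deconvolve,
    highpass_filter,
    spectral_slope,
)
from thzcornea.processing import highpass_gain, process_archive

from oracles import ols_slope_intercept

N = 512
DT = 0.0333
T = np.arange(N) * DT
FREQS = np.fft.rfftfreq(N, DT)


def trace(amplitude):
    return THzTrace(T, amplitude)


class TestHighpass:
    def test_dc_trace_is_rejected_entirely(self):
        out = highpass_filter(trace(np.full(N, 3.7)))
        assert np.max(np.abs(out.amplitude)) <= 1e-10 * 3.7

    def test_gain_is_half_at_cutoff(self):
        assert highpass_gain(0.1, 0.1) == pytest.approx(0.5, abs=1e-12)
        assert highpass_gain(0.25, 0.25) == pytest.approx(0.5, abs=1e-12)

    def test_bin_sinusoid_scaled_by_closed_form_gain(self):
        m = 17  # an exact DFT bin
        f0 = m / (N * DT)
        x = np.sin(2 * np.pi * f0 * T)
        out = highpass_filter(trace(x), cutoff_thz=0.1)
        assert np.allclose(out.amplitude, highpass_gain(f0, 0.1) * x, atol=1e-10)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_filter(trace(np.zeros(N)), cutoff_thz=0.5 / DT)


class TestSpectrum:
    def test_unit_impulse_has_flat_unit_magnitude(self):
        x = np.zeros(N)
        x[0] = 1.0
        spec = compute_spectrum(trace(x))
        assert np.allclose(np.abs(spec.values), 1.0, atol=1e-12)
        assert spec.freq_thz[1] == pytest.approx(1.0 / (N * DT))

    def test_bin_sinusoid_peaks_in_single_bin(self):
        m = 23
        x = np.cos(2 * np.pi * (m / (N * DT)) * T)
        mag = np.abs(compute_spectrum(trace(x)).values)
        others = np.delete(mag, m)
        assert mag[m] > 1e6 * np.max(others + 1e-300)

    def test_parseval_energy_conserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=N)
        spec = compute_spectrum(trace(x)).values
        e_freq = (np.abs(spec[0]) ** 2 + 2 * np.sum(np.abs(spec[1:-1]) ** 2) + np.abs(spec[-1]) ** 2) / N
        e_time = np.sum(x**2)
        assert abs(e_freq - e_time) <= 1e-10 * e_time

    def test_nonuniform_axis_rejected(self):
        t_bad = T.copy()
        t_bad[10] += 0.01
        with pytest.raises(ValueError, match="uniform"):
            THzTrace(t_bad, np.zeros(N))


class TestDeconvolve:
    def _pulse_spec(self):
        u = (T - 8.0) / 0.5
        return compute_spectrum(trace((1 - u * u) * np.exp(-u * u / 2)))

    def test_self_deconvolution_is_unity(self):
        ref = self._pulse_spec()
        h = deconvolve(ref, ref, regularization=0.0)
        strong = np.abs(ref.values) > 1e-9 * np.max(np.abs(ref.values))
        assert np.allclose(np.abs(h.values[strong]), 1.0, atol=1e-8)

    def test_zero_sample_gives_zero_response(self):
        ref = self._pulse_spec()
        zero = Spectrum(ref.freq_thz, np.zeros_like(ref.values))
        assert np.all(deconvolve(zero, ref).values == 0.0)

    def test_pure_delay_recovered_in_magnitude_and_phase(self):
        ref = self._pulse_spec()
        k = 30
        shifted = compute_spectrum(trace(np.roll(np.fft.irfft(ref.values, N), k)))
        h = deconvolve(shifted, ref, regularization=0.0)
        band = (ref.freq_thz > 0.2) & (ref.freq_thz < 1.2)
        assert np.allclose(np.abs(h.values[band]), 1.0, atol=1e-8)
        # independent delay estimate: peak of the cross-correlation
        xr = np.fft.irfft(ref.values, N)
        xs = np.roll(xr, k)
        lag = np.argmax(np.correlate(xs, xr, "full")) - (N - 1)
        assert lag == k
        phase_slope = np.polyfit(ref.freq_thz[band], np.unwrap(np.angle(h.values[band])), 1)[0]
        assert phase_slope == pytest.approx(-2 * np.pi * lag * DT, rel=1e-6)

    def test_grid_mismatch_and_negative_regularization_rejected(self):
        ref = self._pulse_spec()
        other = Spectrum(ref.freq_thz * 2.0, ref.values)
        with pytest.raises(ValueError, match="grid"):
            deconvolve(other, ref)
        with pytest.raises(ValueError, match="regularization"):
            deconvolve(ref, ref, regularization=-1e-3)


class TestSpectralSlope:
    def test_flat_spectrum_has_zero_slope(self):
        spec = Spectrum(FREQS, np.ones_like(FREQS, dtype=complex))
        assert spectral_slope(spec) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered_to_machine_precision(self):
        values = 1.0 - 0.5 * (FREQS - 0.4)
        spec = Spectrum(FREQS, values.astype(complex))
        assert spectral_slope(spec) == pytest.approx(-0.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        mag = 0.4 + 0.1 * rng.random(len(FREQS))
        spec = Spectrum(FREQS, mag.astype(complex))
        band = SlopeBand()
        mask = band.mask(FREQS)
        oracle, _ = ols_slope_intercept(FREQS[mask], mag[mask])
        assert spectral_slope(spec, band) == pytest.approx(oracle, abs=1e-8)

    def test_too_few_bins_rejected(self):
        freqs = np.array([0.0, 0.5, 1.0, 1.5])
        spec = Spectrum(freqs, np.ones(4, dtype=complex))
        with pytest.raises(ValueError, match="bins"):
            spectral_slope(spec, SlopeBand(0.4, 0.8))

    @given(a=st.floats(1e-3, 1e3))
    def test_slope_scales_linearly_with_amplitude(self, a):
        rng = np.random.default_rng(3)
        mag = 0.4 + 0.1 * rng.random(len(FREQS))
        s1 = spectral_slope(Spectrum(FREQS, mag.astype(complex)))
        s2 = spectral_slope(Spectrum(FREQS, (a * mag).astype(complex)))
        assert s2 == pytest.approx(a * s1, rel=1e-9)


class TestProcessArchive:
    def test_slope_table_schema_and_determinism(self, tiny_archive, tiny_config):
        t1 = process_archive(tiny_archive["archive"])
        t2 = process_archive(tiny_archive["archive"])
        assert list(t1.columns) == [
            "sample_id", "frame_index", "t_min", "iop_mmHg",
            "pixel_row", "pixel_col", "slope_ps",
        ]
        g = tiny_config.grid_size
        assert len(t1) == 6 * tiny_config.protocol.n_frames * g * g
        assert np.array_equal(t1["slope_ps"].to_numpy(), t2["slope_ps"].to_numpy())

    def test_batch_path_agrees_with_single_trace_ops(self, tiny_archive):
        from thzcornea import archive as arch

        table = process_archive(tiny_archive["archive"])
        time_ps = arch.read_time_axis(tiny_archive["archive"])
        ref = THzTrace(time_ps, arch.read_reference(tiny_archive["archive"]))
        fr = next(arch.iter_frames(tiny_archive["archive"]))
        one = THzTrace(time_ps, fr.traces[4, 4].astype(float))
        h = deconvolve(
            compute_spectrum(highpass_filter(one)),
            compute_spectrum(highpass_filter(ref)),
        )
        expected = spectral_slope(h)
        got = table[
            (table.sample_id == fr.sample_id)
            & (table.frame_index == fr.frame_index)
            & (table.pixel_row == 4)
            & (table.pixel_col == 4)
        ]["slope_ps"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-9)
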