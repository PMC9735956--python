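import dataclasses

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from thzcornea import (
    CohortConfig,
    ProtocolSpec,
    ReferenceSpec,
    SlopeBand,
    compute_spectrum,
    deconvolve,
    generate_cohort,
    highpass_filter,
    pump_efficacy_from_ecd,
    reference_pulse,
    spectral_slope,
    stratified_reflectance,
    synthesize_trace,
)
from thzcornea.hydration import HydrationDynamics
from thzcornea.layers import LayerStack
from thzcornea.dielectric import bruggeman_mix, debye_permittivity, refractive_index
from thzcornea.features import period_windows

from oracles import ols_slope_intercept

REF = ReferenceSpec(n_samples=512)


class TestReferencePulse:
    def test_energy_concentrated_in_band(self):
        pulse = reference_pulse(REF)
        freqs = REF.freq_axis()
        power = np.abs(np.fft.rfft(pulse)) ** 2
        in_band = power[(freqs >= 0.1) & (freqs <= 2.0)].sum()
        assert in_band / power.sum() > 0.99
        assert 0.3 <= freqs[np.argmax(power)] <= 1.0

    def test_peak_normalised(self):
        assert np.max(np.abs(reference_pulse(REF))) == pytest.approx(1.0)

    def test_trace_length_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            ReferenceSpec(n_samples=1000)


class TestSynthesizeTrace:
    def test_identity_channel_returns_the_pulse(self):
        n_freq = REF.n_samples // 2 + 1
        trace = synthesize_trace(np.ones(n_freq), REF)
        assert np.allclose(trace.amplitude, reference_pulse(REF), atol=1e-12)

    def test_zero_reflectance_returns_silence(self):
        trace = synthesize_trace(np.zeros(REF.n_samples // 2 + 1), REF)
        assert np.all(trace.amplitude == 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            synthesize_trace(np.ones(100), REF)

    def test_noise_needs_rng_and_nonnegative_sd(self):
        refl = np.ones(REF.n_samples // 2 + 1)
        with pytest.raises(ValueError):
            synthesize_trace(refl, REF, noise_sd=-0.1)
        with pytest.raises(ValueError):
            synthesize_trace(refl, REF, noise_sd=0.1)  # no rng supplied

    def test_noise_is_seed_deterministic(self):
        refl = np.ones(REF.n_samples // 2 + 1)
        a = synthesize_trace(refl, REF, 0.1, np.random.default_rng(5)).amplitude
        b = synthesize_trace(refl, REF, 0.1, np.random.default_rng(5)).amplitude
        c = synthesize_trace(refl, REF, 0.1, np.random.default_rng(6)).amplitude
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_halfspace_slope_survives_the_processing_chain(self):
        """Deconvolution must hand back the slope of the imposed |r(f)|."""
        freqs = REF.freq_axis()
        n = refractive_index(bruggeman_mix(debye_permittivity(freqs), 4.0, 0.85))
        refl = stratified_reflectance(LayerStack([], n_substrate=n), freqs)
        sample = highpass_filter(synthesize_trace(refl, REF))
        reference = highpass_filter(synthesize_trace(np.full(len(freqs), -1.0 + 0j), REF))
        h = deconvolve(compute_spectrum(sample), compute_spectrum(reference))
        band = SlopeBand()
        mask = band.mask(freqs)
        oracle, _ = ols_slope_intercept(freqs[mask], np.abs(refl)[mask])
        assert spectral_slope(h, band) == pytest.approx(oracle, rel=0.01)


class TestPumpEfficacy:
    def test_monotone_in_ecd_and_bounded(self):
        ecds = np.linspace(200.0, 8000.0, 50)
        effs = np.array([pump_efficacy_from_ecd(e) for e in ecds])
        assert np.all(np.diff(effs) > 0.0)
        assert np.all((effs >= 0.0) & (effs <= 1.0))

    def test_nonpositive_ecd_rejected(self):
        with pytest.raises(ValueError):
            pump_efficacy_from_ecd(0.0)


class TestGenerateCohort:
    def test_default_cohort_is_19_samples_in_7_6_6_groups(self):
        cohort = generate_cohort(CohortConfig(reference=REF), seed=0)
        labels = cohort.labels()
        assert len(labels) == 19
        counts = labels.groupby("group_mmHg").size().to_dict()
        assert counts == {25.0: 7, 35.0: 6, 45.0: 6}
        assert (labels["ecd_cells_per_mm2"] > 0).all()

    def test_inconsistent_group_sizes_rejected(self):
        with pytest.raises(ValueError, match="group sizes"):
            generate_cohort(CohortConfig(reference=REF), seed=0, n_samples=20)

    def test_same_seed_bitwise_identical_different_seed_not(self, tiny_config):
        a = generate_cohort(tiny_config, seed=3)
        b = generate_cohort(tiny_config, seed=3)
        c = generate_cohort(tiny_config, seed=4)
        assert [s.ecd for s in a.samples] == [s.ecd for s in b.samples]
        fa = next(a.iter_trace_frames()).traces
        fb = next(b.iter_trace_frames()).traces
        fc = next(c.iter_trace_frames()).traces
        assert np.array_equal(fa, fb)
        assert not np.array_equal(fa, fc)

    def test_static_sample_when_no_influx(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config,
            noise_sd=0.0,
            dynamics=HydrationDynamics(influx_rate=0.0),
        )
        cohort = generate_cohort(cfg, seed=3)
        frames = list(cohort.iter_trace_frames())
        sample0 = [f for f in frames if f.sample_id == "S00"]
        assert np.allclose(sample0[0].traces, sample0[-1].traces, atol=1e-7)

    def test_intact_samples_have_smaller_elevated_slope_shift(self):
        """Generator contract: damaged endothelium -> larger |S_Elev|.

        One-sided rank test on a 50-sample cohort, model-domain slopes.
        """
        cfg = CohortConfig(group_sizes={25.0: 17, 35.0: 17, 45.0: 16}, reference=REF)
        cohort = generate_cohort(cfg, seed=12)
        windows = period_windows(cfg.protocol)
        times = cfg.protocol.frame_times()
        idx = np.flatnonzero((times > windows.elevated[0]) & (times <= windows.elevated[1]))
        s_elev = {
            s.sample_id: np.mean(cohort.model_slope_series(s, frame_indices=idx))
            for s in cohort.samples
        }
        labels = cohort.labels().set_index("sample_id")
        intact = [abs(v) for k, v in s_elev.items() if labels.loc[k, "ecd_cells_per_mm2"] > 3000]
        damaged = [abs(v) for k, v in s_elev.items() if labels.loc[k, "ecd_cells_per_mm2"] <= 3000]
        assert len(intact) >= 5 and len(damaged) >= 5
        assert mannwhitneyu(intact, damaged, alternative="less").pvalue < 0.01


class TestReferenceScan:
    def test_reference_is_sign_flipped_pulse(self, tiny_cohort):
        ref_trace = tiny_cohort.reference_trace()
        pulse = reference_pulse(tiny_cohort.config.reference)
        assert np.allclose(ref_trace, -pulse, atol=1e-12)

    def test_self_deconvolution_of_conductor_frame(self, tiny_cohort):
        ref = tiny_cohort.config.reference
        spec = compute_spectrum(synthesize_trace(np.full(ref.n_samples // 2 + 1, -1.0 + 0j), ref))
        h = deconvolve(spec, spec, regularization=0.0)
        strong = np.abs(spec.values) > 1e-9 * np.max(np.abs(spec.values))
        assert np.allclose(np.abs(h.values[strong]), 1.0, atol=1e-8)
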