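"""Sliding-window spectral analysis: normalisation, trend fit, peaks, traces."""

import numpy as np
import pytest

from boldosc import (Hypnogram, InsufficientDataError, RegionTimeSeries,
                     SimConfig, ValidationError, percent_power_change,
                     simulate_bold, simulate_hypnogram, sliding_spectrogram,
                     stage_average_spectrum, window_stages)
from boldosc.containers import OscillationBand, PowerTrace
from boldosc.spectra import (band_power_trace, detect_band_peaks,
                             detect_region_bands, fit_one_over_f,
                             hamming_taper, region_band_power_trace)

TR = 2.08


def _ts(values, tr=TR):
    return RegionTimeSeries(values=np.atleast_2d(values), tr_s=tr)


class TestSlidingSpectrogram:
    def test_window_count(self, rng):
        spec = sliding_spectrogram(_ts(rng.standard_normal(900)), 50, 1)
        assert spec.n_windows == (900 - 50) // 1 + 1 == 851

    def test_unit_sinusoid_at_bin_frequency_gives_half_power(self):
        # amplitude normalisation: a unit sinusoid at a bin frequency puts
        # power 0.5 at that bin in every window, regardless of the taper
        k = 5
        f = k / (50 * TR)
        t = np.arange(600) * TR
        spec = sliding_spectrogram(_ts(np.sin(2 * np.pi * f * t)))
        peak_bin = np.argmax(spec.power[0], axis=0)
        assert np.all(spec.freqs_hz[peak_bin] == pytest.approx(f))
        assert spec.power[0, peak_bin[0], :] == pytest.approx(0.5, rel=1e-3)

    def test_parseval_total_power_matches_time_domain(self, rng):
        # frequency-domain total equals the taper-normalised time-domain
        # power computed directly (independent of the FFT path), within 1%
        x = rng.standard_normal(300)
        spec = sliding_spectrogram(_ts(x), 50, 1)
        taper = hamming_taper(50)
        for w in range(0, spec.n_windows, 50):
            seg = x[w:w + 50]
            seg = seg - (taper * seg).sum() / taper.sum()
            direct = 50 * np.sum((taper * seg) ** 2) / taper.sum() ** 2
            assert spec.power[0, :, w].sum() == pytest.approx(direct, rel=0.01)

    def test_power_nonnegative_finite(self, spectrogram_session):
        assert np.all(spectrogram_session.power >= 0)
        assert np.all(np.isfinite(spectrogram_session.power))

    def test_series_shorter_than_window_rejected(self, rng):
        with pytest.raises(ValidationError, match="shorter"):
            sliding_spectrogram(_ts(rng.standard_normal(40)), 50, 1)

    def test_dc_bin_excluded(self, spectrogram_session):
        assert spectrogram_session.freqs_hz[0] > 0


class TestStageAverage:
    def test_single_stage_equals_time_mean(self, rng):
        ts = _ts(rng.standard_normal((2, 300)))
        hyp = Hypnogram(stages=["N2"] * 21)
        spec = sliding_spectrogram(ts)
        avg = stage_average_spectrum(spec, hyp, "N2")
        assert np.allclose(avg, spec.power.mean(axis=2))

    def test_window_shuffling_leaves_average_unchanged(self, rng,
                                                       spectrogram_session,
                                                       hypnogram,
                                                       stage_labels):
        avg = stage_average_spectrum(spectrogram_session, hypnogram, "N2",
                                     stage_labels=stage_labels)
        perm = rng.permutation(spectrogram_session.n_windows)
        shuffled = spectrogram_session
        import copy
        shuffled = copy.copy(spectrogram_session)
        shuffled.power = spectrogram_session.power[:, :, perm]
        avg2 = stage_average_spectrum(shuffled, hypnogram, "N2",
                                      stage_labels=stage_labels[perm])
        assert np.allclose(avg, avg2)

    def test_absent_stage_raises_with_reason(self, spectrogram_session,
                                             hypnogram, stage_labels):
        with pytest.raises(InsufficientDataError, match="R"):
            stage_average_spectrum(spectrogram_session, hypnogram, "R",
                                   stage_labels=stage_labels)

    def test_wake_gains_zero_keeps_wake_clean_sleep_peaked(self):
        gains = {"W": (0.0, 0.0), "N1": (2.0, 2.0), "N2": (2.0, 2.0),
                 "N3": (2.0, 2.0), "R": (0.0, 0.0)}
        cfg = SimConfig(seed=6, stage_gain=gains)
        hyp = simulate_hypnogram(cfg)
        spec = sliding_spectrogram(simulate_bold(cfg, hyp))
        labels = window_stages(hyp, spec)
        for stage, expect_peak in (("W", False), ("N2", True)):
            spectrum = stage_average_spectrum(spec, hyp, stage,
                                              stage_labels=labels).mean(axis=0)
            fit = fit_one_over_f(spec.freqs_hz, spectrum)
            peaks = detect_band_peaks(spec.freqs_hz, fit)
            assert (peaks["LF"] is not None) == expect_peak


class TestOneOverFFit:
    freqs = np.fft.rfftfreq(50, d=TR)[1:]

    def test_exact_inverse_f_gives_slope_minus_one_zero_residuals(self):
        fit = fit_one_over_f(self.freqs, 3.0 / self.freqs)
        assert fit.slope == pytest.approx(-1.0, abs=1e-6)
        assert np.allclose(fit.residual, 0.0, atol=1e-9)

    def test_flat_spectrum_gives_slope_zero(self):
        fit = fit_one_over_f(self.freqs, np.full_like(self.freqs, 2.5))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_bump_peaks_in_lf_residual(self):
        power = 1.0 / self.freqs * (
            1 + 9 * np.exp(-0.5 * ((self.freqs - 0.055) / 0.006) ** 2))
        fit = fit_one_over_f(self.freqs, power)
        peaks = detect_band_peaks(self.freqs, fit)
        assert peaks["LF"] is not None
        assert abs(peaks["LF"].peak_freq_hz - 0.055) <= 1.0 / 104
        assert peaks["HF"] is None

    def test_nonpositive_bins_excluded_and_counted(self):
        power = 1.0 / self.freqs
        power[2] = 0.0
        fit = fit_one_over_f(self.freqs, power)
        assert fit.n_excluded_nonpositive == 1

    def test_zero_residual_detects_no_peaks(self):
        fit = fit_one_over_f(self.freqs, 1.0 / self.freqs)
        peaks = detect_band_peaks(self.freqs, fit)
        assert peaks == {"LF": None, "HF": None}


class TestPeakRecovery:
    def test_injected_frequencies_recovered_within_one_bin(
            self, default_config, region_params, spectrogram_session,
            stage_labels, region_bands):
        bin_hz = 1.0 / (50 * TR)
        for r, bands in enumerate(region_bands):
            assert bands["LF"] is not None and bands["HF"] is not None
            assert abs(bands["LF"].peak_freq_hz
                       - region_params.lf_freq_hz[r]) <= bin_hz
            assert abs(bands["HF"].peak_freq_hz
                       - region_params.hf_freq_hz[r]) <= bin_hz

    def test_peaks_lie_in_reported_sleep_ranges(self, region_bands):
        lf = np.median([b["LF"].peak_freq_hz for b in region_bands])
        hf = np.median([b["HF"].peak_freq_hz for b in region_bands])
        assert 0.04 <= lf <= 0.07
        assert 0.15 <= hf <= 0.18


class TestBandPowerTrace:
    def test_constant_spectrogram_gives_constant_trace(self,
                                                       spectrogram_session):
        import copy
        spec = copy.copy(spectrogram_session)
        spec.power = np.full_like(spec.power, 3.25)
        band = OscillationBand("LF", (0.03, 0.08), 0.055, (0.04, 0.07))
        trace = band_power_trace(spec, band)
        assert np.allclose(trace.values, 3.25)

    def test_gain_step_ramp_centered_near_transition(self):
        # single W->N2 gain step at a known epoch: the trace's half-rise
        # lands within half a window of the step time
        stages = ["W"] * 30 + ["N2"] * 30
        hyp = Hypnogram(stages=stages)
        cfg = SimConfig(seed=8, n_regions=1, lf_freq_hz=np.array([0.055]),
                        duration_s=1800.0, background_sigma=0.05,
                        stage_gain={"W": (1.0, 0.0), "N1": (1.0, 0.0),
                                    "N2": (2.0, 0.0), "N3": (2.0, 0.0),
                                    "R": (1.0, 0.0)})
        ts = simulate_bold(cfg, hyp)
        spec = sliding_spectrogram(ts)
        band = OscillationBand("LF", (0.03, 0.08), 0.055, (0.04, 0.07))
        trace = band_power_trace(spec, band)
        v = trace.values[0]
        half = 0.5 * (np.median(v[:100]) + np.median(v[-100:]))
        t_half = trace.window_centers_s[np.flatnonzero(v > half)[0]]
        assert abs(t_half - 900.0) <= 52.0

    def test_band_outside_oscillations_is_stage_independent(
            self, spectrogram_session, stage_labels):
        band = OscillationBand("LF", (0.005, 0.12), 0.11, (0.10, 0.12))
        trace = band_power_trace(spec=spectrogram_session, band=band)
        wake = trace.values[:, stage_labels == "W"].mean()
        sleep = trace.values[:, np.isin(stage_labels, ["N2", "N3"])].mean()
        assert sleep == pytest.approx(wake, rel=0.2)

    def test_narrow_band_falls_back_to_nearest_bin_with_warning(
            self, spectrogram_session):
        band = OscillationBand("LF", (0.03, 0.08), 0.0545,
                               (0.0544, 0.0546))
        with pytest.warns(UserWarning, match="nearest"):
            trace = band_power_trace(spectrogram_session, band)
        assert trace.values.shape[0] == spectrogram_session.power.shape[0]


class TestPercentPowerChange:
    def _trace(self, wake_val, sleep_val, n=60):
        labels = np.array(["W"] * n + ["N2"] * n, dtype=object)
        values = np.concatenate([np.full(n, wake_val), np.full(n, sleep_val)])
        return PowerTrace(values=values[None, :],
                          window_centers_s=np.arange(2 * n) * TR,
                          region_labels=["r0"],
                          stage_labels=labels), labels

    def test_example_arithmetic(self):
        trace, labels = self._trace(1.0, 3.5)
        assert percent_power_change(trace, stage_labels=labels)[0] == \
            pytest.approx(250.0)

    def test_identical_stages_give_zero(self):
        trace, labels = self._trace(2.0, 2.0)
        assert percent_power_change(trace, stage_labels=labels)[0] == \
            pytest.approx(0.0)

    def test_invariant_to_global_rescaling(self, bold, hypnogram):
        spec_a = sliding_spectrogram(bold)
        scaled = RegionTimeSeries(values=bold.values * 7.3, tr_s=bold.tr_s,
                                  region_labels=bold.region_labels)
        spec_b = sliding_spectrogram(scaled)
        labels = window_stages(hypnogram, spec_a)
        band = OscillationBand("LF", (0.03, 0.08), 0.055, (0.04, 0.07))
        pc_a = percent_power_change(band_power_trace(spec_a, band),
                                    stage_labels=labels)
        pc_b = percent_power_change(band_power_trace(spec_b, band),
                                    stage_labels=labels)
        assert np.allclose(pc_a, pc_b, rtol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        trace, labels = self._trace(0.0, 1.0)
        with pytest.raises(ValidationError, match="baseline"):
            percent_power_change(trace, stage_labels=labels)

    def test_too_few_windows_absent_with_reason(self):
        trace, labels = self._trace(1.0, 2.0, n=10)
        with pytest.raises(InsufficientDataError, match="windows"):
            percent_power_change(trace, stage_labels=labels)

    def test_calibrated_gain_step_recovered_in_printed_bracket(
            self, spectrogram_session, stage_labels, region_bands):
        # default generator gains encode a ~3.5x duration-weighted power
        # step; the recovered change averaged over regions falls in the
        # 200-300% bracket for both oscillation bands
        for kind in ("LF", "HF"):
            trace, _ = region_band_power_trace(spectrogram_session,
                                               region_bands, kind,
                                               stage_labels=stage_labels)
            pc = percent_power_change(trace, stage_labels=stage_labels)
            assert 200.0 <= pc.mean() <= 300.0


class TestWindowStages:
    def test_majority_and_transition_labelling(self, hypnogram,
                                               spectrogram_session,
                                               stage_labels):
        # labels restricted to stages present plus the transition flag
        assert set(stage_labels) <= {"W", "N1", "N2", "N3", "T"}
        # windows straddling stage boundaries are flagged
        assert (stage_labels == "T").sum() > 0

    def test_pure_stage_window_keeps_stage(self):
        hyp = Hypnogram(stages=["N2"] * 40)
        centers = np.array([300.0])
        labels = window_stages(hyp, centers, tr_s=TR, window_len_s=104.0)
        assert labels[0] == "N2"
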