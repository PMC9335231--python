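"""Synthetic multi-modal sleep recordings: BOLD, EEG, hypnogram, physiology.

The generator produces data with the statistical structure the downstream
analysis assumes, with known ground truth:

* BOLD: per-region scale-free 1/f background plus two stage-gated sinusoids,
  one below 0.1 Hz (light-sleep oscillation) and one above (deep-sleep
  oscillation), with per-region frequencies, gains and gating lags.
* EEG: pink background plus 11-16 Hz spindle bursts and 0.5-4 Hz biphasic
  slow waves whose occurrence rates are stage-gated and modulated by
  infra-slow sinusoidal envelopes.
* Physiology: respiration near 0.25 Hz and cardiac pulse near 1 Hz with
  slowly varying rate/depth/volume.

Everything is deterministic given ``SimConfig.seed``; independent seed
streams keep each modality reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import SimConfig
from .containers import (EventList, Hypnogram, RegionTimeSeries,
                         ValidationError)

_STREAMS = {"params": 0, "hypnogram": 1, "bold": 2, "eeg": 3, "physio": 4}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.seed),
                                spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def one_over_f_noise(n: int, exponent: float, rng: np.random.Generator,
                     sigma: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Generated by frequency-domain shaping of white noise: the rFFT of a white
    draw is multiplied by f^(-exponent/2) (DC bin zeroed), inverted, and the
    result rescaled to standard deviation ``sigma``. This gives exact spectral
    control over the aperiodic background.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x *= sigma / sd
    return x


def band_limited_noise(n: int, fs: float, band: tuple,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    lo, hi = band
    sos = signal.butter(2, [lo, min(hi, 0.49 * fs)], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(config: SimConfig) -> Hypnogram:
    """A W -> N1 -> N2 -> N3 -> N2 -> W stage trajectory.

    Dwell times follow ``config.trajectory`` (scaled to the recording
    duration) with a +/-10% seeded jitter, guaranteeing at least one
    falling-asleep and one waking transition.
    """
    if config.duration_s < 20 * 60:
        raise ValidationError(
            "recording shorter than 20 min cannot fit the wake-sleep-wake trajectory"
        )
    rng = _rng(config, "hypnogram")
    stages = [s for s, _ in config.trajectory]
    dwell = np.array([m for _, m in config.trajectory], dtype=float)
    dwell = dwell * rng.uniform(0.9, 1.1, size=len(dwell))
    n_epochs = int(config.duration_s // config.epoch_s)
    # proportional allocation of epochs, each segment at least one epoch
    counts = np.maximum(1, np.round(dwell / dwell.sum() * n_epochs).astype(int))
    while counts.sum() > n_epochs:
        counts[np.argmax(counts)] -= 1
    counts[-1] += n_epochs - counts.sum()
    labels = np.repeat(stages, counts)
    return Hypnogram(stages=labels, epoch_s=config.epoch_s)


# ---------------------------------------------------------------------------
# Per-region oscillation parameters
# ---------------------------------------------------------------------------

@dataclass
class RegionParams:
    lf_freq_hz: np.ndarray
    hf_freq_hz: np.ndarray
    lf_lag_s: np.ndarray
    hf_lag_s: np.ndarray
    lf_phase: np.ndarray
    hf_phase: np.ndarray


def draw_region_params(config: SimConfig) -> RegionParams:
    """Per-region frequencies, gating lags and phases (seeded stream)."""
    rng = _rng(config, "params")
    R = config.n_regions
    lf = (np.asarray(config.lf_freq_hz, dtype=float) if config.lf_freq_hz is not None
          else rng.uniform(*config.lf_freq_range_hz, size=R))
    hf = (np.asarray(config.hf_freq_hz, dtype=float) if config.hf_freq_hz is not None
          else rng.uniform(*config.hf_freq_range_hz, size=R))
    lf_lag = (np.asarray(config.onset_lag_s, dtype=float)
              if config.onset_lag_s is not None else np.zeros(R))
    hf_lag = (np.asarray(config.offset_lag_s, dtype=float)
              if config.offset_lag_s is not None else np.zeros(R))
    for name, arr in (("lf_freq_hz", lf), ("hf_freq_hz", hf),
                      ("onset_lag_s", lf_lag), ("offset_lag_s", hf_lag)):
        if arr.shape != (R,):
            raise ValidationError(f"{name} must have one entry per region")
    nyq = 0.5 / config.tr_s
    if np.any(lf >= nyq) or np.any(hf >= nyq):
        raise ValidationError(f"oscillation frequency at or above BOLD Nyquist {nyq:.4f} Hz")
    return RegionParams(lf, hf, lf_lag, hf_lag,
                        rng.uniform(0, 2 * np.pi, R), rng.uniform(0, 2 * np.pi, R))


def _smooth_gain_series(hyp: Hypnogram, times: np.ndarray, gain_by_stage: dict,
                        ramp_s: float, dt: float) -> np.ndarray:
    """Stage-gain step function smoothed with a half-cosine ramp.

    Convolving the step series with the normalised derivative of a raised
    cosine yields exact half-cosine transitions of length ``ramp_s`` (shorter
    than one analysis window, avoiding spectral splatter at stage edges).
    """
    stages = hyp.stage_at(times)
    steps = np.array([gain_by_stage.get(s, 0.0) for s in stages], dtype=float)
    m = max(1, int(round(ramp_s / dt)))
    kernel = np.sin(np.pi * (np.arange(m) + 0.5) / m)
    kernel /= kernel.sum()
    padded = np.concatenate([np.repeat(steps[0], m), steps, np.repeat(steps[-1], m)])
    smooth = np.convolve(padded, kernel, mode="same")[m:m + len(steps)]
    return smooth


def stage_gain_series(config: SimConfig, hyp: Hypnogram, times: np.ndarray,
                      band_index: int) -> np.ndarray:
    gains = {s: g[band_index] for s, g in config.stage_gain.items()}
    return _smooth_gain_series(hyp, times, gains, config.gain_ramp_s,
                               float(times[1] - times[0]))


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def simulate_bold(config: SimConfig, hyp: Hypnogram,
                  params: RegionParams | None = None) -> RegionTimeSeries:
    """Region-by-volume BOLD with 1/f background plus stage-gated oscillations.

    Region ``r`` at volume time ``t`` is

        s_r(t) = b_r(t) + g_LF(stage(t - lam_r)) sin(2 pi f_LF,r t + phi_r)
                        + g_HF(stage(t - mu_r)) sin(2 pi f_HF,r t + psi_r)

    where ``b_r`` is 1/f^beta-shaped noise and the stage gains ramp with a
    half-cosine at stage boundaries; ``lam_r``/``mu_r`` delay the gating of
    the two bands region by region.
    """
    if params is None:
        params = draw_region_params(config)
    rng = _rng(config, "bold")
    n_vol = int(config.duration_s // config.tr_s)
    t = np.arange(n_vol) * config.tr_s
    lf_gain = stage_gain_series(config, hyp, t, band_index=0)
    hf_gain = stage_gain_series(config, hyp, t, band_index=1)
    values = np.empty((config.n_regions, n_vol))
    for r in range(config.n_regions):
        bg = one_over_f_noise(n_vol, config.one_over_f_exponent, rng,
                              sigma=config.background_sigma)
        g_lf = np.interp(t - params.lf_lag_s[r], t, lf_gain)
        g_hf = np.interp(t - params.hf_lag_s[r], t, hf_gain)
        values[r] = (bg
                     + g_lf * np.sin(2 * np.pi * params.lf_freq_hz[r] * t
                                     + params.lf_phase[r])
                     + g_hf * np.sin(2 * np.pi * params.hf_freq_hz[r] * t
                                     + params.hf_phase[r]))
    return RegionTimeSeries(values=values, tr_s=config.tr_s,
                            region_labels=[f"region{r:02d}"
                                           for r in range(config.n_regions)])


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _thinned_event_onsets(rate_per_s: np.ndarray, fs: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson onsets by thinning a homogeneous process.

    Candidates are drawn at the global maximum rate and accepted with
    probability rate(t)/rate_max -- simple, exact and seedable.
    """
    lam_max = float(rate_per_s.max())
    if lam_max <= 0:
        return np.array([])
    duration = len(rate_per_s) / fs
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0, duration, size=n_cand))
    accept = rng.uniform(0, 1, size=n_cand) < \
        rate_per_s[np.minimum((cand * fs).astype(int), len(rate_per_s) - 1)] / lam_max
    return cand[accept]


def _spindle_waveform(duration_s: float, freq_hz: float, amp: float,
                      fs: float) -> np.ndarray:
    n = max(1, int(round(duration_s * fs)))
    tau = np.arange(n) / fs
    env = signal.windows.tukey(n, alpha=0.4)
    return amp * env * np.sin(2 * np.pi * freq_hz * tau)


def _slow_wave_waveform(duration_s: float, amp: float, fs: float,
                        neg_fraction: float = 0.45,
                        pos_ratio: float = 0.6) -> np.ndarray:
    """Biphasic wave: negative half-sine then a smaller positive half-sine."""
    n_neg = max(1, int(round(duration_s * neg_fraction * fs)))
    n_pos = max(1, int(round(duration_s * fs)) - n_neg)
    neg = -amp * np.sin(np.pi * (np.arange(n_neg) + 0.5) / n_neg)
    pos = pos_ratio * amp * np.sin(np.pi * (np.arange(n_pos) + 0.5) / n_pos)
    return np.concatenate([neg, pos])


def _band_rms(x: np.ndarray, fs: float, band: tuple) -> float:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return float(signal.sosfiltfilt(sos, x).std())


def simulate_eeg(config: SimConfig, hyp: Hypnogram):
    """EEG channels plus ground-truth event list.

    Background pink noise carries spindle bursts and biphasic slow waves.
    Event onsets follow an inhomogeneous Poisson process: the stage base
    rate multiplied by ``1 + m sin(2 pi f_env t + phase)``, the infra-slow
    envelope that groups events the way the BOLD oscillations gate power.

    Returns
    -------
    eeg : ndarray (n_channels, n_samples)
    fs : float
    truth : EventList of injected events
    envelopes : dict with the modulation envelope per event type
    """
    rng = _rng(config, "eeg")
    fs = config.eeg_fs_hz
    n = int(config.duration_s * fs)
    t = np.arange(n) / fs
    stages = hyp.stage_at(t)

    # occupancy guard: too-busy configurations would force overlaps
    for name, rates, durs in (
            ("spindle", config.spindle_rate_per_min, config.spindle_duration_range_s),
            ("slow_wave", config.sw_rate_per_min, config.sw_duration_range_s)):
        peak_rate = max(rates.values()) / 60.0 * (1 + config.env_mod_depth)
        if peak_rate * np.mean(durs) > config.max_event_occupancy:
            raise ValidationError(
                f"{name} rate implies occupancy above {config.max_event_occupancy}"
            )

    eeg = np.empty((config.n_eeg_channels, n))
    all_events = {c: [] for c in ("onset_s", "duration_s", "type", "channel", "amplitude")}
    envelopes = {}
    for ch in range(config.n_eeg_channels):
        bg = one_over_f_noise(n, 1.0, rng, sigma=1.0)
        sigma_rms = _band_rms(bg, fs, (11.0, 16.0))
        delta_rms = _band_rms(bg, fs, (0.5, 4.0))
        x = bg.copy()
        specs = (
            ("spindle", config.spindle_rate_per_min, config.spindle_env_freq_hz,
             config.spindle_duration_range_s,
             config.spindle_amp_rms_factor * np.sqrt(2.0) * sigma_rms),
            ("slow_wave", config.sw_rate_per_min, config.sw_env_freq_hz,
             config.sw_duration_range_s,
             config.sw_amp_peak_factor * delta_rms),
        )
        for etype, rates, f_env, dur_range, amp in specs:
            base = np.array([rates.get(s, 0.0) for s in stages]) / 60.0
            phase = rng.uniform(0, 2 * np.pi)
            env = 1.0 + config.env_mod_depth * np.sin(2 * np.pi * f_env * t + phase)
            if ch == 0:
                envelopes[etype] = {"freq_hz": f_env, "phase": phase}
            onsets = _thinned_event_onsets(base * env, fs, rng)
            for onset in onsets:
                dur = rng.uniform(*dur_range)
                if onset + dur > config.duration_s:
                    continue  # events must lie within the recording
                # overlapping events superpose (waves can arrive in trains);
                # the occupancy guard above rejects configs where overlap
                # would dominate
                if etype == "spindle":
                    f_sp = rng.uniform(*config.spindle_freq_range_hz)
                    wave = _spindle_waveform(dur, f_sp, amp, fs)
                else:
                    wave = _slow_wave_waveform(dur, amp, fs)
                i0 = int(round(onset * fs))
                x[i0:i0 + len(wave)] += wave[:n - i0]
                last_end = onset + dur
                all_events["onset_s"].append(onset)
                all_events["duration_s"].append(dur)
                all_events["type"].append(etype)
                all_events["channel"].append(f"ch{ch:02d}")
                all_events["amplitude"].append(amp)
        eeg[ch] = x
    truth = (EventList(all_events) if all_events["onset_s"]
             else EventList.empty())
    return eeg, fs, truth, envelopes


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------

def simulate_physio(config: SimConfig):
    """Raw respiratory and cardiac traces with slow rate/depth variability.

    Respiration is a sinusoid-like waveform whose instantaneous rate and
    depth are band-limited (0.04-0.4 Hz) random walks around 0.25 Hz;
    the cardiac trace is a periodic pulse waveform (von-Mises-shaped peaks)
    around 1 Hz with slowly varying rate.

    Returns a dict with ``resp``, ``cardiac``, ``fs`` and ground-truth
    ``rate``/``depth``/``volume`` series.
    """
    rng = _rng(config, "physio")
    fs = config.physio_fs_hz
    n = int(config.duration_s * fs)
    t = np.arange(n) / fs

    def modulated(base, rel_sd):
        if rel_sd <= 0:
            return np.full(n, base)
        mod = band_limited_noise(n, fs, (0.04, 0.4), rng)
        return base * np.clip(1.0 + rel_sd * mod, 0.1, None)

    resp_rate = modulated(config.resp_freq_hz, config.resp_rate_var)
    resp_depth = np.clip(
        1.0 + (config.resp_depth_var * band_limited_noise(n, fs, (0.04, 0.4), rng)
               if config.resp_depth_var > 0 else 0.0), 0.2, None)
    resp_phase = 2 * np.pi * np.cumsum(resp_rate) / fs
    resp = resp_depth * np.sin(resp_phase)

    card_rate = modulated(config.cardiac_freq_hz, config.cardiac_rate_var)
    card_phase = 2 * np.pi * np.cumsum(card_rate) / fs
    kappa = 8.0
    cardiac = np.exp(kappa * (np.cos(card_phase) - 1.0))
    cardiac -= cardiac.mean()

    win = max(1, int(round(6.0 * fs)))
    pad = np.pad(resp, win // 2, mode="reflect")
    csum = np.cumsum(np.insert(pad, 0, 0.0))
    csum2 = np.cumsum(np.insert(pad ** 2, 0, 0.0))
    mean = (csum[win:] - csum[:-win]) / win
    var = np.maximum((csum2[win:] - csum2[:-win]) / win - mean ** 2, 0.0)
    volume = np.sqrt(var)[:n]

    return {"resp": resp, "cardiac": cardiac, "fs": fs, "t_s": t,
            "truth": {"resp_rate_hz": resp_rate, "resp_depth": resp_depth,
                      "resp_volume": volume, "cardiac_rate_hz": card_rate}}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRecording:
    """All modalities of one synthetic session plus the injected truth."""

    config: SimConfig
    hypnogram: Hypnogram
    bold: RegionTimeSeries
    eeg: np.ndarray
    eeg_fs_hz: float
    events_truth: EventList
    envelopes: dict
    physio: dict
    region_params: RegionParams


def simulate_recording(config: SimConfig) -> SyntheticRecording:
    """Generate a complete synchronised recording (all modalities)."""
    hyp = simulate_hypnogram(config)
    params = draw_region_params(config)
    bold = simulate_bold(config, hyp, params)
    eeg, fs, truth, envelopes = simulate_eeg(config, hyp)
    physio = simulate_physio(config)
    return SyntheticRecording(config=config, hypnogram=hyp, bold=bold,
                              eeg=eeg, eeg_fs_hz=fs, events_truth=truth,
                              envelopes=envelopes, physio=physio,
                              region_params=params)
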