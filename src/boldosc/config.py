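"""Simulation configuration: the study conditions the generator emulates."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .containers import STAGES, ValidationError

#: Stage -> (LF amplitude gain, HF amplitude gain). The low-frequency
#: oscillation is most prominent in intermediate (N2) sleep and attenuates
#: in deep (N3) sleep, mirroring spindle prevalence; the high-frequency
#: oscillation ramps up monotonically into N3, mirroring slow waves. The
#: duration-weighted wake->sleep power step is ~3.5x, placing the recovered
#: band-power increase in the 200-300% range reported for sleeping humans.
DEFAULT_STAGE_GAIN = {
    "W": (1.0, 1.0),
    "N1": (1.9, 1.45),
    "N2": (2.0, 1.78),
    "N3": (1.7, 2.1),
    "R": (1.0, 1.0),
}

#: Spindle density by stage, events/min (N2 ~ two per minute).
DEFAULT_SPINDLE_RATE = {"W": 0.0, "N1": 0.5, "N2": 2.0, "N3": 1.0, "R": 0.0}
#: Slow-wave density by stage, events/min (N3 ~ seven per minute).
DEFAULT_SW_RATE = {"W": 0.0, "N1": 0.5, "N2": 2.0, "N3": 7.0, "R": 0.0}

#: Dwell times (minutes) of the default one-hour stage trajectory
#: W -> N1 -> N2 -> N3 -> N2 -> W.
DEFAULT_TRAJECTORY = (("W", 10.0), ("N1", 5.0), ("N2", 12.5),
                      ("N3", 15.0), ("N2", 7.5), ("W", 10.0))


@dataclass
class SimConfig:
    """Parameters of a synthetic simultaneous BOLD/EEG/physiology recording.

    Defaults encode the conditions the analysis targets: TR 2.08 s BOLD with
    a 1/f background plus stage-gated oscillations near 0.04-0.07 Hz and
    0.15-0.18 Hz; EEG with 11-16 Hz spindle bursts (~2/min in N2) and
    0.5-4 Hz slow waves (~7/min in N3); respiration near 0.25 Hz and cardiac
    pulse near 1 Hz with slow rate/depth/volume variability.
    """

    seed: int = 0
    duration_s: float = 3600.0
    tr_s: float = 2.08
    n_regions: int = 12
    eeg_fs_hz: float = 250.0
    physio_fs_hz: float = 50.0
    n_eeg_channels: int = 1

    # Per-region oscillation frequencies; drawn uniformly in these ranges
    # unless explicit per-region arrays are given.
    lf_freq_range_hz: tuple = (0.04, 0.07)
    hf_freq_range_hz: tuple = (0.15, 0.18)
    lf_freq_hz: np.ndarray | None = None
    hf_freq_hz: np.ndarray | None = None

    stage_gain: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_GAIN))
    gain_ramp_s: float = 20.0            # half-cosine ramp at stage changes
    onset_lag_s: np.ndarray | None = None   # per-region delay of LF gating
    offset_lag_s: np.ndarray | None = None  # per-region delay of HF gating

    one_over_f_exponent: float = 1.0
    background_sigma: float = 1.0

    spindle_rate_per_min: dict = field(default_factory=lambda: dict(DEFAULT_SPINDLE_RATE))
    sw_rate_per_min: dict = field(default_factory=lambda: dict(DEFAULT_SW_RATE))
    spindle_freq_range_hz: tuple = (11.0, 16.0)
    spindle_duration_range_s: tuple = (0.5, 2.0)
    sw_duration_range_s: tuple = (1.0, 1.6)
    spindle_amp_rms_factor: float = 5.0  # burst RMS vs sigma-band background RMS
    sw_amp_peak_factor: float = 5.0      # trough depth vs delta-band background RMS
    # Infra-slow envelopes modulating event rates. Note the reported event
    # periodicities (2/min, 7/min) and the BOLD oscillation bands are not
    # numerically identical; both knobs are exposed and deliberately decoupled.
    spindle_env_freq_hz: float = 0.055
    sw_env_freq_hz: float = 0.165
    env_mod_depth: float = 0.8
    max_event_occupancy: float = 0.5     # reject configs busier than this

    resp_freq_hz: float = 0.25
    cardiac_freq_hz: float = 1.0
    resp_rate_var: float = 0.08          # relative sd of slow rate variability
    resp_depth_var: float = 0.15
    cardiac_rate_var: float = 0.05

    epoch_s: float = 30.0
    trajectory: tuple = DEFAULT_TRAJECTORY

    def __post_init__(self):
        if not self.tr_s > 0:
            raise ValidationError("tr_s must be positive")
        if self.duration_s < 10 * 104.0:
            raise ValidationError(
                "duration_s must cover at least ten 104-s analysis windows"
            )
        if self.eeg_fs_hz < 2 * 16.0:
            raise ValidationError("eeg_fs_hz must satisfy Nyquist for 16 Hz spindles")
        nyq = 0.5 / self.tr_s
        for name, rng in (("lf_freq_range_hz", self.lf_freq_range_hz),
                          ("hf_freq_range_hz", self.hf_freq_range_hz)):
            if rng[1] >= nyq:
                raise ValidationError(f"{name} exceeds BOLD Nyquist {nyq:.4f} Hz")
        if not self.lf_freq_range_hz[1] < self.hf_freq_range_hz[0]:
            raise ValidationError("LF frequencies must lie below HF frequencies")
        for stage, gains in self.stage_gain.items():
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r} in stage_gain")
            if min(gains) < 0:
                raise ValidationError("stage gains must be non-negative")
        if self.resp_freq_hz >= 0.5 * self.physio_fs_hz or \
                self.cardiac_freq_hz >= 0.5 * self.physio_fs_hz:
            raise ValidationError("physio frequencies must be below fs/2")

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("lf_freq_hz", "hf_freq_hz", "onset_lag_s", "offset_lag_s"):
            if d[key] is not None:
                d[key] = [float(v) for v in np.asarray(d[key]).ravel()]
        d["trajectory"] = [[s, float(m)] for s, m in d["trajectory"]]
        for key in ("lf_freq_range_hz", "hf_freq_range_hz", "spindle_freq_range_hz",
                    "spindle_duration_range_s", "sw_duration_range_s"):
            d[key] = [float(v) for v in d[key]]
        d["stage_gain"] = {s: [float(g) for g in gg] for s, gg in d["stage_gain"].items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "trajectory" in d:
            d["trajectory"] = tuple((s, float(m)) for s, m in d["trajectory"])
        for key in ("lf_freq_range_hz", "hf_freq_range_hz", "spindle_freq_range_hz",
                    "spindle_duration_range_s", "sw_duration_range_s"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("lf_freq_hz", "hf_freq_hz", "onset_lag_s", "offset_lag_s"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if "stage_gain" in d:
            d["stage_gain"] = {s: tuple(g) for s, g in d["stage_gain"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
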