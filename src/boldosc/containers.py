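"""Core data containers shared by all analysis stages.

Conventions
-----------
* All times are seconds from recording start (``t0_s``).
* Intervals are half-open ``[start, end)``.
* Sliding windows are identified by their center time,
  ``center = t0 + start_index * dt + window_len_s / 2``,
  so that windows computed at different sampling rates (BOLD volumes, EEG
  samples, 2.08-s activity bins) align exactly when they span the same
  wall-clock interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised hypnogram stage labels (AASM, no REM sub-stages).
STAGES = ("W", "N1", "N2", "N3", "R")
#: NREM sleep stages.
NREM_STAGES = ("N1", "N2", "N3")
#: Label given to sliding windows that straddle a stage boundary.
TRANSITION_LABEL = "T"


class ValidationError(ValueError):
    """Input data violated a structural contract."""


class InsufficientDataError(RuntimeError):
    """A quantity is absent for a stated reason (e.g. too few windows).

    Raised instead of silently returning zeros; the message carries the
    reason so batch callers can record it.
    """


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class RegionTimeSeries:
    """Region-by-volume BOLD matrix with its sampling interval.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_volumes)
        BOLD signal, arbitrary units. No missing samples allowed.
    tr_s : float
        Repetition time (volume spacing) in seconds.
    region_labels : sequence of str
        Unique region identifiers, one per row.
    t0_s : float
        Acquisition time of the first volume.
    """

    values: np.ndarray
    tr_s: float
    region_labels: list[str] = None
    t0_s: float = 0.0

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "values")
        if not self.tr_s > 0:
            raise ValidationError(f"tr_s must be positive, got {self.tr_s}")
        if self.region_labels is None:
            self.region_labels = [f"region{i:02d}" for i in range(self.values.shape[0])]
        self.region_labels = [str(r) for r in self.region_labels]
        if len(self.region_labels) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.region_labels)} labels for {self.values.shape[0]} regions"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValidationError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_volumes) * self.tr_s

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s


# Aliases accepted by hypnogram readers, normalised to AASM labels.
STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "AWAKE": "W", "S0": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3", "4": "N3", "SWS": "N3",
    "R": "R", "REM": "R", "N5": "R", "5": "R",
}


def normalize_stage(token: str) -> str:
    key = str(token).strip().upper()
    if key not in STAGE_ALIASES:
        raise ValidationError(f"unknown sleep stage token {token!r}")
    return STAGE_ALIASES[key]


@dataclass
class Hypnogram:
    """Sleep stage per fixed-length scoring epoch."""

    stages: np.ndarray
    epoch_s: float = 30.0

    def __post_init__(self):
        stages = [normalize_stage(s) for s in np.asarray(self.stages).ravel()]
        if len(stages) == 0:
            raise ValidationError("hypnogram has no epochs")
        self.stages = np.asarray(stages, dtype=object)
        if not self.epoch_s > 0:
            raise ValidationError("epoch_s must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def stage_at(self, t_s):
        """Stage at time(s) ``t_s`` (clipped to the scored span)."""
        idx = np.clip(
            (np.asarray(t_s, dtype=float) // self.epoch_s).astype(int),
            0, self.n_epochs - 1,
        )
        return self.stages[idx]

    def per_volume(self, n_volumes: int, tr_s: float, t0_s: float = 0.0) -> np.ndarray:
        """Stage label for each of ``n_volumes`` samples spaced ``tr_s`` apart."""
        return self.stage_at(t0_s + np.arange(n_volumes) * tr_s)

    def contains(self, stage: str) -> bool:
        return normalize_stage(stage) in set(self.stages)


@dataclass
class Spectrogram:
    """Windowed power by (region, frequency, window).

    ``power`` has units of signal-units squared per frequency bin; a
    unit-amplitude sinusoid at a bin frequency contributes total band power
    0.5 regardless of the taper (amplitude normalisation). The DC bin is
    excluded.
    """

    power: np.ndarray  # (n_regions, n_freqs, n_windows)
    freqs_hz: np.ndarray
    window_centers_s: np.ndarray
    window_len_volumes: int
    step_volumes: int
    tr_s: float
    region_labels: list[str]
    taper: str = "hamming"

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.window_centers_s = np.asarray(self.window_centers_s, dtype=float)
        if self.power.ndim != 3:
            raise ValidationError("power must be (region, freq, window)")
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValidationError("spectrogram power must be finite and non-negative")

    @property
    def n_windows(self) -> int:
        return self.power.shape[2]

    @property
    def window_len_s(self) -> float:
        return self.window_len_volumes * self.tr_s


@dataclass
class OscillationBand:
    """A detected spectral peak and its integration band."""

    kind: str                      # "LF" or "HF"
    search_range_hz: tuple
    peak_freq_hz: float
    band_hz: tuple                 # (lo, hi), peak +/- half-width, truncated

    def __post_init__(self):
        if self.kind not in ("LF", "HF"):
            raise ValidationError(f"band kind must be LF or HF, got {self.kind!r}")
        lo, hi = self.search_range_hz
        if not (lo <= self.peak_freq_hz <= hi):
            raise ValidationError("peak frequency outside its search range")


@dataclass
class PowerTrace:
    """Band power (or any windowed scalar) per region per sliding window."""

    values: np.ndarray  # (n_regions, n_windows)
    window_centers_s: np.ndarray
    region_labels: list[str]
    band: OscillationBand | None = None
    stage_labels: np.ndarray | None = None  # per-window stage, incl. "T"

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "values")
        self.window_centers_s = np.asarray(self.window_centers_s, dtype=float)
        if self.values.shape[1] != len(self.window_centers_s):
            raise ValidationError("trace/window-center length mismatch")


EVENT_TYPES = ("spindle", "slow_wave")
EVENT_COLUMNS = ["onset_s", "duration_s", "type", "channel", "amplitude"]


@dataclass
class EventList:
    """Detected (or injected) spindle / slow-wave events.

    Stored as a DataFrame with columns ``onset_s, duration_s, type, channel,
    amplitude``, sorted by onset.
    """

    events: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.events, columns=EVENT_COLUMNS).copy()
        if len(df) and not (df["duration_s"] > 0).all():
            raise ValidationError("event durations must be positive")
        if len(df) and not df["type"].isin(EVENT_TYPES).all():
            bad = sorted(set(df["type"]) - set(EVENT_TYPES))
            raise ValidationError(f"unknown event types: {bad}")
        self.events = df.sort_values("onset_s", kind="stable").reset_index(drop=True)

    @classmethod
    def from_arrays(cls, onset_s, duration_s, type, channel="eeg", amplitude=np.nan):
        n = len(np.atleast_1d(onset_s))
        return cls(pd.DataFrame({
            "onset_s": np.atleast_1d(onset_s).astype(float),
            "duration_s": np.atleast_1d(duration_s).astype(float),
            "type": np.broadcast_to(np.asarray(type, dtype=object), (n,)).copy(),
            "channel": np.broadcast_to(np.asarray(channel, dtype=object), (n,)).copy(),
            "amplitude": np.broadcast_to(np.asarray(amplitude, dtype=float), (n,)).copy(),
        }))

    @classmethod
    def empty(cls):
        return cls(pd.DataFrame(columns=EVENT_COLUMNS))

    def select(self, type: str) -> "EventList":
        return EventList(self.events[self.events["type"] == type])

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_duration_s(self) -> float:
        return float(self.events["duration_s"].sum())


@dataclass
class ActivityTrace:
    """Event activity: seconds of event time per 2.08-s bin, or its
    Hamming-weighted aggregate per 104-s sliding window."""

    values: np.ndarray
    bin_s: float
    t0_s: float = 0.0
    kind: str = "binned"  # "binned" | "windowed"
    window_centers_s: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("activity trace must be 1-D")
        if np.any(self.values < 0):
            raise ValidationError("activity must be non-negative")
        if self.kind == "windowed" and self.window_centers_s is None:
            raise ValidationError("windowed trace needs window centers")


@dataclass
class TransitionSegment:
    """A hypnogram-derived wake--sleep transition interval."""

    kind: str            # "falling_asleep" | "waking"
    t_start_s: float
    t_end_s: float
    rule: str = ""

    def __post_init__(self):
        if self.kind not in ("falling_asleep", "waking"):
            raise ValidationError(f"unknown transition kind {self.kind!r}")
        if not self.t_end_s > self.t_start_s:
            raise ValidationError("segment must have positive length")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class LagMap:
    """Per-region lead/lag of oscillation onset or offset.

    Positive lag means the region *leads* (earlier onset/offset); negative
    means it lags. Region lags are zero-centered by construction.
    """

    region_labels: list[str]
    lag_s: np.ndarray
    n_reliable_pairs: np.ndarray
    band_kind: str              # "LF" | "HF"
    transition_kind: str        # "falling_asleep" | "waking"
    pairwise_lag_s: np.ndarray | None = None  # (R, R), lag[a,b] > 0: a leads b
    peak_r: np.ndarray | None = None


@dataclass
class PhysioRegressors:
    """Volume-by-regressor nuisance matrix (RETROICOR-style)."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.matrix = _as_2d_float(self.matrix, "regressor matrix")
        if self.matrix.shape[1] != len(self.names):
            raise ValidationError("regressor name/column mismatch")


def window_centers(n_samples: int, window_len: int, step: int,
                   dt_s: float, t0_s: float = 0.0) -> np.ndarray:
    """Center times of sliding windows over ``n_samples`` samples.

    Window ``i`` covers samples ``[i*step, i*step + window_len)`` and is
    centered at ``t0 + i*step*dt + window_len*dt/2``.
    """
    n_windows = (n_samples - window_len) // step + 1
    if n_windows < 1:
        raise ValidationError(
            f"series of {n_samples} samples shorter than one window of {window_len}"
        )
    starts = np.arange(n_windows) * step
    return t0_s + starts * dt_s + 0.5 * window_len * dt_s
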