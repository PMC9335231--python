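"""Sliding-window spectral analysis of BOLD time series.

Pipeline: spectrogram -> stage-averaged spectra -> 1/f trend fit ->
band-peak detection -> oscillation-power traces -> wake-to-sleep percent
change. The window contract (104-s Hamming windows stepped one volume at a
time at TR 2.08 s) is shared with every other windowed quantity in the
package so that traces can be correlated sample-for-sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from numpy.lib.stride_tricks import sliding_window_view

from .containers import (Hypnogram, InsufficientDataError, OscillationBand,
                         PowerTrace, RegionTimeSeries, Spectrogram,
                         TRANSITION_LABEL, ValidationError, window_centers)

#: Default window contract (50 volumes of 2.08 s = 104 s, one-volume step).
WINDOW_VOLUMES = 50
STEP_VOLUMES = 1

#: Default peak search ranges. The low-frequency oscillation lives below
#: 0.1 Hz (typically 0.04-0.07 Hz) and the high-frequency one above
#: (typically 0.15-0.18 Hz); the ranges are set slightly wider than those
#: typical brackets while leaving enough bins outside them to anchor the
#: aperiodic 1/f fit.
LF_SEARCH_HZ = (0.03, 0.08)
HF_SEARCH_HZ = (0.13, 0.20)
#: Aperiodic-fit range: the full analysis band minus the two search ranges.
#: At the 1/104 Hz resolution this keeps 11 bins to anchor the trend.
FIT_RANGE_HZ = (0.005, 0.23)
PEAK_HALF_WIDTH_HZ = {"LF": 0.015, "HF": 0.03}
PEAK_THRESHOLD_SD = 2.0
MIN_PEAK_RESIDUAL = 0.3  # log10 units: peak must double the 1/f trend
MIN_WINDOWS = 30
MIN_STAGE_FRACTION = 0.8


def hamming_taper(n: int) -> np.ndarray:
    """Symmetric Hamming taper w[k] = 0.54 - 0.46 cos(2 pi k / (n-1))."""
    return np.hamming(n)


def _windowed_view(values: np.ndarray, window: int, step: int) -> np.ndarray:
    if values.shape[-1] < window:
        raise ValidationError(
            f"series of {values.shape[-1]} samples shorter than one "
            f"window of {window}"
        )
    return sliding_window_view(values, window, axis=-1)[..., ::step, :]


def sliding_spectrogram(ts: RegionTimeSeries,
                        window_volumes: int = WINDOW_VOLUMES,
                        step_volumes: int = STEP_VOLUMES) -> Spectrogram:
    """Sliding-window FFT power spectrogram with a Hamming taper.

    Each window is demeaned (taper-weighted mean, so the tapered DC
    component is exactly zero and dropping the DC bin loses no power),
    tapered, and Fourier transformed. Power is amplitude-normalised by the
    taper's coherent gain so a unit-amplitude sinusoid at a bin frequency
    yields power 0.5 at that bin in every window, independent of the taper
    (the taper's side lobes additionally leak a taper-dependent fraction
    into adjacent bins). The DC bin is dropped.
    """
    taper = hamming_taper(window_volumes)
    win = _windowed_view(ts.values, window_volumes, step_volumes)
    wmean = (win * taper).sum(axis=-1, keepdims=True) / taper.sum()
    win = win - wmean
    X = np.fft.rfft(win * taper, axis=-1)
    # one-sided amplitude normalisation: 2 |X|^2 / (sum w)^2, no doubling
    # at DC or (even-length) Nyquist
    power = 2.0 * (X.real ** 2 + X.imag ** 2) / taper.sum() ** 2
    power[..., 0] /= 2.0
    if window_volumes % 2 == 0:
        power[..., -1] /= 2.0
    power = np.moveaxis(power[..., 1:], -1, 1)  # drop DC -> (R, F, W)
    freqs = np.fft.rfftfreq(window_volumes, d=ts.tr_s)[1:]
    centers = window_centers(ts.n_volumes, window_volumes, step_volumes,
                             ts.tr_s, ts.t0_s)
    return Spectrogram(power=power, freqs_hz=freqs, window_centers_s=centers,
                       window_len_volumes=window_volumes,
                       step_volumes=step_volumes, tr_s=ts.tr_s,
                       region_labels=list(ts.region_labels))


def average_spectrograms(specs: list[Spectrogram],
                         region_labels: list[str]) -> Spectrogram:
    """Mean of per-voxel (or per-member) spectrograms, one output region each.

    Regional spectra are defined as the average of the member voxels'
    spectrograms, not the spectrogram of the averaged series.
    """
    first = specs[0]
    power = np.stack([s.power.mean(axis=0) for s in specs])
    return Spectrogram(power=power, freqs_hz=first.freqs_hz,
                       window_centers_s=first.window_centers_s,
                       window_len_volumes=first.window_len_volumes,
                       step_volumes=first.step_volumes, tr_s=first.tr_s,
                       region_labels=list(region_labels))


def window_stages(hyp: Hypnogram, spec_or_centers, tr_s: float | None = None,
                  window_len_s: float | None = None,
                  min_fraction: float = MIN_STAGE_FRACTION) -> np.ndarray:
    """Assign one stage label per sliding window.

    A window takes the stage of the majority of its volumes; windows where
    no single stage covers at least ``min_fraction`` of the volumes are
    labelled ``"T"`` (transition) and are excluded from stage averages.
    """
    if isinstance(spec_or_centers, Spectrogram):
        centers = spec_or_centers.window_centers_s
        tr_s = spec_or_centers.tr_s
        window_len_s = spec_or_centers.window_len_s
    else:
        centers = np.asarray(spec_or_centers, dtype=float)
        if tr_s is None or window_len_s is None:
            raise ValidationError("tr_s and window_len_s required with raw centers")
    n_vol = int(round(window_len_s / tr_s))
    offsets = (np.arange(n_vol) - (n_vol - 1) / 2.0) * tr_s
    labels = np.empty(len(centers), dtype=object)
    for i, c in enumerate(centers):
        st = hyp.stage_at(c + offsets)
        uniq, counts = np.unique(st.astype(str), return_counts=True)
        k = int(np.argmax(counts))
        labels[i] = uniq[k] if counts[k] / n_vol >= min_fraction else TRANSITION_LABEL
    return labels


def stage_average_spectrum(spec: Spectrogram, hyp: Hypnogram, stage: str,
                           min_windows: int = MIN_WINDOWS,
                           stage_labels: np.ndarray | None = None) -> np.ndarray:
    """Per-region mean spectrum over the windows labelled ``stage``.

    Raises :class:`InsufficientDataError` (absent-with-reason) when the
    stage has fewer than ``min_windows`` non-transition windows.
    """
    if stage_labels is None:
        stage_labels = window_stages(hyp, spec)
    mask = stage_labels == stage
    n = int(mask.sum())
    if n < min_windows:
        raise InsufficientDataError(
            f"stage {stage}: only {n} windows (< {min_windows} required)"
        )
    return spec.power[:, :, mask].mean(axis=2)


@dataclass
class OneOverFFit:
    """Robust log-log line fit of the aperiodic 1/f trend."""

    slope: float
    intercept: float              # log10 power at 1 Hz
    residual: np.ndarray          # log10(power) - fitted line, all bins
    fit_mask: np.ndarray          # bins used for the fit
    n_excluded_nonpositive: int

    def robust_residual_sd(self) -> float:
        r = self.residual[self.fit_mask]
        return float(1.4826 * np.median(np.abs(r - np.median(r))))


def fit_one_over_f(freqs_hz: np.ndarray, power: np.ndarray,
                   fit_range_hz: tuple = FIT_RANGE_HZ,
                   exclude_ranges_hz: tuple = (LF_SEARCH_HZ, HF_SEARCH_HZ)
                   ) -> OneOverFFit:
    """Fit log10(power) ~ slope * log10(f) + intercept, robustly.

    The fit spans ``fit_range_hz`` minus the peak search ranges, so spectral
    peaks do not drag the aperiodic trend; an iteratively reweighted
    least-squares (Huber) line resists any residual contamination.
    Non-positive power bins are excluded and counted.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs_hz >= fit_range_hz[0]) & (freqs_hz <= fit_range_hz[1])
    for lo, hi in exclude_ranges_hz:
        mask &= ~((freqs_hz >= lo) & (freqs_hz <= hi))
    positive = power > 0
    n_nonpos = int((mask & ~positive).sum())
    mask &= positive
    if mask.sum() < 10:
        raise ValidationError(
            f"only {int(mask.sum())} usable bins for the 1/f fit (need >= 10)"
        )
    lx = np.log10(freqs_hz[mask])
    ly = np.log10(power[mask])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.RLM(ly, sm.add_constant(lx), M=sm.robust.norms.HuberT()).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    with np.errstate(divide="ignore"):
        log_power = np.where(positive, np.log10(np.where(positive, power, 1.0)),
                             -np.inf)
    residual = log_power - (intercept + slope * np.log10(freqs_hz))
    return OneOverFFit(slope=slope, intercept=intercept, residual=residual,
                       fit_mask=mask, n_excluded_nonpositive=n_nonpos)


def detect_band_peaks(freqs_hz: np.ndarray, fit: OneOverFFit,
                      lf_search_hz: tuple = LF_SEARCH_HZ,
                      hf_search_hz: tuple = HF_SEARCH_HZ,
                      threshold_sd: float = PEAK_THRESHOLD_SD,
                      min_residual: float = MIN_PEAK_RESIDUAL,
                      half_width_hz: dict = None) -> dict:
    """Locate LF and HF spectral peaks in the 1/f-fit residual.

    A peak is the frequency of the maximum residual within its search range,
    reported only when the residual exceeds both ``threshold_sd`` robust
    standard deviations of the fit-range residuals and the absolute floor
    ``min_residual`` (log10 units; the default 0.3 dex demands at least
    twice the power of the aperiodic trend, which suppresses chance
    excursions that the small-sample robust SD alone does not). The
    integration band is the peak +/- a kind-specific half-width, truncated
    to the search range. A missing peak is an explicit ``None``.
    """
    if half_width_hz is None:
        half_width_hz = PEAK_HALF_WIDTH_HZ
    sd = fit.robust_residual_sd()
    threshold = max(threshold_sd * sd, min_residual)
    out = {}
    for kind, (lo, hi) in (("LF", lf_search_hz), ("HF", hf_search_hz)):
        in_range = (freqs_hz >= lo) & (freqs_hz <= hi)
        if not in_range.any():
            out[kind] = None
            continue
        idx = np.flatnonzero(in_range)
        k = idx[int(np.argmax(fit.residual[idx]))]
        if not np.isfinite(fit.residual[k]) or fit.residual[k] <= threshold:
            out[kind] = None
            continue
        peak = float(freqs_hz[k])
        hw = half_width_hz[kind]
        out[kind] = OscillationBand(kind=kind, search_range_hz=(lo, hi),
                                    peak_freq_hz=peak,
                                    band_hz=(max(lo, peak - hw),
                                             min(hi, peak + hw)))
    return out


def band_power_trace(spec: Spectrogram, band: OscillationBand,
                     stage_labels: np.ndarray | None = None,
                     region: int | None = None) -> PowerTrace:
    """Mean power over the band's frequency bins, per window (per region)."""
    lo, hi = band.band_hz
    mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not mask.any():
        warnings.warn("band narrower than one frequency bin; using nearest bin")
        mask = np.zeros_like(mask)
        mask[int(np.argmin(np.abs(spec.freqs_hz - band.peak_freq_hz)))] = True
    power = spec.power if region is None else spec.power[[region]]
    labels = (spec.region_labels if region is None
              else [spec.region_labels[region]])
    return PowerTrace(values=power[:, mask, :].mean(axis=1),
                      window_centers_s=spec.window_centers_s,
                      region_labels=list(labels), band=band,
                      stage_labels=stage_labels)


def detect_region_bands(spec: Spectrogram, stage_labels: np.ndarray,
                        stages: tuple = ("N1", "N2", "N3"),
                        min_windows: int = MIN_WINDOWS,
                        **peak_kwargs) -> list[dict]:
    """Per-region LF/HF band detection from the sleep-averaged spectrum.

    Peak frequencies differ region by region, so each region's oscillation
    band is centred on its own detected peak (the regional analysis), not on
    a group-level one. Returns one ``{"LF": band|None, "HF": band|None}``
    per region.
    """
    mask = np.isin(stage_labels, list(stages))
    if int(mask.sum()) < min_windows:
        raise InsufficientDataError(
            f"stages {stages}: only {int(mask.sum())} windows"
        )
    spectra = spec.power[:, :, mask].mean(axis=2)
    out = []
    for r in range(spectra.shape[0]):
        fit = fit_one_over_f(spec.freqs_hz, spectra[r])
        out.append(detect_band_peaks(spec.freqs_hz, fit, **peak_kwargs))
    return out


def region_band_power_trace(spec: Spectrogram, region_bands: list[dict],
                            kind: str,
                            stage_labels: np.ndarray | None = None):
    """Band-power trace using each region's own band for one peak kind.

    Regions without a detected peak of that kind are dropped; returns the
    trace plus the indices of the regions retained.
    """
    rows, labels, kept = [], [], []
    for r, bands in enumerate(region_bands):
        band = bands.get(kind)
        if band is None:
            continue
        lo, hi = band.band_hz
        bmask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
        if not bmask.any():
            bmask = np.zeros_like(bmask)
            bmask[int(np.argmin(np.abs(spec.freqs_hz - band.peak_freq_hz)))] = True
        rows.append(spec.power[r][bmask].mean(axis=0))
        labels.append(spec.region_labels[r])
        kept.append(r)
    if not rows:
        raise InsufficientDataError(f"no region has a detected {kind} peak")
    trace = PowerTrace(values=np.asarray(rows),
                       window_centers_s=spec.window_centers_s,
                       region_labels=labels, stage_labels=stage_labels)
    return trace, kept


def percent_power_change(trace: PowerTrace, hyp: Hypnogram | None = None,
                         baseline_stage: str = "W",
                         target_stages: tuple = ("N1", "N2", "N3"),
                         min_windows: int = MIN_WINDOWS,
                         stage_labels: np.ndarray | None = None) -> np.ndarray:
    """Percent change in band power from baseline to target stages, per region.

    100 * (mean target power - mean baseline power) / mean baseline power.
    Invariant to global rescaling of the input series.
    """
    if stage_labels is None:
        stage_labels = trace.stage_labels
    if stage_labels is None:
        if hyp is None:
            raise ValidationError("stage labels or a hypnogram are required")
        stage_labels = window_stages(
            hyp, trace.window_centers_s,
            tr_s=float(np.diff(trace.window_centers_s).min()),
            window_len_s=WINDOW_VOLUMES * float(np.diff(trace.window_centers_s).min()))
    base_mask = stage_labels == baseline_stage
    targ_mask = np.isin(stage_labels, list(target_stages))
    for name, mask in (("baseline", base_mask), ("target", targ_mask)):
        if int(mask.sum()) < min_windows:
            raise InsufficientDataError(
                f"{name} stages have {int(mask.sum())} windows (< {min_windows})"
            )
    base = trace.values[:, base_mask].mean(axis=1)
    targ = trace.values[:, targ_mask].mean(axis=1)
    if np.any(base <= 0):
        raise ValidationError("baseline mean power is non-positive")
    return 100.0 * (targ - base) / base
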