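"""Physiological noise regressors, nuisance regression, and confound spectra.

Implements a RETROICOR-style regressor set (cardiac/respiratory phase
expanded to sin/cos of orders 1-2, plus beat-to-beat rate, respiratory
volume and depth), least-squares removal of those regressors from BOLD,
alias-frequency computation for slowly sampled physiological rhythms, and
sliding-window band power of physiological series for confound checks.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.interpolate import interp1d

from .containers import (PhysioRegressors, PowerTrace, RegionTimeSeries,
                         ValidationError)
from .events import eeg_band_power_trace

CARDIAC_REFRACTORY_S = 0.35
RESP_REFRACTORY_S = 1.5

#: Confound band definitions (Hz offsets / absolute ranges).
RESP_ACTIVITY_HALFWIDTH_HZ = 0.1     # respiration frequency +/- 0.1 Hz
CARDIAC_ACTIVITY_HALFWIDTH_HZ = 0.4  # cardiac pulse frequency +/- 0.4 Hz
RATE_LF_BAND_HZ = (0.04, 0.15)
RATE_HF_BAND_HZ = (0.15, 0.4)


def _find_cycle_peaks(x: np.ndarray, fs: float, refractory_s: float) -> np.ndarray:
    height = np.quantile(x, 0.6)
    peaks, _ = signal.find_peaks(x, height=height,
                                 distance=max(1, int(round(refractory_s * fs))))
    return peaks


def _phase_from_peaks(n: int, fs: float, peaks: np.ndarray) -> np.ndarray:
    """Linear 0 -> 2pi phase between successive peaks, extrapolated at ends."""
    t = np.arange(n) / fs
    tp = peaks / fs
    # unwrapped phase: 2pi k at the k-th peak
    unwrapped = interp1d(tp, 2 * np.pi * np.arange(len(tp)),
                         kind="linear", fill_value="extrapolate")(t)
    return np.mod(unwrapped, 2 * np.pi)


def _respiratory_phase(x: np.ndarray, fs: float) -> np.ndarray:
    """Amplitude-histogram respiratory phase (inhalation vs exhalation signed).

    The trace amplitude is converted to its empirical CDF rank and signed by
    the derivative, yielding a phase in (-pi, pi] that advances through a
    full cycle per breath regardless of waveform shape.
    """
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = (np.arange(len(x)) + 0.5) / len(x)
    slope = np.gradient(signal.savgol_filter(x, max(5, int(fs) | 1), 2))
    return np.pi * ranks * np.where(slope >= 0, 1.0, -1.0)


def _beat_rate_series(peaks: np.ndarray, fs: float, t_out: np.ndarray) -> np.ndarray:
    tp = peaks / fs
    intervals = np.diff(tp)
    mid = 0.5 * (tp[1:] + tp[:-1])
    rate = 1.0 / intervals
    return interp1d(mid, rate, kind="linear", bounds_error=False,
                    fill_value=(rate[0], rate[-1]))(t_out)


def build_regressors(resp: np.ndarray, cardiac: np.ndarray, fs_physio: float,
                     tr_s: float, n_volumes: int,
                     phase_orders: int = 2,
                     volume_window_s: float = 6.0) -> PhysioRegressors:
    """Volume-sampled physiological nuisance regressors.

    Columns: respiratory phase sin/cos (orders 1..``phase_orders``),
    respiratory rate, respiratory volume (windowed SD), respiratory depth
    (cycle peak-to-trough), cardiac phase sin/cos, cardiac rate. All series
    are sampled at volume midpoints; beat-wise quantities are linearly
    interpolated.
    """
    resp = np.asarray(resp, dtype=float)
    cardiac = np.asarray(cardiac, dtype=float)
    if len(resp) / fs_physio < n_volumes * tr_s - tr_s:
        raise ValidationError("physio traces shorter than the BOLD acquisition")
    t_vol = (np.arange(n_volumes) + 0.5) * tr_s

    card_peaks = _find_cycle_peaks(cardiac, fs_physio, CARDIAC_REFRACTORY_S)
    resp_peaks = _find_cycle_peaks(resp, fs_physio, RESP_REFRACTORY_S)
    if len(card_peaks) < 2 or len(resp_peaks) < 2:
        raise ValidationError("fewer than two detected cardiac or respiratory cycles")

    card_phase = _phase_from_peaks(len(cardiac), fs_physio, card_peaks)
    resp_phase = _respiratory_phase(resp, fs_physio)

    idx_vol = np.minimum((t_vol * fs_physio).astype(int), len(resp) - 1)
    cols, names = [], []
    for order in range(1, phase_orders + 1):
        for fn, fname in ((np.sin, "sin"), (np.cos, "cos")):
            cols.append(fn(order * resp_phase[idx_vol]))
            names.append(f"resp_phase_{fname}{order}")
    cols.append(_beat_rate_series(resp_peaks, fs_physio, t_vol))
    names.append("resp_rate")

    # respiratory volume: windowed SD of the raw trace
    win = max(1, int(round(volume_window_s * fs_physio)))
    sq = signal.convolve(resp ** 2, np.ones(win) / win, mode="same")
    mu = signal.convolve(resp, np.ones(win) / win, mode="same")
    vol = np.sqrt(np.maximum(sq - mu ** 2, 0.0))
    cols.append(vol[idx_vol])
    names.append("resp_volume")

    # respiratory depth: peak-to-trough per cycle, interpolated
    troughs = _find_cycle_peaks(-resp, fs_physio, RESP_REFRACTORY_S)
    depth_t, depth_v = [], []
    for p0, p1 in zip(resp_peaks[:-1], resp_peaks[1:]):
        seg = troughs[(troughs > p0) & (troughs < p1)]
        if len(seg):
            depth_t.append(0.5 * (p0 + p1) / fs_physio)
            depth_v.append(resp[p0] - resp[seg[0]])
    if len(depth_v) >= 2:
        depth = interp1d(depth_t, depth_v, kind="linear", bounds_error=False,
                         fill_value=(depth_v[0], depth_v[-1]))(t_vol)
    else:
        depth = np.full(n_volumes, np.ptp(resp))
    cols.append(depth)
    names.append("resp_depth")

    for order in range(1, phase_orders + 1):
        for fn, fname in ((np.sin, "sin"), (np.cos, "cos")):
            cols.append(fn(order * card_phase[idx_vol]))
            names.append(f"cardiac_phase_{fname}{order}")
    cols.append(_beat_rate_series(card_peaks, fs_physio, t_vol))
    names.append("cardiac_rate")

    return PhysioRegressors(matrix=np.column_stack(cols), names=names)


def regress_out(ts: RegionTimeSeries, regressors: PhysioRegressors,
                rank_tol: float = 1e-10):
    """Residualise BOLD against [intercept, linear drift, regressors].

    Collinear columns are dropped (greedy QR pivoting) and reported.
    Residuals are orthogonal to the retained design to numerical precision,
    which also makes the operation idempotent.

    Returns (residual RegionTimeSeries, list of dropped regressor names).
    """
    if regressors.matrix.shape[0] != ts.n_volumes:
        raise ValidationError(
            f"{regressors.matrix.shape[0]} regressor rows for "
            f"{ts.n_volumes} volumes"
        )
    n = ts.n_volumes
    drift = np.linspace(-1, 1, n)
    design = np.column_stack([np.ones(n), drift, regressors.matrix])
    names = ["intercept", "drift"] + list(regressors.names)
    # greedy rank-revealing selection via pivoted QR
    _, R, piv = _pivoted_qr(design)
    diag = np.abs(np.diag(R))
    keep_rank = int((diag > rank_tol * diag[0]).sum())
    kept = sorted(piv[:keep_rank])
    dropped = [names[j] for j in sorted(piv[keep_rank:])]
    X = design[:, kept]
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values - (X @ beta).T
    out = RegionTimeSeries(values=resid, tr_s=ts.tr_s,
                           region_labels=list(ts.region_labels), t0_s=ts.t0_s)
    return out, dropped


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr
    Q, R, piv = qr(a, mode="economic", pivoting=True)
    return Q, R, piv


def alias_frequency(f_hz, tr_s: float):
    """Frequency to which ``f_hz`` aliases when sampled every ``tr_s``.

    Folds f into [0, fs/2] with fs = 1/tr: r = f mod fs; alias = r if
    r <= fs/2 else fs - r. E.g. a 1 Hz cardiac pulse sampled at TR 2.08 s
    appears at ~0.0385 Hz, inside the low-frequency BOLD band.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0) or tr_s <= 0:
        raise ValidationError("f must be >= 0 and tr_s > 0")
    fs = 1.0 / tr_s
    r = np.mod(f, fs)
    alias = np.where(r <= fs / 2, r, fs - r)
    return float(alias) if np.isscalar(f_hz) else alias


def physio_band_power(trace: np.ndarray, fs: float, band_hz: tuple,
                      window_s: float = 104.0, step_s: float = 2.08,
                      t0_s: float = 0.0) -> PowerTrace:
    """Sliding-window band power of a physiological series.

    Uses the BOLD window contract (104-s Hamming windows, 2.08-s steps)
    expressed in seconds at the series' native sampling rate, so bands above
    the BOLD Nyquist (e.g. respiration at 0.25 Hz) remain unaliased.
    """
    return eeg_band_power_trace(np.atleast_2d(trace), fs, band_hz,
                                window_s=window_s, step_s=step_s, t0_s=t0_s)


def principal_peak_frequency(trace: np.ndarray, fs: float,
                             window_s: float = 104.0,
                             step_s: float = 2.08) -> float:
    """Frequency of the principal (non-DC) peak of the time-averaged
    sliding-window spectrum of a 1-D series."""
    x = np.asarray(trace, dtype=float)
    n_win = int(round(window_s * fs))
    n_step = max(1, int(round(step_s * fs)))
    from numpy.lib.stride_tricks import sliding_window_view
    from .spectra import hamming_taper
    view = sliding_window_view(x, n_win)[::n_step]
    taper = hamming_taper(n_win)
    mean_power = None
    for i0 in range(0, len(view), 64):
        blk = view[i0:i0 + 64]
        blk = blk - blk.mean(axis=1, keepdims=True)
        X = np.fft.rfft(blk * taper, axis=1)
        p = (X.real ** 2 + X.imag ** 2).sum(axis=0)
        mean_power = p if mean_power is None else mean_power + p
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    mean_power[0] = 0.0
    return float(freqs[int(np.argmax(mean_power))])
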