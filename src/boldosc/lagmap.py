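"""Regional lead/lag of oscillation onset and offset at wake-sleep transitions.

Around a falling-asleep (or waking) transition, each region's oscillation
power trace rises (or falls) at a slightly different time. Time-lagged
cross-correlation between every pair of region traces gives a pairwise lag
matrix; the per-region summary is the row mean over reliable pairs (lag
projection), zero-centered, with positive values marking regions that lead
(earlier onset/offset).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import (Hypnogram, InsufficientDataError, LagMap, PowerTrace,
                         TransitionSegment, ValidationError)

NREM_SET = {"N1", "N2", "N3"}
DEEP_SET = {"N2", "N3"}
DEFAULT_MARGIN_S = 120.0
DEFAULT_MAX_LAG_S = 60.0
MIN_SUSTAINED_EPOCHS = 2


def _runs(stages: np.ndarray):
    """(start_epoch, end_epoch, stage) for each maximal run of equal stages."""
    runs = []
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            runs.append((start, i, stages[start]))
            start = i
    return runs


def extract_transition(hyp: Hypnogram, kind: str,
                       margin_s: float = DEFAULT_MARGIN_S,
                       min_sustained_epochs: int = MIN_SUSTAINED_EPOCHS
                       ) -> TransitionSegment:
    """Locate the falling-asleep or waking segment of a hypnogram.

    Falling asleep: from the last sustained wake epoch before the first
    sustained NREM run up to the first sustained N2/N3 epoch, padded by
    ``margin_s`` on both sides. Waking is the mirror image (last sustained
    N2/N3 before the first sustained wake run that follows sleep).
    Raises :class:`InsufficientDataError` when no such transition exists.
    """
    if kind not in ("falling_asleep", "waking"):
        raise ValidationError(f"unknown transition kind {kind!r}")
    stages = np.asarray(hyp.stages, dtype=object)
    runs = _runs(stages)
    sustained = [(s, e, st) for s, e, st in runs if e - s >= min_sustained_epochs]

    def epoch_time(e):
        return e * hyp.epoch_s

    if kind == "falling_asleep":
        nrem_idx = next((i for i, (s, e, st) in enumerate(sustained)
                         if st in NREM_SET), None)
        if nrem_idx is None:
            raise InsufficientDataError("no sustained NREM run in hypnogram")
        first_nrem_start = sustained[nrem_idx][0]
        w_runs = [(s, e) for s, e, st in sustained
                  if st == "W" and s < first_nrem_start]
        if not w_runs:
            raise InsufficientDataError("no sustained wake before sleep onset")
        last_w_epoch = w_runs[-1][1] - 1
        deep = next(((s, e) for s, e, st in sustained
                     if st in DEEP_SET and s >= first_nrem_start), None)
        if deep is None:
            raise InsufficientDataError("no sustained N2/N3 after sleep onset")
        t_start = epoch_time(last_w_epoch) - margin_s
        t_end = epoch_time(deep[0] + 1) + margin_s
        rule = (f"last sustained W epoch {last_w_epoch} to first sustained "
                f"N2/N3 epoch {deep[0]}, margin {margin_s:g} s")
    else:
        deep_runs = [(i, s, e) for i, (s, e, st) in enumerate(sustained)
                     if st in DEEP_SET]
        if not deep_runs:
            raise InsufficientDataError("no sustained N2/N3 sleep in hypnogram")
        w_after = None
        last_deep = None
        for i, s, e in deep_runs:
            nxt = next(((s2, e2) for s2, e2, st2 in sustained[i + 1:]
                        if st2 == "W"), None)
            if nxt is not None:
                w_after = nxt
                last_deep = (s, e)
        if w_after is None:
            raise InsufficientDataError("no sustained wake after sleep")
        t_start = epoch_time(last_deep[1] - 1) - margin_s
        t_end = epoch_time(w_after[0] + 1) + margin_s
        rule = (f"last sustained N2/N3 epoch {last_deep[1] - 1} to first "
                f"sustained W epoch {w_after[0]}, margin {margin_s:g} s")
    t_start = max(0.0, t_start)
    t_end = min(hyp.duration_s, t_end)
    return TransitionSegment(kind=kind, t_start_s=t_start, t_end_s=t_end,
                             rule=rule)


def pairwise_lag(a: np.ndarray, b: np.ndarray, step_s: float,
                 max_lag_s: float):
    """Lag maximising the normalized cross-correlation of two traces.

    Computes corr(a[t], b[t + k*step]) over integer shifts k within
    +/- ``max_lag_s``, then refines the peak by parabolic interpolation
    through its two neighbours. Positive lag means ``a`` leads ``b``
    (b is a delayed copy of a).

    Returns (lag_s, peak_r, reliable); ``reliable`` is False when the peak
    sits at the search boundary.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("traces must have equal length")
    max_shift = int(np.floor(max_lag_s / step_s))
    if 3 * max_lag_s > len(a) * step_s:
        raise ValidationError("max_lag_s must be at most a third of the segment")
    a = a - a.mean()
    b = b - b.mean()
    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.empty(len(shifts))
    for i, k in enumerate(shifts):
        if k >= 0:
            x, y = a[: len(a) - k], b[k:]
        else:
            x, y = a[-k:], b[: len(b) + k]
        sx, sy = x.std(), y.std()
        r[i] = ((x - x.mean()) @ (y - y.mean()) / (len(x) * sx * sy)
                if sx > 0 and sy > 0 else 0.0)
    j = int(np.argmax(r))
    reliable = 0 < j < len(shifts) - 1
    if reliable:
        denom = r[j - 1] - 2 * r[j] + r[j + 1]
        delta = 0.5 * (r[j - 1] - r[j + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    lag_s = (shifts[j] + delta) * step_s
    return float(lag_s), float(r[j]), bool(reliable)


def segment_mask(centers_s: np.ndarray, segment: TransitionSegment) -> np.ndarray:
    return (centers_s >= segment.t_start_s) & (centers_s < segment.t_end_s)


def build_lagmap(trace: PowerTrace, segment: TransitionSegment,
                 max_lag_s: float = DEFAULT_MAX_LAG_S,
                 band_kind: str = "LF",
                 baseline: np.ndarray | None = None,
                 min_regions: int = 3,
                 reference: str = "pairwise") -> LagMap:
    """Per-region lead/lag map of oscillation onset/offset in a segment.

    The full pairwise lag matrix is computed over the segment's windows
    (optionally after subtracting a per-region baseline power so the rising
    or falling edge dominates); each region's lag is the mean of its matrix
    row over reliable pairs, then zero-centered. Positive = leads.
    With ``reference="global_mean"`` each region is lagged against the mean
    trace instead (sensitivity mode).
    """
    mask = segment_mask(trace.window_centers_s, segment)
    values = trace.values[:, mask]
    if baseline is not None:
        values = values - np.asarray(baseline, dtype=float)[:, None]
    R = values.shape[0]
    if R < min_regions:
        raise InsufficientDataError(f"need >= {min_regions} regions, got {R}")
    centers = trace.window_centers_s[mask]
    if len(centers) < 2:
        raise InsufficientDataError("segment covers fewer than two windows")
    step_s = float(np.min(np.diff(centers)))
    if len(centers) * step_s < 3 * max_lag_s:
        raise InsufficientDataError(
            f"segment of {len(centers) * step_s:.0f} s too short for "
            f"max lag {max_lag_s:g} s"
        )
    pair = np.full((R, R), np.nan)
    peak = np.full((R, R), np.nan)
    np.fill_diagonal(pair, 0.0)
    np.fill_diagonal(peak, 1.0)
    if reference == "global_mean":
        ref = values.mean(axis=0)
        lags = np.full(R, np.nan)
        n_rel = np.zeros(R, dtype=int)
        for i in range(R):
            lag, r, ok = pairwise_lag(values[i], ref, step_s, max_lag_s)
            if ok:
                lags[i] = lag
                n_rel[i] = 1
    else:
        for i in range(R):
            for j in range(i + 1, R):
                lag, r, ok = pairwise_lag(values[i], values[j], step_s,
                                          max_lag_s)
                if ok:
                    pair[i, j] = lag
                    pair[j, i] = -lag
                    peak[i, j] = peak[j, i] = r
        n_rel = np.sum(np.isfinite(pair), axis=1) - 1
        enough = n_rel >= 1
        if int(enough.sum()) < min_regions:
            raise InsufficientDataError(
                "too few regions with reliable pairwise lags"
            )
        # row mean including the zero diagonal: for a complete matrix this
        # is exactly l_i - mean(l) (excluding the diagonal would inflate
        # every lag by R/(R-1))
        with np.errstate(invalid="ignore"):
            lags = np.nanmean(pair, axis=1)
        lags[~enough] = np.nan
    lags = lags - np.nanmean(lags)  # zero-centered by construction
    return LagMap(region_labels=list(trace.region_labels), lag_s=lags,
                  n_reliable_pairs=np.asarray(n_rel), band_kind=band_kind,
                  transition_kind=segment.kind, pairwise_lag_s=pair,
                  peak_r=peak)


def ordering_recovery(injected_onset_lag_s: np.ndarray,
                      lagmap: LagMap) -> float:
    """Spearman correlation between injected onset delays and recovered
    lag-behind times (-lag_s); 1.0 means the recovered ordering matches."""
    finite = np.isfinite(lagmap.lag_s)
    rho = stats.spearmanr(np.asarray(injected_onset_lag_s)[finite],
                          -lagmap.lag_s[finite]).statistic
    return float(rho)
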