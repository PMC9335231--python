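"""Correlation of BOLD oscillation power with EEG and physiological traces.

Each (region, run, pairing) correlation between two windowed traces is one
observation; the group-level test works on the distribution of Fisher
z-transformed coefficients across regions and runs, mirroring the
histogram-based inference the sliding-window design calls for. Because
adjacent 104-s windows overlap by all but one volume, per-entry p-values
are anticonservative; an effective-sample-size (Bartlett) corrected p is
reported per entry as a diagnostic, while the group test treats each entry
as a single observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .containers import (InsufficientDataError, PowerTrace, RegionTimeSeries,
                         TRANSITION_LABEL, ValidationError, window_centers)
from .spectra import MIN_WINDOWS, WINDOW_VOLUMES, hamming_taper

ALIGN_ATOL_S = 1e-6


@dataclass
class CorrelationEntry:
    """One region-by-run correlation between two windowed traces."""

    region: str
    pairing: str
    scope: str                 # "across_stage" | "within_stage:<stage>"
    r: float
    n_windows: int
    fisher_z: float
    p_effective: float         # Bartlett effective-sample-size corrected
    run: str = "run"


@dataclass
class GroupSummary:
    """Group-level distribution summary of correlation entries."""

    n: int
    mean_r: float
    mean_z: float
    ci95_z: tuple
    t_stat: float
    p_value: float


def _aligned_windows(a_centers: np.ndarray, b_centers: np.ndarray) -> None:
    if len(a_centers) != len(b_centers) or not np.allclose(
            a_centers, b_centers, atol=ALIGN_ATOL_S, rtol=0.0):
        raise ValidationError(
            "window centers of the two traces do not align; traces must be "
            "computed with the shared window contract, not truncated silently"
        )


def _effective_n(x: np.ndarray, y: np.ndarray) -> float:
    """Bartlett effective sample size for the correlation of two
    autocorrelated series (sum over lag-wise autocorrelation products)."""
    n = len(x)
    xd = (x - x.mean()) / (x.std() or 1.0)
    yd = (y - y.mean()) / (y.std() or 1.0)
    max_lag = min(n - 2, 200)
    acf = np.ones(1)
    s = 1.0
    for lag in range(1, max_lag + 1):
        ax = np.corrcoef(xd[:-lag], xd[lag:])[0, 1]
        ay = np.corrcoef(yd[:-lag], yd[lag:])[0, 1]
        term = 2.0 * (1 - lag / n) * ax * ay
        if not np.isfinite(term):
            break
        s += term
        if abs(ax * ay) < 0.01:
            break
    return float(np.clip(n / max(s, 1e-12), 3.0, n))


def correlate_traces(a: PowerTrace, b_values: np.ndarray,
                     b_centers: np.ndarray, pairing: str,
                     scope: str = "across_stage",
                     stage_labels: np.ndarray | None = None,
                     min_windows: int = MIN_WINDOWS,
                     method: str = "pearson",
                     run: str = "run") -> list[CorrelationEntry]:
    """Correlate each region's windowed trace against a reference trace.

    ``scope`` selects windows: ``"across_stage"`` uses all non-transition
    windows; ``"within_stage:N2"`` only windows labelled N2. Entries with
    fewer than ``min_windows`` usable windows are skipped with the reason
    recorded in the raised/collected report (absent-with-reason, never a
    silent zero). Pearson by default, Spearman optional.
    """
    b_values = np.asarray(b_values, dtype=float).ravel()
    _aligned_windows(a.window_centers_s, b_centers)
    if stage_labels is None:
        stage_labels = a.stage_labels
    if scope == "across_stage":
        mask = (stage_labels != TRANSITION_LABEL if stage_labels is not None
                else np.ones(len(b_values), dtype=bool))
    elif scope.startswith("within_stage:"):
        if stage_labels is None:
            raise ValidationError("within-stage scope requires stage labels")
        mask = stage_labels == scope.split(":", 1)[1]
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    n = int(mask.sum())
    if n < min_windows:
        raise InsufficientDataError(
            f"scope {scope}: {n} windows (< {min_windows} required)"
        )
    y = b_values[mask]
    if np.ptp(y) == 0:
        raise ValidationError("reference trace has zero variance in scope")
    entries = []
    for i, region in enumerate(a.region_labels):
        x = a.values[i, mask]
        if np.ptp(x) == 0:
            raise ValidationError(f"region {region} trace has zero variance")
        if method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(x, y).statistic)
        else:
            raise ValidationError(f"unknown correlation method {method!r}")
        z = float(np.arctanh(np.clip(r, -0.999999, 0.999999)))
        n_eff = _effective_n(x, y)
        t = r * np.sqrt(max(n_eff - 2, 1) / max(1 - r ** 2, 1e-12))
        p_eff = float(2 * stats.t.sf(abs(t), max(n_eff - 2, 1)))
        entries.append(CorrelationEntry(region=region, pairing=pairing,
                                        scope=scope, r=r, n_windows=n,
                                        fisher_z=z, p_effective=p_eff,
                                        run=run))
    return entries


def group_distribution(entries: list[CorrelationEntry]) -> GroupSummary:
    """One-sample test of the Fisher-z distribution against zero.

    Each (region, run) coefficient is one observation; returns the mean r
    (back-transformed), the mean z with a 95% CI, and a two-sided t-test.
    """
    if len(entries) < 2:
        raise ValidationError("group test needs at least two entries")
    z = np.array([e.fisher_z for e in entries])
    mean_z = float(z.mean())
    sem = z.std(ddof=1) / np.sqrt(len(z))
    if sem > 0:
        t_stat, p = stats.ttest_1samp(z, 0.0)
        ci = stats.t.interval(0.95, len(z) - 1, loc=mean_z, scale=sem)
    else:
        t_stat, p = (0.0, 1.0) if mean_z == 0 else (np.inf, 0.0)
        ci = (mean_z, mean_z)
    return GroupSummary(n=len(z), mean_r=float(np.tanh(mean_z)),
                        mean_z=mean_z, ci95_z=(float(ci[0]), float(ci[1])),
                        t_stat=float(t_stat), p_value=float(p))


def paired_contrast(entries_a: list[CorrelationEntry],
                    entries_b: list[CorrelationEntry],
                    use_abs: bool = False) -> GroupSummary:
    """Paired test of z(a) - z(b) over matched (region, run) entries."""
    key = lambda e: (e.region, e.run, e.scope)
    bmap = {key(e): e for e in entries_b}
    diffs = []
    for ea in entries_a:
        eb = bmap.get(key(ea))
        if eb is None:
            continue
        za, zb = ea.fisher_z, eb.fisher_z
        if use_abs:
            za, zb = abs(za), abs(zb)
        diffs.append(za - zb)
    if len(diffs) < 2:
        raise ValidationError("paired contrast needs at least two matched pairs")
    d = np.array(diffs)
    t_stat, p = stats.ttest_1samp(d, 0.0)
    mean_d = float(d.mean())
    sem = d.std(ddof=1) / np.sqrt(len(d))
    ci = stats.t.interval(0.95, len(d) - 1, loc=mean_d, scale=sem) \
        if sem > 0 else (mean_d, mean_d)
    return GroupSummary(n=len(d), mean_r=float(np.tanh(mean_d)), mean_z=mean_d,
                        ci95_z=(float(ci[0]), float(ci[1])),
                        t_stat=float(t_stat), p_value=float(p))


def amplitude_trace(ts: RegionTimeSeries,
                    window_volumes: int = WINDOW_VOLUMES,
                    step_volumes: int = 1) -> PowerTrace:
    """Broadband BOLD amplitude per sliding window (control pairing).

    Standard deviation of the demeaned, Hamming-tapered window, compensated
    by the taper's RMS gain so white noise of SD sigma yields a trace at
    sigma. Frequency-blind by construction: the control against which the
    band-specific oscillation-power correlations are contrasted.
    """
    win = sliding_window_view(ts.values, window_volumes, axis=-1)[..., ::step_volumes, :]
    win = win - win.mean(axis=-1, keepdims=True)
    taper = hamming_taper(window_volumes)
    norm = np.sqrt((taper ** 2).sum())
    sd = np.sqrt(((win * taper) ** 2).sum(axis=-1)) / norm
    centers = window_centers(ts.n_volumes, window_volumes, step_volumes,
                             ts.tr_s, ts.t0_s)
    return PowerTrace(values=sd, window_centers_s=centers,
                      region_labels=list(ts.region_labels))
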