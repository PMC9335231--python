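"""End-to-end orchestration: simulate -> regress -> spectra -> events ->
correlations -> lag maps, with a checksummed run manifest."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import events as ev
from . import io, lagmap as lm, multimodal as mm, physio as ph, spectra as sp
from .config import SimConfig
from .containers import InsufficientDataError
from .synth import simulate_recording

log = logging.getLogger("boldosc")


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_simulation(config: SimConfig, outdir) -> dict:
    """Simulate one recording and write every modality as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = simulate_recording(config)
    io.write_bold_tsv(rec.bold, outdir / "bold.tsv")
    io.write_channels_tsv(rec.eeg, rec.eeg_fs_hz, outdir / "eeg.tsv")
    io.write_channels_tsv(
        np.vstack([rec.physio["resp"], rec.physio["cardiac"]]),
        rec.physio["fs"], outdir / "physio.tsv", labels=["resp", "cardiac"])
    io.write_hypnogram(rec.hypnogram, outdir / "hypnogram.txt")
    io.write_events_tsv(rec.events_truth, outdir / "events_truth.tsv")
    config.to_yaml(outdir / "config.yaml")
    truth = {
        "lf_freq_hz": rec.region_params.lf_freq_hz,
        "hf_freq_hz": rec.region_params.hf_freq_hz,
        "onset_lag_s": rec.region_params.lf_lag_s,
        "offset_lag_s": rec.region_params.hf_lag_s,
        "envelopes": rec.envelopes,
    }
    io.write_json(truth, outdir / "truth.json")
    return {"recording": rec, "outdir": outdir}


def run_pipeline(config: SimConfig, outdir, skip_physio: bool = False,
                 max_lag_s: float = lm.DEFAULT_MAX_LAG_S) -> dict:
    """Run the full analysis on a (simulated) recording; return the manifest.

    Stages: simulate, physio regressors + nuisance regression (optional),
    sliding spectrogram, 1/f fit + peak detection, band power traces,
    event detection + activity traces, multimodal correlations, lag maps.
    Deterministic given the config seed; any stage failure halts with the
    stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {},
                "tool": "boldosc", "skipped": []}

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as err:  # halt with stage name and cause
            raise StageFailure(name, err) from err
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    sim = stage("simulate", lambda: write_simulation(config, outdir))
    rec = sim["recording"]
    bold = rec.bold

    if skip_physio:
        manifest["skipped"].append("physio_regression")
    else:
        def _physio():
            reg = ph.build_regressors(rec.physio["resp"], rec.physio["cardiac"],
                                      rec.physio["fs"], bold.tr_s,
                                      bold.n_volumes)
            cleaned, dropped = ph.regress_out(bold, reg)
            return reg, cleaned, dropped
        reg, bold, dropped = stage("physio_regression", _physio)
        manifest["stages"]["physio_regression"]["dropped_columns"] = dropped

    spec = stage("spectrogram", lambda: sp.sliding_spectrogram(bold))
    stage_labels = sp.window_stages(rec.hypnogram, spec)

    def _peaks():
        out = {}
        for target in ("N2", "N3"):
            try:
                spectrum = sp.stage_average_spectrum(
                    spec, rec.hypnogram, target, stage_labels=stage_labels)
            except InsufficientDataError as err:
                manifest["skipped"].append(f"peaks:{target}: {err}")
                continue
            mean_spec = spectrum.mean(axis=0)
            fit = sp.fit_one_over_f(spec.freqs_hz, mean_spec)
            out[target] = sp.detect_band_peaks(spec.freqs_hz, fit)
        return out
    peaks_by_stage = stage("peaks", _peaks)
    bands = {}
    for kind in ("LF", "HF"):
        found = [p[kind] for p in peaks_by_stage.values() if p.get(kind)]
        if found:
            bands[kind] = found[0]
    io.write_json({st: {k: (None if b is None else asdict(b))
                        for k, b in pk.items()}
                   for st, pk in peaks_by_stage.items()},
                  outdir / "peaks.json")

    traces = {}
    def _traces():
        for kind, band in bands.items():
            tr = sp.band_power_trace(spec, band, stage_labels=stage_labels)
            traces[kind] = tr
            io.write_trace_tsv(tr, outdir / f"power_{kind.lower()}.tsv")
        return traces
    stage("powertrace", _traces)

    def _events():
        import pandas as pd
        det = {"spindle": ev.detect_spindles(rec.eeg, rec.eeg_fs_hz),
               "slow_wave": ev.detect_slow_waves(rec.eeg, rec.eeg_fs_hz)}
        allev = pd.concat([d.events for d in det.values()], ignore_index=True)
        io.write_events_tsv(ev.EventList(allev) if len(allev)
                            else ev.EventList.empty(),
                            outdir / "events_detected.tsv")
        span = (bold.t0_s, bold.t0_s + bold.duration_s)
        acts = {t: ev.activity_power_trace(lst, span, t)
                for t, lst in det.items()}
        return det, acts
    detected, activities = stage("events", _events)

    def _correlations():
        entries = {}
        for kind, tr in traces.items():
            for etype, act in activities.items():
                try:
                    entries[f"{kind}_power~{etype}_activity"] = mm.correlate_traces(
                        tr, act.values, act.window_centers_s,
                        pairing=f"{kind}_power~{etype}_activity",
                        stage_labels=stage_labels)
                except InsufficientDataError as err:
                    manifest["skipped"].append(f"correlate:{kind}~{etype}: {err}")
        summary = {k: asdict(mm.group_distribution(v))
                   for k, v in entries.items() if len(v) >= 2}
        io.write_json(summary, outdir / "correlations.json")
        return entries
    stage("correlate", _correlations)

    def _lagmaps():
        out = {}
        for kind, tr in traces.items():
            for tkind in ("falling_asleep", "waking"):
                try:
                    seg = lm.extract_transition(rec.hypnogram, tkind)
                    wake = stage_labels == "W"
                    base = (tr.values[:, wake].mean(axis=1)
                            if wake.sum() else None)
                    lmap = lm.build_lagmap(tr, seg, max_lag_s=max_lag_s,
                                           band_kind=kind, baseline=base)
                    io.write_lagmap_tsv(
                        lmap, outdir / f"lagmap_{kind.lower()}_{tkind}.tsv")
                    out[(kind, tkind)] = lmap
                except InsufficientDataError as err:
                    manifest["skipped"].append(f"lagmap:{kind}:{tkind}: {err}")
        return out
    stage("lagmap", _lagmaps)

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _checksum(p)
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
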