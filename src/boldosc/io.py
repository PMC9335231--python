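"""Readers and writers for the package's plain-text formats.

TSV dialect: tab-separated, '.' decimal, UTF-8, header row, no quoting.
BOLD matrices carry a JSON sidecar (``<name>.json``) with ``tr_s`` and
``t0_s``; the hypnogram is one stage token per line. NIfTI input (4D BOLD
plus a 3D integer atlas) and EDF EEG are supported through nibabel and mne.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (EventList, Hypnogram, LagMap, PowerTrace,
                         RegionTimeSeries, ValidationError, normalize_stage)

_TSV = dict(sep="\t", float_format="%.17g", index=False)  # exact float64 round trip


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as err:  # parse failures are data-validation errors
        raise ValidationError(f"{path}: cannot parse TSV ({err})") from None


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json") if p.suffix != ".tsv" \
        else p.with_suffix(".json")


# --------------------------------------------------------------------------
# BOLD region-by-volume matrices
# --------------------------------------------------------------------------

def write_bold_tsv(ts: RegionTimeSeries, path) -> None:
    """Columns = regions (header row of labels), rows = volumes."""
    df = pd.DataFrame(ts.values.T, columns=ts.region_labels)
    df.to_csv(path, **_TSV)
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"tr_s": ts.tr_s, "t0_s": ts.t0_s}, fh)


def read_bold_tsv(path, tr_s: float | None = None,
                  t0_s: float | None = None) -> RegionTimeSeries:
    df = _read_tsv(path)
    side = _sidecar_path(path)
    meta = {}
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
    tr = tr_s if tr_s is not None else meta.get("tr_s")
    if tr is None:
        raise ValidationError(
            f"{path}: TR not given and no sidecar {side.name}; pass tr_s"
        )
    t0 = t0_s if t0_s is not None else meta.get("t0_s", 0.0)
    values = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite BOLD values")
    return RegionTimeSeries(values=values, tr_s=float(tr),
                            region_labels=list(df.columns), t0_s=float(t0))


# --------------------------------------------------------------------------
# NIfTI + atlas
# --------------------------------------------------------------------------

@dataclass
class Parcellation:
    """Integer voxel->region label volume plus a region table."""

    labels: np.ndarray              # 3-D int array, 0 = background
    table: pd.DataFrame             # columns: id, name, group

    def __post_init__(self):
        ids = self.table["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate region ids in parcellation table")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(int(i) for i in ids)
        if missing:
            raise ValidationError(
                f"atlas labels absent from region table: {sorted(missing)}"
            )


def read_bold_nifti(bold_path, atlas_path, region_table: pd.DataFrame,
                    tr_s: float | None = None):
    """4D NIfTI + integer atlas -> (region series, voxel series, Parcellation).

    Region series are per-label voxel means (time-domain export); for
    spectral analysis the caller may instead compute per-voxel spectrograms
    and average them per region.
    """
    import nibabel as nib
    img = nib.load(str(bold_path))
    atlas = nib.load(str(atlas_path))
    data = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(atlas.dataobj).astype(int)
    if data.ndim != 4:
        raise ValidationError(f"{bold_path}: expected a 4D BOLD image")
    if labels.shape != data.shape[:3]:
        raise ValidationError("atlas grid does not match the BOLD grid")
    tr = tr_s if tr_s is not None else float(img.header.get_zooms()[3])
    if not tr > 0:
        raise ValidationError("TR missing from NIfTI header; pass tr_s")
    parc = Parcellation(labels=labels, table=region_table)
    names, series, voxel_series = [], [], {}
    for rid, name in zip(region_table["id"], region_table["name"]):
        mask = labels == int(rid)
        if not mask.any():
            continue
        vox = data[mask, :]
        voxel_series[str(name)] = vox
        series.append(vox.mean(axis=0))
        names.append(str(name))
    ts = RegionTimeSeries(values=np.asarray(series), tr_s=tr,
                          region_labels=names)
    return ts, voxel_series, parc


# --------------------------------------------------------------------------
# EEG / physio channel tables
# --------------------------------------------------------------------------

def write_channels_tsv(data: np.ndarray, fs: float, path,
                       labels=None, t0_s: float = 0.0) -> None:
    """Channels-by-samples matrix as a TSV with a leading time column."""
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    labels = labels or [f"ch{c:02d}" for c in range(arr.shape[0])]
    t = t0_s + np.arange(arr.shape[1]) / fs
    df = pd.DataFrame({"time_s": t})
    for lab, row in zip(labels, arr):
        df[lab] = row
    df.to_csv(path, **_TSV)


def read_channels_tsv(path):
    """Returns (data (C, N), fs, labels, t0_s)."""
    df = _read_tsv(path)
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValidationError(f"{path}: time column is not uniformly sampled")
    labels = [c for c in df.columns if c != "time_s"]
    return (df[labels].to_numpy(dtype=float).T, 1.0 / dt[0], labels,
            float(t[0]))


def read_eeg_edf(path):
    """EEG from an EDF file via mne (read-only); returns (data, fs, labels)."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


# --------------------------------------------------------------------------
# Hypnogram, events, traces
# --------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + "\n")


def read_hypnogram(path, epoch_s: float = 30.0) -> Hypnogram:
    """One stage token per line; W/N1/N2/N3/R plus common aliases."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    tokens = [ln for ln in lines if ln]
    if not tokens:
        raise ValidationError(f"{path}: empty hypnogram")
    stages = []
    for i, tok in enumerate(tokens, start=1):
        try:
            stages.append(normalize_stage(tok))
        except ValidationError as err:
            raise ValidationError(f"{path}:{i}: {err}") from None
    side = _sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            epoch_s = json.load(fh).get("epoch_s", epoch_s)
    return Hypnogram(stages=stages, epoch_s=epoch_s)


def write_events_tsv(events: EventList, path) -> None:
    events.events.to_csv(path, **_TSV)


def read_events_tsv(path) -> EventList:
    df = _read_tsv(path)
    return EventList(df) if len(df) else EventList.empty()


def write_trace_tsv(trace: PowerTrace, path) -> None:
    df = pd.DataFrame({"window_center_s": trace.window_centers_s})
    for lab, row in zip(trace.region_labels, trace.values):
        df[lab] = row
    if trace.stage_labels is not None:
        df["stage"] = trace.stage_labels
    df.to_csv(path, **_TSV)


def read_trace_tsv(path) -> PowerTrace:
    df = _read_tsv(path)
    labels = [c for c in df.columns if c not in ("window_center_s", "stage")]
    stage = df["stage"].to_numpy(dtype=object) if "stage" in df.columns else None
    return PowerTrace(values=df[labels].to_numpy(dtype=float).T,
                      window_centers_s=df["window_center_s"].to_numpy(dtype=float),
                      region_labels=labels, stage_labels=stage)


def write_lagmap_tsv(lagmap: LagMap, path) -> None:
    pd.DataFrame({
        "region": lagmap.region_labels,
        "lag_s": lagmap.lag_s,
        "n_reliable_pairs": lagmap.n_reliable_pairs,
        "band": lagmap.band_kind,
        "transition": lagmap.transition_kind,
    }).to_csv(path, **_TSV)


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
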