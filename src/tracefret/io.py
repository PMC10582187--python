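"""Trace container I/O: HDF5 and CSV round trips plus JSON manifests.

HDF5 layout::

    /traces/<id>/channels   (n_frames, n_channels) float64
    /traces/<id>/labels     (n_frames,) int64       [optional]
    /traces/<id>/states     (n_frames,) int64       [optional]
    /traces/<id>.attrs      modality, frame_time, snr, category, ...
    /.attrs["manifest"]     JSON string (config, detection factors, seeds)

CSV export is one row per frame (trace_id, frame, channel columns, label,
state) with the manifest in a sidecar ``<name>.manifest.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .alphabet import CHANNELS, n_channels
from .simulate import LabeledTrace, SimConfig, TraceDataset, DetectionModel

__all__ = ["write_traces", "read_traces"]


def write_traces(path, dataset: TraceDataset, format: str = "hdf5") -> None:
    """Write a dataset losslessly (float64 intensities, integer labels)."""
    path = Path(path)
    if format == "hdf5":
        _write_h5(path, dataset)
    elif format == "csv":
        _write_csv(path, dataset)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_traces(path, format: str | None = None, modality: str | None = None) -> TraceDataset:
    """Read a dataset; ``modality`` (if given) is validated against the file."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "hdf5":
        ds = _read_h5(path)
    elif format == "csv":
        ds = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if modality is not None and ds.traces and ds.traces[0].modality != modality:
        raise ValueError(
            f"file contains {ds.traces[0].modality!r} data "
            f"({ds.traces[0].channels.shape[1]} channels), not {modality!r} "
            f"({n_channels(modality)} channels)"
        )
    return ds


def _write_h5(path: Path, dataset: TraceDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(dataset.manifest)
        grp = f.create_group("traces")
        for t in dataset.traces:
            g = grp.create_group(str(t.trace_id))
            g.create_dataset("channels", data=t.channels)
            g.create_dataset("labels", data=t.labels)
            g.create_dataset("states", data=t.states)
            if t.pure_frames is not None:
                g.create_dataset("pure_frames", data=t.pure_frames)
            g.attrs["modality"] = t.modality
            g.attrs["frame_time"] = t.frame_time
            g.attrs["snr"] = t.snr
            g.attrs["category"] = t.category
            g.attrs["bleach_time_s"] = json.dumps(
                {k: (v if np.isfinite(v) else None) for k, v in t.bleach_time_s.items()}
            )


def _read_h5(path: Path) -> TraceDataset:
    traces = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs.get("manifest", "{}"))
        for key in sorted(f["traces"], key=int):
            g = f["traces"][key]
            modality = g.attrs["modality"]
            channels = g["channels"][()]
            if channels.shape[1] != n_channels(modality):
                raise ValueError(
                    f"trace {key}: {channels.shape[1]} channels inconsistent "
                    f"with modality {modality!r}"
                )
            bleach = {
                k: (float(v) if v is not None else np.inf)
                for k, v in json.loads(g.attrs.get("bleach_time_s", "{}")).items()
            }
            traces.append(
                LabeledTrace(
                    modality=modality,
                    channels=channels,
                    labels=g["labels"][()],
                    states=g["states"][()],
                    pure_frames=g["pure_frames"][()] if "pure_frames" in g else None,
                    frame_time=float(g.attrs["frame_time"]),
                    snr=float(g.attrs["snr"]),
                    trace_id=int(key),
                    category=g.attrs.get("category", ""),
                    bleach_time_s=bleach,
                )
            )
    return _dataset_from(traces, manifest)


def _write_csv(path: Path, dataset: TraceDataset) -> None:
    frames = []
    for t in dataset.traces:
        cols = {f"ch_{name}": t.channels[:, i] for i, name in enumerate(CHANNELS[t.modality])}
        df = pd.DataFrame(cols)
        df.insert(0, "frame", np.arange(t.n_frames))
        df.insert(0, "trace_id", t.trace_id)
        df["label"] = t.labels
        df["state"] = t.states
        df["pure"] = (t.pure_frames if t.pure_frames is not None
                      else np.ones(t.n_frames, dtype=bool)).astype(int)
        df["modality"] = t.modality
        df["frame_time"] = t.frame_time
        df["snr"] = t.snr
        df["category"] = t.category
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(dataset.manifest, indent=1)
    )


def _read_csv(path: Path) -> TraceDataset:
    df = pd.read_csv(path)
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    traces = []
    for tid, sub in df.groupby("trace_id", sort=True):
        modality = sub["modality"].iloc[0]
        ch_cols = [f"ch_{name}" for name in CHANNELS[modality]]
        traces.append(
            LabeledTrace(
                modality=modality,
                channels=sub[ch_cols].to_numpy(dtype=float),
                labels=sub["label"].to_numpy(dtype=np.int64),
                states=sub["state"].to_numpy(dtype=np.int64),
                pure_frames=sub["pure"].to_numpy(dtype=bool)
                if "pure" in sub.columns else None,
                frame_time=float(sub["frame_time"].iloc[0]),
                snr=float(sub["snr"].iloc[0]),
                trace_id=int(tid),
                category=str(sub["category"].iloc[0]),
            )
        )
    return _dataset_from(traces, manifest)


def _dataset_from(traces, manifest) -> TraceDataset:
    cfg_dict = dict(manifest.get("config", {}))
    config = None
    if cfg_dict:
        cfg_dict.pop("detection", None)
        known = {k: v for k, v in cfg_dict.items() if k in SimConfig.__dataclass_fields__}
        for key in ("e_range", "dwell_range_frames", "snr_range", "brightness_range",
                    "noisy_snr_range", "bleach_lifetime_frac", "n_states_choices"):
            if known.get(key) is not None:
                known[key] = tuple(known[key])
        try:
            config = SimConfig(**known)
        except (TypeError, ValueError):
            config = None
    det_dict = manifest.get("detection")
    detection = (
        DetectionModel(**det_dict) if det_dict else
        (DetectionModel.ideal(traces[0].modality) if traces else DetectionModel({}, {}, {}))
    )
    if config is None and traces:
        config = SimConfig(
            modality=traces[0].modality,
            n_traces=len(traces),
            n_frames=traces[0].n_frames,
            frame_time=traces[0].frame_time,
        )
    return TraceDataset(traces=traces, config=config, detection=detection, manifest=manifest)
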