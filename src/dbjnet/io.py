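"""File I/O: SNIRF (HDF5) and CSV/TSV recordings, EpochSet containers,
evaluation reports, and the run configuration.

SNIRF files follow the v1.0 group layout (/formatVersion, /nirs/data1 with
dataTimeSeries, time, measurementList entries, and /nirs/stim groups, one
per emotion label). The plain-text dialect is one ``<subject>_hbo.csv``
(rows = samples, columns = channels), one ``<subject>_events.tsv``
(onset_sample, duration_samples, label), and a ``<subject>_meta.json``
sidecar carrying the sampling rate and provenance.

Every artifact written here embeds the configuration hash and master seed
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .evaluate import LosoReport
from .model import DBJNetConfig
from .preprocess import EpochSet, PreprocessConfig
from .simulate import (ContinuousRecording, EventMarker, LABEL_NAMES,
                       SimConfig, config_from_dict, config_to_dict)
from .train import TrainConfig

SCHEMA_VERSION = "1.0"


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Provenance:
    config_hash: str = ""
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# SNIRF
# --------------------------------------------------------------------------

def write_recording_snirf(recording: ContinuousRecording, path,
                          provenance: Provenance | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        if provenance is not None:
            meta.create_dataset("ConfigHash", data=provenance.config_hash)
            meta.create_dataset("MasterSeed", data=str(provenance.seed))
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=recording.hbo.T)
        # length-2 form: [start time, sampling period]
        data1.create_dataset("time",
                             data=np.array([0.0, 1.0 / recording.fs]))
        for i, cid in enumerate(recording.channel_ids):
            ml = data1.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=i % 15 + 1)
            ml.create_dataset("detectorIndex", data=i % 16 + 1)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data="HbO")
            ml.create_dataset("dataTypeIndex", data=1)
        data1.create_dataset(
            "channelIds",
            data=np.array(recording.channel_ids, dtype=h5py.string_dtype()))
        by_label: dict[int, list[EventMarker]] = {}
        for ev in recording.events:
            by_label.setdefault(ev.label, []).append(ev)
        for k, label in enumerate(sorted(by_label)):
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=LABEL_NAMES[label])
            rows = [[ev.onset_sample / recording.fs,
                     ev.duration_samples / recording.fs,
                     float(label)] for ev in by_label[label]]
            stim.create_dataset("data", data=np.array(rows))
    return path


def _h5_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_recording_snirf(path) -> ContinuousRecording:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            nirs = f["nirs"]
            data1 = nirs["data1"]
            hbo = np.asarray(data1["dataTimeSeries"]).T
            time = np.asarray(data1["time"])
            if time.size == 2:
                fs = 1.0 / float(time[1])
            elif time.size > 2:
                fs = 1.0 / float(np.median(np.diff(time)))
            else:
                raise ValueError("time dataset too short to infer fs")
            subject_id = "unknown"
            if "metaDataTags" in nirs and "SubjectID" in nirs["metaDataTags"]:
                subject_id = _h5_str(nirs["metaDataTags"]["SubjectID"])
            if "channelIds" in data1:
                channel_ids = [v.decode() if isinstance(v, bytes) else str(v)
                               for v in data1["channelIds"][()]]
            else:
                channel_ids = [f"CH{i + 1:02d}" for i in range(hbo.shape[0])]
            events: list[EventMarker] = []
            stim_names = sorted(k for k in nirs if k.startswith("stim"))
            if not stim_names:
                raise ValueError(f"{path}: SNIRF file has no stim groups")
            for name in stim_names:
                rows = np.atleast_2d(np.asarray(nirs[name]["data"]))
                for onset_s, dur_s, value in rows:
                    events.append(EventMarker(
                        onset_sample=int(round(onset_s * fs)),
                        duration_samples=int(round(dur_s * fs)),
                        label=int(value),
                    ))
            events.sort(key=lambda e: e.onset_sample)
    except (OSError, KeyError) as exc:
        raise ValueError(f"cannot parse SNIRF file {path}: {exc}") from exc
    return ContinuousRecording(hbo=hbo, fs=fs, subject_id=subject_id,
                               channel_ids=channel_ids, events=events)


# --------------------------------------------------------------------------
# CSV/TSV dialect
# --------------------------------------------------------------------------

def write_recording_csv(recording: ContinuousRecording, out_dir,
                        provenance: Provenance | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = recording.subject_id
    pd.DataFrame(recording.hbo.T, columns=recording.channel_ids).to_csv(
        out_dir / f"{sid}_hbo.csv", index=False)
    pd.DataFrame(
        [(e.onset_sample, e.duration_samples, e.label)
         for e in recording.events],
        columns=["onset_sample", "duration_samples", "label"],
    ).to_csv(out_dir / f"{sid}_events.tsv", sep="\t", index=False)
    meta = {"subject_id": sid, "fs": recording.fs,
            "schema_version": SCHEMA_VERSION}
    if provenance is not None:
        meta["provenance"] = provenance.to_dict()
    (out_dir / f"{sid}_meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir / f"{sid}_hbo.csv"


def read_recording_csv(hbo_path) -> ContinuousRecording:
    hbo_path = Path(hbo_path)
    stem = hbo_path.name
    if not stem.endswith("_hbo.csv"):
        raise ValueError(f"{hbo_path}: expected a <subject>_hbo.csv file")
    sid = stem[: -len("_hbo.csv")]
    meta_path = hbo_path.with_name(f"{sid}_meta.json")
    events_path = hbo_path.with_name(f"{sid}_events.tsv")
    try:
        meta = json.loads(meta_path.read_text())
        fs = float(meta["fs"])
    except (OSError, KeyError, ValueError) as exc:
        raise ValueError(
            f"cannot read sampling rate from {meta_path}: {exc}") from exc
    try:
        df = pd.read_csv(hbo_path)
        ev = pd.read_csv(events_path, sep="\t")
        events = [EventMarker(int(r.onset_sample), int(r.duration_samples),
                              int(r.label)) for r in ev.itertuples()]
    except Exception as exc:
        raise ValueError(f"cannot parse recording {hbo_path}: {exc}") from exc
    return ContinuousRecording(
        hbo=df.to_numpy().T, fs=fs,
        subject_id=meta.get("subject_id", sid),
        channel_ids=list(df.columns), events=events,
    )


def write_recording(recording: ContinuousRecording, path, format: str,
                    provenance: Provenance | None = None) -> Path:
    if format == "snirf":
        return write_recording_snirf(recording, path, provenance)
    if format == "csv":
        return write_recording_csv(recording, path, provenance)
    raise ValueError(f"unknown format {format!r}; choose 'snirf' or 'csv'")


def read_recording(path, format: str | None = None) -> ContinuousRecording:
    path = Path(path)
    if format is None:
        format = "snirf" if path.suffix == ".snirf" else "csv"
    if format == "snirf":
        return read_recording_snirf(path)
    if format == "csv":
        return read_recording_csv(path)
    raise ValueError(f"unknown format {format!r}; choose 'snirf' or 'csv'")


# --------------------------------------------------------------------------
# EpochSet container
# --------------------------------------------------------------------------

def save_epochs(epoch_set: EpochSet, path,
                provenance: Provenance | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epoch_set.data)
        f.create_dataset("labels", data=epoch_set.labels)
        f.create_dataset("subject_ids", data=np.array(
            [str(s) for s in epoch_set.subject_ids],
            dtype=h5py.string_dtype()))
        f.attrs["fs"] = epoch_set.fs
        f.attrs["n_excluded"] = epoch_set.n_excluded
        f.attrs["schema_version"] = SCHEMA_VERSION
        if provenance is not None:
            f.attrs["config_hash"] = provenance.config_hash
            f.attrs["seed"] = provenance.seed
    return path


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=np.asarray(f["data"]),
            labels=np.asarray(f["labels"]),
            subject_ids=np.array([s.decode() for s in f["subject_ids"][()]],
                                 dtype=object),
            fs=float(f.attrs["fs"]),
            n_excluded=int(f.attrs.get("n_excluded", 0)),
        )


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def write_report(report: LosoReport, path,
                 provenance: Provenance | None = None) -> Path:
    """JSON report plus a CSV twin of the per-fold table."""
    if not report.folds:
        raise ValueError("refusing to write a report with no folds")
    path = Path(path)
    doc = {"schema_version": SCHEMA_VERSION, **report.to_dict()}
    if provenance is not None:
        doc["provenance"] = provenance.to_dict()
    path.write_text(json.dumps(doc, indent=2))
    pd.DataFrame([dataclasses.asdict(f) for f in report.folds]).to_csv(
        path.with_suffix(".csv"), index=False)
    return path


def read_report(path) -> LosoReport:
    doc = json.loads(Path(path).read_text())
    return LosoReport.from_dict(doc)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level configuration tying all pipeline stages together."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: DBJNetConfig = field(default_factory=DBJNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tasks: tuple[str, ...] = ("pos_neu_neg",)
    out_dir: str = "results"
    log_level: str = "INFO"
    master_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "sim": config_to_dict(self.sim),
            "preprocess": dataclasses.asdict(self.preprocess),
            "model": self.model.to_dict(),
            "train": dataclasses.asdict(self.train),
            "tasks": list(self.tasks),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "sim" in d:
            kwargs["sim"] = config_from_dict(d.pop("sim"))
        if "preprocess" in d:
            p = d.pop("preprocess")
            extra = set(p) - {f.name for f in
                              dataclasses.fields(PreprocessConfig)}
            if extra:
                raise ValueError(f"unknown PreprocessConfig keys: "
                                 f"{sorted(extra)}")
            if isinstance(p.get("channel_order"), list):
                p["channel_order"] = tuple(p["channel_order"])
            kwargs["preprocess"] = PreprocessConfig(**p)
        if "model" in d:
            kwargs["model"] = DBJNetConfig.from_dict(d.pop("model"))
        if "train" in d:
            t = d.pop("train")
            extra = set(t) - {f.name for f in dataclasses.fields(TrainConfig)}
            if extra:
                raise ValueError(f"unknown TrainConfig keys: {sorted(extra)}")
            kwargs["train"] = TrainConfig(**t)
        if "tasks" in d:
            kwargs["tasks"] = tuple(d.pop("tasks"))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())
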