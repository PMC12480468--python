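"""Reading/writing recordings, study manifests and analysis configuration.

The single internal unit is microvolts; readers convert on load and fail
loudly when the source units are ambiguous. FIF (via mne) is the primary
on-disk recording format, with a self-describing ``.npz`` array container
as the internal alternative; EDF and BDF are supported on the read side.
Events travel as tab-separated ``(onset_sample, label)`` files and feature
tables as CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import montage as mont
from .recording import Recording

TASKS = ("rest_eo", "rest_ec", "p300", "gamma", "artifact")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as FIF (.fif) or internal container (.npz)."""
    path = Path(path)
    if path.suffix == ".fif":
        raw = rec.to_mne_raw()
        if rec.events:
            onsets = [s / rec.fs for s, _ in rec.events]
            import mne
            raw.set_annotations(mne.Annotations(
                onset=onsets, duration=[0.0] * len(onsets),
                description=[l for _, l in rec.events]), verbose="error")
        raw.save(path, overwrite=True, verbose="error")
    elif path.suffix == ".npz":
        np.savez_compressed(
            path, data=rec.data, fs=rec.fs,
            channels=np.array(rec.channels), positions=rec.positions,
            event_samples=np.array([s for s, _ in rec.events], dtype=np.int64),
            event_labels=np.array([l for _, l in rec.events]),
            meta=json.dumps(rec.meta, default=str),
            artifact_mask=(rec.artifact_mask if rec.artifact_mask is not None
                           else np.zeros(0, dtype=bool)))
    else:
        raise ValueError(f"unsupported output format {path.suffix!r} "
                         "(use .fif or .npz)")
    return path


def read_recording(path, fmt: str = None, meta: dict = None) -> Recording:
    """Load a recording from FIF/EDF/BDF/npz; data returned in microvolts.

    Channel labels must map onto the 10-20 montage; unmapped labels raise an
    error naming them. Annotations with onsets beyond the record length are
    dropped (counted in ``meta['dropped_annotations']``).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            events = list(zip(z["event_samples"].tolist(),
                              z["event_labels"].tolist()))
            mask = z["artifact_mask"]
            rec = Recording(
                data=z["data"], fs=float(z["fs"]),
                channels=[str(c) for c in z["channels"]],
                positions=z["positions"], events=events,
                meta={**json.loads(str(z["meta"])), **(meta or {})},
                artifact_mask=mask if mask.size else None)
        return rec
    import mne

    readers = {"fif": mne.io.read_raw_fif, "edf": mne.io.read_raw_edf,
               "bdf": mne.io.read_raw_bdf}
    if fmt not in readers:
        raise ValueError(f"unsupported format {fmt!r}")
    raw = readers[fmt](path, preload=True, verbose="error")
    n = raw.n_times
    n_before = len(raw.annotations)
    keep = [i for i, ann in enumerate(raw.annotations)
            if (ann["onset"] - raw.first_time) * raw.info["sfreq"] < n]
    dropped = n_before - len(keep)
    rec = Recording.from_mne_raw(raw, meta=meta)
    rec.meta["dropped_annotations"] = dropped
    return rec


def write_events_tsv(rec: Recording, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.events, columns=["onset_sample", "label"])
    df.to_csv(path, sep="\t", index=False)
    return path


def write_feature_table(table: pd.DataFrame, path, config_hash: str = None) -> Path:
    path = Path(path)
    out = table.copy()
    if config_hash is not None:
        out["config_hash"] = config_hash
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# study manifest

MANIFEST_COLUMNS = ("path", "subject", "session", "device", "task")


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a study manifest CSV.

    One row per recording with columns path/subject/session/device/task;
    (subject, session, device, task) cells must be unique and referenced
    files must exist.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks columns: {missing}")
    bad_tasks = sorted(set(df["task"]) - set(TASKS))
    if bad_tasks:
        raise ValueError(f"unknown tasks in manifest: {bad_tasks}")
    key = df[["subject", "session", "device", "task"]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].to_dict("records")
        raise ValueError(f"duplicate manifest cells: {dupes}")
    if check_files:
        base = Path(path).parent
        absent = [p for p in df["path"]
                  if not (Path(p).is_absolute() and Path(p).exists()
                          or (base / p).exists())]
        if absent:
            raise ValueError(f"manifest references missing files: {absent}")
    return df


# ---------------------------------------------------------------------------
# analysis configuration

@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, serialized verbatim into run logs."""

    bands: dict = field(default_factory=lambda: {
        "rest": (1.0, 45.0), "p300": (1.0, 60.0), "gamma": (1.0, 120.0)})
    flat_variance: float = 0.1
    extreme_amplitude: float = 500.0
    moderate_amplitude: float = 100.0
    correlation: float = 0.6
    bad_epoch_fraction: float = 0.20
    epoch_window: tuple = (-0.3, 0.7)
    p300_window: tuple = (0.25, 0.5)
    latency_shift: dict = field(default_factory=dict)   # device -> seconds
    tfr_baseline: tuple = (-0.5, -0.1)
    cluster_threshold: float = 1.28
    n_permutations: int = 1000
    icc_reference_device: str = "standard"
    n_boot: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_window", "p300_window", "tfr_baseline"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)
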