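"""Core containers: Recording (continuous data) and Epochs (trials).

Internal unit is microvolts throughout; sample indices are 0-based and all
time intervals are half-open ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import montage as mont


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered 10-20 channel labels, one per data row.
    positions : ndarray, shape (n_channels, 3)
        Unit-sphere electrode coordinates.
    events : list of (int, str)
        (sample index, label) stimulus/annotation markers.
    meta : dict
        Study metadata (subject, session, device, task, ...).
    artifact_mask : ndarray of bool, shape (n_samples,), optional
        Ground-truth artifact annotation (synthetic data only).
    """

    data: np.ndarray
    fs: float
    channels: list
    positions: np.ndarray = None
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    artifact_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if self.positions is None:
            self.positions = mont.positions(self.channels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.data.shape[0], 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        for s, _ in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event sample {s} outside record [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channels=list(self.channels),
            positions=self.positions.copy(),
            events=list(self.events),
            meta=dict(self.meta),
            artifact_mask=None if self.artifact_mask is None else self.artifact_mask.copy(),
        )

    def pick(self, labels) -> "Recording":
        """Restrict to the given channels (in the given order)."""
        labels = [mont.canonical_label(l) for l in labels]
        missing = [l for l in labels if l not in self.channels]
        if missing:
            raise ValueError(f"requested channels absent from recording: {missing}")
        idx = [self.channels.index(l) for l in labels]
        return replace(
            self,
            data=self.data[idx].copy(),
            channels=labels,
            positions=self.positions[idx].copy(),
            events=list(self.events),
            meta=dict(self.meta),
            artifact_mask=None if self.artifact_mask is None else self.artifact_mask.copy(),
        )

    def to_mne_raw(self):
        """Convert to an mne RawArray (volts) carrying the standard montage."""
        import mne

        info = mne.create_info(list(self.channels), self.fs, ch_types="eeg")
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        raw.set_montage(mont.make_dig_montage(self.channels), verbose="error")
        return raw

    @classmethod
    def from_mne_raw(cls, raw, meta=None) -> "Recording":
        data = raw.get_data(picks="eeg", units="uV")
        channels = mont.validate_labels(
            [raw.ch_names[i] for i in
             __import__("mne").pick_types(raw.info, eeg=True)]
        )
        events = []
        for ann in raw.annotations:
            s = int(round((ann["onset"] - raw.first_time) * raw.info["sfreq"]))
            if 0 <= s < data.shape[1]:
                events.append((s, str(ann["description"])))
        return cls(data=data, fs=float(raw.info["sfreq"]), channels=channels,
                   events=events, meta=dict(meta or {}))


@dataclass
class Epochs:
    """Trials x channels x times cut around stimulus onsets.

    ``times`` is the common time axis in seconds relative to onset; the
    baseline is the pre-onset part. ``shift`` records any latency correction
    applied to the onsets before cutting.
    """

    data: np.ndarray            # (n_trials, n_channels, n_times) µV
    times: np.ndarray           # (n_times,) seconds
    fs: float
    channels: list
    labels: np.ndarray          # (n_trials,) per-trial condition labels
    positions: np.ndarray = None
    shift: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be 3-D (trials x channels x times)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[2] != self.times.shape[0]:
            raise ValueError("times must match the last data axis")
        if self.labels.size == 0:
            raise ValueError("epochs must contain at least one trial")
        if self.positions is None:
            self.positions = mont.positions(self.channels)
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, start: float, stop: float) -> np.ndarray:
        """Boolean mask for the half-open window [start, stop)."""
        return (self.times >= start - 1e-9) & (self.times < stop - 1e-9)

    def select(self, label) -> "Epochs":
        keep = self.labels == label
        if not keep.any():
            raise ValueError(f"no trials with label {label!r}")
        return replace(self, data=self.data[keep].copy(), labels=self.labels[keep].copy())

    def average(self, label=None) -> np.ndarray:
        """Trial-average evoked response, optionally for one condition."""
        ep = self if label is None else self.select(label)
        return ep.data.mean(axis=0)

    def decimate(self, factor: int) -> "Epochs":
        """Keep every ``factor``-th sample (no anti-alias filter; use after
        bandpass filtering well below the new Nyquist)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return replace(self, data=self.data[:, :, ::factor].copy(),
                       times=self.times[::factor].copy(), fs=self.fs / factor)
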