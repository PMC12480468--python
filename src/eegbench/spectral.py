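"""Spectral features: log-octave Morlet resting spectra, eyes-closed/open
contrast, IPEG band summaries, multitaper time-frequency maps and the
visual-task time-frequency bin features.

Resting spectra use 45 Morlet wavelets log-spaced in octaves over 1-45 Hz
with a 0.5-octave bandwidth (full width at half maximum of the wavelet's
spectral envelope), reported as one-sided power density in µV²/Hz. Visual
time-frequency maps use DPSS multitapers on 400 ms windows sliding in 50 ms
steps over 5-120 Hz in 2.5 Hz steps with ±5 Hz smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import montage as mont
from .preprocess import SegmentMask
from .recording import Epochs, Recording

N_WAVELETS = 45
FMIN, FMAX = 1.0, 45.0
BANDWIDTH_OCT = 0.5

#: IPEG pharmaco-EEG consensus band edges (Hz), half-open [lo, hi).
IPEG_BANDS = {
    "delta": (1.5, 6.0),
    "theta": (6.0, 8.5),
    "alpha1": (8.5, 10.5),
    "alpha2": (10.5, 12.5),
    "beta1": (12.5, 18.5),
    "beta2": (18.5, 21.0),
    "beta3": (21.0, 30.0),
    "gamma": (30.0, 40.0),
}

TFR_FREQS = np.arange(5.0, 120.0 + 1e-9, 2.5)  # 47 bins
TFR_WINDOW = 0.4           # s
TFR_STEP = 0.05            # s
TFR_HALF_BANDWIDTH = 5.0   # Hz

#: Visual-task time-frequency boxes: (fmin, fmax, tmin, tmax), half-open.
TFR_FEATURE_BOXES = {
    "alphabeta": (10.0, 20.0, 0.05, 1.5),
    "gamma_transient": (50.0, 75.0, 0.05, 0.5),
    "gamma_sustained": (50.0, 75.0, 0.5, 1.0),
}


def morlet_grid(n: int = N_WAVELETS, fmin: float = FMIN, fmax: float = FMAX) -> np.ndarray:
    """Log-octave frequency grid: n points, equal log2 spacing."""
    return 2.0 ** np.linspace(np.log2(fmin), np.log2(fmax), n)


@dataclass
class PowerSpectrum:
    power: np.ndarray          # (n_channels, n_freqs) µV²/Hz
    freqs: np.ndarray
    channels: list
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if (self.power < 0).any():
            raise ValueError("power must be non-negative")
        d = np.diff(np.log2(self.freqs))
        if not (d > 0).all():
            raise ValueError("frequency grid must be strictly increasing")

    def channel_average(self) -> np.ndarray:
        return self.power.mean(axis=0)


def _morlet_wavelet(f: float, fs: float, bandwidth_oct: float = BANDWIDTH_OCT):
    """Complex Morlet at frequency f; spectral FWHM = half an octave."""
    fwhm_hz = f * (2.0 ** (bandwidth_oct / 2) - 2.0 ** (-bandwidth_oct / 2))
    sigma_f = fwhm_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(-t ** 2 / (2 * sigma_t ** 2)) * np.exp(2j * np.pi * f * t)


def morlet_power(rec: Recording, segments: SegmentMask = None,
                 freqs: np.ndarray = None, min_retained_s: float = 10.0) -> PowerSpectrum:
    """Per-channel Morlet power density averaged over kept segments.

    The wavelet transform runs on the continuous recording; power is then
    averaged over the samples of kept segments only, so rejected stretches do
    not enter the estimate (their tails can still leak through long low-
    frequency wavelets; see the methods note).
    """
    freqs = morlet_grid() if freqs is None else np.asarray(freqs, dtype=float)
    if segments is not None:
        if not segments.keep.any():
            raise ValueError("segment mask keeps nothing")
        if segments.kept_seconds() < min_retained_s:
            raise ValueError(
                f"only {segments.kept_seconds():.1f} s retained; "
                f">= {min_retained_s} s required")
        sel = np.zeros(rec.n_samples, dtype=bool)
        for sl in segments.kept_slices():
            sel[sl] = True
    else:
        if rec.duration < min_retained_s:
            raise ValueError(f"recording shorter than {min_retained_s} s")
        sel = np.ones(rec.n_samples, dtype=bool)

    power = np.empty((rec.n_channels, len(freqs)))
    for j, f in enumerate(freqs):
        w = _morlet_wavelet(f, rec.fs)
        norm = 2.0 / (rec.fs * np.sum(np.abs(w) ** 2))  # one-sided density
        for c in range(rec.n_channels):
            y = sps.fftconvolve(rec.data[c], w, mode="same")
            power[c, j] = norm * np.mean(np.abs(y[sel]) ** 2)
    return PowerSpectrum(power=power, freqs=freqs, channels=list(rec.channels),
                         condition=rec.meta.get("condition", ""),
                         meta=dict(rec.meta))


def ec_eo_ratio(ec: PowerSpectrum, eo: PowerSpectrum) -> PowerSpectrum:
    """Eyes-closed over eyes-open power ratio, elementwise (Berger effect)."""
    if list(ec.channels) != list(eo.channels) or not np.allclose(ec.freqs, eo.freqs):
        raise ValueError("spectra must share channels and frequency grid")
    if (eo.power <= 0).any():
        raise ValueError("eyes-open spectrum has non-positive bins")
    return PowerSpectrum(power=ec.power / eo.power, freqs=ec.freqs,
                         channels=list(ec.channels), condition="ec/eo",
                         meta={"kind": "ratio"})


def band_features_ipeg(spec: PowerSpectrum, bands: dict = None,
                       meta: dict = None) -> pd.DataFrame:
    """Mean in-band power per IPEG band, per channel and channel-averaged.

    Band membership is half-open [lo, hi) on the wavelet grid; the feature is
    the plain mean of in-band bins. Emitted as long-format feature rows.
    """
    bands = bands or IPEG_BANDS
    meta = {**spec.meta, **(meta or {})}
    base = {k: meta.get(k) for k in ("subject", "session", "device", "task")}
    rows = []
    for name, (lo, hi) in bands.items():
        sel = (spec.freqs >= lo - 1e-12) & (spec.freqs < hi - 1e-12)
        if not sel.any():
            vals = np.zeros(spec.power.shape[0])
        else:
            vals = spec.power[:, sel].mean(axis=1)
        for c, v in zip(spec.channels, vals):
            rows.append({**base, "feature": name, "channel_scope": c, "value": float(v)})
        rows.append({**base, "feature": name, "channel_scope": "avg",
                     "value": float(vals.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multitaper time-frequency

@dataclass
class TimeFrequencyMap:
    """Power (or baseline-ratio) over channels x frequencies x times.

    ``data`` is (n_trials, n_channels, n_freqs, n_times) for per-trial maps
    or (n_channels, n_freqs, n_times) for trial averages; ``normalization``
    is 'power' (µV²) or 'ratio' (relative to the baseline window).
    """

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list
    normalization: str = "power"
    baseline: tuple = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3-D (avg) or 4-D (per trial)")
        if self.data.shape[-2] != len(self.freqs) or self.data.shape[-1] != len(self.times):
            raise ValueError("data shape does not match freq/time axes")

    @property
    def per_trial(self) -> bool:
        return self.data.ndim == 4

    def average(self) -> "TimeFrequencyMap":
        if not self.per_trial:
            return self
        return TimeFrequencyMap(self.data.mean(axis=0), self.freqs, self.times,
                                list(self.channels), self.normalization,
                                self.baseline, dict(self.meta))


def multitaper_tfr(epochs: Epochs, freqs: np.ndarray = None,
                   window: float = TFR_WINDOW, step: float = TFR_STEP,
                   half_bandwidth: float = TFR_HALF_BANDWIDTH) -> TimeFrequencyMap:
    """Per-trial DPSS multitaper power on the 5-120 Hz / 2.5 Hz / 50 ms grid.

    The time-bandwidth product is set so the spectral smoothing is
    ±``half_bandwidth`` Hz for the ``window``-second analysis windows.
    """
    from mne.time_frequency import tfr_array_multitaper

    freqs = TFR_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError(f"max frequency {freqs.max()} Hz >= Nyquist "
                         f"({epochs.fs / 2} Hz)")
    if epochs.times[-1] - epochs.times[0] < window:
        raise ValueError("epochs shorter than the analysis window")
    decim = step * epochs.fs
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError(f"sampling rate {epochs.fs} Hz does not support a "
                         f"{step} s step (need fs to be a multiple of {1 / step:.0f})")
    decim = int(round(decim))
    n_cycles = freqs * window
    time_bandwidth = 2.0 * window * half_bandwidth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_multitaper(
            epochs.data, sfreq=epochs.fs, freqs=freqs, n_cycles=n_cycles,
            time_bandwidth=time_bandwidth, output="power", decim=decim,
            verbose="error")
    times = epochs.times[::decim]
    # window centers closer than half a window to the epoch edges see zero
    # padding and are biased low; crop them
    valid = ((times >= epochs.times[0] + window / 2 - 1e-9)
             & (times <= epochs.times[-1] - window / 2 + 1e-9))
    power, times = power[..., valid], times[valid]
    return TimeFrequencyMap(power, freqs, times, list(epochs.channels),
                            normalization="power",
                            meta={**epochs.meta, "window": window,
                                  "half_bandwidth": half_bandwidth})


def baseline_normalize(tfr: TimeFrequencyMap, baseline=(-0.5, -0.1)) -> TimeFrequencyMap:
    """Ratio to the mean pre-stimulus power, per channel and frequency.

    The baseline mean is taken over the baseline window and, for per-trial
    maps, over trials, so single-trial fluctuations do not destabilize the
    denominator.
    """
    sel = (tfr.times >= baseline[0] - 1e-9) & (tfr.times < baseline[1] - 1e-9)
    if not sel.any():
        raise ValueError(f"no time points in the baseline window {baseline}")
    if tfr.per_trial:
        base = tfr.data[..., sel].mean(axis=(0, -1))     # (n_ch, n_freqs)
        data = tfr.data / base[None, :, :, None]
    else:
        base = tfr.data[..., sel].mean(axis=-1)
        data = tfr.data / base[:, :, None]
    return TimeFrequencyMap(data, tfr.freqs, tfr.times, list(tfr.channels),
                            normalization="ratio", baseline=tuple(baseline),
                            meta=dict(tfr.meta))


def tfr_bin_features(tfr: TimeFrequencyMap, roi=mont.VISUAL_ROI,
                     boxes: dict = None, meta: dict = None) -> pd.DataFrame:
    """Mean normalized power in the visual-task time-frequency boxes.

    Boxes are half-open in both time and frequency ([start, end)); the value
    averages over ROI channels. Requires a baseline-normalized map; a missing
    ROI channel raises naming it (e.g. an 18-channel device lacking Pz must
    drop it from the ROI explicitly).
    """
    if tfr.normalization != "ratio":
        raise ValueError("tfr must be baseline-normalized (ratio) first")
    boxes = boxes or TFR_FEATURE_BOXES
    missing = [c for c in roi if c not in tfr.channels]
    if missing:
        raise ValueError(f"ROI channels missing from the map: {missing}")
    ch_idx = [tfr.channels.index(c) for c in roi]
    data = tfr.average().data            # (n_ch, n_freqs, n_times)
    base = {k: (meta or {}).get(k, tfr.meta.get(k))
            for k in ("subject", "session", "device", "task")}
    rows = []
    for name, (flo, fhi, tlo, thi) in boxes.items():
        fsel = (tfr.freqs >= flo - 1e-9) & (tfr.freqs < fhi - 1e-9)
        tsel = (tfr.times >= tlo - 1e-9) & (tfr.times < thi - 1e-9)
        if not fsel.any() or not tsel.any():
            raise ValueError(f"box {name} selects no bins on this grid")
        val = data[np.ix_(ch_idx, np.where(fsel)[0], np.where(tsel)[0])].mean()
        rows.append({**base, "feature": name, "channel_scope": "roi",
                     "value": float(val)})
    return pd.DataFrame(rows)
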