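"""Automated EEG cleaning pipeline.

Fixed stage order: bandpass filter -> bad-channel detection -> flat-segment
rejection -> ICA artifact-component removal -> segment classifier ->
spherical-spline interpolation of bad channels -> average reference.

Rejection rules operate on consecutive non-overlapping 2 s epochs. A channel
is bad when more than 20% of epochs trigger any of: (a) variance below
0.1 µV² (flat), (b) peak amplitude above 500 µV (extreme), or (c) peak
amplitude above 100 µV while correlating below 0.6 with every other channel
(decoupled electrode). Flat segments are found by scanning each 2 s segment
with 200 ms sliding windows and dropping the segment if any window variance
falls below 0.1 µV² on any channel. All thresholds are config-exposed;
amplitude thresholds are interpreted in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from . import montage as mont
from .recording import Recording


# ---------------------------------------------------------------------------
# configuration

TASK_BANDS = {"rest": (1.0, 45.0), "p300": (1.0, 60.0), "gamma": (1.0, 120.0)}


@dataclass
class RejectionConfig:
    epoch_len: float = 2.0          # s, channel-rule epochs
    flat_variance: float = 0.1      # µV²
    extreme_amplitude: float = 500.0  # µV, rule (b)
    moderate_amplitude: float = 100.0  # µV, rule (c)
    correlation: float = 0.6
    corr_mode: str = "all"          # 'all': decoupled from every other channel
    bad_epoch_fraction: float = 0.20
    window_len: float = 0.2         # s, flat-segment sliding window
    window_step: float = 0.1        # s (50% overlap)


# ---------------------------------------------------------------------------
# verdict containers

@dataclass
class ChannelVerdict:
    channel: str
    bad: bool
    fraction_bad_epochs: float
    triggering_rules: frozenset

    def to_dict(self):
        return {"channel": self.channel, "bad": bool(self.bad),
                "fraction_bad_epochs": float(self.fraction_bad_epochs),
                "triggering_rules": sorted(self.triggering_rules)}


@dataclass
class SegmentMask:
    """Keep/drop verdicts for consecutive 2 s segments tiling a recording.

    ``bounds`` are half-open (start, stop) sample intervals; a trailing
    partial segment is not tiled and its length is recorded explicitly.
    """

    bounds: list                    # [(start, stop), ...]
    keep: np.ndarray                # bool per segment
    reasons: list                   # None or 'flat' / 'classifier' per segment
    fs: float
    n_trailing_samples: int = 0

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        starts = [b[0] for b in self.bounds]
        stops = [b[1] for b in self.bounds]
        if any(s2 != s1 for s1, s2 in zip(stops[:-1], starts[1:])):
            raise ValueError("segments must tile the recording without overlap")

    @property
    def n_segments(self):
        return len(self.bounds)

    def kept_slices(self):
        return [slice(a, b) for (a, b), k in zip(self.bounds, self.keep) if k]

    def kept_seconds(self) -> float:
        return sum((b - a) for (a, b), k in zip(self.bounds, self.keep) if k) / self.fs

    def merge(self, other: "SegmentMask") -> "SegmentMask":
        """Intersect keep flags with another mask over the same tiling."""
        if self.bounds != other.bounds:
            raise ValueError("masks tile the recording differently")
        keep = self.keep & other.keep
        reasons = [r1 if r1 is not None else r2
                   for r1, r2 in zip(self.reasons, other.reasons)]
        return SegmentMask(self.bounds, keep, reasons, self.fs, self.n_trailing_samples)

    def to_dict(self):
        return {"bounds": [list(b) for b in self.bounds],
                "keep": self.keep.astype(int).tolist(),
                "reasons": self.reasons,
                "n_trailing_samples": int(self.n_trailing_samples)}


def tile_segments(n_samples: int, fs: float, seg_len: float = 2.0):
    """Half-open 2 s segment bounds tiling [0, n_samples); trailing partial
    samples are excluded and counted."""
    step = int(round(seg_len * fs))
    n_full = n_samples // step
    bounds = [(i * step, (i + 1) * step) for i in range(n_full)]
    return bounds, n_samples - n_full * step


# ---------------------------------------------------------------------------
# filtering

def bandpass_filter(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase Hamming-windowed FIR bandpass (firwin design heuristic)."""
    import mne

    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= rec.fs / 2:
        raise ValueError(f"high={high} Hz is at/above Nyquist ({rec.fs / 2} Hz)")
    data = mne.filter.filter_data(
        rec.data, rec.fs, low, high, method="fir", fir_window="hamming",
        fir_design="firwin", phase="zero", verbose="error")
    out = replace(rec, data=data, meta={**rec.meta, "band": (low, high)},
                  channels=list(rec.channels), events=list(rec.events))
    return out


# ---------------------------------------------------------------------------
# channel rules

def detect_bad_channels(rec: Recording, config: RejectionConfig = None) -> list:
    """Apply the per-epoch flat / extreme / decoupled rules channel-wise."""
    cfg = config or RejectionConfig()
    if rec.n_channels < 2:
        raise ValueError("channel correlation rule undefined for a single channel")
    bounds, _ = tile_segments(rec.n_samples, rec.fs, cfg.epoch_len)
    if not bounds:
        raise ValueError("recording shorter than one epoch")
    n_ch = rec.n_channels
    n_ep = len(bounds)
    epoch_bad = np.zeros((n_ch, n_ep), dtype=bool)
    rules_hit = [set() for _ in range(n_ch)]
    for e, (a, b) in enumerate(bounds):
        seg = rec.data[:, a:b]
        var = seg.var(axis=1)
        maxabs = np.abs(seg).max(axis=1)
        flat = var < cfg.flat_variance
        extreme = maxabs > cfg.extreme_amplitude
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(seg)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, -np.inf)
        if cfg.corr_mode == "all":
            decorr = (corr < cfg.correlation).all(axis=1)
        elif cfg.corr_mode == "any":
            decorr = (corr < cfg.correlation).any(axis=1)
        else:
            raise ValueError("corr_mode must be 'all' or 'any'")
        uncorrelated = (maxabs > cfg.moderate_amplitude) & decorr
        epoch_bad[:, e] = flat | extreme | uncorrelated
        for c in range(n_ch):
            if flat[c]:
                rules_hit[c].add("flat")
            if extreme[c]:
                rules_hit[c].add("extreme")
            if uncorrelated[c]:
                rules_hit[c].add("uncorrelated")
    frac = epoch_bad.mean(axis=1)
    return [ChannelVerdict(rec.channels[c], bool(frac[c] > cfg.bad_epoch_fraction),
                           float(frac[c]), frozenset(rules_hit[c]))
            for c in range(n_ch)]


def reject_flat_segments(rec: Recording, config: RejectionConfig = None) -> SegmentMask:
    """Drop 2 s segments containing any 200 ms window with variance < 0.1 µV²."""
    cfg = config or RejectionConfig()
    bounds, trailing = tile_segments(rec.n_samples, rec.fs, cfg.epoch_len)
    if not bounds:
        raise ValueError("recording shorter than one segment")
    wlen = int(round(cfg.window_len * rec.fs))
    wstep = max(1, int(round(cfg.window_step * rec.fs)))
    keep = np.ones(len(bounds), dtype=bool)
    reasons = [None] * len(bounds)
    for i, (a, b) in enumerate(bounds):
        seg = rec.data[:, a:b]
        flat = False
        for start in range(0, seg.shape[1] - wlen + 1, wstep):
            if seg[:, start:start + wlen].var(axis=1).min() < cfg.flat_variance:
                flat = True
                break
        if flat:
            keep[i] = False
            reasons[i] = "flat"
    return SegmentMask(bounds, keep, reasons, rec.fs, trailing)


# ---------------------------------------------------------------------------
# segment features + classifier

#: Versioned feature order for the segment classifier. The first eleven are
#: the artifact-rejection standards (joint probability, kurtosis, amplitude
#: extremes of EEG and ICA time courses, mean channel deviation, epoch
#: variance, peak-to-peak amplitude); the last three fill out the schema with
#: line-noise ratio, spectral slope and maximum sample-to-sample gradient.
SEGMENT_FEATURE_SCHEMA = (
    "jointprob_eeg", "jointprob_ica",
    "kurtosis_eeg", "kurtosis_ica",
    "max_amplitude_eeg", "max_amplitude_ica",
    "min_amplitude_eeg", "min_amplitude_ica",
    "mean_deviation", "epoch_variance", "max_amplitude_difference",
    "line_noise_ratio", "spectral_slope", "max_gradient",
)
SEGMENT_FEATURE_VERSION = "1"


@dataclass
class SegmentFeatures:
    values: np.ndarray
    schema: tuple = SEGMENT_FEATURE_SCHEMA
    version: str = SEGMENT_FEATURE_VERSION
    flags: dict = field(default_factory=dict)

    def as_array(self):
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name):
        return float(self.values[self.schema.index(name)])


class _AmplitudeDensity:
    """Histogram density of amplitudes over a reference signal; used for the
    joint-probability feature (mean negative log-likelihood)."""

    def __init__(self, reference: np.ndarray, n_bins: int = 200):
        x = np.asarray(reference, dtype=float).ravel()
        lo, hi = np.quantile(x, [0.001, 0.999])
        pad = 0.05 * (hi - lo) + 1e-12
        self.edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
        counts, _ = np.histogram(x, bins=self.edges)
        width = self.edges[1] - self.edges[0]
        self.pdf = (counts + 1.0) / ((counts.sum() + n_bins) * width)

    def neg_log_likelihood(self, x: np.ndarray) -> float:
        idx = np.clip(np.searchsorted(self.edges, np.ravel(x)) - 1, 0, len(self.pdf) - 1)
        return float(-np.log(self.pdf[idx]).mean())


class SegmentFeatureExtractor:
    """Computes the 14-feature schema for segments of one recording.

    The joint-probability densities and per-channel means are fit on the full
    recording (and its ICA source time courses when available), so features
    measure how unusual a segment is relative to its own recording.
    """

    def __init__(self, rec: Recording, sources: np.ndarray = None):
        self.fs = rec.fs
        self.channel_means = rec.data.mean(axis=1)
        self.density_eeg = _AmplitudeDensity(rec.data)
        self.sources = sources
        self.density_ica = _AmplitudeDensity(sources) if sources is not None else None
        if sources is not None:
            self.source_means = sources.mean(axis=1)

    def extract(self, segment: np.ndarray, sources_segment: np.ndarray = None) -> SegmentFeatures:
        segment = np.asarray(segment, dtype=float)
        if segment.size == 0:
            raise ValueError("empty segment")
        flags = {}
        vals = np.full(len(SEGMENT_FEATURE_SCHEMA), np.nan)

        def put(name, v):
            vals[SEGMENT_FEATURE_SCHEMA.index(name)] = v

        put("jointprob_eeg", self.density_eeg.neg_log_likelihood(segment))
        if segment.std() == 0:
            flags["zero_variance"] = True
            put("kurtosis_eeg", 0.0)
        else:
            put("kurtosis_eeg",
                float(np.max(spstats.kurtosis(segment, axis=1, fisher=True, bias=True))))
        put("max_amplitude_eeg", float(segment.max()))
        put("min_amplitude_eeg", float(segment.min()))
        put("mean_deviation",
            float(np.abs(segment.mean(axis=1) - self.channel_means).mean()))
        put("epoch_variance", float(segment.var(axis=1).mean()))
        put("max_amplitude_difference",
            float((segment.max(axis=1) - segment.min(axis=1)).max()))
        # spectral extras
        nper = min(segment.shape[1], int(self.fs))
        f, pxx = sps.welch(segment, fs=self.fs, nperseg=nper, axis=1)
        pxx_m = pxx.mean(axis=0)
        total = pxx_m.sum() + 1e-30
        line = pxx_m[(f >= 45) & (f <= 55)].sum()
        put("line_noise_ratio", float(line / total))
        fit_band = (f >= 2) & (f <= min(40, f.max()))
        if fit_band.sum() >= 3 and (pxx_m[fit_band] > 0).all():
            slope = np.polyfit(np.log(f[fit_band]), np.log(pxx_m[fit_band]), 1)[0]
        else:
            slope = 0.0
            flags["slope_undefined"] = True
        put("spectral_slope", float(slope))
        put("max_gradient", float(np.abs(np.diff(segment, axis=1)).max()
                                  if segment.shape[1] > 1 else 0.0))

        if sources_segment is not None and self.density_ica is not None:
            src = np.asarray(sources_segment, dtype=float)
            put("jointprob_ica", self.density_ica.neg_log_likelihood(src))
            put("kurtosis_ica",
                float(np.max(spstats.kurtosis(src, axis=1, fisher=True, bias=True)))
                if src.std() > 0 else 0.0)
            put("max_amplitude_ica", float(src.max()))
            put("min_amplitude_ica", float(src.min()))
        else:
            flags["ica_features_missing"] = True
            for name in ("jointprob_ica", "kurtosis_ica",
                         "max_amplitude_ica", "min_amplitude_ica"):
                put(name, 0.0)
        return SegmentFeatures(vals, flags=flags)

    def extract_all(self, rec: Recording, mask: SegmentMask,
                    sources: np.ndarray = None) -> list:
        out = []
        for a, b in mask.bounds:
            src = None if sources is None else sources[:, a:b]
            out.append(self.extract(rec.data[:, a:b], src))
        return out


def extract_segment_features(segment: np.ndarray, sources: np.ndarray = None,
                             fs: float = 250.0) -> SegmentFeatures:
    """One-off feature extraction using the segment itself as reference."""
    rec = Recording(data=np.asarray(segment, dtype=float), fs=fs,
                    channels=list(mont.STANDARD_1020[: len(segment)]))
    return SegmentFeatureExtractor(rec, sources).extract(segment, sources)


@dataclass
class SegmentClassifier:
    """A trained probabilistic keep/drop model over the 14-feature schema."""

    estimator: object
    schema: tuple
    version: str
    threshold: float = 0.5

    def predict_bad(self, features: list) -> np.ndarray:
        for ft in features:
            if ft.schema != self.schema or ft.version != self.version:
                raise ValueError("segment feature schema does not match the "
                                 f"classifier (model v{self.version})")
        X = np.stack([ft.as_array() for ft in features])
        proba = self.estimator.predict_proba(X)[:, 1]
        return proba >= self.threshold


def train_segment_classifier(features: list, bad_labels, seed: int = 0,
                             n_estimators: int = 200) -> SegmentClassifier:
    """Fit the Random-Forest segment classifier on labelled features
    (1 = artifact/drop, 0 = clean/keep)."""
    from sklearn.ensemble import RandomForestClassifier

    X = np.stack([ft.as_array() for ft in features])
    y = np.asarray(bad_labels, dtype=int)
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(X, y)
    return SegmentClassifier(est, SEGMENT_FEATURE_SCHEMA, SEGMENT_FEATURE_VERSION)


def segment_labels_from_mask(artifact_mask: np.ndarray, bounds: list,
                             min_overlap: float = 0.2) -> np.ndarray:
    """Ground-truth segment labels from a per-sample artifact mask: a
    segment is 'bad' (1) when more than ``min_overlap`` of its samples are
    artifactual."""
    return np.array([int(artifact_mask[a:b].mean() > min_overlap)
                     for a, b in bounds])


def classify_segments(features: list, model: SegmentClassifier,
                      mask: SegmentMask) -> SegmentMask:
    """Apply the trained classifier and merge drops into ``mask``."""
    if len(features) != mask.n_segments:
        raise ValueError("one feature vector per segment required")
    bad = model.predict_bad(features)
    keep = mask.keep & ~bad
    reasons = [r if r is not None else ("classifier" if b else None)
               for r, b in zip(mask.reasons, bad)]
    return SegmentMask(mask.bounds, keep, reasons, mask.fs, mask.n_trailing_samples)


# ---------------------------------------------------------------------------
# ICA component removal

def rule_based_component_classifier(topographies: np.ndarray, sources: np.ndarray,
                                    channels: list, fs: float) -> list:
    """Flag ocular and muscular independent components by simple rules.

    Ocular: |topography| concentrated frontally and source power dominated by
    low frequencies (< 5 Hz). Muscular: source power fraction above 20 Hz
    exceeds 60%. Serves as the default pluggable component classifier.
    """
    frontal_idx = [i for i, c in enumerate(channels) if c in mont.FRONTAL]
    n_ch = len(channels)
    base_frac = len(frontal_idx) / n_ch
    exclude = []
    for k in range(topographies.shape[1]):
        topo = np.abs(topographies[:, k])
        topo = topo / (topo.sum() + 1e-30)
        frontal_frac = topo[frontal_idx].sum()
        f, pxx = sps.welch(sources[k], fs=fs, nperseg=min(len(sources[k]), int(2 * fs)))
        band = (f >= 0.5) & (f <= 45)
        total = pxx[band].sum() + 1e-30
        low_frac = pxx[band & (f < 5)].sum() / total
        high_frac = pxx[band & (f > 20)].sum() / total
        if frontal_frac > 1.8 * base_frac and low_frac > 0.5:
            exclude.append(k)
        elif high_frac > 0.6:
            exclude.append(k)
    return exclude


def remove_artifact_components(rec: Recording, classifier=None, seed: int = 0,
                               n_components=None) -> Recording:
    """ICA-decompose, zero classifier-flagged components, reconstruct.

    ``classifier(topographies, sources, channels, fs) -> indices`` is
    pluggable; the default applies the ocular/muscular rules above. On ICA
    non-convergence the input is passed through with a warning flag.
    """
    import mne

    if rec.n_channels < 8:
        raise ValueError("ICA removal requires at least 8 channels")
    classifier = classifier or rule_based_component_classifier
    raw = rec.to_mne_raw()
    ica = mne.preprocessing.ICA(n_components=n_components, method="fastica",
                                rng=seed, max_iter=1000)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(raw, verbose="error")
    except Exception as err:  # non-convergence or rank trouble: pass through
        warnings.warn(f"ICA failed ({err}); returning recording unchanged")
        out = rec.copy()
        out.meta["ica"] = {"converged": False}
        return out
    sources = ica.get_sources(raw).get_data()
    topos = ica.get_components()
    exclude = list(classifier(topos, sources, list(rec.channels), rec.fs))
    clean = ica.apply(raw.copy(), exclude=exclude, verbose="error")
    out = replace(rec, data=clean.get_data(units="uV"), channels=list(rec.channels),
                  events=list(rec.events),
                  meta={**rec.meta,
                        "ica": {"converged": True, "n_components": topos.shape[1],
                                "excluded": exclude}})
    return out


# ---------------------------------------------------------------------------
# interpolation / referencing / subsampling

def interpolate_bad_channels(rec: Recording, bads: list) -> Recording:
    """Replace bad channels by spherical-spline estimates from good ones."""
    bads = [mont.canonical_label(b) for b in bads]
    unknown = [b for b in bads if b not in rec.channels]
    if unknown:
        raise ValueError(f"bad channels not in recording: {unknown}")
    if not bads:
        return rec.copy()
    n_good = rec.n_channels - len(bads)
    if n_good == 0:
        raise ValueError("all channels bad; nothing to interpolate from")
    if n_good < 4:
        raise ValueError(f"only {n_good} good channels; spherical spline needs >= 4")
    raw = rec.to_mne_raw()
    raw.info["bads"] = bads
    raw.interpolate_bads(reset_bads=True, mode="accurate", verbose="error")
    return replace(rec, data=raw.get_data(units="uV"), channels=list(rec.channels),
                   events=list(rec.events),
                   meta={**rec.meta, "interpolated": bads})


def rereference_average(rec: Recording) -> Recording:
    """Subtract the per-sample mean over channels (average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, channels=list(rec.channels),
                   events=list(rec.events),
                   meta={**rec.meta, "reference": "average"})


def subsample_to_1020(rec: Recording, keep=mont.STANDARD_1020) -> Recording:
    """Restrict to the 19 canonical channels *before* preprocessing.

    Downstream cleaning must run on the subsampled recording so no
    information leaks from the removed channels.
    """
    keep = mont.validate_labels(keep)
    missing = [l for l in keep if l not in rec.channels]
    if missing:
        raise ValueError(f"requested subsampling channels absent: {missing}")
    out = rec.pick(keep)
    out.meta["subsampled_before_preprocessing"] = True
    return out


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PreprocessResult:
    recording: Recording
    verdicts: list
    mask: SegmentMask
    log: dict


def run_preprocessing(rec: Recording, task: str = "rest",
                      rejection: RejectionConfig = None,
                      segment_model: SegmentClassifier = None,
                      component_classifier=None, seed: int = 0,
                      band=None) -> PreprocessResult:
    """Full cleaning pipeline in the fixed stage order (see module docstring)."""
    cfg = rejection or RejectionConfig()
    if band is None:
        if task not in TASK_BANDS:
            raise ValueError(f"unknown task {task!r}; give band= explicitly")
        band = TASK_BANDS[task]
    log = {"task": task, "band": band, "stages": []}

    cur = bandpass_filter(rec, *band)
    log["stages"].append({"stage": "filter", "band": band})

    verdicts = detect_bad_channels(cur, cfg)
    bads = [v.channel for v in verdicts if v.bad]
    log["stages"].append({"stage": "bad_channels", "bads": bads})

    mask = reject_flat_segments(cur, cfg)
    log["stages"].append({"stage": "flat_segments",
                          "dropped": int((~mask.keep).sum()),
                          "total": mask.n_segments})

    good = [c for c in cur.channels if c not in bads]
    if len(good) >= 8:
        sub = cur.pick(good)
        cleaned_sub = remove_artifact_components(sub, classifier=component_classifier,
                                                 seed=seed)
        cur = cur.copy()
        idx = [cur.channels.index(c) for c in good]
        cur.data[idx] = cleaned_sub.data
        log["stages"].append({"stage": "ica", **cleaned_sub.meta.get("ica", {})})
    else:
        log["stages"].append({"stage": "ica", "skipped": "fewer than 8 good channels"})

    if segment_model is not None:
        extractor = SegmentFeatureExtractor(cur)
        feats = extractor.extract_all(cur, mask)
        mask = classify_segments(feats, segment_model, mask)
        log["stages"].append({"stage": "segment_classifier",
                              "dropped": int((~mask.keep).sum())})
    else:
        log["stages"].append({"stage": "segment_classifier", "skipped": "no model"})

    if bads:
        cur = interpolate_bad_channels(cur, bads)
    log["stages"].append({"stage": "interpolation", "channels": bads})

    cur = rereference_average(cur)
    log["stages"].append({"stage": "average_reference"})
    return PreprocessResult(recording=cur, verdicts=verdicts, mask=mask, log=log)
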