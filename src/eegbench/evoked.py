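"""Oddball evoked analysis: epoching, P300 features, the noise-covariance
whitened global field potential (GFP), and per-timepoint decoding.

The GFP statistic: with baseline data X_b (P channels x T_b pooled baseline
samples) the empirical noise covariance is C = (1/T_b) X_b X_bᵀ. Whitening
the trial data, X_w = C^(-1/2) X, calibrates the per-timepoint
GFP = (1/P) Σ_channels x_w² so that P·GFP follows a chi-square with the
whitener's rank when post-stimulus data share the baseline distribution; an
evoked response shows up as GFP rising above the baseline level of ~1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Epochs, Recording


def epoch_oddball(rec: Recording, tmin: float = -0.3, tmax: float = 0.7,
                  latency_shift: float = 0.0, baseline_correct: bool = True) -> Epochs:
    """Cut trials around (shifted) stimulus onsets, half-open [tmin, tmax).

    ``latency_shift`` compensates a known trigger latency by shifting the
    analysis onset (a positive shift moves onsets later in the recording,
    i.e. the response appears ``latency_shift`` seconds earlier in the
    epoch). Each trial is baseline-corrected by its pre-onset channel means
    unless ``baseline_correct=False``. Partial epochs at the record edges
    are dropped and counted.
    """
    if abs(latency_shift) >= 0.1:
        raise ValueError("latency_shift must be below 100 ms")
    if not rec.events:
        raise ValueError("recording has no events")
    n_lo = int(round(tmin * rec.fs))
    n_hi = int(round(tmax * rec.fs))
    times = np.arange(n_lo, n_hi) / rec.fs
    shift = int(round(latency_shift * rec.fs))
    trials, labels, dropped = [], [], 0
    for s, lab in rec.events:
        a, b = s + shift + n_lo, s + shift + n_hi
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, a:b])
        labels.append(lab)
    if not trials:
        raise ValueError("no in-bounds events")
    if not any(l == "deviant" for l in labels):
        raise ValueError("no deviant trials in range")
    data = np.stack(trials)
    if baseline_correct:
        data = data - data[:, :, times < 0].mean(axis=2, keepdims=True)
    return Epochs(data=data, times=times, fs=rec.fs,
                  channels=list(rec.channels), labels=np.array(labels),
                  positions=rec.positions.copy(), shift=latency_shift,
                  meta={**rec.meta, "dropped_partial_epochs": dropped})


def p300_features(epochs: Epochs, channel: str = "Cz",
                  window=(0.25, 0.5), signed: bool = True):
    """Latency and amplitude of the P300 at Cz.

    The deviant-trial average evoked is searched for its maximal deflection
    within the 0.25-0.5 s post-stimulus window: the (signed, by default)
    maximum and its time. Latency ties break to the earliest sample.

    Returns
    -------
    (latency_s, amplitude_uv)
    """
    if channel not in epochs.channels:
        raise ValueError(f"channel {channel} absent from epochs")
    evoked = epochs.average("deviant")[epochs.channels.index(channel)]
    sel = epochs.time_mask(window[0], window[1])
    if not sel.any():
        raise ValueError("analysis window contains no samples")
    seg = evoked[sel] if signed else np.abs(evoked[sel])
    i = int(np.argmax(seg))           # argmax returns the first maximum
    t_win = epochs.times[sel]
    return float(t_win[i]), float(evoked[sel][i] if signed else seg[i])


@dataclass
class NoiseModel:
    """Baseline noise covariance and its inverse square root (whitener)."""

    covariance: np.ndarray     # (P, P) µV²
    whitener: np.ndarray       # (P, P), C^(-1/2) on the retained subspace
    rank: int
    channels: list
    regularization: float = 0.0

    def __post_init__(self):
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


def fit_noise_model(epochs: Epochs, baseline=(-0.3, 0.0),
                    rank_tol: float = 1e-10) -> NoiseModel:
    """Empirical covariance of pooled baseline samples and its whitener.

    Baselines of all trials are concatenated: C = (1/T_b) X_b X_bᵀ. The
    whitener is the eigendecomposition-based pseudo-inverse square root;
    eigenvalues below ``rank_tol`` times the largest are truncated (average-
    referenced data are rank P-1, which this handles automatically).
    """
    sel = epochs.time_mask(baseline[0], baseline[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    xb = epochs.data[:, :, sel]                       # (trials, P, t_b)
    P = epochs.n_channels
    xb = np.transpose(xb, (1, 0, 2)).reshape(P, -1)   # pooled (P, T_b)
    t_b = xb.shape[1]
    if t_b < P + 1:
        raise ValueError(f"{t_b} pooled baseline samples for {P} channels; "
                         "need at least P+1")
    cov = xb @ xb.T / t_b
    evals, evecs = np.linalg.eigh(cov)
    cut = rank_tol * evals.max()
    keep = evals > cut
    rank = int(keep.sum())
    if rank < 2:
        raise ValueError("noise covariance rank below 2")
    inv_sqrt = np.zeros_like(evals)
    inv_sqrt[keep] = 1.0 / np.sqrt(evals[keep])
    whitener = (evecs * inv_sqrt) @ evecs.T
    return NoiseModel(covariance=cov, whitener=whitener, rank=rank,
                      channels=list(epochs.channels), regularization=rank_tol)


@dataclass
class GfpTrace:
    """Whitened GFP per timepoint plus window aggregates."""

    times: np.ndarray
    gfp: np.ndarray                      # (n_times,), trial-averaged
    gfp_per_trial: np.ndarray            # (n_trials, n_times)
    n_channels: int
    rank: int
    window_means: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.gfp < 0).any():
            raise ValueError("GFP must be non-negative")


def p300_windows(epochs: Epochs, half_width: float = 0.05):
    """The two reporting windows: 100 ms around the deviant-evoked P300 peak
    and the fixed 300-600 ms post-stimulus window."""
    peak_t, _ = p300_features(epochs)
    return {"peak_100ms": (peak_t - half_width, peak_t + half_width),
            "300_600ms": (0.3, 0.6)}


def whitened_gfp(epochs: Epochs, model: NoiseModel, windows=None,
                 label: str = "deviant") -> GfpTrace:
    """Whiten each trial and average the per-timepoint GFP across trials.

    GFP(t) = (1/P) Σ_c x_w(c, t)²; under the null that trial data share the
    baseline distribution, P·GFP(t) ~ chi-square(rank)/1 per trial, so the
    baseline level is rank/P (≈1 at full rank). ``windows`` maps names to
    (start, stop) aggregation windows; by default the P300 peak ±50 ms and
    300-600 ms windows are reported when deviant trials are present.
    """
    if list(epochs.channels) != list(model.channels):
        raise ValueError("epochs and noise model have different channel sets")
    ep = epochs if label is None else epochs.select(label)
    xw = np.einsum("qp,ipt->iqt", model.whitener, ep.data)
    gfp_trials = (xw ** 2).mean(axis=1)             # (trials, times)
    gfp = gfp_trials.mean(axis=0)
    if windows is None:
        try:
            windows = p300_windows(epochs)
        except ValueError:
            windows = {}
    aggregates = {}
    for name, (a, b) in windows.items():
        sel = epochs.time_mask(a, b)
        aggregates[name] = float(gfp[sel].mean()) if sel.any() else np.nan
    return GfpTrace(times=epochs.times.copy(), gfp=gfp, gfp_per_trial=gfp_trials,
                    n_channels=epochs.n_channels, rank=model.rank,
                    window_means=aggregates)


def decode_auc(epochs: Epochs, window=None, n_folds: int = 5, C: float = 1.0,
               seed: int = 0, positive_label: str = "deviant"):
    """Per-timepoint logistic-regression decoding of trial labels.

    At each time sample the instantaneous topography (one value per channel)
    feeds an L2-regularized logistic regression; ROC AUC is estimated by
    stratified 5-fold cross-validation, pooling held-out decision values.
    Per-sample standardization is fit on the training folds only.

    Returns
    -------
    auc : ndarray (n_times,)
    window_mean : float
        Mean AUC over ``window`` (the full epoch when None).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    y = (epochs.labels == positive_label).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError(f"need >= {n_folds} trials per class, got {counts}")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(np.zeros(len(y)), y))
    n_times = epochs.data.shape[2]
    auc = np.empty(n_times)
    for t in range(n_times):
        X = epochs.data[:, :, t]
        scores = np.empty(len(y))
        for train, test in splits:
            clf = make_pipeline(StandardScaler(),
                                LogisticRegression(C=C, max_iter=1000))
            clf.fit(X[train], y[train])
            scores[test] = clf.decision_function(X[test])
        auc[t] = roc_auc_score(y, scores)
    if window is None:
        sel = np.ones(n_times, dtype=bool)
    else:
        sel = epochs.time_mask(window[0], window[1])
    return auc, float(auc[sel].mean())
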