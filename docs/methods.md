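# Methods

This note documents the models and numerical choices behind eegbench: what
the synthetic study generator emulates, how each analysis stage is defined,
and where design decisions were genuinely open.

## Synthetic study model

Real multi-device EEG study data are rarely shareable, so every analysis in
this package is exercised against a generative model that reproduces the
statistical structure the analyses assume — not the biophysics of any
particular head or amplifier.

**Background.** Each channel carries an independent Gaussian process with a
1/f power spectrum (spectrally shaped white noise, amplitude flattened
below 1 Hz to keep the process stationary), scaled to `background_sd`
(default 5 µV). On top of this, coherent sources are mixed through smooth
scalp topographies: a Gaussian in chord distance on the unit sphere,
mean-removed so the pattern is dipolar-like (positive focus, shallow
far-field negativity). Zero-mean topographies matter: an all-positive
pattern is common mode and would be attenuated by average referencing,
which the scalp projection of a cortical source is not.

**Alpha / Berger effect.** A single band-limited (9–11 Hz) source with a
posterior-dominant, scalp-wide topography (width 1.0 in chord distance),
amplitude `alpha_sd` = 7 µV at the focal channel — the conventional ~10 µV
posterior alpha peak. Eyes-closed recordings multiply the source variance
by `alpha_boost` (default 2), so the eyes-closed/eyes-open power ratio at
the alpha peak approaches the boost wherever alpha dominates the band.

**Oddball task.** The number of tones is `round(n_deviants / 0.15)`, so
deviants make up ~15% of stimuli by construction; onsets are separated by
uniform 1.2–1.9 s intervals. Every tone evokes a small fronto-central
negative deflection at 100 ms; deviants additionally evoke a positive
centro-parietal bump maximal near Cz, peaking `p300_amplitude` (6 µV) at
`p300_latency` (0.31 s). The template is Gaussian with 35 ms standard
deviation (~80 ms FWHM) — a fast P3-like deflection. The width is a
deliberate conditioning choice: the latency estimator is an argmax on the
sampling grid, and a much broader bump makes neighboring samples differ by
less than the attainable evoked noise floor, turning single-sample latency
recovery into a coin flip. The width is a parameter for users who want
broader, harder conditions.

**Visual task.** Occipito-parietal channels carry continuous 50–75 Hz and
10–20 Hz band-limited processes (independent per channel). During each 1 s
stimulus the gamma process variance is multiplied by `gamma_gain` and the
alpha/beta process variance by `alphabeta_drop`, relative to the
inter-stimulus baseline; stimulus onsets are separated by the stimulus
length plus a uniform 1–1.4 s gap, leaving the −0.5 to −0.1 s baseline
window clean.

**Artifacts.** Blink (frontal 0.3 s bumps, 150 µV), saccade (lateralized
frontal steps of opposite sign at F7/F8), jaw (1 s 30–100 Hz EMG bursts on
temporal channels), head (large slow excursions on all channels), all
scaled by the device's `artifact_susceptibility` and annotated in a
per-sample ground-truth mask used to train and score the segment
classifier.

**Study structure.** Feature-level ground truth follows
`value = mu + subject + session + device + residual` with Gaussian subject,
subject-by-session and residual effects; subject and session effects are
shared across devices (paired design), so the theoretical consistency ICC
between equal-offset devices is σ²_s/(σ²_s+σ²_e) and test–retest agreement
follows analogously. `generate_study` returns the truth table eagerly and
the recordings as lazy specs (a 32-subject four-device study is 256
recordings per task; materializing them is deferred to iteration).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: volume conduction from realistic sources
(mixing is through fixed synthetic topographies), electrode-skin impedance
physics and drift nonstationarity, line noise, heartbeat artifacts,
inter-subject spectral diversity (peak alpha frequency is fixed at 10 Hz),
and any device's true transfer function (devices differ only by broadband
gain, additive noise and artifact susceptibility).

## Preprocessing

Stage order is fixed and logged: bandpass filter → bad-channel detection →
flat-segment rejection → ICA component removal → segment classifier →
spherical-spline interpolation → average reference. Filters are zero-phase
Hamming-windowed FIR (firwin design heuristic for length and transition
bands) at 1–45 Hz (rest), 1–60 Hz (oddball), 1–120 Hz (visual).

Channel rules run on consecutive non-overlapping 2 s epochs; a channel is
bad when more than 20% of epochs show variance < 0.1 µV², peak |amplitude|
above 500 µV, or above 100 µV with Pearson correlation below 0.6 to
*every* other channel in that epoch (a genuinely decoupled electrode; an
"any other channel" reading is selectable in config). Amplitude thresholds
are interpreted in microvolts — scalp EEG never reaches hundreds of
millivolts — and all thresholds are config-exposed. Flat-segment scanning
uses 200 ms windows advancing in 100 ms steps (50% overlap; the step is a
package choice and config-exposed); any window variance below 0.1 µV² on
any channel drops the 2 s segment. Trailing partial segments are excluded
from the tiling and counted.

The segment classifier is a Random Forest over a versioned 14-feature
schema: joint probability (mean negative log-likelihood of segment
amplitudes under a histogram density fit to the whole recording), kurtosis,
maximum and minimum amplitude — each for the EEG channels and for ICA
source time courses — plus mean deviation from channel means, epoch
variance and maximum peak-to-peak amplitude, completed by line-noise ratio
(45–55 Hz power fraction), log-log spectral slope, and maximum
sample-to-sample gradient. The last three complete the schema where the
cited convention is not exhaustive; the order is versioned and enforced at
prediction time. In this package the classifier trains on generator
artifact fixtures with mask-derived labels (a segment is "bad" at > 20%
artifact overlap).

ICA decomposition is delegated to FastICA (via mne); component
*classification* is a pluggable callable, defaulting to two rules: ocular
(|topography| frontally enriched ≥ 1.8× the frontal channel share, plus
< 5 Hz power dominance) and muscular (> 20 Hz power fraction above 60%).
Spherical-spline interpolation uses the standard head-sphere convention
(stiffness order 4, regularization 1e-5). Interpolation requires at least
four good channels; ICA at least eight.

## Spectral estimation

Resting spectra use 45 analytic Morlet wavelets log-spaced in octaves over
1–45 Hz. The bandwidth convention: the wavelet's spectral envelope has a
full width at half maximum of half an octave around its center frequency,
i.e. FWHM(f) = f·(2^0.25 − 2^−0.25). Power is normalized as one-sided
density in µV²/Hz by the window-power rule PSD(f) = 2·E|x⋆w|²/(fs·Σ|w|²),
verified against the Welch level of white noise. Wavelet transforms run on
the continuous recording; power is averaged over kept-segment samples
only. Long low-frequency wavelets (±5σ support ≈ 11 s at 1 Hz) can leak
across segment boundaries; with the ≥ 10 s retained-data requirement this
bias is small but not zero. IPEG band averages use edges delta 1.5–6,
theta 6–8.5, alpha1 8.5–10.5, alpha2 10.5–12.5, beta1 12.5–18.5, beta2
18.5–21, beta3 21–30, gamma 30–40 Hz (half-open bins, plain mean of
in-band wavelet bins; config-exposed).

Visual-task maps use DPSS multitapers on 400 ms windows sliding in 50 ms
steps, 5–120 Hz in 2.5 Hz steps, time-bandwidth 4 (= 2 × 0.4 s × 5 Hz, i.e.
±5 Hz smoothing). Window centers closer than 200 ms to an epoch edge see
zero padding and are cropped — without this the baseline is biased low and
every post-minus-baseline statistic inherits a spurious positive shift.
Baseline normalization divides by the mean power over −0.5 to −0.1 s
(per channel and frequency, averaged over trials for per-trial maps). The
feature boxes (α/β 10–20 Hz × 0.05–1.5 s; γ_t 50–75 Hz × 0.05–0.5 s; γ_s
50–75 Hz × 0.5–1 s) are half-open in both axes, so a bin at exactly 0.5 s
belongs to sustained, not transient gamma; values average the ROI
O1, O2, P3, Pz, P4, C3, Cz, C4 (callers with an 18-channel montage drop Pz
explicitly).

## Evoked analysis

Epochs span −0.3 to 0.7 s around (optionally latency-shifted) onsets and
are baseline-corrected by their pre-onset channel means — without this the
1 Hz highpass biases absolute peak amplitudes low while depressing the
baseline by the same mechanism. P300 latency/amplitude is the signed
maximum of the deviant-average evoked at Cz within 0.25–0.5 s; ties break
to the earliest sample, and a |max| variant is available by flag.

The noise model pools baseline samples across trials (more stable than
per-trial covariances at 25–35 trials): C = (1/T_b) X_b X_bᵀ. The whitener
is the eigendecomposition pseudo-inverse square root with eigenvalues below
1e-10 of the maximum truncated — average-referenced data are rank P−1 and
handled automatically. Whitened GFP is computed per trial and averaged
(the chi-square calibration is a per-trial statement); per-timepoint
P·GFP ~ χ² at the whitener's rank under the null, so baseline GFP ≈
rank/P ≈ 1. Window aggregates report the P300-peak ±50 ms and the
300–600 ms windows; the peak location comes from the same dataset's
deviant grand evoked.

Decoding fits an L2-regularized logistic regression (fixed C = 1) on the
instantaneous topography at each time sample, with per-sample
standardization fit on training folds only, stratified 5-fold CV, and ROC
AUC computed from pooled held-out decision values. Both the full-epoch and
post-stimulus window means are available.

## Reliability

ICCs come from the two-way ANOVA mean squares of a complete subjects ×
raters matrix: consistency ICC(C,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E) and
absolute agreement ICC(A,1) adds (k/n)(MS_C − MS_E) to the denominator
(single-measure forms, matching single-measurement reporting). Rows with
missing cells are dropped. Device comparisons treat devices as raters;
test–retest treats the two recording days as raters and reports absolute
agreement. Confidence intervals are percentile bootstrap over subjects
(resampling rows preserves within-subject pairing); analytic F-based CIs
are deliberately out of scope. Qualitative labels use left-closed bins:
below 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good, 0.9 and above
excellent — 0.75 reads as good.

## Cluster permutation test

Each time-frequency bin is compared against the per-trial, per-frequency
baseline average with a paired t-test across trials (zero-variance bins
get t = 0 and are flagged). Bins with |t| above 1.28 — the 90th percentile
of the standard normal; with the trial counts involved the t distribution
is indistinguishable from normal at this cut — form clusters under the
combined neighborhood: adjacent sensors at the same (frequency, time), or
the same sensor at ±1 frequency or time step (rook adjacency, no
diagonals). Sensor adjacency is Delaunay triangulation on the
azimuthal-equidistant projection of the montage with edges beyond 1.6× the
median edge length pruned (cap config-exposed; isolated channels get their
shortest edge back).

Significance uses trial-wise sign flips of the per-trial difference maps —
the standard exchangeable scheme for a paired design — with
p_FWER = (1 + #{perm ≥ obs})/(n_perm + 1) against the permutation
distribution of the maximum cluster-level statistic. The default cluster
statistic is the maximum absolute t within the cluster; its permutation
maximum over clusters equals the largest supra-threshold |t| in the
permuted map, so no per-permutation clustering is needed — an exact
shortcut, not an approximation. Cluster mass (sum of t) is available as
the conventional alternative and does cluster every permutation. Summaries
report, per sign, the percentage of electrodes in significant clusters at
each time-frequency bin, and per electrode the percentage of
region-of-interest time-frequency bins covered.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed give
byte-identical outputs, including feature CSVs. The validation suite runs
at desk scale as a package choice: decoder null calibration uses 100 label
permutations of a 200-trial oddball session on a 50 Hz decoding grid (the
chance level is invariant to decimation); GFP calibration uses 250 null
epochs (~19k pooled baseline samples, enough that whitener sampling error
stays below what a 10⁴-sample KS test resolves); ICC recovery uses 101
replicate studies of 200 subjects per true-ICC level; type-I calibration
of the cluster test uses 100 null visual datasets of 20 trials with 200
permutations each; Berger and P300 recovery run the full pipeline on 60 s
resting records and a 60-deviant low-noise oddball session respectively.

## Known limitations

* The generator's device differences are gain/noise abstractions; no
  claim is made about any commercial device.
* Morlet segment averaging is exact only for segment-interior samples;
  low-frequency wavelets leak across rejected-segment boundaries.
* The rule-based ICA component classifier is a deliberately simple default
  for the pluggable interface, not a replacement for trained classifiers;
  it will miss mixed or atypical components.
* The flat-signal variance threshold (0.1 µV²) bounds from below the noise
  floor at which the pipeline can operate; recordings quieter than that
  are treated as instrument failure by design.
* ICC machinery covers k = 2 raters per comparison (device pairs, day
  pairs) with single-measure forms; average-measure and k > 2 designs are
  out of scope.
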