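"""Synthetic multi-device, multi-session EEG study generator.

Emulates the statistical structure that the downstream analyses assume:

* 1/f background with a ~10 Hz alpha rhythm of posterior topography and an
  eyes-closed alpha boost (Berger effect),
* device-specific broadband power offsets and sensor noise,
* an auditory oddball stream (~15% deviants) with a P300-like positive
  deflection that is maximal near Cz at 250-500 ms,
* a visual stimulation task with induced 50-75 Hz gamma increase and
  10-20 Hz alpha/beta decrease over occipito-parietal channels,
* artifact conditions (blinks, saccades, jaw EMG, head movement) with a
  per-sample ground-truth mask,
* subject / session / device / residual variance components at the feature
  level, for intraclass-correlation parameter recovery.

Everything is deterministic given the seed. Amplitudes are in microvolts;
the absolute scale is conventional (alpha ~10 µV peak posteriorly), chosen
to resemble adult resting scalp EEG rather than any particular amplifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import montage as mont
from .recording import Recording

DEVIANT_RATE = 0.15


# ---------------------------------------------------------------------------
# study configuration types

@dataclass
class DeviceProfile:
    """Acquisition characteristics of one EEG device.

    broadband_offset multiplies signal *power* (dry electrodes typically sit
    above the gel-based reference); sensor_noise_sd is additive white noise,
    lowfreq_noise_sd adds device-idiosyncratic drift below 6 Hz, and
    artifact_susceptibility scales motion/EMG artifact amplitudes.
    """

    name: str
    broadband_offset: float = 1.0
    sensor_noise_sd: float = 2.0
    lowfreq_noise_sd: float = 1.0
    artifact_susceptibility: float = 1.0
    channel_set: tuple = mont.STANDARD_1020

    def __post_init__(self):
        if not self.broadband_offset > 0:
            raise ValueError("broadband_offset must be > 0")
        if self.sensor_noise_sd < 0 or self.lowfreq_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.artifact_susceptibility < 0:
            raise ValueError("artifact_susceptibility must be >= 0")
        self.channel_set = tuple(mont.validate_labels(self.channel_set))


def default_profiles() -> list:
    """A four-device study: gel-based reference plus three dry devices.

    Offsets emulate the consistent positive broadband power offset of dry
    electrodes relative to standard gel EEG; the 18-channel device lacks Pz.
    """
    no_pz = tuple(l for l in mont.STANDARD_1020 if l != "Pz")
    return [
        DeviceProfile("standard", broadband_offset=1.0, sensor_noise_sd=1.0,
                      lowfreq_noise_sd=0.5),
        DeviceProfile("dry_a", broadband_offset=2.5, sensor_noise_sd=3.0,
                      lowfreq_noise_sd=2.0, artifact_susceptibility=1.5,
                      channel_set=no_pz),
        DeviceProfile("dry_b", broadband_offset=1.8, sensor_noise_sd=2.5,
                      lowfreq_noise_sd=1.5, artifact_susceptibility=1.3),
        DeviceProfile("dry_c", broadband_offset=3.2, sensor_noise_sd=3.5,
                      lowfreq_noise_sd=2.5, artifact_susceptibility=1.8),
    ]


@dataclass
class StudyDesign:
    """Layout and variance components of a synthetic multi-device study.

    Feature-level ground truth follows
    ``value = mu + subject + session + device + residual`` with independent
    Gaussian subject (sd ``subject_sd``), subject-by-session (sd
    ``session_sd``) and residual (sd ``residual_sd``) effects; the device
    term is the fixed per-device offset ``device_effects``.
    """

    n_subjects: int = 32
    devices: list = field(default_factory=default_profiles)
    n_sessions: int = 2
    subject_sd: float = 1.0
    session_sd: float = 0.3
    residual_sd: float = 0.5
    device_effects: list = None
    seed: int = 0

    def __post_init__(self):
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if min(self.subject_sd, self.session_sd, self.residual_sd) < 0:
            raise ValueError("variance components must be >= 0")
        if self.device_effects is None:
            self.device_effects = [0.0] * len(self.devices)
        if len(self.device_effects) != len(self.devices):
            raise ValueError("one device effect per device required")


# ---------------------------------------------------------------------------
# signal building blocks

def _rng(seed):
    return np.random.default_rng(seed)


def colored_noise(n_samples: int, fs: float, beta: float, rng,
                  f_floor: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^beta Gaussian noise via spectral shaping.

    The amplitude response is flattened below ``f_floor`` to keep the
    process stationary (no unbounded drift).
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = 1.0 / np.maximum(freqs, f_floor) ** (beta / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def bandlimited_noise(n_samples: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi] Hz (brick wall)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.where(mask, 1.0, 0.0) * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _topo_weights(positions: np.ndarray, center: np.ndarray, width: float = 0.7,
                  zero_mean: bool = False) -> np.ndarray:
    """Smooth scalp topography: Gaussian in chord distance, max 1 at center.

    ``zero_mean=True`` gives a dipolar-like pattern (positive focus, shallow
    far-field negativity) whose channel mean vanishes, as scalp projections
    of coherent cortical sources do; such sources survive average
    referencing unattenuated at their focal channel.
    """
    d = np.linalg.norm(positions - center, axis=1)
    w = np.exp(-(d ** 2) / (2.0 * width ** 2))
    if zero_mean:
        w = w - w.mean()
    return w / w.max()


def _center(label: str) -> np.ndarray:
    return mont.positions([label])[0]


_OZ_ISH = None


def _posterior_center():
    # midpoint of O1/O2 on the sphere (no Oz in the 19-channel montage)
    p = mont.positions(["O1", "O2"]).mean(axis=0)
    return p / np.linalg.norm(p)


def _background(n_ch: int, n_samples: int, fs: float, rng, sd: float) -> np.ndarray:
    return sd * np.stack([colored_noise(n_samples, fs, 1.0, rng) for _ in range(n_ch)])


def _apply_profile(data: np.ndarray, profile: DeviceProfile, fs: float, rng) -> np.ndarray:
    out = data * np.sqrt(profile.broadband_offset)
    if profile.sensor_noise_sd > 0:
        out = out + profile.sensor_noise_sd * rng.standard_normal(out.shape)
    if profile.lowfreq_noise_sd > 0:
        n = out.shape[1]
        lf = np.stack([bandlimited_noise(n, fs, 0.1, 6.0, rng) for _ in range(out.shape[0])])
        out = out + profile.lowfreq_noise_sd * lf
    return out


# ---------------------------------------------------------------------------
# task generators

def generate_resting(profile: DeviceProfile, condition: str, duration_s: float = 300.0,
                     fs: float = 250.0, alpha_boost: float = 2.0, seed: int = 0,
                     background_sd: float = 5.0, alpha_sd: float = 7.0) -> Recording:
    """Resting-state recording, eyes open or closed.

    A spatially coherent ~10 Hz alpha source with posterior-dominant
    topography rides on independent per-channel 1/f background. Closing the
    eyes multiplies alpha *variance* by ``alpha_boost`` (Berger effect).
    """
    if condition not in ("eyes-open", "eyes-closed"):
        raise ValueError("condition must be 'eyes-open' or 'eyes-closed'")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    if alpha_boost < 1:
        raise ValueError("alpha_boost must be >= 1")
    channels = list(profile.channel_set)
    positions = mont.positions(channels)
    n = int(round(duration_s * fs))
    rng = _rng(seed)

    data = _background(len(channels), n, fs, rng, background_sd)
    alpha_src = bandlimited_noise(n, fs, 9.0, 11.0, rng)
    # posterior-dominant but scalp-wide, as eyes-closed alpha spreads forward
    w = _topo_weights(positions, _posterior_center(), width=1.0, zero_mean=True)
    scale = alpha_sd * (np.sqrt(alpha_boost) if condition == "eyes-closed" else 1.0)
    data += scale * np.outer(w, alpha_src)
    data = _apply_profile(data, profile, fs, rng)
    return Recording(data=data, fs=fs, channels=channels, positions=positions,
                     meta={"task": f"rest_{'ec' if condition == 'eyes-closed' else 'eo'}",
                           "device": profile.name, "condition": condition})


def _evoked_template(times: np.ndarray, amplitude: float, latency: float,
                     width: float = 0.06) -> np.ndarray:
    return amplitude * np.exp(-((times - latency) ** 2) / (2.0 * width ** 2))


def generate_oddball(profile: DeviceProfile, n_deviants: int = 30,
                     isi_range=(1.2, 1.9), p300_amplitude: float = 6.0,
                     p300_latency: float = 0.31, p300_width: float = 0.035,
                     fs: float = 250.0, seed: int = 0,
                     background_sd: float = 5.0, n1_amplitude: float = 2.0) -> Recording:
    """Auditory oddball stream with a P300-like deviant response.

    The total tone count is chosen so deviants make up ~15% of stimuli.
    Each stimulus evokes a small fronto-central N1-like deflection; deviants
    additionally evoke a positive centro-parietal bump peaking
    ``p300_amplitude`` µV at ``p300_latency`` s, maximal near Cz.
    """
    if not (1 <= n_deviants <= 1000):
        raise ValueError("n_deviants must be in [1, 1000]")
    if not (0.25 <= p300_latency <= 0.5):
        raise ValueError("p300_latency must lie in [0.25, 0.5] s (analysis window)")
    if isi_range[0] > isi_range[1]:
        raise ValueError("isi_range must be (low, high) with low <= high")
    channels = list(profile.channel_set)
    positions = mont.positions(channels)
    rng = _rng(seed)

    n_total = int(round(n_deviants / DEVIANT_RATE))
    is_deviant = np.zeros(n_total, dtype=bool)
    is_deviant[rng.choice(n_total, size=n_deviants, replace=False)] = True
    isis = rng.uniform(isi_range[0], isi_range[1], size=n_total)
    onsets_t = 2.0 + np.concatenate([[0.0], np.cumsum(isis[:-1])])
    duration = onsets_t[-1] + 2.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    data = _background(len(channels), n, fs, rng, background_sd)
    w_n1 = _topo_weights(positions, _center("Fz"), width=0.8, zero_mean=True)
    w_p3 = _topo_weights(positions, _center("Cz"), width=0.8, zero_mean=True)
    tmpl_win = np.arange(int(round(0.7 * fs))) / fs
    n1 = -_evoked_template(tmpl_win, n1_amplitude, 0.1, width=0.025)
    p3 = _evoked_template(tmpl_win, p300_amplitude, p300_latency, width=p300_width)
    events = []
    for onset_t, dev in zip(onsets_t, is_deviant):
        s = int(round(onset_t * fs))
        events.append((s, "deviant" if dev else "standard"))
        stop = min(s + len(tmpl_win), n)
        seg = slice(s, stop)
        k = stop - s
        data[:, seg] += np.outer(w_n1, n1[:k])
        if dev:
            data[:, seg] += np.outer(w_p3, p3[:k])
    data = _apply_profile(data, profile, fs, rng)
    return Recording(data=data, fs=fs, channels=channels, positions=positions,
                     events=events,
                     meta={"task": "p300", "device": profile.name,
                           "n_deviants": n_deviants, "p300_latency": p300_latency,
                           "p300_amplitude": p300_amplitude})


def generate_visual(profile: DeviceProfile, n_trials: int = 300,
                    gamma_gain: float = 2.0, alphabeta_drop: float = 0.6,
                    fs: float = 500.0, seed: int = 0, background_sd: float = 5.0,
                    gamma_sd: float = 1.0, alphabeta_sd: float = 3.0,
                    stim_duration: float = 1.0, isi_range=(1.0, 1.4),
                    gamma_channels=None) -> Recording:
    """Visual stimulation task with induced gamma increase and alpha/beta drop.

    Occipito-parietal channels carry continuous 50-75 Hz and 10-20 Hz noise
    processes. During each 1 s stimulus the gamma process power is multiplied
    by ``gamma_gain`` and the alpha/beta process power by ``alphabeta_drop``
    relative to the inter-stimulus baseline.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if gamma_gain < 1:
        raise ValueError("gamma_gain must be >= 1")
    if not (0 < alphabeta_drop <= 1):
        raise ValueError("alphabeta_drop must be in (0, 1]")
    channels = list(profile.channel_set)
    positions = mont.positions(channels)
    rng = _rng(seed)

    gaps = rng.uniform(isi_range[0], isi_range[1], size=n_trials)
    onsets_t = np.empty(n_trials)
    tcur = 2.0
    for i in range(n_trials):
        onsets_t[i] = tcur
        tcur += stim_duration + gaps[i]
    n = int(round((tcur + 1.0) * fs))

    stim_mask = np.zeros(n, dtype=bool)
    events = []
    for onset_t in onsets_t:
        s = int(round(onset_t * fs))
        events.append((s, "stim"))
        stim_mask[s:s + int(round(stim_duration * fs))] = True

    data = _background(len(channels), n, fs, rng, background_sd)
    w_vis = _topo_weights(positions, _posterior_center(), width=0.8)
    if gamma_channels is not None:
        w_gamma = np.array([1.0 if c in set(mont.validate_labels(gamma_channels)) else 0.0
                            for c in channels])
    else:
        w_gamma = w_vis
    g_gain = np.where(stim_mask, np.sqrt(gamma_gain), 1.0)
    ab_gain = np.where(stim_mask, np.sqrt(alphabeta_drop), 1.0)
    for i in range(len(channels)):
        gsrc = bandlimited_noise(n, fs, 50.0, 75.0, rng)
        absrc = bandlimited_noise(n, fs, 10.0, 20.0, rng)
        data[i] += gamma_sd * w_gamma[i] * g_gain * gsrc
        data[i] += alphabeta_sd * w_vis[i] * ab_gain * absrc
    data = _apply_profile(data, profile, fs, rng)
    return Recording(data=data, fs=fs, channels=channels, positions=positions,
                     events=events,
                     meta={"task": "gamma", "device": profile.name,
                           "n_trials": n_trials, "gamma_gain": gamma_gain,
                           "alphabeta_drop": alphabeta_drop,
                           "stim_duration": stim_duration})


ARTIFACT_CONDITIONS = ("rest", "blink", "saccade", "jaw", "head")


def generate_artifacts(profile: DeviceProfile, condition: str,
                       duration_s: float = 60.0, fs: float = 250.0, seed: int = 0,
                       background_sd: float = 5.0) -> Recording:
    """Artifact-task recording with a per-sample ground-truth mask.

    rest: background only. blink/saccade: frontal low-frequency transients.
    jaw: broadband 30-100 Hz EMG bursts on temporal/frontal channels.
    head: large slow broadband excursions on all channels. Amplitudes scale
    with ``profile.artifact_susceptibility``.
    """
    if condition not in ARTIFACT_CONDITIONS:
        raise ValueError(f"condition must be one of {ARTIFACT_CONDITIONS}")
    channels = list(profile.channel_set)
    positions = mont.positions(channels)
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    data = _background(len(channels), n, fs, rng, background_sd)
    mask = np.zeros(n, dtype=bool)
    sus = profile.artifact_susceptibility

    def event_starts(period, jitter, width):
        starts, tcur = [], 1.0
        while tcur + width < duration_s - 0.5:
            starts.append(int(round(tcur * fs)))
            tcur += period + rng.uniform(-jitter, jitter)
        return starts

    if condition == "blink" and sus > 0:
        w = _topo_weights(positions, _center("Fp1") + _center("Fp2"), width=0.5)
        length = int(round(0.3 * fs))
        bump = np.exp(-((np.arange(length) / fs - 0.15) ** 2) / (2 * 0.05 ** 2))
        for s in event_starts(2.0, 0.5, 0.3):
            data[:, s:s + length] += np.outer(w, 150.0 * sus * bump)
            mask[s:s + length] = True
    elif condition == "saccade" and sus > 0:
        w7 = _topo_weights(positions, _center("F7"), width=0.4)
        w8 = _topo_weights(positions, _center("F8"), width=0.4)
        length = int(round(0.4 * fs))
        step = np.tanh((np.arange(length) / fs - 0.05) / 0.01).clip(0, 1)
        for s in event_starts(1.5, 0.4, 0.4):
            sign = rng.choice([-1.0, 1.0])
            data[:, s:s + length] += np.outer(sign * 60.0 * sus * (w7 - w8), step)
            mask[s:s + length] = True
    elif condition == "jaw" and sus > 0:
        w = np.zeros(len(channels))
        for lab in mont.TEMPORAL:
            if lab in channels:
                w[channels.index(lab)] = 1.0
        w += 0.3 * _topo_weights(positions, _center("Cz"), width=1.5)
        length = int(round(1.0 * fs))
        for s in event_starts(3.0, 0.8, 1.0):
            stop = min(s + length, n)
            emg = np.stack([bandlimited_noise(stop - s, fs, 30.0, min(100.0, fs / 2 - 1), rng)
                            for _ in range(len(channels))])
            data[:, s:stop] += 50.0 * sus * w[:, None] * emg
            mask[s:stop] = True
    elif condition == "head" and sus > 0:
        length = int(round(0.8 * fs))
        sway = np.sin(np.pi * np.arange(length) / length)
        for s in event_starts(4.0, 1.0, 0.8):
            amps = 600.0 * sus * (0.5 + rng.random(len(channels)))
            data[:, s:s + length] += np.outer(amps, sway)
            mask[s:s + length] = True

    data = _apply_profile(data, profile, fs, rng)
    return Recording(data=data, fs=fs, channels=channels, positions=positions,
                     meta={"task": "artifact", "device": profile.name,
                           "condition": condition},
                     artifact_mask=mask)


# ---------------------------------------------------------------------------
# study orchestration

TASK_FEATURES = {"rest": "alpha_sd", "p300": "p300_amplitude", "gamma": "gamma_gain"}
TASK_MU = {"rest": 7.0, "p300": 6.0, "gamma": 2.0}


@dataclass
class RecordingSpec:
    """Deferred description of one study-cell recording."""
    subject: int
    session: int
    device: DeviceProfile
    task: str
    seed: int
    params: dict

    def generate(self, **overrides) -> Recording:
        params = {**self.params, **overrides}
        if self.task == "rest_ec":
            rec = generate_resting(self.device, "eyes-closed", seed=self.seed, **params)
        elif self.task == "rest_eo":
            rec = generate_resting(self.device, "eyes-open", seed=self.seed, **params)
        elif self.task == "p300":
            rec = generate_oddball(self.device, seed=self.seed, **params)
        elif self.task == "gamma":
            rec = generate_visual(self.device, seed=self.seed, **params)
        elif self.task == "artifact":
            rec = generate_artifacts(self.device, seed=self.seed, **params)
        else:
            raise ValueError(f"unknown task {self.task!r}")
        rec.meta.update({"subject": self.subject, "session": self.session})
        return rec


@dataclass
class StudyData:
    """Output of :func:`generate_study`: ground truth plus lazy recordings."""
    design: StudyDesign
    truth: pd.DataFrame           # subject, session, device, task, feature, value
    specs: list                   # list of RecordingSpec

    def iter_recordings(self):
        for spec in self.specs:
            yield spec.generate()


def generate_study(design: StudyDesign, tasks=("rest",), make_recordings=True,
                   recording_params=None) -> StudyData:
    """Simulate a full study: ground-truth endpoint table + recording specs.

    Endpoint values follow ``mu + subject + session + device + residual``
    with the design's variance components; the subject and subject-session
    effects are shared across devices (paired design). Recording specs map
    each cell's true value onto the matching generator knob so recordings,
    when materialized, embody the table.
    """
    rng = _rng(design.seed)
    n_s, n_sess = design.n_subjects, design.n_sessions
    subj_eff = design.subject_sd * rng.standard_normal(n_s)
    sess_eff = design.session_sd * rng.standard_normal((n_s, n_sess))

    rows, specs = [], []
    recording_params = recording_params or {}
    for task in tasks:
        if task not in TASK_FEATURES:
            raise ValueError(f"unknown task {task!r}; choose from {list(TASK_FEATURES)}")
        feature, mu = TASK_FEATURES[task], TASK_MU[task]
        for i in range(n_s):
            for j in range(n_sess):
                for k, dev in enumerate(design.devices):
                    value = (mu + subj_eff[i] + sess_eff[i, j]
                             + design.device_effects[k]
                             + design.residual_sd * rng.standard_normal())
                    rows.append({"subject": i, "session": j, "device": dev.name,
                                 "task": task, "feature": feature, "value": value})
                    if make_recordings:
                        cell_seed = int(rng.integers(0, 2 ** 31 - 1))
                        if task == "rest":
                            p = {"alpha_sd": max(value, 0.1),
                                 **recording_params.get("rest", {})}
                            specs.append(RecordingSpec(i, j, dev, "rest_ec", cell_seed, p))
                            specs.append(RecordingSpec(i, j, dev, "rest_eo",
                                                       cell_seed + 1, p))
                        elif task == "p300":
                            p = {"p300_amplitude": max(value, 0.0),
                                 **recording_params.get("p300", {})}
                            specs.append(RecordingSpec(i, j, dev, "p300", cell_seed, p))
                        elif task == "gamma":
                            p = {"gamma_gain": max(value, 1.0),
                                 **recording_params.get("gamma", {})}
                            specs.append(RecordingSpec(i, j, dev, "gamma", cell_seed, p))
    truth = pd.DataFrame(rows)
    return StudyData(design=design, truth=truth, specs=specs)
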