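"""Shared fixtures: quiet device profiles and cached synthetic recordings.

Expensive generated objects are session-scoped so multiple tests can share
one realization; every fixture is seeded and fully deterministic.
"""

import numpy as np
import pytest

from eegbench import montage as mont
from eegbench import preprocess as pp
from eegbench import synth
from eegbench.recording import Epochs, Recording


@pytest.fixture(scope="session")
def quiet_profile():
    """Low-noise gel-like device used where signal recovery is the point."""
    return synth.DeviceProfile("standard", sensor_noise_sd=1.0,
                               lowfreq_noise_sd=0.5)


@pytest.fixture(scope="session")
def noisy_profile():
    return synth.DeviceProfile("dry_c", broadband_offset=3.2,
                               sensor_noise_sd=3.5, lowfreq_noise_sd=2.5,
                               artifact_susceptibility=1.8)


@pytest.fixture(scope="session")
def oddball_recording(quiet_profile):
    return synth.generate_oddball(quiet_profile, n_deviants=30, seed=0)


@pytest.fixture(scope="session")
def oddball_epochs(oddball_recording):
    from eegbench import evoked as ev

    return ev.epoch_oddball(oddball_recording)


@pytest.fixture(scope="session")
def null_epochs():
    """Epochs with no evoked structure: correlated Gaussian noise, for
    whitener / GFP calibration checks."""
    rng = np.random.default_rng(7)
    P, ntr, fs = 19, 250, 250.0
    times = np.arange(int(-0.3 * fs), int(0.7 * fs)) / fs
    mix = rng.standard_normal((P, P)) * 0.3 + np.eye(P)
    data = np.einsum("pq,iqt->ipt", mix,
                     rng.standard_normal((ntr, P, len(times))))
    return Epochs(data=data, times=times, fs=fs,
                  channels=list(mont.STANDARD_1020),
                  labels=np.array(["deviant"] * ntr))


@pytest.fixture(scope="session")
def segment_classifier(quiet_profile):
    """Random forest trained on jaw/rest synthetic fixtures (seeds 0-1)."""
    feats, labels = [], []
    for seed in (0, 1):
        for cond in ("rest", "jaw"):
            rec = synth.generate_artifacts(quiet_profile, cond,
                                           duration_s=60, fs=250, seed=seed)
            bounds = pp.tile_segments(rec.n_samples, rec.fs)[0]
            ex = pp.SegmentFeatureExtractor(rec)
            feats.extend(ex.extract(rec.data[:, a:b]) for a, b in bounds)
            labels.extend(pp.segment_labels_from_mask(rec.artifact_mask, bounds))
    model = pp.train_segment_classifier(feats, labels, seed=0)
    return model, feats, np.asarray(labels)


def make_noise_recording(seed=0, n_ch=3, duration=10.0, fs=250.0, sd=10.0):
    rng = np.random.default_rng(seed)
    data = sd * rng.standard_normal((n_ch, int(duration * fs)))
    return Recording(data=data, fs=fs,
                     channels=list(mont.STANDARD_1020[:n_ch]))
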