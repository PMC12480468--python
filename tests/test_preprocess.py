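"""Cleaning pipeline: filter response, rejection rules against constructed
fixtures and exhaustive oracles, segment features/classifier, ICA removal,
spherical interpolation, referencing and subsampling."""

import numpy as np
import pytest
from scipy import signal as sps

from eegbench import montage as mont
from eegbench import preprocess as pp
from eegbench import synth
from eegbench.recording import Recording

from conftest import make_noise_recording

FS = 250.0


def sine_recording(freq, amp=1.0, duration=20.0, n_ch=2, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data=data, fs=fs, channels=list(mont.STANDARD_1020[:n_ch]))


class TestBandpass:
    def test_dc_removed(self):
        rec = Recording(data=np.full((2, int(20 * FS)), 100.0), fs=FS,
                        channels=["Cz", "Pz"])
        out = pp.bandpass_filter(rec, 1, 45)
        trim = slice(int(5 * FS), int(15 * FS))
        assert np.abs(out.data[:, trim]).mean() < 1.0

    def test_passband_gain_unity(self):
        out = pp.bandpass_filter(sine_recording(10), 1, 45)
        trim = slice(int(5 * FS), int(15 * FS))
        amp = np.abs(sps.hilbert(out.data[0, trim])).mean()
        assert 0.95 <= amp <= 1.05

    def test_stopband_attenuation(self):
        out = pp.bandpass_filter(sine_recording(80), 1, 45)
        trim = slice(int(5 * FS), int(15 * FS))
        amp = out.data[0, trim].std() * np.sqrt(2)
        assert 20 * np.log10(1.0 / max(amp, 1e-12)) >= 20

    def test_nyquist_error(self):
        with pytest.raises(ValueError):
            pp.bandpass_filter(sine_recording(10), 1, 130)


class TestBadChannels:
    def test_flat_channel_flagged(self):
        rec = make_noise_recording(seed=0, n_ch=4, duration=10)
        rec.data[2] = 0.0
        verdicts = pp.detect_bad_channels(rec)
        assert verdicts[2].bad and "flat" in verdicts[2].triggering_rules
        assert not any(v.bad for i, v in enumerate(verdicts) if i != 2)

    def test_extreme_amplitude_flagged(self):
        rec = make_noise_recording(seed=1, n_ch=4, duration=10)
        t = np.arange(rec.n_samples) / rec.fs
        rec.data[0] = 600 * np.sin(2 * np.pi * 5 * t)
        verdicts = pp.detect_bad_channels(rec)
        assert verdicts[0].bad and "extreme" in verdicts[0].triggering_rules

    def test_decoupled_channel_flagged(self):
        """|amp| > 100 with correlation < 0.6 to every other channel."""
        rng = np.random.default_rng(2)
        common = 30 * rng.standard_normal(int(10 * FS))
        data = np.stack([common + rng.standard_normal(len(common))
                         for _ in range(3)]
                        + [150 * rng.standard_normal(len(common))])
        rec = Recording(data=data, fs=FS, channels=list(mont.STANDARD_1020[:4]))
        verdicts = pp.detect_bad_channels(rec)
        assert verdicts[3].bad
        assert "uncorrelated" in verdicts[3].triggering_rules
        assert not any(v.bad for v in verdicts[:3])

    def test_correlated_high_amplitude_not_flagged(self):
        """Equal 50 µV signals defeat the decoupling rule."""
        rng = np.random.default_rng(3)
        sig = 50 * np.sin(2 * np.pi * 7 * np.arange(int(10 * FS)) / FS)
        data = np.stack([sig + 0.5 * rng.standard_normal(sig.size)
                         for _ in range(3)])
        rec = Recording(data=data, fs=FS, channels=list(mont.STANDARD_1020[:3]))
        assert not any(v.bad for v in pp.detect_bad_channels(rec))

    def test_threshold_monotonicity(self):
        """Raising the extreme threshold never adds bad channels."""
        rec = make_noise_recording(seed=4, n_ch=5, duration=10, sd=200)
        bads = []
        for thr in (100.0, 300.0, 500.0, 900.0):
            cfg = pp.RejectionConfig(extreme_amplitude=thr)
            bads.append({v.channel for v in pp.detect_bad_channels(rec, cfg)
                         if v.bad})
        for smaller, larger in zip(bads[1:], bads[:-1]):
            assert smaller <= larger

    def test_single_channel_raises(self):
        rec = make_noise_recording(n_ch=1)
        with pytest.raises(ValueError):
            pp.detect_bad_channels(rec)


class TestFlatSegments:
    def test_healthy_noise_all_kept(self):
        mask = pp.reject_flat_segments(make_noise_recording(sd=10, duration=10))
        assert mask.keep.all()

    def test_constant_stretch_drops_exactly_one_segment(self):
        rec = make_noise_recording(seed=5, n_ch=2, duration=10, sd=10)
        a = int(4.5 * FS)                       # inside segment 2 (4-6 s)
        rec.data[1, a:a + int(0.25 * FS)] = 3.3
        mask = pp.reject_flat_segments(rec)
        assert (~mask.keep).sum() == 1
        assert not mask.keep[2] and mask.reasons[2] == "flat"

    def test_matches_exhaustive_window_oracle(self):
        """Verdicts equal a brute-force scan over every window position."""
        rng = np.random.default_rng(6)
        rec = make_noise_recording(seed=6, n_ch=3, duration=12, sd=0.4)
        rec.data[0, int(7.1 * FS):int(7.4 * FS)] *= 0.02
        cfg = pp.RejectionConfig()
        mask = pp.reject_flat_segments(rec, cfg)
        wlen, wstep = int(0.2 * FS), int(0.1 * FS)
        for i, (a, b) in enumerate(mask.bounds):
            seg = rec.data[:, a:b]
            flat = any(seg[:, s:s + wlen].var(axis=1).min() < cfg.flat_variance
                       for s in range(0, seg.shape[1] - wlen + 1, wstep))
            assert mask.keep[i] == (not flat)

    def test_trailing_partial_segment_recorded(self):
        rec = make_noise_recording(duration=7.4)
        mask = pp.reject_flat_segments(rec)
        assert mask.n_segments == 3
        assert mask.n_trailing_samples == int(1.4 * FS)


class TestSegmentFeatures:
    def test_constant_segment(self):
        ft = pp.extract_segment_features(np.full((2, 500), 7.0))
        assert ft["max_amplitude_eeg"] == ft["min_amplitude_eeg"] == 7.0
        assert ft["max_amplitude_difference"] == 0.0
        assert ft.flags.get("zero_variance")

    def test_gaussian_kurtosis_near_zero(self):
        rng = np.random.default_rng(8)
        ft = pp.extract_segment_features(rng.standard_normal((1, 20000)))
        assert abs(ft["kurtosis_eeg"]) < 0.3

    def test_spike_dominates_amplitude_difference(self):
        rng = np.random.default_rng(9)
        seg = rng.standard_normal((3, 500))
        seg[1, 250] = 500.0
        ft = pp.extract_segment_features(seg)
        assert ft["max_amplitude_difference"] > 450

    def test_schema_is_versioned_14_features(self):
        assert len(pp.SEGMENT_FEATURE_SCHEMA) == 14
        ft = pp.extract_segment_features(np.random.default_rng(0)
                                         .standard_normal((2, 500)))
        assert ft.as_array().shape == (14,)


class TestSegmentClassifier:
    def test_holdout_balanced_accuracy(self, quiet_profile, segment_classifier):
        """>= 0.9 balanced accuracy on held-out jaw/rest segments."""
        model, _, _ = segment_classifier
        feats, labels = [], []
        for cond in ("rest", "jaw"):
            rec = synth.generate_artifacts(quiet_profile, cond, duration_s=60,
                                           fs=250, seed=10)
            bounds = pp.tile_segments(rec.n_samples, rec.fs)[0]
            ex = pp.SegmentFeatureExtractor(rec)
            feats.extend(ex.extract(rec.data[:, a:b]) for a, b in bounds)
            labels.extend(pp.segment_labels_from_mask(rec.artifact_mask, bounds))
        pred = model.predict_bad(feats)
        y = np.asarray(labels)
        bal = 0.5 * (((pred == 1) & (y == 1)).sum() / max(y.sum(), 1)
                     + ((pred == 0) & (y == 0)).sum() / max((y == 0).sum(), 1))
        assert bal >= 0.9

    def test_memorizes_training_bad_segment(self, segment_classifier):
        model, feats, labels = segment_classifier
        bad_idx = int(np.nonzero(labels == 1)[0][0])
        assert model.predict_bad([feats[bad_idx]])[0]

    def test_clean_input_low_drop_fraction(self, quiet_profile, segment_classifier):
        model, _, _ = segment_classifier
        rec = synth.generate_artifacts(quiet_profile, "rest", 60, fs=250, seed=11)
        bounds = pp.tile_segments(rec.n_samples, rec.fs)[0]
        ex = pp.SegmentFeatureExtractor(rec)
        feats = [ex.extract(rec.data[:, a:b]) for a, b in bounds]
        drop_frac = model.predict_bad(feats).mean()
        assert drop_frac <= 0.1

    def test_schema_mismatch_raises(self, segment_classifier):
        model, feats, _ = segment_classifier
        bad = pp.SegmentFeatures(feats[0].as_array(),
                                 schema=tuple(reversed(pp.SEGMENT_FEATURE_SCHEMA)))
        with pytest.raises(ValueError, match="schema"):
            model.predict_bad([bad])

    def test_classify_merges_into_mask(self, segment_classifier, quiet_profile):
        model, _, _ = segment_classifier
        rec = synth.generate_artifacts(quiet_profile, "jaw", 30, fs=250, seed=12)
        mask = pp.reject_flat_segments(rec)
        ex = pp.SegmentFeatureExtractor(rec)
        feats = ex.extract_all(rec, mask)
        merged = pp.classify_segments(feats, model, mask)
        assert (~merged.keep).sum() >= (~mask.keep).sum()
        assert any(r == "classifier" for r in merged.reasons if r)


class TestIcaRemoval:
    def test_blink_component_removed(self, quiet_profile):
        rec = synth.generate_artifacts(quiet_profile, "blink", 60, fs=250, seed=3)
        filt = pp.bandpass_filter(rec, 1, 45)
        clean = pp.remove_artifact_components(filt, seed=0)

        def frontal_low(r):
            idx = [r.channels.index(c) for c in ("Fp1", "Fp2")]
            f, pxx = sps.welch(r.data[idx], fs=r.fs, nperseg=512)
            return pxx[:, (f >= 1) & (f <= 4)].sum()

        assert frontal_low(clean) <= 0.5 * frontal_low(filt)
        assert clean.meta["ica"]["converged"]

    def test_clean_recording_nearly_unchanged(self, quiet_profile):
        rec = synth.generate_resting(quiet_profile, "eyes-open", 40, seed=6)
        filt = pp.bandpass_filter(rec, 1, 45)
        clean = pp.remove_artifact_components(filt, seed=0)
        for c in range(filt.n_channels):
            assert np.corrcoef(filt.data[c], clean.data[c])[0, 1] >= 0.95

    def test_noop_classifier_is_identity_path(self, quiet_profile):
        rec = synth.generate_resting(quiet_profile, "eyes-open", 30, seed=7)
        filt = pp.bandpass_filter(rec, 1, 45)
        out = pp.remove_artifact_components(
            filt, classifier=lambda topo, src, ch, fs: [], seed=0)
        assert np.allclose(out.data, filt.data, atol=1e-6)

    def test_too_few_channels_raises(self):
        with pytest.raises(ValueError):
            pp.remove_artifact_components(make_noise_recording(n_ch=4))


class TestInterpolation:
    def test_constant_field_reproduced(self):
        rec = Recording(data=np.full((19, 500), 42.0), fs=FS,
                        channels=list(mont.STANDARD_1020))
        out = pp.interpolate_bad_channels(rec, ["Cz"])
        assert out.data[rec.channels.index("Cz")] == pytest.approx(42.0, abs=1e-6)

    def test_no_bads_identity(self):
        rec = make_noise_recording(n_ch=19)
        out = pp.interpolate_bad_channels(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_smooth_field_leave_one_out(self):
        """Relative error < 10% when reconstructing each electrode from the
        others on a low-order spherical-harmonic field."""
        pos = mont.positions(mont.STANDARD_1020)
        field = 42 + 30 * pos[:, 0] * pos[:, 2] + 20 * pos[:, 1]
        for i, ch in enumerate(mont.STANDARD_1020):
            rec = Recording(data=np.tile(field[:, None], (1, 50)), fs=FS,
                            channels=list(mont.STANDARD_1020))
            out = pp.interpolate_bad_channels(rec, [ch])
            assert abs(out.data[i, 0] - field[i]) / abs(field[i]) < 0.10

    def test_all_bad_raises(self):
        rec = make_noise_recording(n_ch=5)
        with pytest.raises(ValueError):
            pp.interpolate_bad_channels(rec, list(rec.channels))


class TestReferenceAndSubsample:
    def test_average_reference_zero_sum_and_idempotent(self):
        rec = make_noise_recording(n_ch=6)
        out = pp.rereference_average(rec)
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9
        again = pp.rereference_average(out)
        assert np.allclose(again.data, out.data)

    def test_two_channel_closed_form(self):
        rec = make_noise_recording(n_ch=2)
        out = pp.rereference_average(rec)
        expected = (rec.data[0] - rec.data[1]) / 2
        assert np.allclose(out.data[0], expected)
        assert np.allclose(out.data[1], -expected)

    def test_subsample_30_channel_cap_to_19(self):
        extra = ["F1", "F2", "C1", "C2", "P1", "P2", "FC1", "FC2", "CP1",
                 "CP2", "AFz"]
        labels = list(mont.STANDARD_1020) + extra
        rng = np.random.default_rng(1)
        rec = Recording(data=rng.standard_normal((len(labels), 500)), fs=FS,
                        channels=labels)
        out = pp.subsample_to_1020(rec)
        assert out.channels == list(mont.STANDARD_1020)
        assert out.meta["subsampled_before_preprocessing"]

    def test_subsample_identity_and_missing(self):
        rec = make_noise_recording(n_ch=5)
        assert pp.subsample_to_1020(rec, rec.channels).channels == rec.channels
        with pytest.raises(ValueError, match="O2"):
            pp.subsample_to_1020(rec, ["Fp1", "O2"])


class TestPipeline:
    def test_stage_order_logged(self, quiet_profile):
        rec = synth.generate_resting(quiet_profile, "eyes-open", 30, seed=8)
        res = pp.run_preprocessing(rec, task="rest")
        stages = [s["stage"] for s in res.log["stages"]]
        assert stages == ["filter", "bad_channels", "flat_segments", "ica",
                          "segment_classifier", "interpolation",
                          "average_reference"]

    def test_alpha_power_stable_through_cleaning(self, quiet_profile):
        """On clean data the alpha endpoint survives the pipeline (<10%)."""
        from eegbench import spectral as sp

        rec = synth.generate_resting(quiet_profile, "eyes-closed", 40, seed=9)
        filtered = pp.bandpass_filter(rec, 1, 45)
        res = pp.run_preprocessing(rec, task="rest")

        def alpha(r):
            spec = sp.morlet_power(pp.rereference_average(r))
            sel = (spec.freqs >= 8.5) & (spec.freqs < 12.5)
            return spec.power[:, sel].mean()

        assert abs(alpha(res.recording) - alpha(filtered)) / alpha(filtered) < 0.10
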