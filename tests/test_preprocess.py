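"""Preprocessing: filters, artifact criteria, repair, epoching, ICA."""

import numpy as np
import pandas as pd
import pytest

from eegmci import cohort as syn
from eegmci.containers import EpochSet, Recording
from eegmci.preprocess import (decontaminate, epoch_recording,
                               filter_recording, repair_or_reject,
                               scan_artifacts)

FS = 256.0
CH = 20


def _recording(data: np.ndarray) -> Recording:
    return Recording(data, FS)


def _tone(freq: float, n: int = 20 * 256, amp: float = 10.0) -> np.ndarray:
    t = np.arange(n) / FS
    return np.tile(amp * np.sin(2 * np.pi * freq * t), (CH, 1))


class TestFiltering:
    def test_notch_removes_line_noise(self):
        rec = _recording(_tone(60.0))
        out = filter_recording(rec, "resting")
        mid = slice(2 * 256, -2 * 256)           # ignore edge transients
        assert np.sqrt(np.mean(out.data[:, mid] ** 2)) < \
            0.05 * np.sqrt(np.mean(rec.data[:, mid] ** 2))

    def test_passband_flat_at_10hz(self):
        rec = _recording(_tone(10.0))
        out = filter_recording(rec, "resting")
        mid = slice(2 * 256, -2 * 256)
        ratio = np.abs(out.data[0, mid]).max() / np.abs(rec.data[0, mid]).max()
        assert 0.95 < ratio < 1.05

    def test_erp_mode_attenuates_45hz(self):
        rec = _recording(_tone(45.0))
        out = filter_recording(rec, "erp")
        mid = slice(2 * 256, -2 * 256)
        assert np.abs(out.data[0, mid]).max() < 0.5 * 10.0

    def test_zero_input_zero_output(self):
        out = filter_recording(_recording(np.zeros((CH, 10 * 256))), "erp")
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            filter_recording(_recording(np.zeros((CH, 100))), "resting")


class TestArtifactScan:
    def test_clean_gaussian_rarely_flagged(self):
        flagged = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rec = _recording(10.0 * rng.standard_normal((CH, 30 * 256)))
            mask = scan_artifacts(rec)
            flagged += mask.flags.any(axis=1).sum()
            total += mask.n_windows
        assert flagged / total <= 0.01

    def test_power_criterion_flags_amplified_channel(self):
        rng = np.random.default_rng(0)
        data = 10.0 * rng.standard_normal((CH, 20 * 256))
        # x4 amplitude in one 2-s window => power x16 > 8x channel mean
        data[4, 6 * 256:8 * 256] *= 4.0
        mask = scan_artifacts(_recording(data))
        hit = mask.flags[6]
        assert hit[4] and hit.sum() == 1
        assert "power" in mask.criteria[6][4]

    def test_amplitude_criterion_full_window_450uv(self):
        rng = np.random.default_rng(1)
        data = 5.0 * rng.standard_normal((CH, 10 * 256))
        data[2, 3 * 256:5 * 256] = 450.0
        mask = scan_artifacts(_recording(data))
        assert mask.flags[3, 2]
        assert "amplitude" in mask.criteria[3][2]

    def test_peak_to_peak_criterion(self):
        rng = np.random.default_rng(2)
        data = 5.0 * rng.standard_normal((CH, 10 * 256))
        data[7, 4 * 256 + 100] = 300.0
        data[7, 4 * 256 + 200] = -300.0          # 600 uV swing in one window
        mask = scan_artifacts(_recording(data))
        assert mask.flags[4, 7] or mask.flags[3, 7]


class TestRepairOrReject:
    def test_no_flags_identity(self):
        rng = np.random.default_rng(3)
        rec = _recording(8.0 * rng.standard_normal((CH, 10 * 256)))
        mask = scan_artifacts(rec)
        assert not mask.flags.any()
        out, excl = repair_or_reject(rec, mask)
        np.testing.assert_array_equal(out.data, rec.data)
        assert excl == []

    def test_single_channel_spike_interpolated(self):
        rng = np.random.default_rng(4)
        data = 8.0 * rng.standard_normal((CH, 10 * 256))
        data[9, 5 * 256:5 * 256 + 30] += 600.0   # Cz spike
        rec = _recording(data)
        mask = scan_artifacts(rec)
        out, excl = repair_or_reject(rec, mask)
        assert excl == []
        window = out.data[9, 5 * 256:6 * 256]
        neighbors = out.data[[8, 10, 14], 5 * 256:6 * 256]
        assert np.abs(window).max() < 3 * neighbors.std() + 1e-9

    def test_multichannel_window_excluded(self):
        rng = np.random.default_rng(5)
        data = 8.0 * rng.standard_normal((CH, 10 * 256))
        data[3, 4 * 256:6 * 256] = 450.0
        data[11, 4 * 256:6 * 256] = -450.0
        rec = _recording(data)
        mask = scan_artifacts(rec)
        out, excl = repair_or_reject(rec, mask)
        assert any(lo <= 4 * 256 < hi for lo, hi in excl)

    def test_untouched_outside_flagged_windows(self):
        rng = np.random.default_rng(6)
        data = 8.0 * rng.standard_normal((CH, 12 * 256))
        data[5, 6 * 256:6 * 256 + 40] += 700.0
        rec = _recording(data)
        mask = scan_artifacts(rec)
        out, _ = repair_or_reject(rec, mask)
        touched = np.zeros(rec.n_samples, dtype=bool)
        for w in mask.flagged_windows():
            start = mask.window_starts[w]
            touched[start:start + mask.window_length] = True
        np.testing.assert_array_equal(out.data[:, ~touched],
                                      rec.data[:, ~touched])


class TestEpoching:
    def _events(self, onsets):
        return pd.DataFrame({
            "onset_sample": onsets,
            "trial_type": "target",
            "correct": True,
            "response_time": 0.5,
        })

    def test_epoch_length_and_boundary_drop(self):
        rng = np.random.default_rng(7)
        rec = _recording(5.0 * rng.standard_normal((CH, 30 * 256)))
        events = self._events([0, 5 * 256, 10 * 256, 29 * 256 + 200])
        epochs = epoch_recording(rec, events)
        # first underruns (needs 0.8 s before) and last overruns (1.3 s after)
        assert epochs.n_trials == 2
        assert epochs.data.shape[2] == round(2.1 * 256)

    def test_excluded_interval_drops_overlapping_epoch(self):
        rng = np.random.default_rng(8)
        rec = _recording(5.0 * rng.standard_normal((CH, 40 * 256)))
        onsets = [(3 + 3 * k) * 256 for k in range(10)]
        excl = [(6 * 256, 7 * 256)]              # overlaps the second epoch
        epochs = epoch_recording(rec, self._events(onsets),
                                 exclusion_intervals=excl)
        assert epochs.n_trials == 9

    def test_no_survivors_raises(self):
        rec = _recording(np.zeros((CH, 5 * 256)))
        with pytest.raises(ValueError):
            epoch_recording(rec, self._events([0]))


class TestDecontamination:
    def test_keep_all_roundtrip(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((6, 4000))
        out, info = decontaminate(x[:, :], lambda s, m, fs: np.ones(s.shape[0]),
                                  fs=FS, seed=0)
        assert info["n_rejected"] == 0
        rel = np.linalg.norm(out - x) / np.linalg.norm(x)
        assert rel < 1e-6

    def test_reject_all_zeroes_output(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((5, 3000))
        out, info = decontaminate(x, lambda s, m, fs: np.zeros(s.shape[0]),
                                  fs=FS, seed=0)
        assert info["n_rejected"] == 5
        # only the channel means survive
        assert np.abs(out - out.mean(axis=1, keepdims=True)).max() < 1e-8

    def test_oracle_classifier_removes_sawtooth_source(self):
        """Removing a known artifact source moves the data closer to the
        artifact-free ground truth."""
        rng = np.random.default_rng(11)
        n = 6000
        t = np.arange(n) / FS
        brain = np.array([np.sin(2 * np.pi * 10 * t),
                          np.sin(2 * np.pi * 6 * t + 1.0),
                          rng.standard_normal(n)])
        saw = 40.0 * (2 * ((3.0 * t) % 1.0) - 1.0)
        mix_brain = rng.standard_normal((5, 3))
        mix_saw = rng.standard_normal(5)
        sensor_noise = 0.5 * rng.standard_normal((5, n))   # full-rank floor
        clean = mix_brain @ brain + sensor_noise
        dirty = clean + np.outer(mix_saw, saw)

        def oracle(sources, mixing, fs):
            # flag the component most correlated with the sawtooth
            corr = np.abs([np.corrcoef(s, saw)[0, 1] for s in sources])
            probs = np.ones(sources.shape[0])
            probs[np.argmax(corr)] = 0.0
            return probs

        out, info = decontaminate(dirty, oracle, fs=FS, seed=1)
        assert info["n_rejected"] == 1
        err_pre = np.linalg.norm(dirty - clean)
        err_post = np.linalg.norm(out - clean)
        assert err_post < 0.3 * err_pre

    def test_epochset_roundtrip_shape(self):
        rng = np.random.default_rng(12)
        times = np.arange(-205, 333) / FS
        data = rng.standard_normal((8, 6, times.size))
        meta = pd.DataFrame({"trial_type": ["a"] * 8, "correct": True,
                             "response_time": 0.4})
        epochs = EpochSet(data, times, FS, tuple("c%d" % i for i in range(6)),
                          meta)
        out, _ = decontaminate(epochs, lambda s, m, fs: np.ones(s.shape[0]),
                               fs=FS, seed=2)
        assert out.data.shape == epochs.data.shape
        np.testing.assert_allclose(out.data, epochs.data, atol=1e-6)


class TestDetectionRecall:
    def test_recall_on_injected_artifacts_and_false_rate(self):
        """flat_high / broadband artifacts injected by the generator are
        caught by the scan criteria in >= 90% of cases; clean recordings are
        flagged in <= 1% of windows."""
        caught = injected = 0
        flagged_clean = clean_windows = 0
        for seed in range(6):
            cfg = syn.CohortConfig(n_hc=2, n_mci=2, seed=seed)
            s = syn.make_cohort(cfg)[0]
            rec = syn.simulate_resting(s, 1, cfg, duration=30)
            mask0 = scan_artifacts(rec)
            flagged_clean += mask0.flags.any(axis=1).sum()
            clean_windows += mask0.n_windows
            spec = syn.ArtifactSpec(n_flat_high=2, n_broadband=2)
            dirty, truth = syn.inject_artifacts(rec, spec, seed=seed)
            mask = scan_artifacts(dirty)
            for ev in truth.events:
                injected += 1
                overlap = [w for w, start in enumerate(mask.window_starts)
                           if start < ev.end_sample
                           and start + mask.window_length > ev.start_sample]
                caught += any(mask.flags[w, ev.channels[0]] for w in overlap)
        assert caught / injected >= 0.9
        assert flagged_clean / clean_windows <= 0.01
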