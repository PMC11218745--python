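import numpy as np
import pytest

import gridtap as gt
from gridtap.preprocess import PipelineOrderError
from conftest import random_epochs


def sine_recording(freq, fs=250.0, seconds=60.0, n_ch=2):
    t = np.arange(int(fs * seconds)) / fs
    sig = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return gt.Recording(sample_rate=fs, channel_labels=["a", "b"][:n_ch],
                        signal=sig)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


# measure away from the edges: the 0.1 Hz high-pass has a ~10 s transient
MID = slice(5000, 10000)


class TestBandpass:
    def test_stopband_mains_frequency_suppressed(self):
        rec = sine_recording(50.0)
        out = gt.bandpass(rec)
        assert rms(out.signal[0][MID]) < 0.05 * rms(rec.signal[0][MID])

    def test_passband_alpha_preserved(self):
        rec = sine_recording(10.0)
        out = gt.bandpass(rec)
        assert rms(out.signal[0][MID]) == pytest.approx(
            rms(rec.signal[0][MID]), rel=0.05)

    def test_dc_removed(self):
        rec = gt.Recording(sample_rate=250.0, channel_labels=["a"],
                           signal=5.0 * np.ones((1, 15000)))
        out = gt.bandpass(rec)
        assert np.abs(out.signal[0][MID]).max() < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        rec = sine_recording(10.0, fs=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            gt.bandpass(rec)


class TestEpoching:
    def test_sample_count_at_250hz(self):
        rec = gt.Recording(
            sample_rate=250.0, channel_labels=["a"],
            signal=np.zeros((1, 2000)),
            events=[gt.StimulusEvent(sample=1000, run=1, block=1,
                                     position="front", is_target=True)])
        eps = gt.epoch(rec)
        assert eps.data.shape == (1, 1, 225)

    def test_no_events_gives_empty_set(self):
        rec = gt.Recording(sample_rate=250.0, channel_labels=["a"],
                           signal=np.zeros((1, 100)))
        assert gt.epoch(rec).n_epochs == 0

    def test_epoch_content_is_the_halfopen_slice(self):
        ramp = np.arange(3000, dtype=float)[None, :]
        rec = gt.Recording(
            sample_rate=250.0, channel_labels=["a"], signal=ramp,
            events=[gt.StimulusEvent(sample=1000, run=1, block=1,
                                     position="front", is_target=True)])
        eps = gt.epoch(rec)
        assert np.array_equal(eps.data[0, 0], ramp[0, 975:1200])

    def test_edge_event_excluded_with_warning(self, caplog):
        rec = gt.Recording(
            sample_rate=250.0, channel_labels=["a"],
            signal=np.zeros((1, 300)),
            events=[gt.StimulusEvent(sample=10, run=1, block=1,
                                     position="front", is_target=True)])
        with caplog.at_level("WARNING"):
            eps = gt.epoch(rec)
        assert eps.n_epochs == 0
        assert "without full epoch context" in caplog.text


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        eps = random_epochs(0, n=1)
        eps.data[:] = 7.5
        out = gt.baseline_correct(eps)
        assert np.allclose(out.data, 0.0)

    def test_means_shift_by_baseline(self):
        eps = random_epochs(0, n=1)
        eps.data[:] = 0.0
        eps.data[0, :, :eps.n_pre] = 2.0
        eps.data[0, :, eps.n_pre:] = 5.0
        out = gt.baseline_correct(eps)
        assert np.allclose(out.data[0, :, eps.n_pre:], 3.0)

    def test_prestimulus_means_vanish(self):
        out = gt.baseline_correct(random_epochs(3, n=30))
        pre = out.data[:, :, :out.n_pre].mean(axis=2)
        assert np.all(np.abs(pre) < 1e-9)

    def test_double_correction_rejected(self):
        out = gt.baseline_correct(random_epochs(1))
        with pytest.raises(PipelineOrderError):
            gt.baseline_correct(out)


class TestRejection:
    def test_silent_epochs_all_kept(self):
        eps = gt.baseline_correct(random_epochs(0, scale=0.0))
        assert gt.reject_artifacts(eps).kept.all()

    def test_single_sample_excursion_rejected(self):
        eps = random_epochs(0, scale=0.0)
        eps.data[3, 1, 50] = 80.0
        out = gt.reject_artifacts(gt.baseline_correct(eps))
        assert not out.kept[3]
        assert out.kept.sum() == out.n_epochs - 1

    def test_exactly_threshold_is_kept(self):
        eps = random_epochs(0, scale=0.0, n=2)
        eps.data[0, 0, eps.n_pre + 10] = 75.0
        eps.data[0, 0, eps.n_pre + 11] = -75.0
        out = gt.reject_artifacts(gt.baseline_correct(eps))
        # pre-stimulus is zero, so correction leaves the values at ±75.0
        assert out.kept[0]

    def test_matches_bruteforce_scan(self):
        eps = gt.baseline_correct(random_epochs(11, n=100, scale=40.0))
        out = gt.reject_artifacts(eps)
        expected = np.array([np.abs(eps.data[i]).max() <= 75.0
                             for i in range(eps.n_epochs)])
        assert np.array_equal(out.kept, expected)

    def test_infinite_threshold_is_identity(self):
        eps = gt.baseline_correct(random_epochs(2, n=50, scale=100.0))
        cfg = gt.PreprocessConfig(reject_abs_uv=np.inf)
        assert gt.reject_artifacts(eps, cfg).kept.all()

    def test_channel_scope_restricts_the_scan(self):
        eps = random_epochs(0, scale=0.0)
        eps.data[2, 0, 60] = 200.0
        eps = gt.baseline_correct(eps)
        scoped = gt.reject_artifacts(eps, channels=["ch1", "ch2"])
        assert scoped.kept[2]
        full = gt.reject_artifacts(eps)
        assert not full.kept[2]

    def test_requires_baseline_correction(self):
        with pytest.raises(PipelineOrderError):
            gt.reject_artifacts(random_epochs(0))


class TestAverage:
    def test_single_epoch_per_class(self):
        eps = gt.baseline_correct(random_epochs(5, n=2))
        # event 0 is a target ('front'), event 1 is not
        avg = gt.average(eps)
        assert np.array_equal(avg.target, eps.data[0])
        assert np.array_equal(avg.nontarget, eps.data[1])

    def test_opposite_epochs_cancel(self):
        eps = random_epochs(0, n=3, scale=0.0)
        events = [gt.StimulusEvent(sample=500 + i, run=1, block=1,
                                   position="front" if i < 2 else "back",
                                   is_target=i < 2) for i in range(3)]
        eps.events = events
        eps.data[0, :, eps.n_pre:] = 1.0   # target A
        eps.data[1, :, eps.n_pre:] = -1.0  # target B
        avg = gt.average(gt.baseline_correct(eps))
        assert np.allclose(avg.target[:, eps.n_pre:], 0.0, atol=1e-12)

    def test_matches_oracle_mean(self):
        eps = gt.baseline_correct(random_epochs(8, n=50))
        avg = gt.average(eps)
        tgt = [i for i, ev in enumerate(eps.events) if ev.is_target]
        expected = sum(eps.data[i] for i in tgt) / len(tgt)
        assert np.allclose(avg.target, expected, atol=1e-12)
        assert avg.n_target == len(tgt)

    def test_permutation_invariant(self):
        eps = gt.baseline_correct(random_epochs(9, n=24))
        rng = np.random.default_rng(0)
        perm = rng.permutation(eps.n_epochs)
        shuffled = gt.EpochSet(
            data=eps.data[perm],
            channel_labels=eps.channel_labels, sample_rate=eps.sample_rate,
            epoch_pre_ms=eps.epoch_pre_ms, epoch_post_ms=eps.epoch_post_ms,
            events=[eps.events[i] for i in perm], kept=eps.kept[perm],
            baseline_corrected=True)
        a, b = gt.average(eps), gt.average(shuffled)
        assert np.allclose(a.target, b.target, atol=1e-12)
        assert np.allclose(a.nontarget, b.nontarget, atol=1e-12)

    def test_empty_class_error_names_the_class(self):
        eps = random_epochs(0, n=4)
        eps.events = [gt.StimulusEvent(sample=100 + i, run=1, block=1,
                                       position="back", is_target=False)
                      for i in range(4)]
        eps = gt.baseline_correct(eps)
        with pytest.raises(ValueError, match="target"):
            gt.average(eps)

    def test_requires_baseline_correction(self):
        with pytest.raises(PipelineOrderError):
            gt.average(random_epochs(0))
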