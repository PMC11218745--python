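import numpy as np
import pytest

import gridtap as gt


@pytest.fixture(scope="session")
def montage():
    return gt.default_montage()


@pytest.fixture(scope="session")
def isolated_erp_average(montage):
    """Noise-free average from well-separated target/non-target events."""
    events = [
        gt.StimulusEvent(sample=500, run=1, block=1, position="front",
                         is_target=True),
        gt.StimulusEvent(sample=3000, run=1, block=1, position="back",
                         is_target=False),
    ]
    gen = gt.GeneratorConfig(noise_sd_uv=0.0)
    rec = gt.synthesize_recording(events, montage, gen)
    rec = gt.derive_bipolar(rec, montage)
    eps = gt.baseline_correct(gt.epoch(rec))
    return gt.average(eps)


@pytest.fixture(scope="session")
def small_session(montage):
    """One-run session with strong ERP and moderate noise; ~5 s to build."""
    paradigm = gt.ParadigmConfig(n_runs=1, seed=5)
    gen = gt.GeneratorConfig(noise_sd_uv=6.0, seed=5)
    schedule = gt.schedule_session(paradigm)
    rec = gt.synthesize_recording(schedule, montage, gen)
    rec = gt.bandpass(rec)
    rec = gt.derive_bipolar(rec, montage)
    return gt.baseline_correct(gt.epoch(rec))


def random_epochs(seed, n=20, n_ch=3, fs=250.0, pre=100.0, post=800.0,
                  scale=10.0):
    """Random baseline-corrected-flag-free EpochSet for oracle tests."""
    rng = np.random.default_rng(seed)
    ns = int(round((pre + post) / 1000.0 * fs))
    data = scale * rng.standard_normal((n, n_ch, ns))
    events = [
        gt.StimulusEvent(sample=1000 + 250 * i, run=1, block=1 + (i % 2),
                         position=gt.POSITIONS[i % 4],
                         is_target=(gt.POSITIONS[i % 4] == "front"))
        for i in range(n)
    ]
    return gt.EpochSet(data=data, channel_labels=[f"ch{i}" for i in range(n_ch)],
                       sample_rate=fs, epoch_pre_ms=pre, epoch_post_ms=post,
                       events=events)
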