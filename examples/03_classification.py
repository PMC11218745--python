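"""Classify one session offline with SWLDA for both EEG systems.

For every target block, an SWLDA model is trained on the remaining 47
blocks and the attended position is selected as the argmax of the mean
epoch score per position (leave-one-block-out cross-validation).  An
accuracy of 37.5% (18/48) is the smallest significantly above the 25%
four-choice chance level; 70% is the usability convention.
"""

import gridtap as gt

montage = gt.default_montage()
events = gt.schedule_session(gt.ParadigmConfig(seed=3))
rec = gt.synthesize_recording(events, montage, gt.GeneratorConfig(seed=3))
rec = gt.bandpass(rec)
rec = gt.derive_bipolar(rec, montage)
eps = gt.baseline_correct(gt.epoch(rec))

cfg = gt.ClassifierConfig()
for system in ("cap", "ceegrid"):
    channels = gt.channels_for_system(montage, system)
    res = gt.loocv_accuracy(eps, cfg, channels)
    print(f"{system:8s} ({len(channels):2d} channels): "
          f"{res.n_correct}/{res.n_blocks} blocks correct = "
          f"{res.accuracy_pct:.1f}%  "
          f"above-chance={res.significant}  usable={res.meets_usability}")
# The cap typically outperforms the ear system because the injected
# window-mean amplitude is about twice as large at Cz as at the best
# bipolar ear channel.
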