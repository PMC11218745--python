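"""Build a vibrotactile oddball session and synthesize its EEG.

The paradigm: six runs of eight blocks; within a block each of the four
body positions (front, back, left, right) vibrates ten times while one
position is attended.  The generator renders the schedule into
continuous 250 Hz EEG for the scalp cap and both ear arrays, injecting
a calibrated P300-like deflection after every attended stimulus.
"""

import numpy as np

import gridtap as gt

paradigm = gt.ParadigmConfig(seed=1)
events = gt.schedule_session(paradigm)
n_target = sum(ev.is_target for ev in events)
print(f"schedule: {len(events)} stimuli, {n_target} targets, "
      f"{len(events) - n_target} non-targets")
print(f"stimulus-onset asynchrony: {paradigm.soa_ms:.0f} ms "
      f"({paradigm.stimulus_ms:.0f} ms vibration + "
      f"{paradigm.isi_ms:.0f} ms gap)")

montage = gt.default_montage()
print(f"montage: {len(montage.scalp_channels)} scalp + "
      f"{len(montage.ceegrid_channels)} ear channels, "
      f"{len(montage.bipolar_pairs)} bipolar pairs")

gen = gt.GeneratorConfig(seed=1)
rec = gt.synthesize_recording(events, montage, gen,
                              sample_rate=paradigm.sample_rate)
print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"({rec.duration_s / 60:.1f} min), "
      f"noise SD {np.std(rec.channel('Oz')):.1f} uV")
# A full session is ~21 minutes of signal; the target count (480) is what
# gives the stimulus-locked averages their statistical power.
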