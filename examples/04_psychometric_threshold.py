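"""Estimate a somatosensory sensitivity threshold.

A simulated observer judges pairs of vibrations (100% reference, second
stimulus descending a 5%-step grid) as equal or different; the adaptive
scheduler spends extra trials where the responses are still ambiguous.
The threshold is the second-stimulus intensity reported equal in half
the trials — the 0.5 crossing of the fitted logistic.
"""

import gridtap as gt
from gridtap.psychophysics import SchedulerState, response_ratios

observer = gt.PsychoSimConfig(true_threshold_pct=78.0, slope=4.0, seed=4)
scheduler = SchedulerState(grid=observer.intensity_grid, seed=4)
trials = gt.run_discrimination_session(observer, scheduler)
print(f"collected {len(trials)} trials")

ratios = response_ratios(trials)
for intensity in sorted(ratios, reverse=True):
    bar = "#" * int(round(20 * ratios[intensity]))
    print(f"  {intensity:5.0f}%  ratio {ratios[intensity]:4.2f}  {bar}")

fit = gt.estimate_threshold(trials)
print(f"fitted threshold: {fit.threshold_pct:.1f}% "
      f"(true {observer.true_threshold_pct}%), slope {fit.slope:.1f}")
# The response ratio runs from 0 (always 'different') to 1 (always
# 'equal'); the threshold is where the fitted curve crosses 0.5.
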