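# Methods

This note documents the models, parameter choices and numerical
conventions behind `gridtap`, and what the synthetic cohorts can and
cannot say about real recordings.

## Paradigm model

A session is six runs of eight target blocks. Within a block, each of
the four tactor positions (front, back, left, right) vibrates exactly
ten times in a seeded random order (no constraint on immediate stimulus
repetitions; only the counts are fixed), with onsets spaced by the
stimulus-onset asynchrony of 620 ms (220 ms vibration + 400 ms
inter-stimulus interval). The block target sequence is rejection-sampled
per run so each position is target exactly twice per run and no two
consecutive blocks — including across run boundaries — share a target.
Blocks are separated by a 2 s silent gap (a package choice; the gap only
has to exceed the epoch span so block epochs never straddle a boundary),
with 1 s lead-in and 1.5 s tail. A full session is therefore 480 target
and 1,440 non-target stimuli over ~21.5 minutes at 250 Hz.

## Signal model

Channels: 12 scalp electrodes (Fz, FC1, FC2, C3, Cz, C4, P3, Pz, P4,
O1, Oz, O2) and 18 recordable ear electrodes (R1–R8, L1–L8, L4a, L4b;
R4a and R4b serve as ground and reference and carry no data). Eight
vertical bipolar derivations (R1−R8, R2−R7, R3−R6, R4−R5 and left
counterparts) are computed sample-wise. `default_montage()` can mirror
the ground/reference exclusion to the left ear
(`mirror_reference_exclusion=True`), since real adapter wirings differ;
the default keeps 18 ear channels, matching the channel count used for
classification (18 monopolar + 8 bipolar).

**ERP template.** Each target stimulus adds a Gaussian-windowed positive
deflection (σ = 80 ms) peaking 463 ms post-stimulus at scalp channels
and 501 ms at ear channels. The template's peak value is calibrated *per
channel* so that the mean of a noise-free, baseline-corrected epoch over
the channel's analysis window (350–650 ms scalp, 400–700 ms ear) equals
the configured amplitude exactly — the default amplitudes are the
group-mean window amplitudes of the two systems (Cz 3.53, Fz 2.70,
Pz 2.68; R2−R7 1.87, R3−R6 1.69, L2−L7 1.58, L3−L6 1.63 μV). Because the
calibration is computed on the same sample grid, with the same baseline
subtraction, as the extraction stage, the identity holds to machine
precision and is asserted at 1e-9 in the tests. Bipolar amplitudes are
realized by adding ±half the template to the pair's parent electrodes.
Templates of consecutive stimuli superpose linearly (the SOA of 620 ms
is shorter than the 900 ms epoch span, so neighbouring target epochs
contaminate each other's baselines by a few percent of the peak — as in
real recordings, and deliberately not corrected). Non-target stimuli
evoke nothing by default (`nontarget_amplitude_scale` enables a small
response). Whole-subject polarity inversion (`polarity_sign = −1`)
models the rare participants whose average deflection is negative.

**Noise.** Per-channel background noise with a 1/f power spectrum
(generated by spectral shaping of white Gaussian noise at an
FFT-friendly padded length, in single precision — quantization is ~7
orders below physiological noise), scaled to `noise_sd_uv`. Within each
ear array a fraction `ear_noise_corr` of the noise *variance* is a
shared component: real neighbouring ear electrodes record largely common
background, which is what keeps a bipolar difference from being √2
noisier than its parents. Scalp channels are independent. The defaults
(`noise_sd_uv = 19.0`, `ear_noise_corr = 0.55`) were fixed once by a
small calibration sweep so that the *default heterogeneous cohort*
lands near the two systems' published group accuracies (~81% cap,
~63% ear); they are a synthetic operating point, not measured
quantities, and single-trial SNR in real data may differ in structure
(non-stationarity, ocular/muscle topographies) as well as level.

**Artifacts.** With probability `artifact_epoch_rate` per stimulus, a
Gaussian excursion (σ = 40 ms) peaking at `artifact_amplitude_uv`
(default 150 μV, validated to exceed the 75 μV rejection threshold) is
added on all channels at a random latency 100–700 ms post-stimulus.
Because epochs of neighbouring stimuli overlap in time, an excursion can
trip more than one epoch — intended, as real movement artifacts do.

## Preprocessing conventions

* Band-pass: 4th-order Butterworth per pass, applied forward–backward
  (zero phase, doubled order), 0.1–30 Hz. The 48–52 Hz notch of the
  acquisition chain is a property of the stored/simulated data, not a
  pipeline stage.
* Epochs: half-open sample window `[onset − 100 ms, onset + 800 ms)`,
  0-based indices → 225 samples at 250 Hz; sample *k* has latency
  `(k − 25)/250` s. Events without full context are excluded with a
  logged warning.
* Baseline: subtract the pre-stimulus mean per epoch and channel;
  re-correction raises. Rejection requires corrected input (the
  threshold is evaluated post-correction; configurable in principle by
  reordering calls, but the enforced order is the documented one).
* Rejection: an epoch is dropped when any sample on any *scoped* channel
  exceeds 75 μV in absolute value, strictly — exactly ±75.0 is kept. The
  scope defaults to all channels; the study driver scopes it to the
  channels entering each system's ERP analysis so one unused noisy
  electrode cannot discard a whole session.
* Averaging: arithmetic mean over kept epochs per class; empty classes
  are an error naming the class.

## ERP features

Window means are taken over samples whose latency lies in the closed
interval `[start, end]` after rounding to the sample grid. Peak latency
is the argmax (or argmin for negative polarity) within a 300–700 ms
search window, ties resolving to the earliest sample; the search window
is a package default since the extraction window choice is analysis
convention.

## Classification

Features: per channel, means of consecutive 50 ms bins over 0–800 ms
(16 bins; a bin width that does not divide 800 ms drops the trailing
partial bin with a warning). Channel sets: the 12 cap electrodes, or all
18 ear electrodes plus the 8 bipolar channels (26 × 16 = 416 features).

SWLDA: forward–backward stepwise least-squares regression of the labels
(+1 target / −1 non-target) on the features. Forward step: add the
candidate with the smallest partial-F p-value if below `p_enter`;
backward step: remove any included feature whose p-value exceeds
`p_remove` (the feature just added is exempt, preventing enter/remove
cycling). Stops at `max_features`, when nothing changes, or when the fit
is numerically exact. The defaults (0.10 / 0.15 / 60) are the standard
P300-classifier convention. Implementation: incremental QR with the
candidate geometry tracked against the original centered matrix (the new
basis vector is orthogonal to the previous ones, so candidate
projections never require a residualized copy); the selection path is
identical to a naive re-fit-everything implementation, which the tests
assert against a from-scratch statsmodels-based oracle. With selection
disabled (`p_enter = p_remove = 1`, unlimited features) the weights
equal ordinary least squares.

Selection: per block, the mean epoch score per position; argmax wins,
ties resolve to canonical order (front, back, left, right). LOO
cross-validation leaves out one *target block* (48 folds) — leaving out
single epochs would leak the held-out block's other repetitions into
training. Degenerate folds (no feature entered) count as incorrect and
are logged. Artifact-rejected epochs are kept for classification by
default (`reject_for_classification` flips this), since rejection
belongs to the physiological analysis.

Chance bound: the smallest k with exact binomial tail
P(X ≥ k | n, 0.25) < α. For 48 selections at α = 0.05: k = 18, i.e.
37.5%, floor-rounded to 37 when reported as an integer percent.

## Psychophysics

Observer model: P("equal") = logistic((intensity − threshold)/slope);
default slope 4 (percentage points), giving the gradual transition seen
in real response curves. Scheduler: one seeded random sweep over the
grid (100% down to 50% in 5% steps — thresholds near 75% sit comfortably
inside), then uniform sampling among intensities whose running response
ratio is strictly inside (0.2, 0.8) — untested intensities count as
ambiguous — falling back to the full grid; budget 53 trials (the
observed maximum in comparable data). The band, fallback and budget are
scheduler conventions, configurable.

Fit: 2-parameter logistic with asymptotes fixed at 0 and 1 (the response
scale is defined on [0, 1]; no lapse parameters), weighted least squares
with trial-count weights; a binomial-likelihood fit is available behind
`likelihood=True`. One-sided data or optimizer failure yield a
non-converged fit; `estimate_threshold` raises in that case, mirroring
how participants without a determinable threshold are excluded. A
midpoint outside the tested grid is flagged `boundary`.

Parameter recovery at the defaults (true threshold 74.6%, slope 4,
40-trial budget) is unbiased within 2 percentage points over 500
simulated observers, with spread shrinking as the budget grows — which
validates the estimator, not any claim about real observers' lapse or
attention dynamics (deliberately absent from the model).

## Group statistics

Paired t (two-tailed, df = n−1), Pearson r (p from the t transform), and
one-way within-subject ANOVA via pingouin with partial η². Mauchly's
test at α = 0.05 triggers the Greenhouse–Geisser df correction (the
correction threshold is a package policy). Post-hocs: all pairwise
paired t-tests among the seven channels of interest with
Bonferroni-multiplied p-values capped at 1. Degenerate inputs (identical
conditions, zero-variance differences) short-circuit to exact null
results instead of 0/0. The accuracy table marks subjects below the
37.5% bound with `+`, significant-but-below-70% with `*`, and missing
values with `–`.

## Study driver and heterogeneity

`run_study` simulates a cohort: per subject, a log-normal ERP amplitude
scale (σ = 0.45, median 1), a log-normal noise scale (σ = 0.15),
polarity inversion with probability 0.05 (≈ the 2-in-37 rate seen in
per-subject overviews), and a true sensitivity threshold drawn
N(74.6, 9²) clipped to the grid. These distributions emulate the
between-subject spread of real cohorts (accuracies from chance to 100%)
and are package choices. Per-subject failures are logged and excluded;
the study continues. All seeds derive from one master seed via
`SeedSequence.spawn`, so outputs are byte-identical across reruns.

## Problem sizes used in validation

The validation suite runs: 200 signal-free cap-only subjects for the
chance-level calibration (the mean accuracy is checked against its own
95% CI around 25%, which absorbs the within-subject dependence of the
48 folds; the above-bound rate against 5% plus two binomial SEs);
a 5-level × 20-subject amplitude sweep (scales 0.25–1.5, Spearman ρ of
the level means); 50 random stepwise problems against the independent
oracle; 500 psychometric replicates; 50 random datasets per statistical
test; and one 50-subject default cohort for the cap-vs-ear ordering.
Cap-only cohorts are used where only scalp accuracy is asserted, since
synthesizing the ear arrays would triple the cost without changing the
claim. `scripts/acceptance.py` reports the same quantities at 60 null
subjects, 5 × 8 sweep subjects and a 20-subject cohort.

**A note on null calibration.** Per-block correctness on signal-free
data is *exactly* 25%: the assignment of positions to stimulus slots is
independent of the scores, so the argmax hits the target with
probability 1/4 regardless of what the model learned — and the measured
grand mean agrees. The *distribution* of per-subject accuracies,
however, is wider than iid-binomial (SD ≈ 9 points vs 6.25): fold
outcomes of leave-one-block-out CV are positively dependent because
every fold's stepwise model shares almost all of its training data with
every other fold, and a 60-feature model fitted to pure noise overfits
enough to make that dependence material. Consequently the fraction of
null subjects above the 37.5% screen is ~8%, about twice the 3.7% an
independence assumption predicts, under both white and 1/f noise — a
property of block-LOO with an overfitting classifier, not of the noise
model. The validation suite states the independence-based bound and
therefore flags this, by design; screens derived from the iid binomial
should be read as approximate for this CV design.

## Known limitations

* The generator's ERP is a single fixed-shape template; real P300s vary
  in latency and width across trials and subjects, which SWLDA partially
  absorbs but which is not modelled.
* Noise is stationary 1/f with a fixed within-ear correlation; no
  ocular/muscle topographies, electrode drift or impedance changes.
* Accuracy levels are a calibrated operating point — comparisons
  *between* configurations (systems, SNR levels, trial counts) are
  meaningful; absolute accuracies are not predictions for new hardware.
* EDF export quantizes to 16 bits over each channel's range and pads the
  last one-second record with zeros; events travel in the companion
  `events.tsv`, not as EDF+ annotations.
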