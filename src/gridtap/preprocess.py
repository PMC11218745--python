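"""The offline signal path: filter → epoch → baseline → reject → average.

Continuous data are zero-phase band-pass filtered (0.1–30 Hz), split
into epochs of 800 ms post-stimulus plus 100 ms pre-stimulus, baseline
corrected against the pre-stimulus mean, screened for ±75 μV artifact
excursions, and averaged separately into target and non-target classes.
Stage order is enforced through flags on :class:`EpochSet`: baseline
correction refuses already-corrected input, rejection requires corrected
input.  The 48–52 Hz notch named in the acquisition chain is a property
of the stored signals (applied at recording/simulation time), not a
stage of this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .events import StimulusEvent
from .recording import Recording

logger = logging.getLogger(__name__)


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked out of order."""


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass_hz: tuple[float, float] = (0.1, 30.0)
    filter_order: int = 4
    epoch_pre_ms: float = 100.0
    epoch_post_ms: float = 800.0
    reject_abs_uv: float = 75.0

    def __post_init__(self) -> None:
        low, high = self.bandpass_hz
        if not (0 < low < high):
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.epoch_pre_ms < 0 or self.epoch_post_ms <= 0:
            raise ValueError("epoch windows must be positive")


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``data`` is (n_epochs, n_channels, n_samples).

    Epoch sample ``k`` has latency ``(k - n_pre) / fs`` relative to the
    stimulus onset under the half-open convention
    ``[onset - pre, onset + post)``.
    """

    data: np.ndarray
    channel_labels: list[str]
    sample_rate: float
    epoch_pre_ms: float
    epoch_post_ms: float
    events: list[StimulusEvent]
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kept is None:
            self.kept = np.ones(len(self.events), dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[0] != len(self.events):
            raise ValueError("one event per epoch required")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel label count mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_pre(self) -> int:
        return int(round(self.epoch_pre_ms / 1000.0 * self.sample_rate))

    @property
    def latencies_ms(self) -> np.ndarray:
        return (np.arange(self.data.shape[2]) - self.n_pre) \
            / self.sample_rate * 1000.0

    @property
    def is_target(self) -> np.ndarray:
        return np.array([ev.is_target for ev in self.events], dtype=bool)

    def channel_index(self, labels: list[str]) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.channel_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"channels not in epoch set: {missing}")
        return np.array([index[lab] for lab in labels])


@dataclass
class ERPAverage:
    """Per-class, per-channel average waveforms with epoch counts."""

    target: np.ndarray        # (n_channels, n_samples)
    nontarget: np.ndarray
    channel_labels: list[str]
    sample_rate: float
    epoch_pre_ms: float
    epoch_post_ms: float
    n_target: int
    n_nontarget: int

    @property
    def latencies_ms(self) -> np.ndarray:
        n_pre = int(round(self.epoch_pre_ms / 1000.0 * self.sample_rate))
        return (np.arange(self.target.shape[1]) - n_pre) \
            / self.sample_rate * 1000.0

    def waveform(self, channel: str, which: str = "target") -> np.ndarray:
        idx = self.channel_labels.index(channel)
        return (self.target if which == "target" else self.nontarget)[idx]


def bandpass(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering doubles the effective order and leaves
    ERP latencies untouched.  Events are carried over unchanged.
    """
    low, high = cfg.bandpass_hz
    nyq = rec.sample_rate / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = butter(cfg.filter_order, [low, high], btype="bandpass",
                 fs=rec.sample_rate, output="sos")
    filtered = sosfiltfilt(sos, rec.signal, axis=1)
    return Recording(
        sample_rate=rec.sample_rate,
        channel_labels=list(rec.channel_labels),
        signal=filtered,
        events=list(rec.events),
        meta={**rec.meta, "bandpass_hz": cfg.bandpass_hz},
    )


def epoch(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Slice one epoch per event, time-locked to the stimulus onset.

    Uses the half-open sample window ``[onset - n_pre, onset + n_post)``;
    at 250 Hz and (−100, 800) ms this yields 225 samples.  Events too
    close to a recording edge are excluded with a logged warning.
    """
    n_pre = int(round(cfg.epoch_pre_ms / 1000.0 * rec.sample_rate))
    n_post = int(round(cfg.epoch_post_ms / 1000.0 * rec.sample_rate))
    slices = []
    kept_events = []
    n_dropped = 0
    for ev in rec.events:
        lo, hi = ev.sample - n_pre, ev.sample + n_post
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        slices.append(rec.signal[:, lo:hi])
        kept_events.append(ev)
    if n_dropped:
        logger.warning("excluded %d event(s) without full epoch context", n_dropped)
    data = np.stack(slices) if slices else \
        np.empty((0, rec.n_channels, n_pre + n_post))
    return EpochSet(
        data=data,
        channel_labels=list(rec.channel_labels),
        sample_rate=rec.sample_rate,
        epoch_pre_ms=cfg.epoch_pre_ms,
        epoch_post_ms=cfg.epoch_post_ms,
        events=kept_events,
    )


def baseline_correct(eps: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel pre-stimulus mean."""
    if eps.baseline_corrected:
        raise PipelineOrderError("epochs are already baseline-corrected")
    if eps.n_pre == 0:
        raise PipelineOrderError("no pre-stimulus samples to correct against")
    base = eps.data[:, :, :eps.n_pre].mean(axis=2, keepdims=True)
    return replace(eps, data=eps.data - base, kept=eps.kept.copy(),
                   events=list(eps.events), baseline_corrected=True)


def reject_artifacts(eps: EpochSet, cfg: PreprocessConfig = PreprocessConfig(),
                     channels: list[str] | None = None) -> EpochSet:
    """Flag epochs exceeding the absolute amplitude threshold.

    An epoch is rejected when any sample on any scoped channel is
    strictly above ``reject_abs_uv`` in absolute value (exactly 75.0 μV
    is kept).  ``channels`` restricts the scan to the channels entering
    the analysis; by default all channels are scanned.  Requires
    baseline-corrected input.
    """
    if not eps.baseline_corrected:
        raise PipelineOrderError("reject_artifacts requires baseline-corrected epochs")
    if channels is None:
        scoped = eps.data
    else:
        scoped = eps.data[:, eps.channel_index(channels), :]
    if eps.n_epochs == 0:
        return replace(eps, kept=eps.kept.copy(), events=list(eps.events))
    peak = np.abs(scoped).max(axis=(1, 2))
    kept = eps.kept & ~(peak > cfg.reject_abs_uv)
    n_rej = int((~kept & eps.kept).sum())
    if n_rej:
        logger.info("rejected %d/%d epochs above ±%.1f uV",
                    n_rej, eps.n_epochs, cfg.reject_abs_uv)
    return replace(eps, kept=kept, events=list(eps.events))


def average(eps: EpochSet) -> ERPAverage:
    """Average kept epochs separately into target and non-target classes."""
    if not eps.baseline_corrected:
        raise PipelineOrderError("average requires baseline-corrected epochs")
    is_tgt = eps.is_target
    masks = {"target": eps.kept & is_tgt, "non-target": eps.kept & ~is_tgt}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"no kept {name} epochs to average")
    return ERPAverage(
        target=eps.data[masks["target"]].mean(axis=0),
        nontarget=eps.data[masks["non-target"]].mean(axis=0),
        channel_labels=list(eps.channel_labels),
        sample_rate=eps.sample_rate,
        epoch_pre_ms=eps.epoch_pre_ms,
        epoch_post_ms=eps.epoch_post_ms,
        n_target=int(masks["target"].sum()),
        n_nontarget=int(masks["non-target"].sum()),
    )
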