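"""The in-memory multichannel recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import StimulusEvent


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with stimulus events.

    ``signal`` is a ``(n_channels, n_samples)`` float array; row order
    matches ``channel_labels``.  Every event's sample index must lie
    within the signal.
    """

    sample_rate: float
    channel_labels: list[str]
    signal: np.ndarray
    events: list[StimulusEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.signal.shape[1]
        for ev in self.events:
            if not (0 <= ev.sample < n):
                raise ValueError(
                    f"event at sample {ev.sample} outside recording of {n} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r} in recording") from None
        return self.signal[idx]

    def pick(self, labels: list[str]) -> np.ndarray:
        """Return a (len(labels), n_samples) view-copy in the given order."""
        return np.stack([self.channel(lab) for lab in labels])
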