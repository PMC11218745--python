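"""Stimulus events and the BIDS-style events table.

A session is a stream of vibrotactile stimuli delivered at four body
positions (front, back, left, right).  Each event knows which run and
block it belongs to and whether its position was the attended target of
that block.  On disk, events live in a tab-separated table with columns
``onset_s, duration_s, run, block, position, is_target`` — onsets in
seconds, converted to integer sample indices internally by rounding to
the nearest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

#: Closed vocabulary of stimulation sites, in canonical order.
POSITIONS: tuple[str, ...] = ("front", "back", "left", "right")

EVENT_COLUMNS = ("onset_s", "duration_s", "run", "block", "position", "is_target")


class EventError(ValueError):
    """Raised for malformed event tables or out-of-range events."""


@dataclass(frozen=True)
class StimulusEvent:
    """One vibrotactile stimulus.

    Parameters
    ----------
    sample
        Onset as a 0-based sample index into the recording.
    run
        1-based run number.
    block
        1-based block number within the run.
    position
        Stimulation site, one of :data:`POSITIONS`.
    is_target
        True when ``position`` is the attended target of this block.
    duration_s
        Vibration duration in seconds (0.22 s in the default paradigm).
    """

    sample: int
    run: int
    block: int
    position: str
    is_target: bool
    duration_s: float = 0.22

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise EventError(
                f"unknown position {self.position!r}; expected one of {POSITIONS}"
            )
        if self.sample < 0:
            raise EventError(f"event sample must be >= 0, got {self.sample}")

    def with_sample(self, sample: int) -> "StimulusEvent":
        return replace(self, sample=int(sample))


def events_to_frame(events: list[StimulusEvent], sample_rate: float) -> pd.DataFrame:
    """Tabulate events with onsets in seconds."""
    return pd.DataFrame(
        {
            "onset_s": [ev.sample / sample_rate for ev in events],
            "duration_s": [ev.duration_s for ev in events],
            "run": [ev.run for ev in events],
            "block": [ev.block for ev in events],
            "position": [ev.position for ev in events],
            "is_target": [int(ev.is_target) for ev in events],
        }
    )


def write_events(events: list[StimulusEvent], path: str | Path, sample_rate: float) -> None:
    """Write events as a BIDS-style tab-separated table."""
    events_to_frame(events, sample_rate).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path, sample_rate: float) -> list[StimulusEvent]:
    """Read a tab-separated events table.

    Onsets must be non-decreasing within each run; positions outside the
    closed vocabulary and missing columns raise :class:`EventError`.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventError(f"events table missing column(s): {missing}")
    events: list[StimulusEvent] = []
    for row in table.itertuples(index=False):
        if row.onset_s < 0:
            raise EventError(f"negative onset {row.onset_s}")
        events.append(
            StimulusEvent(
                sample=int(round(row.onset_s * sample_rate)),
                run=int(row.run),
                block=int(row.block),
                position=str(row.position),
                is_target=bool(row.is_target),
                duration_s=float(row.duration_s),
            )
        )
    for run in table["run"].unique():
        onsets = table.loc[table["run"] == run, "onset_s"].to_numpy()
        if (onsets[1:] < onsets[:-1]).any():
            raise EventError(f"onsets not non-decreasing within run {run}")
    return events
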