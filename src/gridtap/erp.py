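"""Physiological ERP features: window-mean amplitudes and peak latencies.

The feature of record is the mean amplitude of the target average over a
fixed post-stimulus window — 350–650 ms at the scalp sites of interest
(Fz, Cz, Pz) and 400–700 ms at the vertical bipolar ear channels
(R2−R7, R3−R6, L2−L7, L3−L6), where the deflection peaks later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ERPAverage
from .simulate import CEEGRID_WINDOW, SCALP_WINDOW

logger = logging.getLogger(__name__)

#: Default channels of interest and their analysis windows.
CHANNELS_OF_INTEREST: tuple[tuple[str, tuple[float, float]], ...] = (
    ("Fz", SCALP_WINDOW),
    ("Cz", SCALP_WINDOW),
    ("Pz", SCALP_WINDOW),
    ("R2-R7", CEEGRID_WINDOW),
    ("R3-R6", CEEGRID_WINDOW),
    ("L2-L7", CEEGRID_WINDOW),
    ("L3-L6", CEEGRID_WINDOW),
)

#: Default search window for peak latency (ms post-stimulus).
PEAK_SEARCH_WINDOW: tuple[float, float] = (300.0, 700.0)


@dataclass(frozen=True)
class AmplitudeWindow:
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_ms < self.end_ms):
            raise ValueError(
                f"window must satisfy 0 <= start < end, got "
                f"({self.start_ms}, {self.end_ms})")


def _window_samples(avg: ERPAverage, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    AmplitudeWindow(start, end)
    lat = avg.latencies_ms
    if end > lat[-1] + 1e-9:
        raise ValueError(f"window ({start}, {end}) ms extends beyond the epoch")
    mask = (lat >= start) & (lat <= end)
    if not mask.any():
        raise ValueError(f"window ({start}, {end}) ms contains no samples")
    return mask


def mean_amplitude(avg: ERPAverage, channel: str,
                   window: tuple[float, float],
                   which: str = "target") -> float:
    """Mean of the class-average waveform over samples whose latency lies
    in the closed interval ``[start_ms, end_ms]``."""
    mask = _window_samples(avg, window)
    return float(avg.waveform(channel, which)[mask].mean())


def peak_latency(avg: ERPAverage, channel: str,
                 search_window: tuple[float, float] = PEAK_SEARCH_WINDOW,
                 polarity: int = 1, which: str = "target") -> float:
    """Latency (ms) of the extreme value of the requested polarity.

    ``polarity=+1`` finds the maximum, ``-1`` the minimum; ties resolve
    to the earliest sample.
    """
    mask = _window_samples(avg, search_window)
    wave = avg.waveform(channel, which)[mask]
    lat = avg.latencies_ms[mask]
    idx = int(np.argmax(polarity * wave))  # argmax takes the first of ties
    return float(lat[idx])


def feature_table(
    subjects: dict[str, ERPAverage],
    channels: tuple[tuple[str, tuple[float, float]], ...] = CHANNELS_OF_INTEREST,
    search_window: tuple[float, float] = PEAK_SEARCH_WINDOW,
) -> pd.DataFrame:
    """One row per subject × channel-of-interest.

    Columns: subject, channel, window, mean_amplitude_uv,
    peak_latency_ms, n_epochs.  Subjects missing a channel contribute no
    row for it (logged).  Group means/SDs come from
    :func:`summarize_features`.
    """
    rows = []
    for subject, avg in subjects.items():
        for channel, window in channels:
            if channel not in avg.channel_labels:
                logger.warning("subject %s has no channel %s; row skipped",
                               subject, channel)
                continue
            rows.append({
                "subject": subject,
                "channel": channel,
                "window": f"{window[0]:g}-{window[1]:g}",
                "mean_amplitude_uv": mean_amplitude(avg, channel, window),
                "peak_latency_ms": peak_latency(avg, channel, search_window),
                "n_epochs": avg.n_target,
            })
    return pd.DataFrame(
        rows, columns=["subject", "channel", "window", "mean_amplitude_uv",
                       "peak_latency_ms", "n_epochs"])


def summarize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SD of amplitude and latency per channel."""
    out = table.groupby("channel", sort=False).agg(
        window=("window", "first"),
        mean_amplitude_uv=("mean_amplitude_uv", "mean"),
        sd_amplitude_uv=("mean_amplitude_uv", "std"),
        mean_latency_ms=("peak_latency_ms", "mean"),
        n_subjects=("subject", "nunique"),
    ).reset_index()
    return out
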