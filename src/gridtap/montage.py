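"""Electrode montages and bipolar derivations.

The study montage combines a 12-electrode scalp cap (Fz, FC1, FC2, C3,
Cz, C4, P3, Pz, P4, O1, Oz, O2) with two around-the-ear cEEGrid arrays.
Each cEEGrid carries ten electrodes; on the right ear R4a serves as
ground and R4b as reference, so they are not data channels, leaving 18
recordable ear channels (R1–R8, L1–L8, L4a, L4b).  Vertical bipolar
channels — differences of electrode pairs spanning the ear, e.g. R2−R7 —
approximate sensitivity toward central scalp sources and are where the
tactile P300 is largest in the ear recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

SCALP_CHANNELS: tuple[str, ...] = (
    "Fz", "FC1", "FC2", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "Oz", "O2",
)

#: The eight vertical bipolar derivations: four per ear, large
#: inter-electrode distance pairs first.
BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("R1", "R8"), ("R2", "R7"), ("R3", "R6"), ("R4", "R5"),
    ("L1", "L8"), ("L2", "L7"), ("L3", "L6"), ("L4", "L5"),
)


class MissingChannelError(KeyError):
    """A referenced channel is absent from the recording or montage."""


@dataclass(frozen=True)
class Montage:
    """Channel layout: data channels, their roles, and bipolar pairs.

    ``roles`` may also describe non-data electrodes (ground/reference);
    only ``channels`` are recordable.  ``bipolar_pairs`` holds
    ``(minuend, subtrahend, derived_label)`` triples; derived labels are
    named ``"<minuend>-<subtrahend>"`` and are disjoint from ``channels``.
    """

    name: str
    channels: tuple[str, ...]
    roles: dict[str, str] = field(default_factory=dict)
    bipolar_pairs: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        chans = set(self.channels)
        if len(chans) != len(self.channels):
            raise ValueError("duplicate channel labels in montage")
        labels = [lab for _, _, lab in self.bipolar_pairs]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate bipolar derived labels")
        if chans & set(labels):
            raise ValueError("bipolar derived labels collide with channel labels")
        for minu, subt, _ in self.bipolar_pairs:
            for ch in (minu, subt):
                if ch not in chans:
                    raise MissingChannelError(ch)

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if self.roles.get(c) == "scalp")

    @property
    def ceegrid_channels(self) -> tuple[str, ...]:
        return tuple(
            c for c in self.channels
            if self.roles.get(c) in ("ceegrid_left", "ceegrid_right")
        )

    @property
    def bipolar_labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, lab in self.bipolar_pairs)


def default_montage(mirror_reference_exclusion: bool = False) -> Montage:
    """The study montage: 12 scalp + 18 cEEGrid channels + 8 bipolar pairs.

    Parameters
    ----------
    mirror_reference_exclusion
        When True, exclude L4a/L4b from the data channels as well,
        mirroring the right ear's ground (R4a) and reference (R4b).  The
        default keeps them recordable (18 ear channels), matching the
        channel count used for classification.
    """
    right = tuple(f"R{i}" for i in range(1, 9))
    left = tuple(f"L{i}" for i in range(1, 9))
    left_extra = () if mirror_reference_exclusion else ("L4a", "L4b")
    channels = SCALP_CHANNELS + right + left + left_extra

    roles: dict[str, str] = {c: "scalp" for c in SCALP_CHANNELS}
    roles.update({c: "ceegrid_right" for c in right})
    roles.update({c: "ceegrid_left" for c in left + left_extra})
    roles["R4a"] = "ground"
    roles["R4b"] = "reference"
    if mirror_reference_exclusion:
        roles["L4a"] = "ground"
        roles["L4b"] = "reference"

    pairs = tuple((m, s, f"{m}-{s}") for m, s in BIPOLAR_PAIRS)
    return Montage(
        name="cap12+ceegrid", channels=channels, roles=roles, bipolar_pairs=pairs
    )


def cap_montage() -> Montage:
    """The 12-electrode scalp cap alone (no ear arrays).

    Useful for cap-only simulation studies where synthesizing the ear
    channels would be wasted work.
    """
    return Montage(name="cap12", channels=SCALP_CHANNELS,
                   roles={c: "scalp" for c in SCALP_CHANNELS})


def derive_bipolar(rec: Recording, montage: Montage) -> Recording:
    """Append the montage's bipolar channels (minuend − subtrahend).

    Original channels and events are preserved; a missing pair member
    raises :class:`MissingChannelError` naming the channel.
    """
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    labels = []
    for minu, subt, lab in montage.bipolar_pairs:
        for ch in (minu, subt):
            if ch not in index:
                raise MissingChannelError(
                    f"channel {ch!r} required for bipolar pair {lab!r} "
                    "is missing from the recording"
                )
        rows.append(rec.signal[index[minu]] - rec.signal[index[subt]])
        labels.append(lab)
    signal = np.vstack([rec.signal] + rows) if rows else rec.signal.copy()
    return Recording(
        sample_rate=rec.sample_rate,
        channel_labels=list(rec.channel_labels) + labels,
        signal=signal,
        events=list(rec.events),
        meta={**rec.meta, "bipolar": labels},
    )
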