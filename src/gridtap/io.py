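"""Reading and writing recordings.

Two on-disk forms are supported:

* **EDF** (``.edf``) — the open interchange format; written by the
  package's own 16-bit writer, read back through MNE.  Quantization to
  the 16-bit digital range and zero-padding to whole one-second data
  records are inherent to the format.  EDF carries no event table here;
  events travel in the companion ``events.tsv``.
* **Internal container** (``.npz`` + JSON sidecar) — a lossless pair of
  files: the signal as a compressed NumPy array, and a sidecar holding
  sample rate, channel labels, events and free-form metadata.  This is
  the format the pipeline itself uses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._edf import write_edf
from .events import StimulusEvent
from .recording import Recording


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording; format chosen by extension (.npz or .edf)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, signal=rec.signal)
        sidecar = {
            "sample_rate": rec.sample_rate,
            "channel_labels": list(rec.channel_labels),
            "events": [dataclasses.asdict(ev) for ev in rec.events],
            "meta": rec.meta,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    elif path.suffix == ".edf":
        write_edf(path, rec.signal, rec.channel_labels, rec.sample_rate)
    else:
        raise ValueError(f"unknown recording extension {path.suffix!r}")


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` or any EDF."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            signal = npz["signal"]
        sidecar = json.loads(_sidecar_path(path).read_text())
        events = [StimulusEvent(**ev) for ev in sidecar["events"]]
        return Recording(
            sample_rate=float(sidecar["sample_rate"]),
            channel_labels=list(sidecar["channel_labels"]),
            signal=signal,
            events=events,
            meta=sidecar.get("meta", {}),
        )
    if path.suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            sample_rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            signal=raw.get_data() * 1e6,  # MNE returns volts
            events=[],
            meta={"source": str(path), "format": "edf"},
        )
    raise ValueError(f"unknown recording extension {path.suffix!r}")
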