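"""Minimal EDF writer (16-bit European Data Format).

Only what this package needs: continuous μV-scaled channels at a common
integer-friendly sample rate.  Reading EDF goes through MNE; this writer
exists because no installed library exports EDF.  Signals are quantized
to 16 bits over each channel's physical range, and the last data record
is zero-padded to a whole record (one record = one second).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{width - 2}g}}", "{:.6g}", "{:.4g}", "{:.2g}"):
        s = fmt.format(value)
        if len(s) <= width:
            return _ascii(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path: str | Path, signal: np.ndarray, labels: list[str],
              sample_rate: float) -> None:
    """Write ``signal`` (channels x samples, μV) as an EDF file."""
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    if len(labels) != n_ch:
        raise ValueError("label count does not match signal rows")
    fs = int(round(sample_rate))
    if abs(fs - sample_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    n_rec = max(1, math.ceil(n_samp / fs))

    pmin = signal.min(axis=1)
    pmax = signal.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    header = b""
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)          # patient id (anonymous)
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (1 + n_ch)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_rec), 8)
    header += _ascii("1", 8)                 # record duration, seconds
    header += _ascii(str(n_ch), 4)
    for lab in labels:
        header += _ascii(lab, 16)
    header += _ascii("", 80) * n_ch          # transducer
    header += _ascii("uV", 8) * n_ch
    for lo in pmin:
        header += _num(float(lo), 8)
    for hi in pmax:
        header += _num(float(hi), 8)
    header += _num(dmin, 8) * n_ch
    header += _num(dmax, 8) * n_ch
    header += _ascii("", 80) * n_ch          # prefiltering
    header += _ascii(str(fs), 8) * n_ch
    header += _ascii("", 32) * n_ch

    # re-read the ASCII physical bounds so quantization matches the header
    plo = np.array([float(_num(float(v), 8).decode()) for v in pmin])
    phi = np.array([float(_num(float(v), 8).decode()) for v in pmax])
    scale = (dmax - dmin) / (phi - plo)

    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = signal
    digital = np.rint((padded - plo[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
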