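"""Minimal EDF/EDF+C writer (16-bit integer samples, 1-second records).

Covers exactly what this package needs for interoperability tests and
exports: a single common sampling rate, physical units taken from the
caller, per-channel physical min/max computed from the data. Reading goes
through mne's EDF reader, which honours these header fields.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(s: str, n: int) -> bytes:
    b = s[:n].ljust(n)
    return b.encode("ascii")


def write_edf(path: Path, data: np.ndarray, fs: float, channel_names,
              units: str = "uV") -> Path:
    """Write ``data`` (channels x samples, in ``units``) as EDF+C.

    Records are 1 s long; a final partial record is padded by repeating the
    last sample (readers see the padded length — callers that need the
    exact length should write whole seconds).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    nch, nsamp = data.shape
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("only integer sampling rates are supported")
    nrec = int(np.ceil(nsamp / spr))
    pad = nrec * spr - nsamp
    if pad:
        data = np.pad(data, ((0, 0), (0, pad)), mode="edge")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax <= pmin
    pmax[flat] = pmin[flat] + 1.0
    # The header stores physical bounds as 8-char ASCII; use the parsed
    # (truncated) values for the gain so the round-trip is self-consistent.
    pmin_s = [f"{v:.4f}"[:8] for v in pmin]
    pmax_s = [f"{v:.4f}"[:8] for v in pmax]
    pmin_a = np.array([float(s) for s in pmin_s])
    pmax_a = np.array([float(s) for s in pmax_s])
    gain = (pmax_a - pmin_a) / (_DIG_MAX - _DIG_MIN)
    offset = pmin_a - gain * _DIG_MIN

    hdr = io.BytesIO()
    hdr.write(_field("0", 8))                      # version
    hdr.write(_field("X X X X", 80))               # patient id
    hdr.write(_field("Startdate X X X X", 80))     # recording id
    hdr.write(_field("01.01.00", 8))               # start date
    hdr.write(_field("00.00.00", 8))               # start time
    hdr.write(_field(str(256 * (nch + 1)), 8))     # header bytes
    hdr.write(_field("EDF+C", 44))                 # reserved
    hdr.write(_field(str(nrec), 8))
    hdr.write(_field("1", 8))                      # record duration, s
    hdr.write(_field(str(nch), 4))
    for name in channel_names:
        hdr.write(_field(f"EEG {name}", 16))
    for _ in range(nch):
        hdr.write(_field("", 80))                  # transducer
    for _ in range(nch):
        hdr.write(_field(units, 8))
    for s in pmin_s:
        hdr.write(_field(s, 8))
    for s in pmax_s:
        hdr.write(_field(s, 8))
    for _ in range(nch):
        hdr.write(_field(str(_DIG_MIN), 8))
    for _ in range(nch):
        hdr.write(_field(str(_DIG_MAX), 8))
    for _ in range(nch):
        hdr.write(_field("", 80))                  # prefiltering
    for _ in range(nch):
        hdr.write(_field(str(spr), 8))
    for _ in range(nch):
        hdr.write(_field("", 32))                  # reserved

    dig = np.round((data - offset[:, None]) / gain[:, None])
    dig = dig.clip(_DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(nrec):
            for c in range(nch):
                fh.write(dig[c, r * spr:(r + 1) * spr].tobytes())
    return path
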