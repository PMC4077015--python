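"""Minimal EDF (European Data Format) reader/writer for interchange.

EDF stores 16-bit integers with per-channel linear physical scaling, so a
write/read round trip quantizes the signal (relative error ~= 2^-15 of the
channel's full scale).  The lossless container for tests is the native
.bin+.json pair in :mod:`assrlab.lfp_io`; EDF exists so recordings can be
inspected with standard electrophysiology tools.

Restrictions kept deliberately: integer sampling rate, one-second data
records (the final record is zero-padded), plain EDF (no EDF+ annotations).
The true sample count is stamped into the recording-id header field so our
own reader can strip the padding; other readers see whole-second signals.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np

from .lfp_io import Recording

_HEADER_BYTES = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def _phys_field(value: float) -> tuple[str, float]:
    """Format a physical min/max into <= 8 ASCII chars, rounded away from zero.

    Returns (text, parsed value); rounding away from zero guarantees the
    declared physical range always covers the data, so no sample clips.
    """
    # at most 7 chars for the magnitude, so the sign of phys_min still fits
    for fmt in ("%.2e", "%.1e", "%.0e"):
        text = fmt % value
        if len(text) <= 7:
            parsed = float(text)
            if abs(parsed) < abs(value):
                # bump the last mantissa digit away from zero
                digits = int(fmt[2])
                step = 10.0 ** -digits
                mant, _, exp = text.partition("e")
                bumped = float(mant) + (step if value > 0 else -step)
                text = ("%." + str(digits) + "fe" + exp) % bumped
                parsed = float(text)
            if len(text) <= 7:
                return text, parsed
    raise ValueError(f"cannot encode physical range {value!r}")


def write_edf(recording: Recording, path) -> None:
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = int(math.ceil(recording.n_samples / spr))
    ns = recording.n_channels

    data = np.zeros((ns, n_records * spr), dtype=np.float64)
    data[:, : recording.n_samples] = recording.signals

    phys_fields = [_phys_field(v) for v in np.maximum(np.abs(data).max(axis=1), 1e-12)]
    phys_max = np.array([v for _, v in phys_fields])
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(f"{recording.animal_id} {recording.genotype}", 80),
            _field(f"assrlab n={recording.n_samples} t0={recording.t0!r}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HEADER_BYTES * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_field(cid, 16) for cid in recording.channel_ids),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(recording.units, 8) for _ in range(ns)),
            b"".join(_field("-" + phys_fields[i][0], 8) for i in range(ns)),
            b"".join(_field(phys_fields[i][0], 8) for i in range(ns)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(str(spr), 8) for _ in range(ns)),
            b"".join(_field("", 32) for _ in range(ns)),
        ]
    )
    # records are channel-blocked: ch0 samples, ch1 samples, ... per record
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig_header + records.tobytes())


def read_edf(path) -> Recording:
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER_BYTES:
        raise ValueError("truncated EDF header")

    def txt(off: int, width: int) -> str:
        return blob[off : off + width].decode("ascii", errors="replace").strip()

    patient = txt(8, 80)
    rec_id = txt(88, 80)
    n_records = int(txt(236, 8))
    record_dur = float(txt(244, 8))
    ns = int(txt(252, 4))

    base = _HEADER_BYTES

    def sig_txt(block: int, width: int, i: int) -> str:
        off = base + block + i * width
        return blob[off : off + width].decode("ascii", errors="replace").strip()

    labels = [sig_txt(0, 16, i) for i in range(ns)]
    units = sig_txt(16 * ns + 80 * ns, 8, 0) or "V"
    pmin = np.array([float(sig_txt(ns * (16 + 80 + 8), 8, i)) for i in range(ns)])
    pmax = np.array([float(sig_txt(ns * (16 + 80 + 8 + 8), 8, i)) for i in range(ns)])
    dmin = np.array([int(sig_txt(ns * (16 + 80 + 8 * 3), 8, i)) for i in range(ns)])
    dmax = np.array([int(sig_txt(ns * (16 + 80 + 8 * 4), 8, i)) for i in range(ns)])
    spr = [int(sig_txt(ns * (16 + 80 + 8 * 4 + 8 + 80), 8, i)) for i in range(ns)]
    if len(set(spr)) != 1:
        raise ValueError("mixed per-channel sampling rates are not supported")
    spr0 = spr[0]
    fs = spr0 / record_dur

    data_off = _HEADER_BYTES * (1 + ns)
    raw = np.frombuffer(blob, dtype="<i2", offset=data_off)
    raw = raw[: n_records * ns * spr0].reshape(n_records, ns, spr0)
    digital = raw.transpose(1, 0, 2).reshape(ns, n_records * spr0).astype(np.float64)
    scale = (pmax - pmin) / (dmax - dmin)
    signals = pmin[:, None] + (digital - dmin[:, None]) * scale[:, None]

    m = re.search(r"n=(\d+)", rec_id)
    if m:
        signals = signals[:, : int(m.group(1))]
    mt = re.search(r"t0=([0-9eE+.\-]+)", rec_id)
    parts = patient.split()
    genotype = parts[1] if len(parts) > 1 and parts[1] in ("control", "mutant") else "unknown"
    return Recording(
        signals=signals,
        fs=fs,
        channel_ids=labels,
        animal_id=parts[0] if parts else "unknown",
        genotype=genotype,
        t0=float(mt.group(1)) if mt else 0.0,
        units=units,
    )
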