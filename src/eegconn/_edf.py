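"""Minimal EDF (European Data Format) writer.

Only the subset of EDF needed to round-trip multichannel numeric data is
implemented: one continuous recording, identical integer sampling rate on
every channel, 1-second data records, 16-bit little-endian samples with a
symmetric physical range per channel.  Reading is delegated to
:func:`mne.io.read_raw_edf`, which handles the full format.
"""

from __future__ import annotations

import datetime
import math

import numpy as np

__all__ = ["write_edf"]


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ASCII chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    channel_labels: list[str],
    fs: float,
    physical_dim: str = "uV",
    patient_id: str = "X",
) -> None:
    """Write ``data`` (n_channels x n_samples, physical units) to *path*.

    ``fs`` must be a positive integer and ``n_samples`` a multiple of ``fs``
    (whole seconds); each data record holds one second of signal.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length does not match data")
    if fs <= 0 or fs != int(fs):
        raise ValueError("EDF writer requires a positive integer sampling rate")
    fs = int(fs)
    if n_samp % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = n_samp // fs

    # Symmetric physical range per channel, rounded up so that every sample
    # is representable; digital range is the full signed 16-bit span.
    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.ceil(np.max(np.abs(data), axis=1)), 1.0)

    start = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field("Startdate 01-JAN-2000", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )
    header += b"".join(_field(lab, 16) for lab in channel_labels)
    header += b"".join(_field("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_field(physical_dim, 8) for _ in range(n_ch))
    header += b"".join(_field(f"{-m:g}", 8) for m in phys_max)
    header += b"".join(_field(f"{m:g}", 8) for m in phys_max)
    header += b"".join(_field(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_field(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_field(str(fs), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    # physical -> digital, clipped to the representable span
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.empty_like(data, dtype=np.int16)
    for c in range(n_ch):
        d = np.rint((data[c] + phys_max[c]) * scale[c] + dig_min)
        digital[c] = np.clip(d, dig_min, dig_max).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.astype("<i2").tobytes())


def quantization_step(physical_max: float) -> float:
    """Physical size of one digital step for the symmetric range used here."""
    return 2.0 * math.ceil(max(physical_max, 1.0)) / 65535.0
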