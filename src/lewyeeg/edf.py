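"""Minimal European Data Format (EDF) I/O.

Writing uses a small self-contained 16-bit EDF encoder (physical units uV,
one-second data records).  Reading delegates to :func:`mne.io.read_raw_edf`,
which also serves as the round-trip oracle for the writer in the test suite.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(path, data_uv: np.ndarray, fs: float, labels, patient_id: str = "X",
              recording_id: str = "lewyeeg") -> None:
    """Write channels x samples data (uV) as a 16-bit EDF file.

    The sampling rate must be an integer (one data record per second).
    Trailing samples that do not fill a whole record are dropped.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    if data_uv.ndim != 2 or data_uv.shape[0] != len(labels):
        raise ValueError("data must be (n_channels, n_samples) matching labels")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = data_uv.shape
    n_rec = n_samp // fs
    if n_rec < 1:
        raise ValueError("need at least one second of data")
    data_uv = data_uv[:, : n_rec * fs]

    # per-channel symmetric physical range with headroom against clipping
    absmax = np.maximum(np.abs(data_uv).max(axis=1), 1e-6)
    phys = np.ceil(absmax * 1.01)
    dig_min, dig_max = -32768, 32767

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("AgAgCl electrode", 80) for _ in labels)
    header += b"".join(_field("uV", 8) for _ in labels)
    header += b"".join(_field(f"{-p:.0f}", 8) for p in phys)
    header += b"".join(_field(f"{p:.0f}", 8) for p in phys)
    header += b"".join(_field(str(dig_min), 8) for _ in labels)
    header += b"".join(_field(str(dig_max), 8) for _ in labels)
    header += b"".join(_field("", 80) for _ in labels)
    header += b"".join(_field(str(fs), 8) for _ in labels)
    header += b"".join(_field("", 32) for _ in labels)

    scale = (dig_max - dig_min) / (2.0 * phys)  # digital units per uV
    digital = np.rint(data_uv * scale[:, None]).clip(dig_min, dig_max).astype("<i2")
    # records: for each second, all samples of ch0, then ch1, ...
    recs = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
    Path(path).write_bytes(header + recs.tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data in uV, sampling rate, channel labels)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
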