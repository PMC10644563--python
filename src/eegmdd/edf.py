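"""Minimal EDF (European Data Format) writer and an MNE-backed reader.

The writer produces plain EDF: a 256-byte fixed header, one 256-byte header
block per signal, and 1-second data records of little-endian 16-bit integers
scaled per channel between the physical extrema. It exists because the
generator must emit cohorts in the field's interchange format; reading goes
through MNE's EDF reader so the files stay interoperable with standard
tooling (a round-trip against MNE is part of the test suite).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import Recording

_DIG_MAX = 32767
_DIG_MIN = -32768


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} ({width} bytes max)")
    return b.ljust(width)


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a Recording (µV) as a 16-bit EDF file with 1-s data records.

    The sampling rate must be a positive integer. A trailing partial second
    is zero-padded into the final record so no samples are lost; readers see
    ``ceil(duration)`` seconds.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.signal.shape
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = rec.signal

    # per-channel symmetric physical range with headroom; >= 1 µV so flat
    # signals do not collapse the scale
    phys_max = np.maximum(np.ceil(np.abs(padded).max(axis=1)) + 1.0, 1.0)
    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    digital = np.clip(
        np.round((padded + phys_max[:, None]) * scale[:, None]) + _DIG_MIN,
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    header = b"".join([
        _field("0", 8),                        # version
        _field(rec.subject_id, 80),            # patient id
        _field("synthetic resting EEG", 80),   # recording id
        _field("01.01.00", 8),                 # start date dd.mm.yy
        _field("00.00.00", 8),                 # start time
        _field(str(256 * (1 + n_ch)), 8),      # header length
        _field("", 44),                        # reserved
        _field(str(n_records), 8),
        _field("1", 8),                        # record duration, s
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(c, 16) for c in rec.channels),
        b"".join(_field("AgAgCl electrode", 80) for _ in rec.channels),
        b"".join(_field("uV", 8) for _ in rec.channels),
        b"".join(_field(f"{-m:g}", 8) for m in phys_max),
        b"".join(_field(f"{m:g}", 8) for m in phys_max),
        b"".join(_field(str(_DIG_MIN), 8) for _ in rec.channels),
        b"".join(_field(str(_DIG_MAX), 8) for _ in rec.channels),
        b"".join(_field("", 80) for _ in rec.channels),
        b"".join(_field(str(fs), 8) for _ in rec.channels),
        b"".join(_field("", 32) for _ in rec.channels),
    ])
    records = digital.reshape(n_ch, n_records, fs)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            fh.write(records[:, r, :].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (µV) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    subject_id = (raw.info["subject_info"] or {}).get("his_id", Path(path).stem)
    return Recording(
        subject_id=subject_id or Path(path).stem,
        channels=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        signal=raw.get_data() * 1e6,  # V -> µV
        reference="Pz",
        history=[f"read_edf({Path(path).name})"],
    )
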