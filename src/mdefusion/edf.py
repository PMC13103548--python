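"""Minimal EDF I/O.

Reading is delegated to :mod:`mne` (robust against the many EDF dialects in
the wild). Writing is a compact EDF implementation sufficient for fixture
recordings: one data record per second, 16-bit samples, physical dimension
microvolts. The written files round-trip through any standards-compliant
reader to within the 16-bit quantization step of the stored physical range.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .montage import canonical_name
from .types import FormatError, ParameterError, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _phys_str(x: float, width: int = 8) -> str:
    """Format a physical bound into EDF's 8-character field without corruption."""
    for fmt in (".6g", ".4g", ".2g", ".1e"):
        s = format(x, fmt)
        if len(s) <= width:
            return s
    return format(x, ".0e")[:width]


def write_edf(rec: Recording, path) -> Path:
    """Write one recording to ``path`` as EDF (16-bit, microvolts).

    The recording duration must be an integer number of seconds and the
    sampling rate an integer (one data record per second).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.signal.shape
    if n_samp % fs != 0:
        raise ParameterError("EDF writer requires an integer number of seconds")
    n_records = n_samp // fs

    sig = np.asarray(rec.signal, dtype=np.float64)
    # symmetric physical range per channel, padded so extremes stay in range;
    # use the value as *written* into the 8-char header field for scaling
    phys_max = np.empty(n_ch)
    for i in range(n_ch):
        hi = max(np.abs(sig[i]).max(), 1e-6) * 1.0000001
        while float(_phys_str(hi, 7)) < np.abs(sig[i]).max():
            hi *= 1.001
        phys_max[i] = float(_phys_str(hi, 7))
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((sig - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field(rec.subject_id, 80),
        _field(f"Startdate 01-JAN-2000 {rec.dataset_tag or 'X'}", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_sig = b"".join([
        b"".join(_field(ch, 16) for ch in rec.channels),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(_phys_str(phys_min[i]), 8) for i in range(n_ch)),
        b"".join(_field(_phys_str(phys_max[i]), 8) for i in range(n_ch)),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])

    with open(path, "wb") as fh:
        fh.write(header + per_sig)
        # records: per record, all samples of signal 0, then signal 1, ...
        rec3 = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(rec3.tobytes())
    return path


def write_sidecar(rec: Recording, edf_path) -> Path:
    """Write the JSON sidecar carrying subject metadata next to an EDF."""
    p = Path(edf_path).with_suffix(".json")
    p.write_text(json.dumps({
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "dataset_tag": rec.dataset_tag,
    }, indent=1))
    return p


def read_edf(path, subject_id: Optional[str] = None, group: Optional[str] = None,
             dataset_tag: str = "") -> Recording:
    """Read an EDF file into a :class:`Recording` (signal in microvolts).

    Channel labels are canonicalized (``EEG T3-REF`` -> ``T7``). Subject
    metadata is taken from a JSON sidecar (same stem, ``.json``) when
    present, unless overridden by the arguments.
    """
    import mne  # deferred: mne import is slow

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - mne raises assorted types
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = [canonical_name(c) for c in raw.ch_names]
    return Recording(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        group=group or meta.get("group", "HC"),
        fs=float(raw.info["sfreq"]),
        channels=channels,
        signal=data,
        dataset_tag=dataset_tag or meta.get("dataset_tag", ""),
    )
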