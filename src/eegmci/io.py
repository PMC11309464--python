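"""Disk formats: EDF recordings and BIDS-style tab-separated event files.

Recordings are written as plain EDF (16-bit, physical units microvolts,
1-second data records).  The writer is a minimal self-contained
implementation of the EDF header and sample packing; reading goes through
MNE's EDF reader, which doubles as an independent round-trip check of the
writer in the test suite.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording

__all__ = ["write_edf", "read_edf", "write_events", "read_events"]


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording to EDF (16-bit, microvolts, 1-s data records).

    The sampling rate must be a positive integer.  The last data record is
    zero-padded when the recording length is not a whole number of seconds.
    """
    fs = int(round(recording.fs))
    if abs(recording.fs - fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF export requires an integer sampling rate")
    data = recording.data
    n_ch, n_samples = data.shape
    n_records = int(np.ceil(n_samples / fs))
    pad = n_records * fs - n_samples
    if pad:
        data = np.concatenate([data, np.zeros((n_ch, pad))], axis=1)
    phys_max = float(np.ceil(max(np.abs(data).max(), 1.0)))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.clip(np.round(data / gain), dig_min, dig_max).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),                       # local patient id
        _field("Startdate X X X X", 80),             # local recording id
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),                              # record duration, s
        _field(str(n_ch), 4),
    ])
    labels = b"".join(_field(ch, 16) for ch in recording.channels)
    transducer = b"".join(_field("", 80) for _ in range(n_ch))
    dim = b"".join(_field("uV", 8) for _ in range(n_ch))
    pmin = b"".join(_field(f"{phys_min:g}", 8) for _ in range(n_ch))
    pmax = b"".join(_field(f"{phys_max:g}", 8) for _ in range(n_ch))
    dmin = b"".join(_field(str(dig_min), 8) for _ in range(n_ch))
    dmax = b"".join(_field(str(dig_max), 8) for _ in range(n_ch))
    prefilter = b"".join(_field("", 80) for _ in range(n_ch))
    spr = b"".join(_field(str(fs), 8) for _ in range(n_ch))
    reserved = b"".join(_field("", 32) for _ in range(n_ch))
    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax
                 + dmin + dmax + prefilter + spr + reserved)
        # records: per record, all samples of signal 1, then signal 2, ...
        records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(records.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6           # volts -> microvolts
    return Recording(data, float(raw.info["sfreq"]),
                     tuple(raw.ch_names))


_EVENT_COLUMNS = ["onset", "duration", "trial_type", "response",
                  "response_time"]


def write_events(events: pd.DataFrame, path: str | Path, fs: float,
                 stimulus_duration_s: float = 0.4) -> None:
    """Write a per-trial event table as a BIDS-style TSV.

    Expects columns ``onset_sample``, ``trial_type``, ``correct`` and
    ``response_time``; onsets are converted to seconds and correctness is
    encoded as a ``correct``/``incorrect`` response column.
    """
    out = pd.DataFrame({
        "onset": events["onset_sample"].to_numpy() / fs,
        "duration": stimulus_duration_s,
        "trial_type": events["trial_type"],
        "response": np.where(events["correct"].fillna(False), "correct",
                             "incorrect"),
        "response_time": events["response_time"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path, fs: float) -> pd.DataFrame:
    """Read a BIDS-style events TSV back into the pipeline's event format."""
    tsv = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(tsv.columns)
    if missing:
        raise ValueError(f"events file lacks columns: {sorted(missing)}")
    return pd.DataFrame({
        "onset_sample": np.round(tsv["onset"].to_numpy() * fs).astype(int),
        "trial_type": tsv["trial_type"],
        "correct": tsv["response"] == "correct",
        "response_time": tsv["response_time"],
    })
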