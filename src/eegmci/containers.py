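"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .montage import CHANNELS_1020


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Unique 10-20 channel labels, one per row of ``data``.
    annotations : list of (onset_sample, kind, payload)
        Free-form event markers attached to the recording.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = CHANNELS_1020
    annotations: list[tuple[int, str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, self.channels,
                         list(self.annotations))


@dataclass
class EpochSet:
    """Stimulus-locked trials.

    ``data`` is (n_trials, n_channels, n_times) in microvolts; ``times`` is
    the shared axis in seconds relative to stimulus onset (default span
    [-0.8, +1.3] s).  ``metadata`` carries one row per trial with at least
    ``trial_type``, ``correct`` and ``response_time`` columns.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channels: tuple[str, ...]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x times)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must equal trial count")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.fs, rtol=1e-6):
            raise ValueError("time axis must be uniform at the sampling rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times, self.fs, self.channels,
                        self.metadata.iloc[mask].reset_index(drop=True))

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Return the sub-epoch covering [tmin, tmax) (half-open, by sample)."""
        keep = (self.times >= tmin - 1e-9) & (self.times < tmax - 1e-9)
        return EpochSet(self.data[:, :, keep], self.times[keep], self.fs,
                        self.channels, self.metadata)
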