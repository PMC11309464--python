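"""Resting-state power spectral density, band aggregation and the
Theta-to-Alpha ratio.

The PSD follows a fixed formula chain: 1-s epochs with 50% overlap, a
Kaiser(beta=6) window, a 256-point FFT giving 1-Hz bins from 1 to 40 Hz,
unscaled ``psd(f) = (1/Fs) * 2|X(f)|^2`` per epoch, linear averaging over
the 3 overlapping epochs centred on each non-overlapping epoch, conversion
to log10, and finally averaging the log values across the session's
non-overlapping epochs (300 of them for a clean 5-minute recording).  The
relative dialect divides each bin by the channel's 1-40 Hz bin sum per
epoch before the smoothing step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import kaiser

from .containers import Recording

__all__ = ["PsdMatrix", "BandDefinition", "BANDS", "compute_psd",
           "band_power", "theta_alpha_ratio"]

FREQ_BINS = np.arange(1, 41)      # Hz, inclusive
PSD_FLOOR = 1e-12                 # pre-log floor for degenerate input


@dataclass(frozen=True)
class BandDefinition:
    """Closed frequency band; edge bins are inclusive on both ends."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi <= 40):
            raise ValueError("band must lie within 1-40 Hz")

    def bins(self) -> np.ndarray:
        """Indices into the 1-40 Hz bin axis covered by this band."""
        return np.where((FREQ_BINS >= self.lo) & (FREQ_BINS <= self.hi))[0]


#: Historical band definitions; note the overlapping printed edges
#: (3 Hz in delta and the theta bands, 13 Hz in the beta bands, 25-30 Hz
#: shared by Beta and Gamma) are preserved as defined.
BANDS: dict[str, BandDefinition] = {b.name: b for b in (
    BandDefinition("delta", 1, 3),
    BandDefinition("slow_theta", 3, 5),
    BandDefinition("theta", 3, 7),
    BandDefinition("slow_alpha", 8, 10),
    BandDefinition("alpha", 8, 13),
    BandDefinition("slow_beta", 13, 20),
    BandDefinition("beta", 13, 30),
    BandDefinition("gamma", 25, 40),
)}


@dataclass
class PsdMatrix:
    """Channels x 40-bin log10 PSD table for one recording session."""

    values: np.ndarray            # (n_channels, 40), log10 units
    dialect: str                  # "absolute" or "relative"
    channels: tuple[str, ...]
    n_epochs_used: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.channels), FREQ_BINS.size):
            raise ValueError("PSD matrix must be channels x 40 bins")
        if self.dialect not in ("absolute", "relative"):
            raise ValueError("dialect must be 'absolute' or 'relative'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PSD values must be finite")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (channel, bin_hz, value) table."""
        rows = [(ch, int(f), self.values[i, j], self.dialect)
                for i, ch in enumerate(self.channels)
                for j, f in enumerate(FREQ_BINS)]
        return pd.DataFrame(rows, columns=["channel", "bin_hz", "value", "dialect"])


def _epoch_psd(recording: Recording, exclusion_intervals) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch unscaled PSD for every 50%-overlap 1-s epoch.

    Returns (psd, valid): psd is (n_epochs, n_channels, 40); valid flags
    epochs that do not intersect an excluded interval.
    """
    fs = recording.fs
    # 1-s epochs; at the native 256 Hz this is the 256-point FFT with exact
    # 1-Hz bins, and the same holds for any integer sampling rate >= 81 Hz
    n_per = int(round(fs))
    if abs(fs - n_per) > 1e-9 or n_per <= 2 * FREQ_BINS[-1]:
        raise ValueError("PSD chain requires an integer sampling rate > 80 Hz")
    hop = n_per // 2
    n_epochs = max((recording.n_samples - n_per) // hop + 1, 0)
    if n_epochs < 3:
        raise ValueError("recording too short for PSD (need >= 3 s)")
    window = kaiser(n_per, 6.0)
    starts = np.arange(n_epochs) * hop
    idx = starts[:, None] + np.arange(n_per)[None, :]
    segments = recording.data[:, idx]                    # (ch, ep, n_per)
    spec = np.fft.rfft(segments * window[None, None, :], axis=2)
    psd = (1.0 / fs) * 2.0 * np.abs(spec[:, :, FREQ_BINS]) ** 2
    psd = np.transpose(psd, (1, 0, 2))                   # (ep, ch, 40)
    valid = np.ones(n_epochs, dtype=bool)
    for lo, hi in exclusion_intervals or []:
        valid &= ~((starts < hi) & (starts + n_per > lo))
    return psd, valid


def compute_psd(recording: Recording, dialect: str = "absolute",
                exclusion_intervals=None) -> PsdMatrix:
    """Session PSD for a cleaned resting recording.

    Epochs intersecting ``exclusion_intervals`` (sample-index pairs from the
    artifact-rejection stage) are skipped: an excluded centre epoch drops
    out of the session average, and an excluded neighbour drops out of that
    centre's 3-epoch smoothing.
    """
    if dialect not in ("absolute", "relative"):
        raise ValueError("dialect must be 'absolute' or 'relative'")
    psd, valid = _epoch_psd(recording, exclusion_intervals)
    n_epochs = psd.shape[0]
    if dialect == "relative":
        total = np.sum(psd, axis=2, keepdims=True)
        psd = psd / np.maximum(total, PSD_FLOOR)
    # non-overlapping epochs sit at even epoch indices (starts 0, 1, 2, ... s)
    centers = np.arange(0, n_epochs, 2)
    logs = []
    for c in centers:
        if not valid[c]:
            continue
        group = [k for k in (c - 1, c, c + 1) if 0 <= k < n_epochs and valid[k]]
        smoothed = np.mean(psd[group], axis=0)
        logs.append(np.log10(np.maximum(smoothed, PSD_FLOOR)))
    if not logs:
        raise ValueError("no usable epochs after exclusion")
    values = np.mean(logs, axis=0)
    return PsdMatrix(values, dialect, recording.channels, n_epochs_used=len(logs))


def band_power(psd: PsdMatrix, bands: list[str] | None = None) -> pd.DataFrame:
    """Mean log PSD over the bins of each band, per channel.

    Returns a channels x bands table (rows indexed by channel label).
    """
    names = list(BANDS) if bands is None else list(bands)
    cols = {}
    for name in names:
        if name not in BANDS:
            raise KeyError(f"unknown band: {name!r}")
        cols[name] = psd.values[:, BANDS[name].bins()].mean(axis=1)
    return pd.DataFrame(cols, index=list(psd.channels))


def theta_alpha_ratio(band_table: pd.DataFrame) -> pd.Series:
    """Per-channel Theta-to-Alpha ratio.

    With band power stored in log10 units this is the difference of mean
    log powers, i.e. the log of the linear power ratio; higher values index
    EEG slowing.
    """
    for required in ("theta", "alpha"):
        if required not in band_table.columns:
            raise KeyError(f"band table lacks {required!r}")
    return (band_table["theta"] - band_table["alpha"]).rename("tar")
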