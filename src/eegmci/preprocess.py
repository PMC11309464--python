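"""EEG preprocessing: filtering, moving-window artifact handling, epoching,
and component-based decontamination.

The artifact stage scans 2-s windows with 50% overlap (1-s hop) and flags a
window/channel when either (i) the channel's power in the window exceeds 8x
the mean power across all channels in that window, or (ii) the amplitude
stays above 400 uV in magnitude for more than half of the window, or the
within-window peak-to-peak range exceeds 500 uV.  Windows with exactly one
flagged channel are repaired by neighbour interpolation; windows with two or
more flagged channels are excluded.  The pipeline order is fixed:
filter -> scan -> repair -> epoch -> decontaminate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import EpochSet, Recording
from .montage import neighbor_matrix

__all__ = [
    "SegmentMask", "PreprocessingReport", "filter_recording", "scan_artifacts",
    "repair_or_reject", "epoch_recording", "decontaminate",
    "heuristic_component_classifier", "EPOCH_WINDOW",
]

EPOCH_WINDOW = (-0.8, 1.3)          # s relative to stimulus onset
POWER_RATIO_LIMIT = 8.0
AMPLITUDE_LIMIT_UV = 400.0
RANGE_LIMIT_UV = 500.0
BRAIN_PROB_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

_BANDPASS = {"resting": (0.3, 49.0), "erp": (0.3, 40.0)}
NOTCH_HZ = 60.0


def filter_recording(recording: Recording, mode: str) -> Recording:
    """Zero-phase band-pass (0.3-49 Hz resting, 0.3-40 Hz ERP) followed by a
    60 Hz notch.

    Realised as a 4th-order Butterworth band-pass and an IIR notch (Q=30),
    both applied forward-backward so component latencies are preserved.
    """
    if mode not in _BANDPASS:
        raise ValueError("mode must be 'resting' or 'erp'")
    lo, hi = _BANDPASS[mode]
    fs = recording.fs
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * int(fs)
    if recording.n_samples <= padlen:
        raise ValueError("recording too short to filter")
    data = signal.sosfiltfilt(sos, recording.data, axis=1, padlen=padlen)
    if NOTCH_HZ < fs / 2:
        b, a = signal.iirnotch(NOTCH_HZ, Q=30.0, fs=fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return Recording(data, fs, recording.channels, list(recording.annotations))


# ---------------------------------------------------------------------------
# artifact detection
# ---------------------------------------------------------------------------


@dataclass
class SegmentMask:
    """Verdict of the moving-window artifact scan.

    ``flags`` is (n_windows, n_channels); ``criteria`` records, per window,
    the criterion string for each flagged channel ("power" and/or
    "amplitude").  ``status`` is filled by :func:`repair_or_reject` with
    one of ``clean``, ``interpolated:<channel>`` or ``excluded``.
    """

    window_starts: np.ndarray           # sample index of each window
    window_length: int
    flags: np.ndarray                   # bool (n_windows, n_channels)
    criteria: list[dict[int, str]]
    status: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.window_starts.size

    def flagged_windows(self) -> np.ndarray:
        return np.where(self.flags.any(axis=1))[0]


def scan_artifacts(recording: Recording) -> SegmentMask:
    """Flag 2-s windows (1-s hop) per channel under the power-ratio and
    amplitude criteria."""
    fs = recording.fs
    win = int(round(2 * fs))
    hop = int(round(fs))
    n = recording.n_samples
    if n < win:
        raise ValueError("recording shorter than one 2-s window")
    starts = np.arange(0, n - win + 1, hop)
    idx = starts[:, None] + np.arange(win)[None, :]
    seg = recording.data[:, idx]                      # (ch, win_idx, win)
    power = np.mean(seg**2, axis=2)                   # (ch, n_win)
    mean_power = np.mean(power, axis=0, keepdims=True)
    crit_power = power > POWER_RATIO_LIMIT * mean_power
    frac_high = np.mean(np.abs(seg) > AMPLITUDE_LIMIT_UV, axis=2)
    ptp = np.ptp(seg, axis=2)
    crit_amp = (frac_high > 0.5) | (ptp > RANGE_LIMIT_UV)
    flags = (crit_power | crit_amp).T                 # (n_win, ch)
    criteria: list[dict[int, str]] = []
    for w in range(starts.size):
        entry: dict[int, str] = {}
        for ch in np.where(flags[w])[0]:
            kinds = []
            if crit_power[ch, w]:
                kinds.append("power")
            if crit_amp[ch, w]:
                kinds.append("amplitude")
            entry[int(ch)] = "+".join(kinds)
        criteria.append(entry)
    return SegmentMask(starts, win, flags, criteria)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def repair_or_reject(recording: Recording, mask: SegmentMask,
                     ) -> tuple[Recording, list[tuple[int, int]]]:
    """Interpolate single-channel artifacts; exclude multi-channel windows.

    A window with exactly one flagged channel has that channel's samples
    replaced by the average of its unflagged scalp neighbours (all unflagged
    channels when no neighbour qualifies).  Windows with two or more flagged
    channels — including all-channel windows — are collected into merged
    ``exclusion_intervals`` of (start, stop) sample pairs.  Samples outside
    flagged windows are never altered.
    """
    if mask.flags.shape[1] != recording.n_channels:
        raise ValueError("mask does not match recording channel count")
    rec = recording.copy()
    try:
        adjacency = neighbor_matrix(recording.channels)
    except KeyError:          # non-10-20 labels: average all clean channels
        adjacency = None
    exclusions: list[tuple[int, int]] = []
    status = []
    n_flagged = mask.flags.sum(axis=1)
    for w, start in enumerate(mask.window_starts):
        seg = slice(int(start), int(start) + mask.window_length)
        if n_flagged[w] == 0:
            status.append("clean")
        elif n_flagged[w] == 1:
            ch = int(np.where(mask.flags[w])[0][0])
            donors = np.where(~mask.flags[w])[0]
            if adjacency is not None:
                neigh = [d for d in donors if adjacency[ch, d]]
                donors = np.array(neigh) if neigh else donors
            rec.data[ch, seg] = recording.data[donors, seg].mean(axis=0)
            status.append(f"interpolated:{recording.channels[ch]}")
        else:
            exclusions.append((int(start), int(start) + mask.window_length))
            status.append("excluded")
    mask.status = status
    return rec, _merge_intervals(exclusions)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def epoch_recording(recording: Recording, events: pd.DataFrame,
                    window: tuple[float, float] = EPOCH_WINDOW,
                    exclusion_intervals: list[tuple[int, int]] | None = None,
                    ) -> EpochSet:
    """Cut one epoch per event, dropping epochs that underrun/overrun the
    recording or intersect an excluded interval.

    ``events`` must provide ``onset_sample`` plus any metadata columns
    (``trial_type``, ``correct``, ``response_time`` are carried through).
    Raises if no epoch survives.
    """
    fs = recording.fs
    n_pre = int(round(-window[0] * fs))
    n_post = int(round(window[1] * fs))
    times = np.arange(-n_pre, n_post) / fs
    keep_rows, slabs = [], []
    for row in events.itertuples(index=True):
        onset = int(row.onset_sample)
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > recording.n_samples:
            continue
        if any(lo < e_hi and hi > e_lo
               for e_lo, e_hi in (exclusion_intervals or [])):
            continue
        keep_rows.append(row.Index)
        slabs.append(recording.data[:, lo:hi])
    if not slabs:
        raise ValueError("no epochs survived epoching")
    meta = events.loc[keep_rows].reset_index(drop=True)
    return EpochSet(np.stack(slabs), times, fs, recording.channels, meta)


# ---------------------------------------------------------------------------
# ICA decontamination
# ---------------------------------------------------------------------------


class ComponentClassifier(Protocol):
    """Maps ICA components to brain probabilities in [0, 1]."""

    def __call__(self, sources: np.ndarray, mixing: np.ndarray,
                 fs: float) -> np.ndarray: ...


def heuristic_component_classifier(sources: np.ndarray, mixing: np.ndarray,
                                   fs: float) -> np.ndarray:
    """Default stand-in classifier scoring components by artifact signatures.

    Components with heavy-tailed amplitude (spikes), dominant low-frequency
    power (drifts/movement) or loading concentrated on one channel (channel
    artifacts) receive low brain pseudo-probability.  This is a transparent
    heuristic, applied through the same <10% rejection rule as any injected
    classifier.
    """
    n_comp = sources.shape[0]
    probs = np.empty(n_comp)
    freqs = np.fft.rfftfreq(sources.shape[1], 1.0 / fs)
    spec = np.abs(np.fft.rfft(sources, axis=1)) ** 2
    low = spec[:, freqs < 2.0].sum(axis=1) / np.maximum(spec.sum(axis=1), 1e-30)
    kurt = kurtosis(sources, axis=1, fisher=True)
    load = np.abs(mixing) / np.maximum(
        np.sum(np.abs(mixing), axis=0, keepdims=True), 1e-30)
    concentration = load.max(axis=0)
    for i in range(n_comp):
        score = 1.0
        score *= 1.0 / (1.0 + np.exp((kurt[i] - 15.0) / 5.0))      # spikiness
        score *= 1.0 / (1.0 + np.exp((low[i] - 0.85) / 0.05))      # drift
        score *= 1.0 / (1.0 + np.exp((concentration[i] - 0.75) / 0.08))
        probs[i] = score
    return probs


def decontaminate(data: np.ndarray | EpochSet,
                  component_classifier: ComponentClassifier | None = None,
                  fs: float = 256.0, seed: int = 0,
                  ) -> tuple[np.ndarray | EpochSet, dict]:
    """ICA decontamination: unmix at full rank, drop components whose brain
    probability falls below 10%, and re-mix.

    Accepts continuous data (channels x samples) or an :class:`EpochSet`
    (epochs are concatenated along time for fitting and re-split after
    cleaning).  Returns the cleaned data and an info dict with the number of
    rejected components and a ``converged`` flag; if the decomposition does
    not converge the input is returned unchanged with the flag cleared.
    """
    if component_classifier is None:
        component_classifier = heuristic_component_classifier
    if isinstance(data, EpochSet):
        epochs = data
        n_trials, n_ch, n_t = epochs.data.shape
        flat = np.transpose(epochs.data, (1, 0, 2)).reshape(n_ch, n_trials * n_t)
        cleaned, info = decontaminate(flat, component_classifier, epochs.fs, seed)
        out = np.transpose(cleaned.reshape(n_ch, n_trials, n_t), (1, 0, 2))
        return EpochSet(out, epochs.times, epochs.fs, epochs.channels,
                        epochs.metadata.copy()), info
    x = np.asarray(data, dtype=float)
    n_ch = x.shape[0]
    mean = x.mean(axis=1, keepdims=True)
    ica = FastICA(n_components=n_ch, whiten="unit-variance",
                  random_state=seed, max_iter=500, tol=1e-4)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform((x - mean).T).T   # (n_comp, n_samples)
        except ConvergenceWarning:
            return x.copy(), {"converged": False, "n_rejected": 0,
                              "brain_probs": None}
    probs = np.asarray(component_classifier(sources, ica.mixing_, fs), dtype=float)
    keep = probs >= BRAIN_PROB_THRESHOLD
    cleaned = ica.mixing_ @ (sources * keep[:, None]) + mean
    info = {"converged": converged, "n_rejected": int(np.sum(~keep)),
            "brain_probs": probs}
    return cleaned, info


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


@dataclass
class PreprocessingReport:
    """Data-quality metrics mirroring a session's preprocessing outcome."""

    percent_usable: float
    n_windows: int
    n_windows_power: int
    n_windows_amplitude: int
    n_interpolated: int
    n_excluded: int
    n_components_rejected: int = 0

    @classmethod
    def from_mask(cls, mask: SegmentMask, n_samples: int,
                  exclusion_intervals: list[tuple[int, int]],
                  n_components_rejected: int = 0) -> "PreprocessingReport":
        excluded = sum(hi - lo for lo, hi in exclusion_intervals)
        power = sum("power" in c for crit in mask.criteria for c in crit.values())
        amp = sum("amplitude" in c for crit in mask.criteria for c in crit.values())
        interp = sum(s.startswith("interpolated") for s in mask.status)
        return cls(
            percent_usable=100.0 * (1.0 - excluded / n_samples),
            n_windows=mask.n_windows,
            n_windows_power=power,
            n_windows_amplitude=amp,
            n_interpolated=interp,
            n_excluded=sum(s == "excluded" for s in mask.status),
            n_components_rejected=n_components_rejected,
        )

    def to_dict(self) -> dict:
        return self.__dict__.copy()
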