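"""ERP measurement: baseline correction, trial rejection, averaging with the
minimum-trial rule, classical component measures, grand averages, and
behavioural summaries.

Trials are baseline-corrected against the 100 ms before stimulus onset,
rejected when any channel exceeds 100 uV within [-50, +700] ms or when the
response was incorrect/missing, and averaged per stimulus type; averages
built from fewer than 9 surviving trials are excluded.  Classical component
measures (mean amplitude, peak amplitude, peak latency) are taken per
channel inside fixed analysis windows centred on the known components:
P1 [80, 200] ms for the attention task's early peak, P200 [130, 280] ms for
the recognition task's, and LPP [400, 800] ms for the late positive
potential in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "ErpAverage", "ComponentMeasure", "BehavioralSummary", "TooFewTrialsError",
    "COMPONENT_WINDOWS", "baseline_correct", "reject_trials", "average_erp",
    "measure_component", "grand_average", "behavioral_summary",
]

BASELINE_WINDOW = (-0.1, 0.0)       # s, mean removed per trial/channel
REJECT_WINDOW = (-0.05, 0.7)        # s, amplitude screen
REJECT_LIMIT_UV = 100.0
MIN_TRIALS = 9

#: Default analysis windows (s); configurable at call sites.
COMPONENT_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (0.08, 0.20),
    "P200": (0.13, 0.28),
    "LPP": (0.40, 0.80),
}


class TooFewTrialsError(ValueError):
    """Raised when fewer than the minimum trial count survives averaging."""


@dataclass
class ErpAverage:
    """Per-subject average ERP for one stimulus type."""

    waveform: np.ndarray            # (n_channels, n_times), uV
    times: np.ndarray
    channels: tuple[str, ...]
    n_trials_averaged: int
    stimulus_type: str
    subject: str = ""
    visit: int = 0

    def channel(self, label: str) -> np.ndarray:
        return self.waveform[self.channels.index(label)]


@dataclass
class ComponentMeasure:
    """Classical per-channel measures inside one analysis window."""

    component: str
    window: tuple[float, float]
    mean_amplitude: np.ndarray      # per channel, uV
    peak_amplitude: np.ndarray
    peak_latency: np.ndarray        # s
    channels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": list(self.channels),
            "component": self.component,
            "mean_amplitude": self.mean_amplitude,
            "peak_amplitude": self.peak_amplitude,
            "peak_latency": self.peak_latency,
        })

    def at(self, label: str) -> dict[str, float]:
        i = self.channels.index(label)
        return {"mean_amplitude": float(self.mean_amplitude[i]),
                "peak_amplitude": float(self.peak_amplitude[i]),
                "peak_latency": float(self.peak_latency[i])}


@dataclass
class BehavioralSummary:
    """Task-level response summary: accuracy in %, mean RT over correct trials."""

    task: str
    accuracy_pct: float
    mean_rt_s: float                # nan when no correct trial exists
    n_trials: int


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial/channel's mean over [-100, 0) ms. Idempotent."""
    lo, hi = BASELINE_WINDOW
    sel = (epochs.times >= lo - 1e-9) & (epochs.times < hi - 1e-9)
    if not sel.any() or epochs.times[0] > lo + 1e-9:
        raise ValueError("epoch window does not cover the baseline interval")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.times, epochs.fs,
                    epochs.channels, epochs.metadata.copy())


def reject_trials(epochs: EpochSet) -> EpochSet:
    """Drop over-amplitude (>100 uV within [-50, 700] ms on any channel) and
    incorrect/unanswered trials.  The two criteria are independent, so their
    application order does not matter."""
    lo, hi = REJECT_WINDOW
    sel = (epochs.times >= lo - 1e-9) & (epochs.times <= hi + 1e-9)
    peak = np.abs(epochs.data[:, :, sel]).max(axis=(1, 2))
    amp_ok = peak <= REJECT_LIMIT_UV
    correct = (epochs.metadata["correct"].astype("boolean")
               .fillna(False).to_numpy(dtype=bool))
    return epochs.select(amp_ok & correct)


def average_erp(epochs: EpochSet, stimulus_type: str, subject: str = "",
                visit: int = 0) -> ErpAverage:
    """Pointwise mean over surviving trials of one stimulus type.

    Raises :class:`TooFewTrialsError` when fewer than 9 trials remain, so a
    thin acquisition is excluded loudly rather than averaged silently.
    """
    mask = (epochs.metadata["trial_type"] == stimulus_type).to_numpy()
    n = int(mask.sum())
    if n < MIN_TRIALS:
        raise TooFewTrialsError(
            f"{n} trials of type {stimulus_type!r} < minimum {MIN_TRIALS}")
    wave = epochs.data[mask].mean(axis=0)
    return ErpAverage(wave, epochs.times, epochs.channels, n, stimulus_type,
                      subject, visit)


def measure_component(erp: ErpAverage, component: str,
                      windows: dict[str, tuple[float, float]] | None = None,
                      ) -> ComponentMeasure:
    """Mean amplitude, peak amplitude and peak latency inside the component's
    analysis window, per channel.  Latency ties take the earliest maximum."""
    windows = COMPONENT_WINDOWS if windows is None else windows
    if component not in windows:
        raise KeyError(f"unknown component {component!r}")
    lo, hi = windows[component]
    sel = np.where((erp.times >= lo - 1e-9) & (erp.times <= hi + 1e-9))[0]
    if sel.size == 0 or lo < erp.times[0] - 1e-9 or hi > erp.times[-1] + 1e-9:
        raise ValueError("analysis window outside the epoch span")
    seg = erp.waveform[:, sel]
    peak_idx = np.argmax(seg, axis=1)           # argmax returns first maximum
    return ComponentMeasure(
        component=component, window=(lo, hi),
        mean_amplitude=seg.mean(axis=1),
        peak_amplitude=seg[np.arange(seg.shape[0]), peak_idx],
        peak_latency=erp.times[sel][peak_idx],
        channels=erp.channels,
    )


def grand_average(erps: list[ErpAverage]) -> ErpAverage:
    """Unweighted mean across subjects (each subject counts once, regardless
    of how many trials entered their average)."""
    if not erps:
        raise ValueError("no ERP averages to combine")
    first = erps[0]
    for e in erps[1:]:
        if e.waveform.shape != first.waveform.shape or \
                not np.allclose(e.times, first.times):
            raise ValueError("ERP averages have mismatching axes")
    wave = np.mean([e.waveform for e in erps], axis=0)
    return ErpAverage(wave, first.times, first.channels,
                      n_trials_averaged=len(erps),
                      stimulus_type=first.stimulus_type, subject="grand")


def behavioral_summary(events: pd.DataFrame, task: str) -> BehavioralSummary:
    """Accuracy (% correct of all scoreable trials; non-responses count as
    incorrect) and mean reaction time over correct trials only."""
    if len(events) == 0:
        raise ValueError("no scoreable trials")
    correct = (events["correct"].astype("boolean")
               .fillna(False).to_numpy(dtype=bool))
    accuracy = 100.0 * correct.mean()
    rts = events.loc[correct, "response_time"]
    mean_rt = float(rts.mean()) if len(rts) else float("nan")
    return BehavioralSummary(task, float(accuracy), mean_rt, len(events))
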