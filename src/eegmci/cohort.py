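"""Synthetic two-visit HC/MCI EEG cohorts.

Generates everything the downstream analysis consumes without any external
data: eyes-closed resting EEG with group band-power shifts (Theta 3-7 Hz
elevated, slow-Beta 13-20 Hz suppressed in MCI), ERP sessions for the
3-choice vigilance task (3CVT) and the standard image recognition task (SIR)
with a delayed early component and a reduced late positive potential (LPP),
behavioural responses (slower RT, lower accuracy in MCI), a 1-year follow-up
visit with configurable test-retest consistency, and injectable artifacts
with ground-truth masks.

Model
-----
Background EEG is random-phase spectral synthesis of a 1/f^chi power spectrum
(chi ~ 1) plus a Gaussian alpha peak (~10 Hz) weighted occipitally.  Group
and subject band effects act multiplicatively on the power spectrum inside
the Theta and slow-Beta bands, so a configured shift of ``g`` standardised
units on band log-power is realised exactly (the measured band log power is
the model value plus a small estimation error).  ERP trials superpose a
Gaussian early peak (fronto-central) and a raised-cosine LPP plateau
(centro-parietal) on band-limited noise.

Repeatability is carried by latent subject traits shared across visits:
every subject-level quantity is ``sqrt(icc) * z_subject + sqrt(1-icc) *
z_visit`` in standardised units, so the configured ``test_retest_icc`` is
the model test-retest correlation of each trait.  MCI severity (the trait
scaling all group effects) is drawn once per subject, N(1, 0.3^2), and is
identical at both visits.

Three fidelities are exposed, all driven by the same parametric model:

- :func:`simulate_resting` / :func:`simulate_erp_session` -- full-waveform
  recordings (the reference path, exportable to EDF);
- :func:`sample_resting_psd_grids` -- per-subject channel x frequency
  log-PSD grids drawn directly from the spectral model, for replicated
  statistical calibration studies;
- :func:`simulate_erp_epochs` -- stimulus-locked trials without the
  continuous carrier recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.signal.windows import kaiser

from .containers import EpochSet, Recording
from .montage import CHANNELS_1020, topography

__all__ = [
    "CohortConfig", "Subject", "TaskDesign", "ArtifactSpec",
    "ArtifactEvent", "ArtifactGroundTruth",
    "make_cohort", "make_3cvt_design", "make_sir_design",
    "simulate_resting", "simulate_erp_session", "simulate_erp_epochs",
    "simulate_behavior", "sample_resting_psd_grids", "expected_log10_psd",
    "inject_artifacts",
]

# ---------------------------------------------------------------------------
# configuration and cohort containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Group effects are expressed the way the corresponding biomarkers are
    reported: band-power and LPP shifts in Hedges-g units, the early-peak
    delay in milliseconds, reaction time in milliseconds and accuracy in
    percentage points (negative = worse in MCI).  Defaults are the reported
    MCI-vs-HC group differences this generator emulates.
    """

    n_hc: int = 20
    n_mci: int = 20
    n_channels: int = 20
    fs: float = 256.0
    # group effects (MCI relative to HC), scaled per subject by severity
    theta_shift: float = 0.45          # g units, Theta 3-7 Hz log power up
    beta_shift: float = -0.66          # g units, slow-Beta 13-20 Hz down
    early_latency_shift_ms: float = 15.0
    lpp_amplitude_shift: float = -0.7  # g units on LPP amplitude
    rt_shift_ms: tuple[tuple[str, float], ...] = (("3cvt", 55.0), ("sir", 117.0))
    accuracy_shift: tuple[tuple[str, float], ...] = (("3cvt", -5.0), ("sir", -7.0))
    test_retest_icc: float = 0.85
    seed: int = 0
    # structural (between-subject / noise) scales
    resting_duration: float = 300.0    # s
    band_log_sd: float = 0.15          # between-subject SD of band log10 power
    channel_log_jitter: float = 0.03   # per-channel band-gain jitter (log10)
    background_sigma: float = 20.0     # resting broadband RMS, uV
    alpha_amplitude: float = 12.0      # occipital alpha RMS at peak channel, uV
    one_over_f_exponent: float = 1.0
    erp_noise_sigma: float = 12.0      # single-trial background RMS, uV
    early_amp: float = 6.0             # uV at topography centre
    lpp_amp: float = 5.0
    lpp_gain_sd: float = 0.5           # between-subject LPP gain SD
    latency_jitter_sd_ms: float = 20.0
    rt_subject_sd: tuple[tuple[str, float], ...] = (("3cvt", 0.045), ("sir", 0.10))
    acc_subject_sd: float = 4.0        # percentage points
    severity_mean: float = 1.0
    severity_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_mci < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0.0 <= self.test_retest_icc <= 1.0:
            raise ValueError("test_retest_icc must lie in [0, 1]")

    def rt_shift(self, task: str) -> float:
        return dict(self.rt_shift_ms)[task]

    def acc_shift(self, task: str) -> float:
        return dict(self.accuracy_shift)[task]

    def rt_sd(self, task: str) -> float:
        return dict(self.rt_subject_sd)[task]

    @property
    def channels(self) -> tuple[str, ...]:
        return CHANNELS_1020[: self.n_channels]


@dataclass(frozen=True)
class Subject:
    """One cohort member; the severity trait is shared across visits."""

    id: str
    index: int
    group: str                  # "HC" or "MCI"
    latent_severity: float
    mmse_change: float          # 1-year MMSE change (outcome model)


# stream ids for per-subject random substreams
_TRAITS = {
    "theta": 0, "beta": 1, "alpha": 2, "lpp": 3, "latency": 4, "erp_amp": 5,
    "rt_3cvt": 6, "rt_sir": 7, "acc_3cvt": 8, "acc_sir": 9,
}
_STREAM_CH_JITTER = 20
_STREAM_RESTING = 50
_STREAM_ERP = {"3cvt": 60, "sir": 61}
_STREAM_BEHAV = {"3cvt": 70, "sir": 71}
_STREAM_TRIAL = {"3cvt": 80, "sir": 81}


def _rng(config: CohortConfig, subject: Subject, visit: int, stream: int):
    """Deterministic generator for (cohort seed, subject, visit, stream)."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, subject.index, visit, stream]))


def _trait(config: CohortConfig, subject: Subject, visit: int, name: str,
           size: int | None = None) -> np.ndarray | float:
    """Standard-normal subject trait with test-retest correlation ``icc``.

    Visit 0 denotes the cross-visit (stable) component; callers pass the
    actual visit (1 or 2) and get sqrt(icc)*stable + sqrt(1-icc)*visit_noise.
    """
    stream = _TRAITS[name]
    icc = config.test_retest_icc
    z_base = _rng(config, subject, 0, stream).standard_normal(size)
    z_vis = _rng(config, subject, visit, stream).standard_normal(size)
    return np.sqrt(icc) * z_base + np.sqrt(1.0 - icc) * z_vis


def make_cohort(config: CohortConfig) -> list[Subject]:
    """Draw the cohort roster: ids, groups, severities, 1-year outcomes.

    The MMSE-like outcome declines with latent severity plus idiosyncratic
    noise, so baseline disease severity is prognostic of decline.
    """
    subjects = []
    for i in range(config.n_hc + config.n_mci):
        group = "HC" if i < config.n_hc else "MCI"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i, 0, 99]))
        if group == "MCI":
            severity = config.severity_mean + config.severity_sd * rng.standard_normal()
        else:
            severity = 0.0
        mmse_change = -1.2 * severity + 1.2 * rng.standard_normal()
        subjects.append(Subject(
            id=f"{'hc' if group == 'HC' else 'mci'}{i:03d}", index=i,
            group=group, latent_severity=severity, mmse_change=mmse_change))
    return subjects


# ---------------------------------------------------------------------------
# task designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskDesign:
    """Ordered trial list with onsets, stimulus timing and block structure."""

    name: str
    trials: pd.DataFrame      # trial_type, block, onset_s, soa_s
    stimulus_duration_s: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[str, int]:
        return self.trials["trial_type"].value_counts().to_dict()

    def truncate(self, n_trials: int) -> "TaskDesign":
        """First ``n_trials`` trials (scaled sessions for simulation studies)."""
        return TaskDesign(self.name, self.trials.iloc[:n_trials].reset_index(drop=True),
                          self.stimulus_duration_s)


_3CVT_SOA_RANGES = ((1.5, 3.0), (3.0, 6.0), (6.0, 10.0), (6.0, 10.0))


def _order_without_runs(types: list[str], rng, max_run: int = 8) -> list[str]:
    """Shuffle until no run of identical types exceeds ``max_run``."""
    types = list(types)
    for _ in range(2000):
        rng.shuffle(types)
        run, longest, prev = 0, 0, None
        for t in types:
            run = run + 1 if t == prev else 1
            prev = t
            longest = max(longest, run)
        if longest <= max_run:
            return types
    raise RuntimeError("could not satisfy maximum-run constraint")


def make_3cvt_design(seed: int = 0) -> TaskDesign:
    """3-choice vigilance task: 376 trials, 264 targets / 55 nontargets /
    57 distractors, 400 ms stimuli, SOA increasing across 4 quartiles.

    The SOA is drawn uniformly per quartile from (1.5-3, 3-6, 6-10, 6-10) s;
    the trial order is pseudorandom with no run of more than 8 identical
    stimulus types.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    types = ["target"] * 264 + ["nontarget"] * 55 + ["distractor"] * 57
    types = _order_without_runs(types, rng)
    n = len(types)
    quartile = np.minimum(np.arange(n) // (n // 4), 3)
    lo = np.array([_3CVT_SOA_RANGES[q][0] for q in quartile])
    hi = np.array([_3CVT_SOA_RANGES[q][1] for q in quartile])
    soa = rng.uniform(lo, hi)
    onsets = 2.0 + np.concatenate([[0.0], np.cumsum(soa[:-1])])
    trials = pd.DataFrame({
        "trial_type": types,
        "block": [f"quartile{q + 1}" for q in quartile],
        "onset_s": onsets,
        "soa_s": soa,
    })
    return TaskDesign("3cvt", trials, stimulus_duration_s=0.4)


def make_sir_design(seed: int = 0) -> TaskDesign:
    """Standard image recognition task.

    Encoding phase: two identical blocks of the 20 target images, fixed 3-s
    onset-to-onset interval, 1.5 s on screen.  Testing block: 100 trials (the
    20 targets interspersed with 80 novel images, shuffled), 3-s interval,
    400 ms on screen.  Only the testing block carries the 400-ms stimulus
    duration; encoding rows record their own timing in the trial table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    rows = []
    onset = 2.0
    for block in ("encoding1", "encoding2"):
        for _ in range(20):
            rows.append(("target_encoding", block, onset, 3.0))
            onset += 3.0
    onset += 5.0  # pause before the testing block
    test_types = ["target"] * 20 + ["novel"] * 80
    rng.shuffle(test_types)
    for t in test_types:
        rows.append((t, "testing", onset, 3.0))
        onset += 3.0
    trials = pd.DataFrame(rows, columns=["trial_type", "block", "onset_s", "soa_s"])
    return TaskDesign("sir", trials, stimulus_duration_s=0.4)


# ---------------------------------------------------------------------------
# resting-state model and synthesis
# ---------------------------------------------------------------------------

_BAND_BOXES = {"theta": (3.0, 7.0), "beta": (13.0, 20.0)}
# Session-mean log10 PSD estimation error: SD^2 ~ _MEAS_FLOOR^2 + _MEAS_C1^2/K
# (K non-overlapping 1-s epochs; the floor is window spectral leakage) plus a
# negative chi-square (Jensen) bias.  Constants measured once against the
# waveform path (see docs/methods.md).
_MEAS_C1 = 0.35
_MEAS_FLOOR = 0.026
_MEAS_BIAS = -0.079


def _band_shift_log10(config: CohortConfig, subject: Subject, visit: int,
                      band: str) -> float:
    """Subject/visit band gain in log10-power units, including group effect."""
    es = {"theta": config.theta_shift, "beta": config.beta_shift}[band]
    trait = _trait(config, subject, visit, band)
    shift = config.band_log_sd * trait
    if subject.group == "MCI":
        shift += es * config.band_log_sd * subject.latent_severity
    return float(shift)


def _one_sided_psd(config: CohortConfig, subject: Subject, visit: int,
                   freqs: np.ndarray) -> np.ndarray:
    """Model one-sided PSD, (n_channels, n_freqs), uV^2/Hz."""
    chans = config.channels
    n_ch = len(chans)
    f = np.maximum(freqs, 1.0)
    # broadband 1/f floor scaled to the configured RMS over 0.3-49 Hz
    chi = config.one_over_f_exponent
    base = 1.0 / f ** chi
    band_lo, band_hi = 0.3, 49.0
    norm = np.log(band_hi / band_lo) if abs(chi - 1.0) < 1e-9 else (
        (band_hi ** (1 - chi) - band_lo ** (1 - chi)) / (1 - chi))
    p0 = config.background_sigma ** 2 / norm
    gain = np.zeros((n_ch, freqs.size))
    jit_base = _rng(config, subject, 0, _STREAM_CH_JITTER).standard_normal((n_ch, 2))
    jit_vis = _rng(config, subject, visit, _STREAM_CH_JITTER).standard_normal((n_ch, 2))
    icc = config.test_retest_icc
    jitter = np.sqrt(icc) * jit_base + np.sqrt(1 - icc) * jit_vis
    for k, band in enumerate(("theta", "beta")):
        lo, hi = _BAND_BOXES[band]
        inband = (freqs >= lo - 0.5) & (freqs < hi + 0.5)
        shift = _band_shift_log10(config, subject, visit, band)
        gain[:, inband] += shift + config.channel_log_jitter * jitter[:, [k]]
    psd = p0 * base[None, :] * 10.0 ** gain
    # occipitally weighted alpha peak
    alpha_gain = 10.0 ** (0.5 * config.band_log_sd
                          * _trait(config, subject, visit, "alpha"))
    amp = config.alpha_amplitude * topography((0.0, -0.85), 0.55, chans) * alpha_gain
    bump = np.exp(-((freqs - 10.0) ** 2) / (2 * 1.5 ** 2))
    bump /= max(np.trapezoid(bump, freqs), 1e-12)
    psd = psd + amp[:, None] ** 2 * bump[None, :]
    psd[:, (freqs < band_lo) | (freqs > band_hi)] = 0.0
    return psd


def _synthesize(psd_one_sided: np.ndarray, freqs: np.ndarray, n: int,
                fs: float, rng) -> np.ndarray:
    """Random-phase time series with the given one-sided PSD (rows=channels)."""
    nz = np.where(psd_one_sided.any(axis=0))[0]     # band-limited spectra
    amp = np.sqrt(psd_one_sided[:, nz] * fs * n / 2.0)
    z = rng.standard_normal((psd_one_sided.shape[0], nz.size, 2))
    spec = np.zeros((psd_one_sided.shape[0], freqs.size), dtype=complex)
    spec[:, nz] = amp * (z[..., 0] + 1j * z[..., 1]) / np.sqrt(2.0)
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real
    return sp_fft.irfft(spec, n=n, axis=1)


def _synthesize_segment(psd_fn, n: int, n_rows_shape, fs: float, rng
                        ) -> np.ndarray:
    """Synthesize at the next FFT-friendly length and crop to ``n`` samples.

    ``psd_fn`` maps a frequency grid to the (rows, n_freqs) one-sided PSD;
    cropping a stationary series leaves its spectrum unchanged.
    """
    nfast = sp_fft.next_fast_len(n, real=True)
    freqs = np.fft.rfftfreq(nfast, 1.0 / fs)
    return _synthesize(psd_fn(freqs), freqs, nfast, fs, rng)[:, :n]


def simulate_resting(subject: Subject, visit: int, config: CohortConfig,
                     duration: float | None = None) -> Recording:
    """Eyes-closed resting EEG for one subject/visit.

    Five minutes by default; ``duration`` overrides for scaled studies.
    Identical (config, subject, visit) inputs reproduce the recording
    bit-exactly.
    """
    duration = config.resting_duration if duration is None else duration
    n = int(round(duration * config.fs))
    rng = _rng(config, subject, visit, _STREAM_RESTING)
    data = _synthesize_segment(
        lambda f: _one_sided_psd(config, subject, visit, f), n,
        config.n_channels, config.fs, rng)
    return Recording(data, config.fs, config.channels,
                     annotations=[(0, "task", "resting_ec")])


def expected_log10_psd(subject: Subject, visit: int,
                       config: CohortConfig) -> np.ndarray:
    """Model-expected log10 unscaled PSD on the 1-40 Hz analysis bins.

    Matches the spectral pipeline's scale: ``E[psd(f)] = S1(f) * sum(w^2)``
    for a Kaiser(beta=6) window of 256 samples.
    """
    bins = np.arange(1.0, 41.0)
    psd = _one_sided_psd(config, subject, visit, bins)
    w2 = float(np.sum(kaiser(256, 6.0) ** 2))
    return np.log10(np.maximum(psd * w2, 1e-300))


def sample_resting_psd_grids(subjects: list[Subject], visit: int,
                             config: CohortConfig, duration: float | None = None,
                             ) -> np.ndarray:
    """Draw per-subject channel x frequency log10-PSD grids (absolute dialect)
    directly from the spectral model.

    Equivalent in distribution (to first and second moments) to running
    :func:`simulate_resting` through the spectral pipeline, with the
    session-mean estimation error applied analytically; used for replicated
    calibration studies where waveform synthesis would dominate the run time.
    """
    duration = config.resting_duration if duration is None else duration
    n_epochs = max(int(duration) - 1, 1)
    sd = np.hypot(_MEAS_FLOOR, _MEAS_C1 / np.sqrt(n_epochs))
    grids = np.empty((len(subjects), config.n_channels, 40))
    for i, s in enumerate(subjects):
        rng = _rng(config, s, visit, _STREAM_RESTING + 1)
        grids[i] = (expected_log10_psd(s, visit, config) + _MEAS_BIAS
                    + sd * rng.standard_normal((config.n_channels, 40)))
    return grids


# ---------------------------------------------------------------------------
# ERP model and synthesis
# ---------------------------------------------------------------------------

_EARLY_LATENCY = {"3cvt": 0.15, "sir": 0.20}
_EARLY_WIDTH = 0.025          # s, Gaussian SD of the early peak
_LPP_SPAN = (0.40, 0.80)      # s
_LPP_EDGE = 0.10              # raised-cosine edge of the plateau
_RT_BASE = {"3cvt": 0.55, "sir": 0.85}
_ACC_BASE = {"3cvt": 95.0, "sir": 85.0}
_ANALYZED_TYPE = {"3cvt": "target", "sir": "novel"}


def _erp_subject_params(config: CohortConfig, subject: Subject, visit: int,
                        task: str) -> dict[str, float]:
    sev = subject.latent_severity
    latency = _EARLY_LATENCY[task] + (config.latency_jitter_sd_ms / 1000.0
                                      * _trait(config, subject, visit, "latency"))
    if subject.group == "MCI":
        latency += config.early_latency_shift_ms / 1000.0 * sev
    amp_gain = max(1.0 + 0.2 * _trait(config, subject, visit, "erp_amp"), 0.1)
    lpp_gain = 1.0 + config.lpp_gain_sd * _trait(config, subject, visit, "lpp")
    if subject.group == "MCI":
        lpp_gain += config.lpp_amplitude_shift * config.lpp_gain_sd * sev
    lpp_gain = max(lpp_gain, 0.05)
    rt_mean = _RT_BASE[task] + config.rt_sd(task) * _trait(
        config, subject, visit, f"rt_{task}")
    if subject.group == "MCI":
        rt_mean += config.rt_shift(task) / 1000.0 * sev
    rt_mean = max(rt_mean, 0.25)
    acc = _ACC_BASE[task] + config.acc_subject_sd * _trait(
        config, subject, visit, f"acc_{task}")
    if subject.group == "MCI":
        acc += config.acc_shift(task) * sev
    acc = float(np.clip(acc, 5.0, 99.9))
    return {"latency": latency, "amp_gain": amp_gain, "lpp_gain": lpp_gain,
            "rt_mean": rt_mean, "p_correct": acc / 100.0}


def _erp_template(config: CohortConfig, times: np.ndarray, latency: float,
                  amp_gain: float, lpp_gain: float) -> np.ndarray:
    """(n_channels, n_times) stimulus-locked template in uV."""
    chans = config.channels
    early_topo = topography((0.0, 0.30), 0.65, chans)       # fronto-central
    lpp_topo = topography((0.0, -0.30), 0.65, chans)        # centro-parietal
    early = (config.early_amp * amp_gain
             * np.exp(-((times - latency) ** 2) / (2 * _EARLY_WIDTH ** 2)))
    lo, hi = _LPP_SPAN
    lpp_shape = np.zeros_like(times)
    rise = (times >= lo) & (times < lo + _LPP_EDGE)
    flat = (times >= lo + _LPP_EDGE) & (times <= hi - _LPP_EDGE)
    fall = (times > hi - _LPP_EDGE) & (times <= hi)
    lpp_shape[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - lo) / _LPP_EDGE))
    lpp_shape[flat] = 1.0
    lpp_shape[fall] = 0.5 * (1 - np.cos(np.pi * (hi - times[fall]) / _LPP_EDGE))
    lpp = config.lpp_amp * lpp_gain * lpp_shape
    return early_topo[:, None] * early[None, :] + lpp_topo[:, None] * lpp[None, :]


def _erp_noise_psd(config: CohortConfig, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD of the ERP background (0.3-40 Hz, 1/f), per channel."""
    f = np.maximum(freqs, 1.0)
    base = 1.0 / f
    lo, hi = 0.3, 40.0
    p0 = config.erp_noise_sigma ** 2 / np.log(hi / lo)
    psd = np.tile(p0 * base, (config.n_channels, 1))
    psd[:, (freqs < lo) | (freqs > hi)] = 0.0
    return psd


def _draw_behavior(rng, params: dict[str, float], n_trials: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(correct, rt) for n trials; RT is a shifted log-normal with the
    subject's mean; incorrect trials keep an RT (a response was given)."""
    correct = rng.random(n_trials) < params["p_correct"]
    t0, sigma_ln = 0.15, 0.35
    mean_excess = max(params["rt_mean"] - t0, 0.05)
    mu = np.log(mean_excess) - sigma_ln ** 2 / 2.0
    rt = t0 + np.exp(mu + sigma_ln * rng.standard_normal(n_trials))
    return correct, rt


def simulate_behavior(subject: Subject, visit: int, task: str,
                      config: CohortConfig, n_trials: int | None = None
                      ) -> pd.DataFrame:
    """Per-trial correctness and reaction time for a full task run
    (376 scoreable trials for 3CVT, the 100-trial testing block for SIR)."""
    if n_trials is None:
        n_trials = 376 if task == "3cvt" else 100
    params = _erp_subject_params(config, subject, visit, task)
    rng = _rng(config, subject, visit, _STREAM_BEHAV[task])
    correct, rt = _draw_behavior(rng, params, n_trials)
    return pd.DataFrame({"correct": correct, "response_time": rt})


def simulate_erp_epochs(subject: Subject, visit: int, task: str,
                        config: CohortConfig, n_trials: int = 64) -> EpochSet:
    """Stimulus-locked trials of the analysed stimulus class, directly in
    epoch form (time axis [-0.8, +1.3) s), bypassing the continuous carrier.

    This is the scaled fidelity used by replicated calibration studies; the
    trial templates, behavioural draws and subject parameters are identical
    to :func:`simulate_erp_session`.
    """
    fs = config.fs
    n_pre, n_post = int(round(0.8 * fs)), int(round(1.3 * fs))
    times = np.arange(-n_pre, n_post) / fs
    params = _erp_subject_params(config, subject, visit, task)
    rng = _rng(config, subject, visit, _STREAM_ERP[task])
    trial_rng = _rng(config, subject, visit, _STREAM_TRIAL[task])
    lat_jit = 0.005 * trial_rng.standard_normal(n_trials)
    amp_jit = 1.0 + 0.1 * trial_rng.standard_normal(n_trials)

    def flat_psd(freqs):
        # batch the noise synthesis over trials x channels
        one = _erp_noise_psd(config, freqs)
        return np.broadcast_to(one[None, :, :], (n_trials, *one.shape)
                               ).reshape(n_trials * config.n_channels, -1)

    noise = _synthesize_segment(flat_psd, times.size,
                                n_trials * config.n_channels, fs, rng)
    data = noise.reshape(n_trials, config.n_channels, times.size)
    for t in range(n_trials):
        data[t] += _erp_template(
            config, times, params["latency"] + lat_jit[t],
            params["amp_gain"] * amp_jit[t], params["lpp_gain"] * amp_jit[t])
    correct, rt = _draw_behavior(trial_rng, params, n_trials)
    meta = pd.DataFrame({
        "trial_type": _ANALYZED_TYPE[task],
        "correct": correct,
        "response_time": rt,
    })
    return EpochSet(data, times, fs, config.channels, meta)


def simulate_erp_session(subject: Subject, visit: int, design: TaskDesign,
                         config: CohortConfig) -> tuple[Recording, pd.DataFrame]:
    """Continuous EEG for one task session plus the per-trial event table.

    Every trial adds the stimulus-locked template (early peak + LPP) to an
    ongoing 1/f background; events carry onset, stimulus type, response
    correctness and reaction time.
    """
    fs = config.fs
    task = design.name
    onsets = design.trials["onset_s"].to_numpy()
    dur = float(onsets[-1]) + 3.0
    n = int(round(dur * fs))
    rng = _rng(config, subject, visit, _STREAM_ERP[task])
    data = _synthesize_segment(lambda f: _erp_noise_psd(config, f), n,
                               config.n_channels, fs, rng)
    params = _erp_subject_params(config, subject, visit, task)
    trial_rng = _rng(config, subject, visit, _STREAM_TRIAL[task])
    n_trials = design.n_trials
    lat_jit = 0.005 * trial_rng.standard_normal(n_trials)
    amp_jit = 1.0 + 0.1 * trial_rng.standard_normal(n_trials)
    tmpl_times = np.arange(0, int(round(1.0 * fs))) / fs
    onset_samples = np.round(onsets * fs).astype(int)
    for t, start in enumerate(onset_samples):
        tmpl = _erp_template(config, tmpl_times, params["latency"] + lat_jit[t],
                             params["amp_gain"] * amp_jit[t],
                             params["lpp_gain"] * amp_jit[t])
        stop = min(start + tmpl.shape[1], n)
        data[:, start:stop] += tmpl[:, : stop - start]
    correct, rt = _draw_behavior(trial_rng, params, n_trials)
    events = design.trials.copy()
    events["onset_sample"] = onset_samples
    events["correct"] = correct
    events["response_time"] = rt
    rec = Recording(data, fs, config.channels,
                    annotations=[(0, "task", task)])
    return rec, events


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactSpec:
    """Counts of artifacts to inject per kind."""

    n_spike: int = 0
    n_flat_high: int = 0
    n_drift: int = 0
    n_broadband: int = 0

    def __post_init__(self) -> None:
        if min(self.n_spike, self.n_flat_high, self.n_drift, self.n_broadband) < 0:
            raise ValueError("artifact counts must be non-negative")


@dataclass(frozen=True)
class ArtifactEvent:
    start_sample: int
    end_sample: int
    channels: tuple[int, ...]
    kind: str


@dataclass
class ArtifactGroundTruth:
    events: list[ArtifactEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


_ARTIFACT_LEN_S = {"spike": 0.08, "flat_high": 1.5, "drift": 5.0,
                   "broadband_power": 2.5}


def inject_artifacts(recording: Recording, spec: ArtifactSpec, seed: int = 0
                     ) -> tuple[Recording, ArtifactGroundTruth]:
    """Insert artifacts at random positions; return the corrupted copy and
    the ground-truth event list.

    ``flat_high`` holds +450 uV for 1.5 s; ``broadband_power`` scales a
    2.5-s segment so its power exceeds 12x the channel-average power (above
    the 8x detection criterion); ``spike`` is a brief 600-uV triangular
    deflection; ``drift`` is a slow +-300 uV ramp.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    rec = recording.copy()
    truth = ArtifactGroundTruth()
    fs, n = recording.fs, recording.n_samples
    kinds = (["spike"] * spec.n_spike + ["flat_high"] * spec.n_flat_high
             + ["drift"] * spec.n_drift + ["broadband_power"] * spec.n_broadband)
    for kind in kinds:
        length = int(round(_ARTIFACT_LEN_S[kind] * fs))
        if length >= n:
            raise ValueError("recording too short for the requested artifact")
        start = int(rng.integers(0, n - length))
        ch = int(rng.integers(0, recording.n_channels))
        seg = slice(start, start + length)
        if kind == "spike":
            shape = 1.0 - np.abs(np.linspace(-1, 1, length))
            rec.data[ch, seg] += 600.0 * shape
        elif kind == "flat_high":
            rec.data[ch, seg] = 450.0
        elif kind == "drift":
            rec.data[ch, seg] += np.linspace(0.0, 300.0, length)
        else:  # broadband_power
            seg_power = float(np.mean(rec.data[ch, seg] ** 2))
            ref_power = float(np.mean(rec.data**2))
            gain = np.sqrt(12.0 * ref_power / max(seg_power, 1e-12))
            rec.data[ch, seg] *= max(gain, 1.0)
        truth.events.append(ArtifactEvent(start, start + length, (ch,), kind))
    return rec, truth


def null_config(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with every group effect set to zero."""
    return replace(config, theta_shift=0.0, beta_shift=0.0,
                   early_latency_shift_ms=0.0, lpp_amplitude_shift=0.0,
                   rt_shift_ms=(("3cvt", 0.0), ("sir", 0.0)),
                   accuracy_shift=(("3cvt", 0.0), ("sir", 0.0)))
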