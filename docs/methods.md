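# Methods

`eegmci` implements a complete EEG/ERP biomarker analysis chain for mild
cognitive impairment (MCI) and a synthetic cohort generator that emulates
the group effects the chain is designed to detect.  This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Analysis chain

### Preprocessing (`eegmci.preprocess`)

Filtering is a zero-phase (forward-backward) 4th-order Butterworth
band-pass — 0.3–49 Hz for resting data, 0.3–40 Hz for ERP data — followed
by a 60 Hz IIR notch (Q = 30).  Zero-phase application preserves component
latencies, which later become predictors; the filter realization itself is
a free implementation choice and is documented here because latency
measures depend on it.

Artifact handling scans 2-s windows with 50% overlap (1-s hop).  A window
is flagged on a channel when (i) the channel's power in that window exceeds
8× the mean power across all channels *in the same window*, or (ii) the
magnitude stays above 400 µV for more than half the window, or the
within-window peak-to-peak range exceeds 500 µV.  Interpretations fixed
here: the 8× reference is window-local; "changing more than 500 µV" is read
as peak-to-peak range.  Windows with exactly one flagged channel are
repaired by averaging the channel's unflagged scalp neighbours (distance
threshold on standard 10–20 positions; all clean channels if no neighbour
qualifies); windows with two or more flagged channels are excluded, and a
sample is excluded if any covering window is excluded.  Samples outside
flagged windows are never modified.

ERP data are epoched at [-0.8, +1.3] s around stimulus onset; epochs that
cross an excluded interval or the recording edge are dropped.

Component-based decontamination unmixes the data at full rank
(components = W·data, no dimension reduction; scikit-learn FastICA with a
fixed seed), asks an injectable classifier for a per-component brain
probability, removes components below 10%, and re-mixes.  A pretrained
component classifier is deliberately out of scope: the default classifier
is a transparent heuristic scoring kurtosis (spikes), low-frequency power
fraction (drift) and single-channel loading concentration (channel
artifacts).  Any classifier honouring the interface can be injected and
the 10% rule applies unchanged.  Non-convergence falls back to identity
with a cleared `converged` flag.  For epoched data the decomposition is
fit on the concatenated epochs.

### Spectral analysis (`eegmci.spectral`)

Per channel: 1-s epochs with 50% overlap; Kaiser(β = 6) window; 256-point
FFT at 256 Hz giving 1-Hz bins 1–40 Hz; unscaled per-epoch PSD
`psd(f) = (1/Fs)·2|X(f)|²`; linear averaging over the three overlapping
epochs centred on each non-overlapping epoch (edge epochs average what
exists); log10; then the mean of the log values over the session's
non-overlapping epochs (300 for a clean 5-minute recording).  Epochs
touching excluded intervals drop out of both the session average and the
smoothing of their neighbours.  The relative dialect normalises each
epoch's bins by the channel's 1–40 Hz bin sum *before* smoothing; the
normalisation range is an assumption recorded here.  Pre-log values are
floored at 1e-12 so degenerate (all-zero) input stays finite.

Bands: delta 1–3, slow-theta 3–5, theta 3–7, slow-alpha 8–10, alpha 8–13,
slow-beta 13–20, beta 13–30, gamma 25–40 Hz; band edges are inclusive and
the printed overlaps (3 Hz, 13 Hz, 25–30 Hz) are preserved deliberately.
Band power is the arithmetic mean of log-PSD over the band's bins.  The
theta-to-alpha ratio is the difference of mean log powers, i.e. the log of
the linear power ratio — the natural form when PSD is stored in log units.

### ERP analysis (`eegmci.erp`)

Baseline: subtract the mean over the 100 ms before onset, per
trial/channel.  Trial rejection: drop trials exceeding 100 µV in magnitude
on any channel within [-50, +700] ms, and incorrect or unanswered trials.
Averages with fewer than 9 surviving trials raise an explicit exclusion
error rather than returning a thin average.  Component measures (mean
amplitude, peak amplitude, peak latency; earliest maximum on ties) use
fixed analysis windows — P1 [80, 200] ms, P200 [130, 280] ms, LPP
[400, 800] ms — chosen inside the loosely described component ranges and
exposed as configuration, because they are analysis parameters that must be
reproducible.  Grand averages weight subjects equally regardless of trial
counts.  Behavioural accuracy counts non-responses as incorrect; mean RT
uses correct trials only.  The analysed stimulus classes are the frequent
targets in the attention task (3CVT) and the novel images in the
recognition task (SIR).

### Cluster statistics (`eegmci.cluster`)

Grids are channels × 40 frequency bins (800 cells) for resting PSD and
channels × 256 time points over [-0.2, +0.8) s for ERPs (5120 cells at
256 Hz).  First level: two-sided pooled-variance two-sample t per cell
(paired t on within-subject differences in the longitudinal design);
zero-variance cells get t = 0, p = 1 with a warning.  Cells with p < 0.01
and matching t sign are grouped under edge connectivity — neighbours share
one dimension and are adjacent in the other.  Channel adjacency defaults to
consecutive rows of the fixed montage ordering (anterior→posterior,
left→right); because scalp sites have no canonical linear order, an
explicit channel-neighbour matrix may be supplied, and a distance-based
10–20 matrix ships with the package.  This is the central interpretive
decision of the module.  Clusters smaller than 2 cells (channel-frequency)
or 20 cells (channel-time) are discarded; each cluster records its size and
tsize (sum of member t values).  The null distribution re-runs the
identical procedure under 1000 label shuffles (or random pair sign-flips),
keeping the largest |tsize| per iteration, 0 when none forms; with 10 or
fewer subjects the full assignment set is enumerated instead.  A cluster's
percentile is the fraction of null values ≤ its |tsize| (ties count as
below); significance is percentile ≥ 95.  The subject-level summary (CBA)
is the unweighted mean of the subject's grid over the cluster cells.
Sign handling — same-sign clusters, max |tsize| null — gives standard
two-sided max-statistic control.

### Composite score (`eegmci.model`)

Twelve predictors: one CBA each from relative and absolute resting PSD, two
CBAs plus an early-peak latency per ERP task (latency channel Cz for 3CVT
and Fz for SIR by default, with Pz available — the source material is
internally inconsistent on this point and the choice is configuration), and
RT + accuracy per task.  Per modality the significant cluster(s) define the
CBA; when none reaches the 95th percentile the highest-percentile cluster
is used; a modality with no clusters at all is a hard error naming the
modality, since the feature cannot be defined.  Rows are complete-case.

The classifier standardises each predictor by training mean/SD and fits a
soft-margin linear SVM (C = 1, the toolbox default the analysis emulates);
scores are signed decision values, score > 0 ⇒ MCI.  Evaluation: midrank
AUC, accuracy and balanced accuracy at the fixed score-0 operating point,
and Hedges g of the score separation.  Cross-validation is stratified
5-fold with standardisation and fitting strictly inside training folds;
out-of-fold scores are pooled and evaluated once.  Split validation
requires disjoint train/test subjects and evaluates each visit with its own
labels; paired test-visit scores feed the reliability metrics.  In split
mode feature selection (cluster definitions) uses training-visit-1 data
only at the point where the pipeline defines clusters from baseline.
Predictor importance is reported both as relative |weight| percentages and
as permutation feature importance (column shuffles, no refit, 100 repeats).

### Reliability (`eegmci.reliability`)

Hedges g with the small-sample correction J = 1 − 3/(4n − 9).  Test-retest
consistency is Cronbach's alpha for two measurements,
α = 2·(1 − (s₁² + s₂²)/s²_sum) — the consistency-type ICC(3,k); the
absolute-agreement variants are deliberately not implemented.  Pearson r
uses the t-based two-sided p.  The prognostic quadrant summary
cross-tabulates baseline classification (score > 0) against subsequent
decline (outcome change below a configurable threshold, default 0) and
reports quadrant fractions and the score-outcome correlation.

## Synthetic cohort generator (`eegmci.cohort`)

The generator defines the study conditions.  Background EEG is random-phase
spectral synthesis of a 1/f^χ spectrum (χ = 1, band-limited 0.3–49 Hz,
broadband RMS 20 µV) plus a Gaussian 10 Hz alpha peak weighted occipitally
(12 µV RMS at the peak channel) — equivalent to a randomly amplitude-
modulated oscillator.  Group and subject band effects multiply the power
spectrum inside theta (3–7 Hz) and slow-beta (13–20 Hz), so a configured
effect of g standardised units on band log-power is realised exactly up to
estimation error.  Between-subject band spread is 0.15 log10 units — a
realistic ~1.4× inter-individual power range.

ERP trials superpose a Gaussian early peak (σ = 25 ms; 150 ms base latency
for 3CVT, 200 ms for SIR; fronto-central topography; 6 µV) and a
raised-cosine LPP plateau (400–800 ms, centro-parietal, 5 µV) on 1/f noise
(12 µV RMS single-trial, 0.3–40 Hz).  MCI shifts: early latency delayed by
`early_latency_shift_ms`·severity; LPP gain reduced by
`lpp_amplitude_shift` (g units against the 0.5 between-subject gain SD);
RT increased (shifted log-normal, subject-mean SD 45 ms for 3CVT and
100 ms for SIR); accuracy reduced in percentage points.  Severity ~
N(1, 0.3²) in MCI, 0 in HC, fixed per subject across visits.  All
subject-level quantities combine a stable trait and visit noise as
√ICC·z_subject + √(1−ICC)·z_visit, so `test_retest_icc` is the model
test-retest correlation.  A simple outcome model ties a 1-year MMSE-like
change to severity (slope −1.2 points per severity unit, noise SD 1.2), so
baseline severity is prognostic of decline.

Defaults are the emulated group differences: theta +0.45 g, slow-beta
−0.66 g, early delay 15 ms, LPP −0.7 g, RT +55/+117 ms (3CVT/SIR),
accuracy −5/−7 points, ICC 0.85.

Task designs: 3CVT — 376 trials (264 targets, 55 nontargets, 57
distractors), 400-ms stimuli, pseudorandom order with no run of more than
8 identical types (standing in for a "pre-defined sequence with no obvious
pattern"), SOA drawn uniformly per quartile from 1.5–3, 3–6, 6–10, 6–10 s
(the simplest draw rule consistent with the stated ranges; only ranges, not
a distribution, are specified).  SIR — two 20-target encoding blocks (3-s
onsets, 1.5 s on screen) and a shuffled 100-trial testing block (20 targets
+ 80 novel, 3-s onsets, 400 ms on screen).

Artifact injection inserts spikes (600 µV, 80 ms), flat-high segments
(450 µV, 1.5 s — exceeding the 400 µV/half-window criterion by
construction), slow drifts (±300 µV, 5 s) and broadband power segments
(scaled to 12× the mean power, above the 8× criterion), with ground-truth
intervals for recall measurement.

### Fidelities and their consistency

Three generator fidelities share one parametric model:

1. **Waveform** (`simulate_resting`, `simulate_erp_session`): continuous
   recordings, exportable to EDF; the reference path.
2. **Grid** (`sample_resting_psd_grids`): per-subject channel × frequency
   log-PSD grids drawn from the model expectation plus the session-mean
   estimation error.  The error model — SD² = 0.026² + 0.35²/K for K
   non-overlapping epochs, with a −0.079 log10 chi-square (Jensen) bias —
   was measured once against the waveform path and frozen; a test holds
   the two fidelities together.
3. **Epoch** (`simulate_erp_epochs`): stimulus-locked trials without the
   carrier recording.

The scaled fidelities exist so that replicated operating-characteristic
studies run on a single CPU; they are first-class, tested code.

## Validation studies and problem sizes

`eegmci.studies` (driven by both the test suite and
`scripts/acceptance.py`) measures:

- **Type-I error**: 500 null cohorts, n = 20/20, 30-s waveform resting
  records, 200-iteration nulls; the fraction of datasets with any
  significant cluster should sit near 5%.
- **Detection and recovery**: 100 cohorts at n = 40/40 with all effects at
  0.9 standardised units (latency delay 20 ms against 20 ms jitter).  The
  0.9 magnitude sits at the upper end of the emulated effect range and was
  fixed a priori by a power calculation: at n = 40/40 the per-cell t
  noncentrality is ≈ 4, comfortably above the first-level threshold
  (t ≈ 2.64), whereas effects near 0.5 have ~50% per-cell power by
  construction and cannot support a high detection requirement.  Resting
  grids use the grid fidelity; ERP grids are built from 64 retained trials
  per subject via the epoch fidelity.
- **Behavioural recovery**: group RT/accuracy differences at n = 40/40,
  averaged over three cohort draws to average out subject sampling error.
- **Generator calibration**: 200 cohort draws comparing configured vs
  recovered Hedges g for theta and slow-beta band power, plus the
  across-visit consistency of theta power measured on healthy controls
  (n = 48; a mixed cohort would inflate the estimate through the stable
  group separation).  Note that Cronbach's alpha for two visits is the
  stepped-up reliability 2r/(1+r) of their average, so a configured trait
  correlation of 0.85 appears as α ≈ 0.90 — the same relation the alpha-vs-r
  pairs of real test-retest reports follow.
- **Classifier**: the full pipeline at n = 60/60, effects 0.9, 60-s resting
  records, 64 ERP trials, 200-iteration nulls; cross-validated AUC, a
  50-shuffle label-permutation null, split validation at both visits, the
  score test-retest ICC and the prognostic quadrant correlation.  The
  cohort size is chosen so every modality forms clusters with overwhelming
  probability (feature assembly is a hard error when one cannot).

These sizes are the package's chosen study conditions; the full-length
defaults (5-minute resting, complete task designs, 1000 permutations)
remain the pipeline defaults.

## What passing tests do and do not show

The generator produces stationary Gaussian band-limited backgrounds with
spatially independent noise (only band gains and ERP topographies are
spatially structured), template-identical ERP waveforms within subject, and
artifact shapes matched to the detection criteria.  Real EEG has
non-stationary rhythms, correlated scalp noise, eye/muscle/cardiac sources
with characteristic topographies, latency variability within trials, and
artifacts that do not respect the thresholds.  Passing the synthetic suites
therefore demonstrates that the statistics are calibrated (type-I error),
that the chain recovers known effects at the configured sizes, and that
no information leaks across training boundaries — not that the reported
clinical effect sizes or AUCs would be reproduced on real cohorts.

## Known limitations

- The component classifier is a heuristic; with it, decontamination is a
  conservative spike/drift/channel-artifact remover, not a validated
  physiological source classifier.
- Channel adjacency in cluster formation defaults to a linear montage
  chain; the scalp-distance matrix is provided but not the default, to
  keep the default grid exactly 4-connected.
- The relative-PSD normalisation range (1–40 Hz) and the consistency-form
  ICC are assumptions, recorded above.
- EDF export uses one global 16-bit physical range per file (quantisation
  ≈ range/65535), and events live in a separate tab-separated file.
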