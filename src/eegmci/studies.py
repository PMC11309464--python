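"""Replicated calibration studies of the full analysis chain.

Each study regenerates synthetic cohorts from scratch and runs the package's
own statistics, measuring operating characteristics: the type-I error of the
cluster-permutation procedure under a null cohort, detection rates and
effect-size recovery under calibrated group effects, behavioural-shift
recovery, generator calibration (configured vs recovered Hedges g and
test-retest ICC), and classifier performance with reliability propagation.

Problem sizes are scaled for single-CPU replication (short resting records,
64 retained ERP trials, 200-iteration permutation nulls); the full-length
defaults remain available through :mod:`eegmci.pipeline`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import cohort as syn
from .cluster import Cluster, cluster_analysis
from .model import cross_validate
from .pipeline import RunConfig, run_baseline, run_longitudinal
from .reliability import PairedMeasurements, hedges_g, icc_alpha
from .spectral import BANDS, compute_psd

_SEED_MOD = 2**31 - 1


def _derive_seed(base: int, stride: int, r: int) -> int:
    return (base * stride + r) % _SEED_MOD

__all__ = [
    "design_counts", "null_calibration", "effect_recovery",
    "behavioral_recovery", "generator_calibration", "classifier_study",
    "study_config",
]

#: Group effects for the detection/recovery study: magnitudes at the upper
#: end of the emulated range, fixed a priori by a power calculation (the
#: per-cell t noncentrality at n=40/40 must clear the p<0.01 first-level
#: threshold with margin for reliable cluster detection).
STUDY_EFFECT = 0.9
STUDY_LATENCY_SHIFT_MS = 20.0

THETA_BINS = (3, 7)          # Hz, injected resting increase
BETA_BINS = (13, 20)         # Hz, injected resting decrease
EARLY_WINDOW = (0.06, 0.30)  # s, window containing the early-peak effect
LPP_WINDOW = (0.40, 0.80)    # s


def study_config(n_per_group: int = 40, seed: int = 0,
                 effects: bool = True) -> syn.CohortConfig:
    """Cohort conditions for the detection/recovery studies."""
    cfg = syn.CohortConfig(
        n_hc=n_per_group, n_mci=n_per_group, seed=seed,
        theta_shift=STUDY_EFFECT, beta_shift=-STUDY_EFFECT,
        early_latency_shift_ms=STUDY_LATENCY_SHIFT_MS,
        lpp_amplitude_shift=-STUDY_EFFECT)
    return cfg if effects else syn.null_config(cfg)


def design_counts() -> dict[str, int]:
    """Trial-count fidelity of the generated task designs."""
    cvt = syn.make_3cvt_design()
    sir = syn.make_sir_design()
    cvt_counts = cvt.counts()
    testing = sir.trials[sir.trials["block"] == "testing"]
    encoding = sir.trials[sir.trials["block"].str.startswith("encoding")]
    return {
        "cvt_n_trials": cvt.n_trials,
        "cvt_n_targets": cvt_counts.get("target", 0),
        "cvt_n_nontargets": cvt_counts.get("nontarget", 0),
        "cvt_n_distractors": cvt_counts.get("distractor", 0),
        "sir_testing_trials": len(testing),
        "sir_testing_targets": int((testing["trial_type"] == "target").sum()),
        "sir_testing_novel": int((testing["trial_type"] == "novel").sum()),
        "sir_encoding_presentations": len(encoding),
    }


def _resting_grids(subjects: list[syn.Subject], visit: int,
                   cfg: syn.CohortConfig, duration: float,
                   dialect: str = "absolute") -> np.ndarray:
    """Waveform-path PSD grids for every subject."""
    return np.array([
        compute_psd(syn.simulate_resting(s, visit, cfg, duration=duration),
                    dialect).values
        for s in subjects])


def null_calibration(n_replicates: int = 500, n_per_group: int = 20,
                     n_perm: int = 200, duration: float = 30.0,
                     seed: int = 0) -> dict:
    """Type-I error of the full cluster procedure under the null.

    Each replicate draws a fresh no-effect cohort, simulates resting EEG,
    computes absolute PSD grids and runs first level -> clusters ->
    permutation null -> 95th-percentile assessment; the false-positive rate
    is the fraction of replicates yielding any significant cluster.
    """
    hits = 0
    for r in range(n_replicates):
        cfg = study_config(n_per_group, seed=_derive_seed(seed, 100003, r),
                           effects=False)
        subjects = syn.make_cohort(cfg)
        grids = _resting_grids(subjects, 1, cfg, duration)
        labels = np.array([s.group for s in subjects])
        res = cluster_analysis(grids, labels, "independent",
                               "channel_frequency", n_perm=n_perm,
                               seed=cfg.seed + 7)
        hits += any(c.significant for c in res.clusters)
    return {"replicates": n_replicates,
            "significant_cluster_rate": hits / n_replicates}


def _overlaps(cluster: Cluster, bin_lo: int, bin_hi: int) -> bool:
    lo, hi = cluster.bin_window
    return hi >= bin_lo and lo <= bin_hi


def effect_recovery(n_replicates: int = 100, n_per_group: int = 40,
                    n_perm: int = 200, duration: float = 60.0,
                    n_trials: int = 64, seed: int = 0) -> dict:
    """Detection and effect-size recovery under calibrated group effects.

    Resting replicates: absolute-PSD cluster analysis must find a
    significant positive cluster overlapping Theta (3-7 Hz) and a negative
    one overlapping slow-Beta (13-20 Hz); the CBA Hedges g of the
    theta-overlapping cluster is recovered and compared to the configured
    effect.  ERP replicates (3CVT epochs): significant clusters overlapping
    the early-peak window and a negative cluster in the LPP window.
    """
    theta_hits = beta_hits = rest_hits = 0
    early_hits = lpp_hits = erp_hits = 0
    theta_gs, lpp_gs = [], []
    t_grid = None
    for r in range(n_replicates):
        cfg = study_config(n_per_group, seed=_derive_seed(seed, 90001, r))
        subjects = syn.make_cohort(cfg)
        labels = np.array([s.group for s in subjects])
        # resting-state channel x frequency analysis (grid fidelity)
        grids = syn.sample_resting_psd_grids(subjects, 1, cfg,
                                             duration=duration)
        res = cluster_analysis(grids, labels, "independent",
                               "channel_frequency", n_perm=n_perm,
                               seed=cfg.seed + 7)
        sig = [c for c in res.clusters if c.significant]
        theta = [c for c in sig if c.sign > 0
                 and _overlaps(c, THETA_BINS[0] - 1, THETA_BINS[1] - 1)]
        beta = [c for c in sig if c.sign < 0
                and _overlaps(c, BETA_BINS[0] - 1, BETA_BINS[1] - 1)]
        theta_hits += bool(theta)
        beta_hits += bool(beta)
        rest_hits += bool(theta) or bool(beta)
        if theta:
            cba = res.cba(theta[0])
            theta_gs.append(hedges_g(cba[labels == "MCI"],
                                     cba[labels == "HC"]))
        # ERP channel x time analysis (epoch path, 3CVT)
        erp_grids = np.array([
            _subject_erp_grid(s, cfg, "3cvt", n_trials)
            for s in subjects])
        if t_grid is None:
            from .pipeline import modality_grid_time_axis
            t_grid = modality_grid_time_axis(cfg.fs)
        eres = cluster_analysis(erp_grids, labels, "independent",
                                "channel_time", n_perm=n_perm,
                                seed=cfg.seed + 13)
        esig = [c for c in eres.clusters if c.significant]
        eb = [np.searchsorted(t_grid, w) for w in (EARLY_WINDOW, LPP_WINDOW)]
        early = [c for c in esig if _overlaps(c, eb[0][0], eb[0][1] - 1)]
        lpp = [c for c in esig if c.sign < 0
               and _overlaps(c, eb[1][0], eb[1][1] - 1)]
        early_hits += bool(early)
        lpp_hits += bool(lpp)
        erp_hits += bool(early) or bool(lpp)
        if lpp:
            cba = eres.cba(lpp[0])
            lpp_gs.append(hedges_g(cba[labels == "MCI"],
                                   cba[labels == "HC"]))
    n = n_replicates
    return {
        "replicates": n,
        "configured_effect_size": STUDY_EFFECT,
        "resting_detection_rate": rest_hits / n,
        "theta_detection_rate": theta_hits / n,
        "beta_detection_rate": beta_hits / n,
        "erp_detection_rate": erp_hits / n,
        "early_detection_rate": early_hits / n,
        "lpp_detection_rate": lpp_hits / n,
        "theta_cba_hedges_g": float(np.mean(theta_gs)) if theta_gs else float("nan"),
        "lpp_cba_hedges_g": float(np.mean(lpp_gs)) if lpp_gs else float("nan"),
    }


def _subject_erp_grid(subject: syn.Subject, cfg: syn.CohortConfig, task: str,
                      n_trials: int) -> np.ndarray:
    """Average-ERP channel x time grid for one subject (epoch fidelity)."""
    from . import erp as erpmod
    from .pipeline import _crop_to_grid

    epochs = syn.simulate_erp_epochs(subject, 1, task, cfg, n_trials=n_trials)
    epochs = erpmod.baseline_correct(epochs)
    epochs = erpmod.reject_trials(epochs)
    avg = erpmod.average_erp(epochs, syn._ANALYZED_TYPE[task],
                             subject=subject.id)
    return _crop_to_grid(avg)


def behavioral_recovery(n_per_group: int = 40, seed: int = 0) -> dict:
    """Recovered group reaction-time and accuracy differences under the
    default (emulated) behavioural effects."""
    cfg = syn.CohortConfig(n_hc=n_per_group, n_mci=n_per_group, seed=seed)
    subjects = syn.make_cohort(cfg)
    out = {}
    for task in ("3cvt", "sir"):
        rt = {"HC": [], "MCI": []}
        acc = {"HC": [], "MCI": []}
        for s in subjects:
            b = syn.simulate_behavior(s, 1, task, cfg)
            rt[s.group].append(b.loc[b["correct"], "response_time"].mean())
            acc[s.group].append(100.0 * b["correct"].mean())
        out[f"rt_shift_ms_{task}"] = 1000.0 * (np.mean(rt["MCI"])
                                               - np.mean(rt["HC"]))
        out[f"accuracy_shift_pct_{task}"] = (np.mean(acc["MCI"])
                                             - np.mean(acc["HC"]))
        out[f"rt_hedges_g_{task}"] = hedges_g(np.array(rt["MCI"]),
                                              np.array(rt["HC"]))
    return out


def generator_calibration(n_replicates: int = 200, n_per_group: int = 40,
                          duration: float = 300.0, seed: int = 0) -> dict:
    """Configured vs recovered band effects and test-retest consistency.

    Uses the generator's grid fidelity (full-session epoch counts) to
    measure the Hedges g of Theta/slow-Beta band power at Cz across many
    cohort draws, and the across-visit ICC of Theta band power.
    """
    cfg0 = syn.CohortConfig(n_hc=n_per_group, n_mci=n_per_group, seed=seed)
    cz = cfg0.channels.index("Cz")
    theta_bins = BANDS["theta"].bins()
    beta_bins = BANDS["slow_beta"].bins()
    theta_gs, beta_gs = [], []
    for r in range(n_replicates):
        cfg = dataclasses.replace(cfg0, seed=_derive_seed(seed, 70001, r))
        subjects = syn.make_cohort(cfg)
        grids = syn.sample_resting_psd_grids(subjects, 1, cfg,
                                             duration=duration)
        labels = np.array([s.group for s in subjects])
        th = grids[:, cz, theta_bins].mean(axis=1)
        be = grids[:, cz, beta_bins].mean(axis=1)
        theta_gs.append(hedges_g(th[labels == "MCI"], th[labels == "HC"]))
        beta_gs.append(hedges_g(be[labels == "MCI"], be[labels == "HC"]))
    # test-retest of theta band power across visits, measured on healthy
    # controls only: in a mixed cohort the stable group separation inflates
    # the ICC above the configured within-group trait consistency
    cfg = dataclasses.replace(cfg0, n_hc=48, n_mci=2, seed=seed + 555)
    subjects = [s for s in syn.make_cohort(cfg) if s.group == "HC"]
    v1 = syn.sample_resting_psd_grids(subjects, 1, cfg, duration=duration)
    v2 = syn.sample_resting_psd_grids(subjects, 2, cfg, duration=duration)
    pm = PairedMeasurements(
        np.array([s.id for s in subjects]),
        v1[:, cz, theta_bins].mean(axis=1), v2[:, cz, theta_bins].mean(axis=1))
    return {
        "configured_theta_g": cfg0.theta_shift,
        "recovered_theta_g": float(np.mean(theta_gs)),
        "configured_beta_g": cfg0.beta_shift,
        "recovered_beta_g": float(np.mean(beta_gs)),
        "configured_icc": cfg0.test_retest_icc,
        "recovered_theta_icc": icc_alpha(pm),
    }


def classifier_study(n_per_group: int = 60, n_perm: int = 200,
                     n_shuffles: int = 50, seed: int = 0) -> dict:
    """Classifier pipeline on the calibrated cohort: cross-validated AUC,
    the label-shuffled null, and split validation with score reliability.

    Runs at the calibrated study effect sizes with 60 subjects per group so
    every modality forms clusters with overwhelming probability (feature
    assembly is, by design, a hard error when a modality has none).
    """
    rcfg = RunConfig(
        cohort=study_config(n_per_group, seed=seed),
        fidelity="epochs", resting_duration=60.0, n_erp_trials=64,
        n_perm=n_perm, seed=seed)
    base = run_baseline(rcfg)
    rng = np.random.default_rng(seed + 31)
    shuffled_aucs = []
    for _ in range(n_shuffles):
        feats = base.features.copy()
        feats["label"] = rng.permutation(feats["label"].to_numpy())
        if min(np.bincount((feats["label"] == "MCI").astype(int))) < rcfg.cv_folds:
            continue
        shuffled_aucs.append(cross_validate(feats, k=rcfg.cv_folds,
                                            seed=seed).auc)
    lon = run_longitudinal(rcfg)
    out = {
        "cv_auc": base.evaluation.auc,
        "cv_accuracy_pct": base.evaluation.accuracy_pct,
        "cv_balanced_accuracy_pct": base.evaluation.balanced_accuracy_pct,
        "score_effect_size_g": base.evaluation.effect_size_g,
        "shuffled_cv_auc": float(np.mean(shuffled_aucs)),
        "n_predictors": int(len(base.features.columns) - 1),
    }
    if lon.score_retest:
        out["score_retest_icc"] = lon.score_retest["icc"]
        out["score_retest_r"] = lon.score_retest["r"]
    for visit, rep in lon.split_reports.items():
        out[f"split_auc_visit{visit}"] = rep.auc
        out[f"split_accuracy_pct_visit{visit}"] = rep.accuracy_pct
    if lon.quadrants:
        out["quadrant_score_outcome_r"] = lon.quadrants["r"]
    return out
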