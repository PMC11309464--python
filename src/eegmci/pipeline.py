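"""End-to-end orchestration: cohort synthesis (or loading), preprocessing,
spectral and ERP feature extraction, cluster statistics, the 12-predictor
classifier, and test-retest reliability, with JSON/Markdown reports.

``run_baseline`` analyses the first visit: per-modality cluster reports for
the six data modalities (relative PSD, absolute PSD, 3CVT ERPs, 3CVT
performance, SIR ERPs, SIR performance), a per-predictor effect-size table,
the assembled feature CSV, the cross-validated classifier evaluation and a
data-quality summary.  ``run_longitudinal`` adds the paired (within-subject)
cluster analyses per group, per-feature test-retest ICC and Pearson r,
split validation on held-out subjects at both visits, the score test-retest
consistency, and the prognostic quadrant summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as syn
from . import erp as erpmod
from . import model as mdl
from .cluster import ClusterAnalysis, cluster_analysis
from .containers import EpochSet
from .preprocess import (PreprocessingReport, epoch_recording,
                         filter_recording, repair_or_reject, scan_artifacts)
from .reliability import (PairedMeasurements, hedges_g, icc_alpha, pearson_r,
                          prognostic_quadrants)
from .spectral import compute_psd

__all__ = ["RunConfig", "VisitData", "BaselineResults", "LongitudinalResults",
           "run_baseline", "run_longitudinal", "extract_visit_data",
           "modality_grid_time_axis"]

MODALITIES = ("psd_rel", "psd_abs", "erp_3cvt", "erp_3cvt_performance",
              "erp_sir", "erp_sir_performance")

ERP_GRID_SPAN = (-0.2, 0.8)     # s, channel x time analysis window
ERP_GRID_POINTS = 256


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    fidelity: str = "epochs"            # "epochs" (scaled) or "session" (full)
    resting_duration: float | None = None   # s; None -> cohort default
    n_erp_trials: int = 64              # per subject, epochs fidelity
    session_trials: int | None = None   # truncate designs, session fidelity
    alpha: float = 0.01
    min_size_frequency: int = 2
    min_size_time: int = 20
    n_perm: int = 1000
    seed: int = 0
    latency_channels: tuple[tuple[str, str], ...] = (("3cvt", "Cz"), ("sir", "Fz"))
    classifier_mode: str = "crossval"   # "crossval" or "split"
    cv_folds: int = 5
    test_fraction: float = 0.5          # split mode: fraction held out
    output_dir: str | None = None

    def latency_channel_map(self) -> dict[str, str]:
        return dict(self.latency_channels)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        cd = d.pop("cohort", {})
        for key in ("rt_shift_ms", "accuracy_shift", "rt_subject_sd"):
            if key in cd and cd[key] is not None:
                cd[key] = tuple((k, float(v)) for k, v in cd[key])
        for key in ("latency_channels",):
            if key in d and d[key] is not None:
                d[key] = tuple((a, b) for a, b in d[key])
        return cls(cohort=syn.CohortConfig(**cd), **d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def modality_grid_time_axis(fs: float = 256.0) -> np.ndarray:
    """The 256-point channel x time grid axis over [-0.2, +0.8) s."""
    start = int(round(ERP_GRID_SPAN[0] * fs))
    return (start + np.arange(ERP_GRID_POINTS)) / fs


@dataclass
class VisitData:
    """Per-subject measurements of one visit, ready for the statistics."""

    visit: int
    subjects: list[str]
    labels: dict[str, str]
    psd_abs: np.ndarray                 # (n, ch, 40) log10
    psd_rel: np.ndarray
    erp_grids: dict[str, np.ndarray]    # task -> (n, ch, 256) uV
    erp_subjects: dict[str, list[str]]
    latencies: pd.DataFrame             # subject, task, channel, peak_latency
    behavior: pd.DataFrame              # subject, task, accuracy_pct, mean_rt_s
    quality: list[dict]


def _erp_epochs_for(subject: syn.Subject, visit: int, task: str,
                    rcfg: RunConfig) -> tuple[EpochSet, pd.DataFrame]:
    """One subject's cleaned analysed-type epochs plus full-task behaviour."""
    ccfg = rcfg.cohort
    if rcfg.fidelity == "epochs":
        epochs = syn.simulate_erp_epochs(subject, visit, task, ccfg,
                                         n_trials=rcfg.n_erp_trials)
        behavior = syn.simulate_behavior(subject, visit, task, ccfg)
        return epochs, behavior
    design = (syn.make_3cvt_design(ccfg.seed) if task == "3cvt"
              else syn.make_sir_design(ccfg.seed))
    if rcfg.session_trials:
        design = design.truncate(rcfg.session_trials)
    rec, events = syn.simulate_erp_session(subject, visit, design, ccfg)
    rec = filter_recording(rec, "erp")
    mask = scan_artifacts(rec)
    rec, exclusions = repair_or_reject(rec, mask)
    analyzed = events[events["trial_type"] == syn._ANALYZED_TYPE[task]]
    epochs = epoch_recording(rec, analyzed, exclusion_intervals=exclusions)
    scoreable = events[events["block"] != "encoding1"] if task == "sir" \
        else events
    scoreable = scoreable[~scoreable["trial_type"].str.contains("encoding")]
    return epochs, scoreable[["correct", "response_time"]]


def extract_visit_data(subjects: list[syn.Subject], visit: int,
                       rcfg: RunConfig) -> VisitData:
    """Measure every subject: resting PSD grids (both dialects), per-task
    average-ERP channel x time grids, classical early-component latencies,
    and behavioural summaries.

    Subjects whose ERP acquisition fails the minimum-trial rule are dropped
    from that task's modality only (listwise completeness is enforced later
    at feature assembly).
    """
    ccfg = rcfg.cohort
    labels = {s.id: s.group for s in subjects}
    psd_abs, psd_rel, kept = [], [], []
    quality: list[dict] = []
    for s in subjects:
        rec = syn.simulate_resting(s, visit, ccfg,
                                   duration=rcfg.resting_duration)
        if rcfg.fidelity == "session":
            rec = filter_recording(rec, "resting")
            mask = scan_artifacts(rec)
            rec, exclusions = repair_or_reject(rec, mask)
            quality.append(PreprocessingReport.from_mask(
                mask, rec.n_samples, exclusions).to_dict() | {
                    "subject": s.id, "task": "resting", "visit": visit})
        else:
            exclusions = []
        psd_abs.append(compute_psd(rec, "absolute", exclusions).values)
        psd_rel.append(compute_psd(rec, "relative", exclusions).values)
        kept.append(s.id)
    erp_grids: dict[str, np.ndarray] = {}
    erp_subjects: dict[str, list[str]] = {}
    lat_rows, behav_rows = [], []
    window_name = {"3cvt": "P1", "sir": "P200"}
    for task in ("3cvt", "sir"):
        grids, ids = [], []
        for s in subjects:
            epochs, behavior = _erp_epochs_for(s, visit, task, rcfg)
            epochs = erpmod.baseline_correct(epochs)
            epochs = erpmod.reject_trials(epochs)
            try:
                avg = erpmod.average_erp(epochs, syn._ANALYZED_TYPE[task],
                                         subject=s.id, visit=visit)
            except erpmod.TooFewTrialsError:
                continue
            cropped = _crop_to_grid(avg)
            grids.append(cropped)
            ids.append(s.id)
            comp = erpmod.measure_component(avg, window_name[task])
            for ch in avg.channels:
                lat_rows.append((s.id, task, ch, comp.at(ch)["peak_latency"]))
            summary = erpmod.behavioral_summary(behavior, task)
            behav_rows.append((s.id, task, summary.accuracy_pct,
                               summary.mean_rt_s))
        erp_grids[task] = np.array(grids)
        erp_subjects[task] = ids
    latencies = pd.DataFrame(lat_rows, columns=["subject", "task", "channel",
                                                "peak_latency"])
    behavior = pd.DataFrame(behav_rows, columns=["subject", "task",
                                                 "accuracy_pct", "mean_rt_s"])
    return VisitData(visit, kept, labels, np.array(psd_abs), np.array(psd_rel),
                     erp_grids, erp_subjects, latencies, behavior, quality)


def _crop_to_grid(avg: erpmod.ErpAverage) -> np.ndarray:
    """Crop an average ERP to the 256-point [-0.2, +0.8) s analysis grid."""
    fs = 1.0 / np.mean(np.diff(avg.times))
    start = int(round((ERP_GRID_SPAN[0] - avg.times[0]) * fs))
    seg = avg.waveform[:, start: start + ERP_GRID_POINTS]
    if seg.shape[1] != ERP_GRID_POINTS:
        raise ValueError("epoch window too short for the analysis grid")
    return seg


def _visit_cluster_analyses(data: VisitData, rcfg: RunConfig,
                            ) -> dict[str, tuple[ClusterAnalysis, list[str]]]:
    out = {}
    labels_for = lambda ids: np.array([data.labels[i] for i in ids])
    out["psd_rel"] = (cluster_analysis(
        data.psd_rel, labels_for(data.subjects), "independent",
        "channel_frequency", rcfg.alpha, rcfg.min_size_frequency,
        rcfg.n_perm, rcfg.seed), data.subjects)
    out["psd_abs"] = (cluster_analysis(
        data.psd_abs, labels_for(data.subjects), "independent",
        "channel_frequency", rcfg.alpha, rcfg.min_size_frequency,
        rcfg.n_perm, rcfg.seed + 1), data.subjects)
    for k, task in enumerate(("3cvt", "sir")):
        ids = data.erp_subjects[task]
        out[f"erp_{task}"] = (cluster_analysis(
            data.erp_grids[task], labels_for(ids), "independent",
            "channel_time", rcfg.alpha, rcfg.min_size_time,
            rcfg.n_perm, rcfg.seed + 2 + k), ids)
    return out


def _feature_table(analyses: dict, data: VisitData, rcfg: RunConfig,
                   clusters_by_modality: dict | None = None,
                   ) -> mdl.FeatureTable:
    if clusters_by_modality is None:
        sources = analyses
    else:
        sources = {}
        for modality, (analysis, ids) in analyses.items():
            sources[modality] = (clusters_by_modality[modality],
                                 analysis.grids, ids)
    return mdl.assemble_features(sources, data.latencies, data.behavior,
                                 data.labels, rcfg.latency_channel_map())


def _effect_size_table(features: mdl.FeatureTable) -> pd.DataFrame:
    """Per-predictor MCI-vs-HC Hedges g (the individual-biomarker summary)."""
    rows = []
    y = features["label"].to_numpy()
    for name in mdl.PREDICTORS:
        vals = features[name].to_numpy(dtype=float)
        try:
            g = hedges_g(vals[y == "MCI"], vals[y == "HC"])
        except ValueError:
            g = float("nan")
        rows.append((name, g))
    return pd.DataFrame(rows, columns=["predictor", "hedges_g"])


@dataclass
class BaselineResults:
    config: RunConfig
    analyses: dict
    features: mdl.FeatureTable
    effect_sizes: pd.DataFrame
    evaluation: mdl.EvalReport
    quality: list[dict]

    def modality_sections(self) -> dict[str, dict]:
        """Machine-readable per-modality report (six data modalities)."""
        sections = {}
        for modality, (analysis, _ids) in self.analyses.items():
            sections[modality] = {
                "n_clusters": len(analysis.clusters),
                "clusters": [c.to_dict() for c in analysis.clusters[:10]],
            }
        for task in ("3cvt", "sir"):
            cols = (f"RT-{task.upper()}", f"PC-{task.upper()}")
            y = self.features["label"].to_numpy()
            perf = {}
            for col in cols:
                v = self.features[col].to_numpy(dtype=float)
                try:
                    perf[col] = {"hedges_g": hedges_g(v[y == "MCI"], v[y == "HC"]),
                                 "mean_hc": float(v[y == "HC"].mean()),
                                 "mean_mci": float(v[y == "MCI"].mean())}
                except ValueError:
                    perf[col] = {"hedges_g": float("nan")}
            sections[f"erp_{task}_performance"] = perf
        return sections

    def to_report(self) -> dict:
        return {
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "n_subjects": int(len(self.features)),
            "modalities": self.modality_sections(),
            "effect_sizes": self.effect_sizes.set_index("predictor")[
                "hedges_g"].round(4).to_dict(),
            "classifier": self.evaluation.to_dict(),
            "data_quality": self.quality,
        }


def run_baseline(rcfg: RunConfig, output_dir: str | Path | None = None,
                 ) -> BaselineResults:
    """Baseline MCI-vs-HC analysis on a synthetic cohort.

    Reproducible bit-exactly from (config, seed); writes JSON + Markdown
    reports and the feature CSV when an output directory is given.
    """
    subjects = syn.make_cohort(rcfg.cohort)
    data = extract_visit_data(subjects, 1, rcfg)
    analyses = _visit_cluster_analyses(data, rcfg)
    features = _feature_table(analyses, data, rcfg)
    effect_sizes = _effect_size_table(features)
    evaluation = mdl.cross_validate(features, k=rcfg.cv_folds, seed=rcfg.seed)
    results = BaselineResults(rcfg, analyses, features, effect_sizes,
                              evaluation, data.quality)
    if output_dir is not None:
        _write_baseline_reports(results, Path(output_dir))
    return results


@dataclass
class LongitudinalResults:
    config: RunConfig
    paired_clusters: dict
    feature_reliability: pd.DataFrame
    split_reports: dict
    score_retest: dict | None
    quadrants: dict | None

    def to_report(self) -> dict:
        return {
            "config_hash": self.config.config_hash,
            "paired_clusters": {
                k: {"n_significant": sum(c.significant for c in v.clusters),
                    "n_clusters": len(v.clusters)}
                for k, v in self.paired_clusters.items()},
            "feature_reliability": self.feature_reliability.round(4).to_dict(
                orient="records"),
            "split_validation": {str(k): r.to_dict()
                                 for k, r in self.split_reports.items()},
            "score_retest": self.score_retest,
            "prognostic_quadrants": self.quadrants,
        }


def run_longitudinal(rcfg: RunConfig, output_dir: str | Path | None = None,
                     ) -> LongitudinalResults:
    """Two-visit analysis: within-subject paired cluster statistics per
    group, per-feature test-retest reliability, split validation with scores
    at both visits, and the prognostic quadrant summary."""
    subjects = syn.make_cohort(rcfg.cohort)
    v1 = extract_visit_data(subjects, 1, rcfg)
    v2 = extract_visit_data(subjects, 2, rcfg)
    analyses1 = _visit_cluster_analyses(v1, rcfg)

    # paired within-subject change analyses, per group and modality
    paired: dict[str, ClusterAnalysis] = {}
    for group in ("HC", "MCI"):
        for modality, grids1, grids2, ids in (
                ("psd_rel", v1.psd_rel, v2.psd_rel, v1.subjects),
                ("psd_abs", v1.psd_abs, v2.psd_abs, v1.subjects),
                ("erp_3cvt", v1.erp_grids["3cvt"], v2.erp_grids["3cvt"],
                 v1.erp_subjects["3cvt"]),
                ("erp_sir", v1.erp_grids["sir"], v2.erp_grids["sir"],
                 v1.erp_subjects["sir"])):
            space = ("channel_frequency" if modality.startswith("psd")
                     else "channel_time")
            min_size = (rcfg.min_size_frequency if space == "channel_frequency"
                        else rcfg.min_size_time)
            sel = [i for i, sid in enumerate(ids)
                   if v1.labels[sid] == group]
            if len(sel) < 2:
                continue
            diffs = grids2[sel] - grids1[sel]
            paired[f"{modality}:{group}"] = cluster_analysis(
                diffs, None, "paired", space, rcfg.alpha, min_size,
                rcfg.n_perm, rcfg.seed + 10)

    # baseline-defined clusters applied to both visits
    clusters_by_modality = {
        m: mdl.select_clusters(a, 2 if m.startswith("erp") else 1, m)
        for m, (a, _ids) in analyses1.items()}
    feats1 = _feature_table(analyses1, v1, rcfg, clusters_by_modality)
    # visit-2 grids evaluated on the baseline-defined clusters
    sources2 = {}
    for m, (a1, ids1) in analyses1.items():
        if m.startswith("psd"):
            grids2 = v2.psd_rel if m == "psd_rel" else v2.psd_abs
            ids2 = v2.subjects
        else:
            task = m.split("_", 1)[1]
            grids2, ids2 = v2.erp_grids[task], v2.erp_subjects[task]
        sources2[m] = (clusters_by_modality[m], grids2, ids2)
    feats2 = mdl.assemble_features(sources2, v2.latencies, v2.behavior,
                                   v2.labels, rcfg.latency_channel_map())

    # per-feature test-retest reliability on subjects with both visits
    common = feats1.index.intersection(feats2.index)
    rel_rows = []
    for name in mdl.PREDICTORS:
        pm = PairedMeasurements(np.asarray(common),
                                feats1.loc[common, name].to_numpy(float),
                                feats2.loc[common, name].to_numpy(float))
        r, p = pearson_r(pm)
        rel_rows.append((name, icc_alpha(pm), r, p))
    reliability = pd.DataFrame(rel_rows,
                               columns=["predictor", "icc", "r", "p"])

    # split validation: held-out subjects evaluated at both visits
    rng = np.random.default_rng(rcfg.seed + 1000)
    subject_ids = np.array(list(common))
    y = np.array([v1.labels[s] for s in subject_ids])
    test_ids: list[str] = []
    for group in ("HC", "MCI"):
        members = subject_ids[y == group]
        n_test = max(int(round(rcfg.test_fraction * members.size)), 2)
        test_ids.extend(rng.permutation(members)[:n_test])
    train_tbl = feats1.drop(index=test_ids)
    test1 = feats1.loc[[s for s in test_ids if s in feats1.index]]
    test2 = feats2.loc[[s for s in test_ids if s in feats2.index]]
    model, reports, retest = mdl.split_validation(
        train_tbl, {1: test1, 2: test2})
    score_retest = None
    if retest is not None:
        r, p = pearson_r(retest)
        score_retest = {"icc": icc_alpha(retest), "r": r, "p": p,
                        "n": retest.visit1.size}

    # prognostic quadrants on held-out baseline scores vs outcome change
    quadrants = None
    if len(test1):
        mmse = {s.id: s.mmse_change for s in subjects}
        scores = mdl.predict_scores(model, test1)
        change = np.array([mmse[s] for s in test1.index])
        quadrants = prognostic_quadrants(scores.to_numpy(), change)

    results = LongitudinalResults(rcfg, paired, reliability, reports,
                                  score_retest, quadrants)
    if output_dir is not None:
        _write_longitudinal_reports(results, Path(output_dir))
    return results


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default))


def _write_baseline_reports(results: BaselineResults, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(results.to_report(), outdir / "baseline_report.json")
    results.features.to_csv(outdir / "features.csv")
    results.effect_sizes.to_csv(outdir / "effect_sizes.csv", index=False)
    (outdir / "run_config.yaml").write_text(results.config.to_yaml())
    ev = results.evaluation
    md = [
        "# Baseline analysis report",
        f"Config hash: `{results.config.config_hash}`; "
        f"n = {len(results.features)} subjects with complete data.",
        "", "## Classifier (cross-validated)",
        f"- AUC: {ev.auc:.3f}",
        f"- Accuracy: {ev.accuracy_pct:.1f}%",
        f"- Balanced accuracy: {ev.balanced_accuracy_pct:.1f}%",
        f"- Score separation (Hedges g): {ev.effect_size_g:.2f}",
        "", "## Individual predictors (Hedges g, MCI - HC)",
        results.effect_sizes.round(3).to_markdown(index=False),
    ]
    (outdir / "baseline_report.md").write_text("\n".join(md))


def _write_longitudinal_reports(results: LongitudinalResults,
                                outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(results.to_report(), outdir / "longitudinal_report.json")
    results.feature_reliability.to_csv(outdir / "feature_reliability.csv",
                                       index=False)
    md = ["# Longitudinal analysis report"]
    if results.score_retest:
        sr = results.score_retest
        md += ["", f"Score test-retest: ICC = {sr['icc']:.2f}, "
               f"r = {sr['r']:.2f} (n = {sr['n']})"]
    if results.quadrants:
        fr = results.quadrants["fractions"]
        md += ["", "Prognostic quadrants (Q1-Q4): "
               + ", ".join(f"{fr[q] * 100:.0f}%" for q in
                           ("Q1", "Q2", "Q3", "Q4"))]
    md += ["", "## Per-feature reliability",
           results.feature_reliability.round(3).to_markdown(index=False)]
    (outdir / "longitudinal_report.md").write_text("\n".join(md))
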