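"""The 12-predictor composite MCI score: feature assembly, linear-SVM
training, validation, and predictor-importance ranking.

The feature set draws two cluster-based aggregated (CBA) measures from
resting-state PSD (relative and absolute dialects), two CBA measures plus an
early-component latency from each ERP task, and reaction time and accuracy
per task — 12 predictors in total.  Per modality the CBA comes from the
significant cluster(s); when no cluster in a modality reaches significance
the highest-percentile cluster is used instead.  The classifier is a
soft-margin linear SVM (C = 1) on per-predictor standardised features, with
positive decision scores indicating MCI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cluster import ClusterAnalysis
from .reliability import PairedMeasurements, hedges_g

__all__ = [
    "PREDICTORS", "FeatureTable", "LinearSvmModel", "EvalReport",
    "assemble_features", "train_svm", "predict_scores", "evaluate",
    "cross_validate", "split_validation", "weight_importance",
    "permutation_importance",
]

#: Canonical predictor order and naming.
PREDICTORS: tuple[str, ...] = (
    "EEG-PSDrel", "EEG-PSDabs",
    "3CVT-cluster-1", "3CVT-cluster-2", "3CVT-Latency",
    "SIR-cluster-1", "SIR-cluster-2", "SIR-Latency",
    "RT-3CVT", "PC-3CVT", "RT-SIR", "PC-SIR",
)

#: Default channel for the early-component latency predictor per task.
LATENCY_CHANNELS: dict[str, str] = {"3cvt": "Cz", "sir": "Fz"}

FeatureTable = pd.DataFrame  # rows: subjects; columns: PREDICTORS + "label"


class MissingModalityError(ValueError):
    """A modality produced no cluster at any percentile."""


#: modality key -> feature names drawn from its ranked clusters
_MODALITY_FEATURES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("psd_rel", ("EEG-PSDrel",)),
    ("psd_abs", ("EEG-PSDabs",)),
    ("erp_3cvt", ("3CVT-cluster-1", "3CVT-cluster-2")),
    ("erp_sir", ("SIR-cluster-1", "SIR-cluster-2")),
)


def select_clusters(analysis: ClusterAnalysis, n_clusters: int,
                    modality: str) -> list["Cluster"]:
    """Pick the cluster(s) defining a modality's CBA features.

    Significant clusters are preferred; if none reached the 95th-percentile
    threshold the highest-percentile cluster(s) are selected instead.  A
    modality that cannot supply the requested count is a hard error.
    """
    top = analysis.top_clusters(n_clusters)
    if len(top) < n_clusters:
        raise MissingModalityError(
            f"modality {modality!r} yielded {len(top)} cluster(s); "
            f"{n_clusters} needed")
    return top


def assemble_features(cluster_results: dict,
                      latencies: pd.DataFrame, behavior: pd.DataFrame,
                      labels: dict[str, str],
                      latency_channels: dict[str, str] | None = None,
                      ) -> FeatureTable:
    """Build the subjects x 12 feature table.

    Parameters
    ----------
    cluster_results
        Maps modality keys ``psd_rel``, ``psd_abs``, ``erp_3cvt``,
        ``erp_sir`` to either an ``(analysis, subject_ids)`` pair — the
        clusters are then selected here (significant first, highest
        percentile as fallback) — or an explicit
        ``(clusters, grids, subject_ids)`` triple, used when clusters
        defined at baseline are applied to another visit's grids.
    latencies
        Tidy frame (subject, task, channel, peak_latency) of classical
        early-component latencies.
    behavior
        Tidy frame (subject, task, accuracy_pct, mean_rt_s).
    labels
        subject id -> "HC"/"MCI".

    Subjects missing any modality are dropped (listwise completeness).
    """
    from .cluster import extract_cba

    latency_channels = {**LATENCY_CHANNELS, **(latency_channels or {})}
    columns: dict[str, pd.Series] = {}
    for modality, names in _MODALITY_FEATURES:
        if modality not in cluster_results:
            raise MissingModalityError(f"missing modality {modality!r}")
        entry = cluster_results[modality]
        if len(entry) == 2:
            analysis, subjects = entry
            clusters = select_clusters(analysis, len(names), modality)
            grids = analysis.grids
        else:
            clusters, grids, subjects = entry
            if len(clusters) < len(names):
                raise MissingModalityError(
                    f"modality {modality!r} supplied {len(clusters)} "
                    f"cluster(s); {len(names)} needed")
        for rank, name in enumerate(names):
            cba = np.array([extract_cba(g, clusters[rank]) for g in grids])
            columns[name] = pd.Series(cba, index=list(subjects))
    for task, name in (("3cvt", "3CVT-Latency"), ("sir", "SIR-Latency")):
        sel = latencies[(latencies["task"] == task)
                        & (latencies["channel"] == latency_channels[task])]
        columns[name] = sel.set_index("subject")["peak_latency"]
    for task, rt_name, pc_name in (("3cvt", "RT-3CVT", "PC-3CVT"),
                                   ("sir", "RT-SIR", "PC-SIR")):
        sel = behavior[behavior["task"] == task].set_index("subject")
        columns[rt_name] = sel["mean_rt_s"]
        columns[pc_name] = sel["accuracy_pct"]
    table = pd.DataFrame(columns)[list(PREDICTORS)].dropna(axis=0, how="any")
    table["label"] = pd.Series(labels)
    table = table.dropna(subset=["label"])
    return table


# ---------------------------------------------------------------------------
# linear SVM
# ---------------------------------------------------------------------------


@dataclass
class LinearSvmModel:
    """Linear SVM with per-predictor training-set standardisation baked in.

    score(x) = w . (x - mu) / sigma + b; MCI is the positive class
    (score > 0 classifies MCI).
    """

    weights: np.ndarray
    bias: float
    mu: np.ndarray
    sigma: np.ndarray
    feature_names: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps({
            "weights": self.weights.tolist(), "bias": self.bias,
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "feature_names": list(self.feature_names),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearSvmModel":
        d = json.loads(text)
        return cls(np.array(d["weights"]), float(d["bias"]),
                   np.array(d["mu"]), np.array(d["sigma"]),
                   tuple(d["feature_names"]))


def _xy(features: FeatureTable) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    names = tuple(c for c in features.columns if c != "label")
    x = features[list(names)].to_numpy(dtype=float)
    y = (features["label"].to_numpy() == "MCI").astype(int)
    return x, y, names


def train_svm(features: FeatureTable, labels: np.ndarray | None = None,
              ) -> LinearSvmModel:
    """Standardise by training mean/SD and fit a linear SVM (C = 1)."""
    if labels is not None:
        features = features.copy()
        features["label"] = np.asarray(labels)
    x, y, names = _xy(features)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 subjects per class")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    xs = (x - mu) / sigma
    svc = SVC(kernel="linear", C=1.0)
    svc.fit(xs, y)
    return LinearSvmModel(weights=svc.coef_.ravel().copy(),
                          bias=float(svc.intercept_[0]),
                          mu=mu, sigma=sigma, feature_names=names)


def predict_scores(model: LinearSvmModel, features: FeatureTable) -> pd.Series:
    """Signed decision scores using the model's stored standardisation."""
    names = tuple(c for c in features.columns if c != "label")
    if names != model.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    x = features[list(names)].to_numpy(dtype=float)
    xs = (x - model.mu) / model.sigma
    return pd.Series(xs @ model.weights + model.bias, index=features.index,
                     name="mci_score")


@dataclass
class EvalReport:
    """Classification performance at the score>0 operating point."""

    auc: float
    accuracy_pct: float
    balanced_accuracy_pct: float
    sensitivity: float
    specificity: float
    effect_size_g: float
    n: int
    scores: pd.Series | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "scores"}
        return d


def evaluate(scores: pd.Series | np.ndarray, labels: np.ndarray) -> EvalReport:
    """AUC (midrank ties), accuracy and balanced accuracy at score>0, and
    the Hedges-g separation of the score distributions (MCI minus HC)."""
    s = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == "MCI").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to evaluate")
    auc = float(roc_auc_score(y, s))
    pred = (s > 0).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    sens = tp / np.sum(y == 1)
    spec = tn / np.sum(y == 0)
    acc = 100.0 * (tp + tn) / y.size
    bac = 100.0 * (sens + spec) / 2.0
    try:
        g = hedges_g(s[y == 1], s[y == 0])
    except ValueError:
        g = float("nan")
    idx = scores.index if isinstance(scores, pd.Series) else None
    return EvalReport(auc, float(acc), float(bac), float(sens), float(spec),
                      g, int(y.size), pd.Series(s, index=idx))


def cross_validate(features: FeatureTable, k: int = 5, seed: int = 0,
                   ) -> EvalReport:
    """Stratified k-fold cross-validation with fold-internal standardisation.

    The scaler and SVM see only the training folds; pooled out-of-fold
    scores are evaluated once.
    """
    x, y, names = _xy(features)
    if y.size < k:
        raise ValueError("fewer subjects than folds")
    oof = np.empty(y.size)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(x, y):
        sub = features.iloc[train_idx]
        model = train_svm(sub)
        oof[test_idx] = predict_scores(model, features.iloc[test_idx]).to_numpy()
    return evaluate(pd.Series(oof, index=features.index),
                    features["label"].to_numpy())


def split_validation(train_table: FeatureTable,
                     test_tables_by_visit: dict[int, FeatureTable],
                     ) -> tuple[LinearSvmModel, dict[int, EvalReport],
                                PairedMeasurements | None]:
    """Fit on the training subjects; evaluate each test visit separately.

    Training and test subject sets must be disjoint.  When two test visits
    share subjects, their paired scores are returned for reliability
    analysis (visit order follows the sorted visit keys).
    """
    train_subjects = set(train_table.index)
    for visit, table in test_tables_by_visit.items():
        overlap = train_subjects & set(table.index)
        if overlap:
            raise ValueError(
                f"train/test subject overlap at visit {visit}: {sorted(overlap)[:3]}")
    model = train_svm(train_table)
    reports: dict[int, EvalReport] = {}
    scores_by_visit: dict[int, pd.Series] = {}
    for visit, table in sorted(test_tables_by_visit.items()):
        scores = predict_scores(model, table)
        reports[visit] = evaluate(scores, table["label"].to_numpy())
        scores_by_visit[visit] = scores
    retest = None
    if len(scores_by_visit) >= 2:
        v1, v2 = sorted(scores_by_visit)[:2]
        common = scores_by_visit[v1].index.intersection(scores_by_visit[v2].index)
        if len(common) >= 3:
            retest = PairedMeasurements(
                np.asarray(common),
                scores_by_visit[v1].loc[common].to_numpy(),
                scores_by_visit[v2].loc[common].to_numpy())
    return model, reports, retest


def weight_importance(model: LinearSvmModel) -> pd.DataFrame:
    """Predictors ranked by relative absolute SVM weight (percent of the
    total absolute weight; sums to 100)."""
    w = np.abs(model.weights)
    pct = 100.0 * w / w.sum()
    out = pd.DataFrame({"predictor": model.feature_names, "weight_pct": pct})
    return out.sort_values("weight_pct", ascending=False).reset_index(drop=True)


def permutation_importance(model: LinearSvmModel, features: FeatureTable,
                           n_rep: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mean drop in AUC/accuracy/balanced accuracy when one predictor's
    values are shuffled across subjects (no refit), averaged over ``n_rep``
    shuffles per predictor."""
    rng = np.random.default_rng(seed)
    labels = features["label"].to_numpy()
    base = evaluate(predict_scores(model, features), labels)
    rows = []
    for name in model.feature_names:
        d_auc = d_acc = d_bac = 0.0
        for _ in range(n_rep):
            shuffled = features.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            rep = evaluate(predict_scores(model, shuffled), labels)
            d_auc += rep.auc - base.auc
            d_acc += rep.accuracy_pct - base.accuracy_pct
            d_bac += rep.balanced_accuracy_pct - base.balanced_accuracy_pct
        rows.append((name, d_auc / n_rep, d_acc / n_rep, d_bac / n_rep))
    out = pd.DataFrame(rows, columns=["predictor", "d_auc", "d_accuracy_pct",
                                      "d_balanced_accuracy_pct"])
    return out.sort_values("d_auc").reset_index(drop=True)
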