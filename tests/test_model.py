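"""Feature assembly and the linear-SVM composite MCI score."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from eegmci.cluster import Cluster, ClusterAnalysis, NullDistribution, StatGrid
from eegmci.model import (PREDICTORS, LinearSvmModel, assemble_features,
                          cross_validate, evaluate, permutation_importance,
                          predict_scores, split_validation, train_svm,
                          weight_importance)


def _toy_features(n=40, informative=1.5, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x1 = np.concatenate([rng.normal(0, 1, half),
                         rng.normal(informative, 1, half)])
    x2 = rng.standard_normal(n)
    table = pd.DataFrame({"f1": x1, "f2": x2},
                         index=[f"s{i}" for i in range(n)])
    table["label"] = ["HC"] * half + ["MCI"] * half
    return table


def _fake_analysis(cba_values: np.ndarray, percentiles, seed=0):
    """ClusterAnalysis stub with grids whose cluster-cell means equal the
    requested per-subject CBA values."""
    n = cba_values.shape[0]
    n_clusters = len(percentiles)
    grids = np.zeros((n, 4, 10))
    clusters = []
    for k, pct in enumerate(percentiles):
        cells = np.array([[k, 2 * k], [k, 2 * k + 1]])
        grids[:, k, 2 * k] = grids[:, k, 2 * k + 1] = cba_values[:, k] \
            if cba_values.ndim == 2 else cba_values
        clusters.append(Cluster(cells=cells, size=2, tsize=10.0 - k, sign=1,
                                space="channel_frequency", percentile=pct,
                                significant=pct >= 95))
    grid = StatGrid(np.zeros((4, 10)), np.ones((4, 10)),
                    "channel_frequency", "independent", n - 2)
    null = NullDistribution(np.zeros(10), 10, seed)
    return ClusterAnalysis(grid, clusters, null, grids, None)


class TestAssembleFeatures:
    def _inputs(self, n=10):
        subjects = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(1)
        results = {
            "psd_rel": (_fake_analysis(rng.standard_normal((n, 1)), [99.0]),
                        subjects),
            "psd_abs": (_fake_analysis(rng.standard_normal((n, 1)), [89.0]),
                        subjects),
            "erp_3cvt": (_fake_analysis(rng.standard_normal((n, 2)),
                                        [98.0, 97.0]), subjects),
            "erp_sir": (_fake_analysis(rng.standard_normal((n, 2)),
                                       [99.0, 98.0]), subjects),
        }
        latencies = pd.DataFrame(
            [(s, task, ch, 0.2) for s in subjects
             for task in ("3cvt", "sir") for ch in ("Cz", "Fz", "Pz")],
            columns=["subject", "task", "channel", "peak_latency"])
        behavior = pd.DataFrame(
            [(s, task, 90.0, 0.6) for s in subjects
             for task in ("3cvt", "sir")],
            columns=["subject", "task", "accuracy_pct", "mean_rt_s"])
        labels = {s: ("HC" if i < n // 2 else "MCI")
                  for i, s in enumerate(subjects)}
        return results, latencies, behavior, labels

    def test_width_is_twelve_with_fallback_cluster(self):
        results, lat, beh, labels = self._inputs()
        table = assemble_features(results, lat, beh, labels)
        assert list(table.columns[:-1]) == list(PREDICTORS)
        assert table.shape == (10, 13)
        # the 89th-percentile (non-significant) absolute-PSD cluster is
        # included through the highest-percentile fallback rule
        assert table["EEG-PSDabs"].notna().all()

    def test_missing_modality_drops_subject(self):
        results, lat, beh, labels = self._inputs()
        beh = beh[~((beh["subject"] == "s3") & (beh["task"] == "sir"))]
        table = assemble_features(results, lat, beh, labels)
        assert "s3" not in table.index
        assert len(table) == 9

    def test_zero_cluster_modality_is_hard_error(self):
        results, lat, beh, labels = self._inputs()
        results["psd_abs"] = (_fake_analysis(np.zeros((10, 1)), []),
                              list(results["psd_abs"][1]))
        with pytest.raises(ValueError, match="psd_abs"):
            assemble_features(results, lat, beh, labels)

    def test_latency_channel_config(self):
        results, lat, beh, labels = self._inputs()
        lat.loc[(lat["task"] == "3cvt") & (lat["channel"] == "Pz"),
                "peak_latency"] = 0.33
        table = assemble_features(results, lat, beh, labels,
                                  latency_channels={"3cvt": "Pz"})
        assert (table["3CVT-Latency"] == 0.33).all()


class TestTrainPredict:
    def test_separable_toy_perfect_training_accuracy(self):
        table = _toy_features(informative=5.0)
        model = train_svm(table)
        rep = evaluate(predict_scores(model, table), table["label"].to_numpy())
        assert rep.accuracy_pct == 100.0
        assert rep.auc == 1.0

    def test_row_duplication_keeps_boundary(self):
        # on well-separated data no dual coefficient saturates the box
        # constraint, so the margin solution ignores sample multiplicity
        table = _toy_features(informative=12.0)
        doubled = pd.concat([table, table])
        m1, m2 = train_svm(table), train_svm(doubled)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-4)

    def test_single_class_rejected(self):
        table = _toy_features()
        table["label"] = "MCI"
        with pytest.raises(ValueError):
            train_svm(table)

    def test_training_standardisation_reused_not_refit(self):
        """Scores on shifted test data must use the training moments; a
        leaky refit on test moments gives different scores."""
        table = _toy_features(seed=3)
        model = train_svm(table)
        test = table.drop(columns="label") + 2.0   # distribution shift
        test["label"] = table["label"]
        scores = predict_scores(model, test)
        leaky = LinearSvmModel(model.weights, model.bias,
                               test.drop(columns="label").mean().to_numpy(),
                               test.drop(columns="label").std(ddof=0).to_numpy(),
                               model.feature_names)
        leaky_scores = predict_scores(leaky, test)
        assert not np.allclose(scores, leaky_scores)

    def test_json_roundtrip(self):
        model = train_svm(_toy_features())
        back = LinearSvmModel.from_json(model.to_json())
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.feature_names == model.feature_names


class TestEvaluate:
    def test_auc_extremes_and_tie_convention(self):
        labels = np.array(["HC", "HC", "MCI", "MCI"])
        assert evaluate(np.array([-2.0, -1.0, 1.0, 2.0]), labels).auc == 1.0
        assert evaluate(np.zeros(4), labels).auc == 0.5

    def test_balanced_accuracy_from_confusion_counts(self):
        # 2 TP, 1 FN, 3 TN, 1 FP -> sens 2/3, spec 3/4, BAC 70.83%
        scores = np.array([1.0, 1.0, -1.0, -1.0, -1.0, -1.0, 1.0])
        labels = np.array(["MCI", "MCI", "MCI", "HC", "HC", "HC", "HC"])
        rep = evaluate(scores, labels)
        assert rep.sensitivity == pytest.approx(2 / 3)
        assert rep.specificity == pytest.approx(3 / 4)
        assert rep.balanced_accuracy_pct == pytest.approx(70.8333, abs=1e-3)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(30)
        labels = np.where(rng.random(30) < 0.5, "HC", "MCI")
        if len(set(labels)) < 2:
            labels[0] = "HC"; labels[1] = "MCI"
        a = evaluate(scores, labels).auc
        b = evaluate(np.exp(scores / 2), labels).auc
        assert a == pytest.approx(b)


class TestCrossValidation:
    def test_seed_determinism(self):
        table = _toy_features(n=30, seed=5)
        r1 = cross_validate(table, k=5, seed=9)
        r2 = cross_validate(table, k=5, seed=9)
        assert r1.auc == r2.auc
        np.testing.assert_allclose(r1.scores, r2.scores)

    def test_separable_high_auc_and_shuffled_null(self):
        table = _toy_features(n=60, informative=3.0, seed=6)
        assert cross_validate(table, seed=0).auc >= 0.95
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(50):
            shuffled = table.copy()
            shuffled["label"] = rng.permutation(table["label"].to_numpy())
            aucs.append(cross_validate(shuffled, seed=0).auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestSplitValidation:
    def test_subject_overlap_is_error(self):
        table = _toy_features(n=20, seed=8)
        with pytest.raises(ValueError, match="overlap"):
            split_validation(table, {1: table})

    def test_two_visit_scores_are_paired(self):
        train = _toy_features(n=30, informative=2.5, seed=9)
        test1 = _toy_features(n=20, informative=2.5, seed=10)
        test1.index = [f"t{i}" for i in range(20)]
        test2 = test1.copy()
        test2[["f1", "f2"]] += 0.2 * np.random.default_rng(11).standard_normal(
            (20, 2))
        model, reports, retest = split_validation(train, {1: test1, 2: test2})
        assert set(reports) == {1, 2}
        assert retest is not None and retest.visit1.size == 20
        assert reports[1].auc > 0.8


class TestImportance:
    def test_weight_percentages(self):
        model = LinearSvmModel(np.array([3.0, -1.0]), 0.0, np.zeros(2),
                               np.ones(2), ("a", "b"))
        out = weight_importance(model)
        assert out["weight_pct"].tolist() == pytest.approx([75.0, 25.0])
        assert out["weight_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert out["predictor"].tolist() == ["a", "b"]   # sign irrelevant

    def test_zero_weight_predictor_has_no_effect(self):
        table = _toy_features(n=60, informative=3.0, seed=12)
        model = train_svm(table)
        model.weights[1] = 0.0
        out = permutation_importance(model, table, n_rep=100, seed=0)
        d_auc = out.set_index("predictor").loc["f2", "d_auc"]
        assert abs(d_auc) < 0.01

    def test_dominant_predictor_ranked_first_by_both_methods(self):
        table = _toy_features(n=80, informative=3.0, seed=13)
        model = train_svm(table)
        wi = weight_importance(model)
        pi = permutation_importance(model, table, n_rep=50, seed=1)
        assert wi.iloc[0]["predictor"] == "f1"
        assert pi.iloc[0]["predictor"] == "f1"     # largest drop sorts first
        rho = spearmanr(
            wi.set_index("predictor")["weight_pct"].reindex(["f1", "f2"]),
            -pi.set_index("predictor")["d_auc"].reindex(["f1", "f2"]))
        assert rho.statistic > 0
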