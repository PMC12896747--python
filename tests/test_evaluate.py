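"""Metric definitions against hand and brute-force oracles."""

import numpy as np
import pytest

from oilauth.evaluate import (auc_roc, blind_evaluation,
                              classification_report, regression_report,
                              repeated_runs)
from oilauth.featurize import FeatureRecord


class TestClassificationReport:
    def test_hand_computed_binary_counts(self):
        # TP=2, FP=1, FN=0, TN=1 with positive class "adulterated"
        y_true = ["adulterated", "adulterated", "pure CAO", "pure CAO"]
        y_pred = ["adulterated", "adulterated", "adulterated", "pure CAO"]
        rep = classification_report(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision["adulterated"] == pytest.approx(2 / 3)
        assert rep.recall["adulterated"] == pytest.approx(1.0)
        assert rep.f1["adulterated"] == pytest.approx(0.8)
        assert rep.n_misclassified == 1

    def test_perfect_prediction(self):
        y = ["a", "b", "a", "b"]
        s = np.array([[0.9, 0.1], [0.1, 0.9], [0.8, 0.2], [0.2, 0.8]])
        rep = classification_report(y, y, s)
        assert rep.accuracy == 1.0
        assert rep.precision["macro"] == rep.recall["macro"] == 1.0
        assert rep.f1["macro"] == 1.0
        assert rep.auc["roc"] == 1.0

    def test_micro_equals_accuracy_multiclass(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("abc"), 50)
        y_pred = rng.choice(list("abc"), 50)
        rep = classification_report(y_true, y_pred)
        assert rep.precision["micro"] == rep.recall["micro"] \
            == rep.accuracy

    def test_confusion_matrix_structure(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(list("abc"), 60)
        y_pred = rng.choice(list("abc"), 60)
        rep = classification_report(y_true, y_pred)
        assert rep.confusion.sum() == 60
        for j, c in enumerate(rep.classes):
            assert rep.confusion[j].sum() == (y_true == c).sum()
        assert rep.n_misclassified == \
            rep.confusion.sum() - np.trace(rep.confusion)

    def test_multiclass_ovr_auc_present(self):
        rng = np.random.default_rng(2)
        y = rng.choice(list("abc"), 30)
        s = rng.dirichlet(np.ones(3), 30)
        rep = classification_report(y, y, s, classes=np.array(list("abc")))
        assert {"macro", "micro"} <= rep.auc.keys()
        assert all(0 <= v <= 1 for v in rep.auc.values())


def _auc_brute(y, s):
    """All-pairs Mann–Whitney oracle, ties counted half."""
    pos = s[np.asarray(y, bool)]
    neg = s[~np.asarray(y, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0

    def test_tie_convention(self):
        assert auc_roc([1, 0], [0.7, 0.7]) == 0.5

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 2000).astype(bool)
        s = rng.normal(size=2000)
        assert auc_roc(y, s) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        y = rng.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            y[0] = ~y[0]
        s = rng.integers(0, 8, n).astype(float)  # heavy ties
        assert auc_roc(y, s) == pytest.approx(_auc_brute(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([1, 1], [0.2, 0.3])


class TestRegressionReport:
    def test_hand_computed_case(self):
        rep = regression_report([0, 10, 20, 30], [1, 9, 21, 29])
        assert rep.rmse_p == pytest.approx(1.0, abs=1e-12)
        sd = np.std([0, 10, 20, 30], ddof=1)
        assert sd == pytest.approx(12.9099, abs=1e-4)
        assert rep.rpd == pytest.approx(sd, abs=1e-9)  # RPD = SD / 1.0

    def test_perfect_prediction(self):
        rep = regression_report([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.r2_p == 1.0 and rep.rmse_p == 0.0
        assert np.isinf(rep.rpd)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = regression_report(y, np.full(4, y.mean()))
        assert rep.r2_p == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.normal(size=20)
            p = y + rng.normal(0, 0.3, size=20)
            rep = regression_report(y, p)
            assert rep.rmse_p == pytest.approx(
                np.sqrt(np.mean((y - p) ** 2)), abs=1e-12)
            assert rep.r2_p == pytest.approx(
                1 - ((y - p) ** 2).sum() / ((y - y.mean()) ** 2).sum(),
                abs=1e-12)
            assert rep.rpd == pytest.approx(np.std(y, ddof=1) / rep.rmse_p,
                                            abs=1e-12)

    def test_calibration_side(self):
        rep = regression_report([0.0, 1, 2], [0.0, 1, 2],
                                which="calibration")
        assert rep.r2_c == 1.0 and rep.rpd is None

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_report([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRepeatedRuns:
    def test_deterministic_pipeline_zero_sd(self):
        summary, per_run = repeated_runs(lambda seed: {"acc": 0.9},
                                         n_runs=5, base_seed=0)
        mean, sd = summary["acc"]
        assert mean == 0.9 and sd == 0.0
        assert len(per_run) == 5

    def test_single_run_flagged(self):
        with pytest.warns(RuntimeWarning, match="single run"):
            summary, _ = repeated_runs(lambda seed: {"m": 1.0}, n_runs=1)
        assert summary["m"] == (1.0, 0.0)

    def test_mean_matches_per_run_values(self):
        summary, per_run = repeated_runs(
            lambda seed: {"v": float(seed % 7)}, n_runs=10, base_seed=1)
        vals = [r["v"] for r in per_run]
        assert summary["v"][0] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_failure_names_run_index(self):
        def flaky(seed, _calls=[]):
            _calls.append(1)
            if len(_calls) == 3:
                raise RuntimeError("boom")
            return {"x": 1.0}

        with pytest.raises(RuntimeError, match="run 2"):
            repeated_runs(flaky, n_runs=5, base_seed=0)


class _StubModel:
    def __init__(self, classes, pred):
        self.classes_ = np.asarray(classes)
        self._pred = np.asarray(pred)

    def predict(self, x):
        return self._pred[:x.shape[0]]

    def predict_proba(self, x):
        return np.array([[1.0 if c == p else 0.0 for c in self.classes_]
                         for p in self._pred[:x.shape[0]]])


def _recs(labels):
    return [FeatureRecord(sample_id=f"b{i}",
                          binned_block=np.zeros(3), tic_block=np.empty(0),
                          label=lab) for i, lab in enumerate(labels)]


class TestBlindEvaluation:
    def test_ledger_length_matches_off_diagonal(self):
        recs = _recs(["CAO", "COO", "OLO"])
        model = _StubModel(["CAO", "COO", "OLO"], ["CAO", "OLO", "OLO"])
        rep, ledger = blind_evaluation(model, recs, train_ids=["t1"])
        assert len(ledger) == rep.n_misclassified == 1
        assert ledger[0]["true"] == "COO"
        assert ledger[0]["predicted"] == "OLO"

    def test_all_correct_empty_ledger(self):
        recs = _recs(["CAO", "COO"])
        model = _StubModel(["CAO", "COO"], ["CAO", "COO"])
        _, ledger = blind_evaluation(model, recs, train_ids=[])
        assert ledger == []

    def test_overlap_with_training_rejected(self):
        recs = _recs(["CAO", "COO"])
        model = _StubModel(["CAO", "COO"], ["CAO", "COO"])
        with pytest.raises(ValueError, match="overlap"):
            blind_evaluation(model, recs, train_ids=["b0"])

    def test_empty_blind_set_rejected(self):
        model = _StubModel(["CAO"], ["CAO"])
        with pytest.raises(ValueError, match="empty"):
            blind_evaluation(model, [], train_ids=[])
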