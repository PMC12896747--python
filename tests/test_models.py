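"""Classifier suite, data splitting, and the composition quantifier."""

import numpy as np
import pytest

from oilauth._nn import ConvAttentionNet
from oilauth.featurize import FeatureRecord
from oilauth.models import (ClassifierSpec, QuantifierSpec, build_cnn,
                            predict, split_data, task_labels,
                            train_classifier, train_quantifier)


def _records(x, labels, fractions=None):
    out = []
    for i in range(x.shape[0]):
        out.append(FeatureRecord(
            sample_id=f"s{i}", binned_block=x[i], tic_block=np.empty(0),
            label=labels[i],
            fractions=None if fractions is None else fractions[i]))
    return out


@pytest.fixture(scope="module")
def separable():
    """Two classes, margin ~5 SD, 200 samples, seed 42."""
    rng = np.random.default_rng(42)
    n = 200
    y = np.array(["CAO"] * (n // 2) + ["COO"] * (n // 2))
    x = rng.normal(size=(n, 10))
    x[:, 0] += np.where(y == "CAO", 0.0, 5.0)
    return _records(x, y)


class TestSplitData:
    def test_80_20(self, separable):
        tr, te = split_data(separable, 0.2, seed=42)
        assert len(tr) == 160 and len(te) == 40
        assert {r.sample_id for r in tr}.isdisjoint(
            {r.sample_id for r in te})

    def test_deterministic(self, separable):
        tr1, _ = split_data(separable, 0.2, seed=7)
        tr2, _ = split_data(separable, 0.2, seed=7)
        assert [r.sample_id for r in tr1] == [r.sample_id for r in tr2]

    def test_stratified_proportions(self, separable):
        _, te = split_data(separable, 0.2, seed=0)
        labs = [r.label for r in te]
        assert abs(labs.count("CAO") - labs.count("COO")) <= 1

    def test_singleton_class_falls_back(self):
        rng = np.random.default_rng(0)
        recs = _records(rng.normal(size=(6, 3)),
                        ["a", "a", "a", "a", "a", "b"])
        with pytest.warns(RuntimeWarning, match="single sample"):
            split_data(recs, 0.34, seed=0)


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["rf", "lr", "gbt"])
    def test_separable_data_perfect_accuracy(self, separable, kind):
        tr, te = split_data(separable, 0.2, seed=42)
        m = train_classifier(ClassifierSpec(kind=kind), tr, "binary")
        x = np.vstack([r.vector for r in te])
        y = task_labels(te, "binary")
        assert (m.predict(x) == y).mean() == 1.0

    def test_predictions_within_training_labels(self, separable):
        tr, te = split_data(separable, 0.2, seed=42)
        m = train_classifier(ClassifierSpec(kind="rf"), tr, "multiclass")
        x = np.vstack([r.vector for r in te])
        assert set(m.predict(x)) <= set(m.classes_)

    def test_rf_deterministic(self, separable):
        tr, te = split_data(separable, 0.2, seed=42)
        x = np.vstack([r.vector for r in te])
        p1 = train_classifier(ClassifierSpec(kind="rf"), tr,
                              "binary").predict_proba(x)
        p2 = train_classifier(ClassifierSpec(kind="rf"), tr,
                              "binary").predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_svm_scores_monotone_with_decision(self, separable):
        tr, te = split_data(separable, 0.2, seed=42)
        m = train_classifier(ClassifierSpec(kind="svm"), tr, "binary")
        x = np.vstack([r.vector for r in te])
        p = m.predict_proba(x)
        d = m._model.decision_function(x)
        order = np.argsort(d)
        assert np.all(np.diff(p[order, 1]) >= 0)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        recs = _records(rng.normal(size=(10, 3)), ["CAO"] * 10)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(ClassifierSpec(kind="rf"), recs, "binary")

    def test_empty_and_batch_consistency(self, separable):
        tr, te = split_data(separable, 0.2, seed=42)
        m = train_classifier(ClassifierSpec(kind="lr"), tr, "binary")
        assert predict(m, np.empty((0, 10))).shape == (0, 2)
        x = np.vstack([r.vector for r in te])
        batch = m.predict_proba(x)
        singles = np.vstack([m.predict_proba(x[i:i + 1]) for i in range(5)])
        np.testing.assert_allclose(batch[:5], singles, atol=1e-12)
        assert np.all((batch >= 0) & (batch <= 1))

    def test_dimension_mismatch_names_expected(self, separable):
        tr, _ = split_data(separable, 0.2, seed=42)
        m = train_classifier(ClassifierSpec(kind="rf"), tr, "binary")
        with pytest.raises(ValueError, match="10"):
            m.predict_proba(np.zeros((2, 4)))


class TestConvAttentionNet:
    def test_softmax_rows_sum_to_one(self):
        net = build_cnn(3338, 2, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 3338))
        p = net.predict_proba(x)
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_reduced_input_many_classes(self):
        net = build_cnn(10, 16, seed=0)
        p = net.predict_proba(np.zeros((2, 10)))
        assert p.shape == (2, 16)

    def test_forward_deterministic(self):
        net = build_cnn(20, 3, seed=1)
        x = np.random.default_rng(1).normal(size=(4, 20))
        np.testing.assert_array_equal(net.predict_proba(x),
                                      net.predict_proba(x))

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_cnn(3, 2)

    @pytest.mark.parametrize("loss", ["ce", "mse"])
    def test_gradients_match_finite_differences(self, loss):
        """Backprop of every layer family agrees with central differences."""
        rng = np.random.default_rng(0)
        net = ConvAttentionNet(12, 3, loss=loss, seed=1)
        x = rng.normal(size=(4, 12))
        y = np.abs(rng.normal(size=(4, 3)))
        y /= y.sum(axis=1, keepdims=True)
        _, grads = net._loss_grads(x, y)
        eps = 1e-6
        for key in ("Wc1", "Wc2", "Ws1", "Ws2", "Wsp", "Wm1", "Wr1",
                    "Wr2", "Wf1", "Wo", "bo", "bsp"):
            p = net.params[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            old = p[idx]
            p[idx] = old + eps
            lp, _ = net._loss_grads(x, y)
            p[idx] = old - eps
            lm, _ = net._loss_grads(x, y)
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=1e-4,
                                                    abs=1e-8), key

    def test_cnn_learns_separable_problem(self, separable):
        tr, te = split_data(separable, 0.2, seed=42)
        spec = ClassifierSpec(kind="cnn", epochs=40, patience=10)
        m = train_classifier(spec, tr, "binary")
        x = np.vstack([r.vector for r in te])
        y = task_labels(te, "binary")
        assert (m.predict(x) == y).mean() >= 0.9


class TestQuantifier:
    def test_output_on_simplex_even_out_of_distribution(self):
        rng = np.random.default_rng(0)
        fr = rng.dirichlet(np.ones(5), size=40)
        x = fr @ rng.uniform(1, 10, size=(5, 12))
        recs = _records(x, [""] * 40, fr)
        q = train_quantifier(QuantifierSpec(epochs=3, patience=2), recs)
        wild = rng.normal(0, 100, size=(7, 12))
        p = q.predict(wild)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_invalid_fractions_rejected(self):
        rng = np.random.default_rng(1)
        fr = np.full((10, 5), 0.3)  # sums to 1.5
        recs = _records(rng.normal(size=(10, 8)), [""] * 10, fr)
        with pytest.raises(ValueError, match="fractions"):
            train_quantifier(QuantifierSpec(), recs)

    def test_recovers_composition_near_linear_oracle(
            self, small_noisefree_records):
        """On the zero-noise linear simulator a linear model recovers the
        CAO fraction essentially exactly (R2 >= 0.999); the quantifier on
        PCA features must approach that upper bound within 0.05."""
        from sklearn.linear_model import LinearRegression
        from oilauth.embed import EmbedConfig, fit_transform
        from oilauth.evaluate import regression_report
        from oilauth.models import split_data

        recs = small_noisefree_records
        tr, te = split_data(recs, 0.2, seed=42,
                            labels=[r.label for r in recs])
        xtr = np.vstack([r.binned_block for r in tr])
        xte = np.vstack([r.binned_block for r in te])
        ytr = np.vstack([r.fractions for r in tr])[:, 0]
        yte = np.vstack([r.fractions for r in te])[:, 0]
        lin = LinearRegression().fit(xtr, ytr)
        r2_lin = regression_report(yte, lin.predict(xte)).r2_p
        assert r2_lin >= 0.999

        ztr, emb = fit_transform(np.vstack([r.vector for r in tr]),
                                 EmbedConfig(method="pca"))
        q = train_quantifier(QuantifierSpec(seed=42), tr, features=ztr)
        pred = q.predict(emb.transform(np.vstack([r.vector for r in te])))
        r2_q = regression_report(yte, pred[:, 0]).r2_p
        assert r2_q >= 0.95
        assert r2_q >= r2_lin - 0.05
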