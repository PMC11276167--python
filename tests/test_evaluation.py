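"""Macro metrics against independent oracles; baselines; ELM; t-SNE."""

import numpy as np
import pytest
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)

import lvdlnet as lv
from lvdlnet.evaluation import (
    BaselineSpec,
    ELMClassifier,
    comparison_table,
    confusion,
    embed_tsne,
    macro_metrics,
    pca_reduce,
    run_baseline,
    train_elm,
)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([0, 1, 2, 2, 1, 0])
        cm = confusion(y, y, 3)
        assert np.array_equal(cm, np.diag([2, 2, 2]))

    def test_small_enumeration(self):
        cm = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert cm.tolist() == [[1, 1], [0, 2]]

    def test_row_sums_are_true_class_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        cm = confusion(y_true, y_pred, 4)
        assert np.array_equal(cm.sum(axis=1), np.bincount(y_true, minlength=4))
        assert cm.sum() == 100

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 5], [0, 1], 3)
        with pytest.raises(ValueError):
            confusion([0, 1], [0], 2)


class TestMacroMetrics:
    def test_perfect_matrix_gives_all_ones(self):
        m = macro_metrics(np.diag([10, 20, 30]))
        assert (m.acc, m.mac_p, m.mac_r, m.mac_f) == (1.0, 1.0, 1.0, 1.0)

    def test_symmetric_two_class_example(self):
        m = macro_metrics(np.array([[3, 1], [1, 3]]))
        assert m.acc == pytest.approx(0.75)
        assert m.mac_p == pytest.approx(0.75)
        assert m.mac_r == pytest.approx(0.75)
        assert m.mac_f == pytest.approx(0.75)

    def test_empty_predicted_class_zero_convention(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            m = macro_metrics(np.array([[2, 0], [2, 0]]))
        assert m.mac_r == pytest.approx(0.5)
        assert m.mac_p == pytest.approx(0.25)
        assert m.acc == pytest.approx(0.5)

    def test_agrees_with_per_class_oracle_on_random_labels(self):
        """100 random (y_true, y_pred) instances, k in 2..6, against the
        scikit-learn macro-averaged scores with the same zero convention."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(k, 60))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            labels = np.arange(k)
            cm = confusion(y_true, y_pred, k)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = macro_metrics(cm)
            assert m.acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert m.mac_p == pytest.approx(
                precision_score(y_true, y_pred, labels=labels, average="macro",
                                zero_division=0)
            )
            assert m.mac_r == pytest.approx(
                recall_score(y_true, y_pred, labels=labels, average="macro",
                             zero_division=0)
            )
            assert m.mac_f == pytest.approx(
                f1_score(y_true, y_pred, labels=labels, average="macro",
                         zero_division=0)
            )

    def test_invariant_under_joint_label_permutation(self):
        rng = np.random.default_rng(7)
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        perm = rng.permutation(5)
        m1 = macro_metrics(confusion(y_true, y_pred, 5))
        m2 = macro_metrics(confusion(perm[y_true], perm[y_pred], 5))
        for a, b in zip(m1.to_dict().values(), m2.to_dict().values()):
            assert a == pytest.approx(b)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            macro_metrics(np.zeros((3, 3), dtype=int))


class TestPCA:
    def test_full_rank_projection_reconstructs_centered_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        scores, _, model = pca_reduce(X, X[:5], 8)
        recon = scores @ model.components_ + model.mean_
        np.testing.assert_allclose(recon, X, atol=1e-8)
        np.testing.assert_allclose(
            model.components_ @ model.components_.T, np.eye(8), atol=1e-8
        )
        assert np.all(np.diff(model.explained_variance_) <= 1e-12)

    def test_component_count_validated(self):
        X = np.random.default_rng(1).normal(size=(10, 4))
        with pytest.raises(ValueError):
            pca_reduce(X, X, 9)


class TestELM:
    def _toy(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-2, 0.5, (n // 2, 3)), rng.normal(2, 0.5, (n // 2, 3))])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = self._toy()
        elm = train_elm(X, y, n_hidden=50, seed=1)
        assert np.mean(elm.predict(X) == y) == 1.0

    def test_output_weights_match_least_squares_oracle(self):
        X, y = self._toy(seed=3)
        elm = ELMClassifier(n_hidden=20, seed=5, ridge=0.0).fit(X, y)
        H = elm._hidden(X)
        T = np.column_stack([(y == 0), (y == 1)]).astype(float)
        beta, *_ = np.linalg.lstsq(H, T, rcond=None)
        np.testing.assert_allclose(elm.beta_, beta, atol=1e-6)

    def test_same_seed_same_predictions(self):
        X, y = self._toy(seed=2)
        p1 = ELMClassifier(n_hidden=30, seed=9).fit(X, y).predict(X)
        p2 = ELMClassifier(n_hidden=30, seed=9).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_capacity_monotonicity_on_six_class_toy(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(c, 1.0, (30, 4)) for c in range(6)])
        y = np.repeat(np.arange(6), 30)
        small = ELMClassifier(n_hidden=1, seed=0).fit(X, y)
        big = ELMClassifier(n_hidden=100, seed=0).fit(X, y)
        assert np.mean(big.predict(X) == y) > np.mean(small.predict(X) == y)

    def test_invalid_hidden_count(self):
        with pytest.raises(ValueError):
            ELMClassifier(n_hidden=0)


class TestBaselines:
    def test_run_baseline_deterministic(self, small_ds, small_feats, small_split):
        spec = BaselineSpec("vnir_intervals", "svm", seed=1)
        m1 = run_baseline(spec, small_feats, small_ds.labels, small_split)
        m2 = run_baseline(spec, small_feats, small_ds.labels, small_split)
        assert m1 == m2

    def test_pca_svm_on_easy_vnir_intervals(self, small_ds, small_feats, small_split):
        m = run_baseline(
            BaselineSpec("vnir_intervals", "svm", seed=0),
            small_feats, small_ds.labels, small_split,
        )
        assert m.acc > 0.9

    @pytest.mark.parametrize("clf", ["lda", "knn", "svm", "elm"])
    def test_all_classifiers_run(self, small_ds, small_feats, small_split, clf):
        m = run_baseline(
            BaselineSpec("libs_intervals", clf, n_components=10, seed=0),
            small_feats, small_ds.labels, small_split,
        )
        assert 0.0 <= m.acc <= 1.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BaselineSpec("libs_lines", "svm")
        with pytest.raises(ValueError):
            BaselineSpec("libs_peaks", "forest")

    def test_comparison_table_rows(self, small_ds, small_feats, small_split):
        from lvdlnet.evaluation import MetricsReport

        specs = [
            BaselineSpec("libs_peaks", "svm", seed=0),
            BaselineSpec("libs_intervals", "svm", seed=0),
            BaselineSpec("vnir_intervals", "svm", seed=0),
            BaselineSpec("vnir_full", "svm", seed=0),
        ]
        deep = {
            "DL-LIBS": MetricsReport(0.9, 0.9, 0.9, 0.9),
            "DL-VNIR": MetricsReport(0.95, 0.95, 0.95, 0.95),
            "LVDLNet": MetricsReport(0.99, 0.99, 0.99, 0.99),
        }
        table = comparison_table(specs, deep, small_feats, small_ds.labels, small_split)
        assert len(table) == 7
        for col in ("Acc", "Mac_F", "Mac_P", "Mac_R"):
            assert table[col].between(0, 1).all()


class TestTsne:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        e1 = embed_tsne(X, seed=3)
        e2 = embed_tsne(X, seed=3)
        assert e1.shape == (40, 2)
        np.testing.assert_allclose(e1, e2)

    def test_duplicate_rows_embed_nearby(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (15, 5)), rng.normal(8, 1, (15, 5))])
        X[10] = X[3]  # exact duplicate pair
        emb = embed_tsne(X, seed=0, perplexity=5)
        d_dup = np.linalg.norm(emb[10] - emb[3])
        from scipy.spatial.distance import pdist

        assert d_dup < np.median(pdist(emb))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            embed_tsne(np.zeros((5, 3)), seed=0)
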