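"""SVM validation ladder: metrics, normalization, CV and cross-platform."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from lncolink import (
    ConfusionMatrix,
    ExpressionStudy,
    auc_from_scores,
    average_by_gene,
    confusion_metrics,
    cross_platform_eval,
    crossvalidate_svm,
    generate_validation_rnaseq,
    minmax_normalize,
    train_test_split_eval,
)


def _study(values, n_t, n_n, platform="microarray", features=None):
    f = features or [f"f{i}" for i in range(values.shape[0])]
    s = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionStudy(f, s, values, ["tumor"] * n_t + ["normal"] * n_n, platform)


def _separable(n_feat=10, n_per=10, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(0, 1, size=(n_feat, 2 * n_per))
    v[:, :n_per] += gap
    return _study(v, n_per, n_per)


class TestConfusionMetrics:
    def test_training_matrix_reproduces_published_cells(self):
        rep = confusion_metrics(ConfusionMatrix(tp=7, fp=0, fn=1, tn=8))
        assert rep.sensitivity == pytest.approx(0.875)
        assert rep.specificity == 1.0
        assert rep.precision == 1.0
        assert rep.accuracy == pytest.approx(0.9375)

    def test_rna_test_matrix_reproduces_published_cells(self):
        rep = confusion_metrics(ConfusionMatrix(tp=15, fp=3, fn=6, tn=18))
        assert rep.sensitivity == pytest.approx(15 / 21)
        assert rep.specificity == pytest.approx(18 / 21)
        assert rep.precision == pytest.approx(15 / 18)
        assert rep.accuracy == pytest.approx(33 / 42)

    def test_perfect_classifier(self):
        rep = confusion_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert (rep.sensitivity, rep.specificity, rep.precision, rep.accuracy) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominator_flagged_none(self):
        rep = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=2, tn=3))
        assert rep.precision is None and rep.accuracy == pytest.approx(0.6)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))


class TestAuc:
    def test_scores_equal_labels(self):
        labels = ["tumor"] * 3 + ["normal"] * 3
        assert auc_from_scores([1, 1, 1, 0, 0, 0], labels) == 1.0

    def test_all_scores_tied(self):
        labels = ["tumor"] * 3 + ["normal"] * 3
        assert auc_from_scores([2, 2, 2, 2, 2, 2], labels) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_roc_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        if len(set(y)) < 2:
            y[0] = 1 - y[0]
        labels = ["tumor" if v else "normal" for v in y]
        assert auc_from_scores(scores, labels) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-9
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = ["tumor"] * 15 + ["normal"] * 15
        a = auc_from_scores(scores, labels)
        b = auc_from_scores(np.exp(2 * scores), labels)
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([1, 2], ["tumor", "tumor"])


class TestMatrixPrep:
    def test_minmax_basic_and_idempotent(self):
        s = _study(np.array([[2.0, 4.0, 6.0, 4.0], [1.0, 1.0, 2.0, 1.5]]), 2, 2)
        out = minmax_normalize(s)
        np.testing.assert_allclose(out.values[0], [0, 0.5, 1, 0.5])
        np.testing.assert_allclose(minmax_normalize(out).values, out.values)

    def test_minmax_constant_feature_is_half(self):
        s = _study(np.array([[3.0, 3.0, 3.0, 3.0]]), 2, 2)
        np.testing.assert_allclose(minmax_normalize(s).values, 0.5)

    def test_average_by_gene_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(9, 6))
        probes = [f"p{i}" for i in range(9)]
        gmap = {f"p{i}": f"g{i % 3}" for i in range(9)}
        s = _study(v, 3, 3, features=probes)
        out = average_by_gene(s, gmap)
        for gi in range(3):
            rows = [i for i in range(9) if i % 3 == gi]
            np.testing.assert_allclose(
                out.values[out.feature_ids.index(f"g{gi}")], v[rows].mean(axis=0)
            )

    def test_single_probe_genes_unchanged(self):
        v = np.arange(8.0).reshape(2, 4)
        s = _study(v, 2, 2)
        out = average_by_gene(s, {"f0": "a", "f1": "b"})
        np.testing.assert_array_equal(out.values, v)

    def test_unmapped_probe_raises(self):
        s = _study(np.ones((2, 4)), 2, 2)
        with pytest.raises(KeyError, match="no gene mapping"):
            average_by_gene(s, {"f0": "a"})


class TestCrossValidation:
    def test_separable_data_perfect(self):
        _, score, cm, rep = crossvalidate_svm(_separable(), k=5, seed=0)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_deterministic_fold_assignment(self):
        s = _separable(seed=4)
        p1, s1, *_ = crossvalidate_svm(s, seed=9)
        p2, s2, *_ = crossvalidate_svm(s, seed=9)
        np.testing.assert_array_equal(s1, s2)

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(7)
        aucs = []
        for rep_i in range(30):
            v = rng.normal(size=(8, 24))
            s = _study(v, 12, 12)
            aucs.append(crossvalidate_svm(s, seed=rep_i)[3].auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate_svm(_separable(n_per=4), k=5)


class TestSplitEval:
    def test_split_sizes_and_separable_performance(self):
        out = train_test_split_eval(_separable(n_per=16), train_per_group=8, seed=0)
        cm_tr, rep_tr = out["training"]
        cm_te, rep_te = out["testing"]
        assert cm_tr.total == 16 and cm_te.total == 16
        assert rep_tr.accuracy == 1.0 and rep_te.accuracy == 1.0


class TestCrossPlatform:
    def test_test_copy_of_training_reproduces_resubstitution(self):
        s = _separable(n_feat=6, n_per=8)
        out = cross_platform_eval(s, s, s.feature_ids, seed=0)
        cm, rep = out["blind_test"]
        assert rep.accuracy == 1.0

    def test_missing_gene_raises_with_names(self):
        s = _separable(n_feat=4, n_per=8)
        t = _study(np.ones((2, 6)) + np.random.default_rng(0).normal(0, .1, (2, 6)),
                   3, 3, features=["f0", "f1"])
        with pytest.raises(KeyError, match="f2"):
            cross_platform_eval(s, t, s.feature_ids, seed=0)

    def test_array_train_rnaseq_test_with_signal(self):
        # d=2 signal on a 38-gene panel, 21+21 RPKM test samples
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(38)]
        dirs = {g: ("up" if i % 2 else "down") for i, g in enumerate(genes)}
        logv = rng.normal(6, 1, size=(38, 32))
        for i, g in enumerate(genes):
            logv[i, :16] += 2.0 if dirs[g] == "up" else -2.0
        train = _study(np.exp(logv), 16, 16, features=genes)
        test = generate_validation_rnaseq(
            genes, n_per_group=21, effect_size=2.0, seed=11, directions=dirs
        )
        out = cross_platform_eval(train, test, genes, seed=11)
        _, rep = out["blind_test"]
        assert rep.auc >= 0.8

    def test_label_permuted_test_accuracy_near_half(self):
        rng = np.random.default_rng(13)
        genes = [f"G{i}" for i in range(10)]
        train = _separable(n_feat=10, n_per=10, seed=13)
        train = ExpressionStudy(genes, train.sample_ids, train.values,
                                train.groups, "microarray")
        accs = []
        for i in range(20):
            v = rng.normal(size=(10, 20))
            test = _study(v, 10, 10, features=genes)
            _, rep = cross_platform_eval(train, test, genes, seed=i)["blind_test"]
            accs.append(rep.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.15
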