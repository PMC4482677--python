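"""Confusion matrices, kappa, significance and cross-validation."""

import numpy as np
import pytest
from scipy import stats

from evobci.metrics import (
    ConfusionMatrix,
    accuracy,
    cohens_kappa,
    confusion_matrix,
    crossval,
    detection_and_laterality,
    kappa_significance,
)


def sklearn_kappa(cm_counts):
    """Independent oracle: expand the matrix to label pairs."""
    from sklearn.metrics import cohen_kappa_score

    y_true, y_pred = [], []
    for i, row in enumerate(cm_counts):
        for j, c in enumerate(row):
            y_true += [i] * int(c)
            y_pred += [j] * int(c)
    return cohen_kappa_score(y_true, y_pred,
                             labels=list(range(len(cm_counts))))


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_total_disagreement(self):
        cm = confusion_matrix([0, 1], [1, 0], 2)
        assert np.array_equal(cm.counts, [[0, 1], [1, 0]])

    def test_matches_brute_force_pair_counts(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion_matrix(y_true, y_pred, 4)
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == int(
                    np.sum((y_true == i) & (y_pred == j)))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], 2)


class TestKappa:
    def test_perfect_diagonal_is_one(self):
        assert cohens_kappa(ConfusionMatrix(np.diag([5, 9, 3]))) == 1.0

    def test_independent_marginals_give_zero(self):
        row = np.array([30, 70])
        col = np.array([40, 60])
        counts = np.outer(row, col)  # N = 10000, exactly independent
        assert cohens_kappa(ConfusionMatrix(counts)) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_hand_computed_example(self):
        # p_o = 60/80 = 0.75, p_e = 0.5 -> kappa = 0.5
        cm = ConfusionMatrix(np.array([[30, 10], [10, 30]]))
        assert cohens_kappa(cm) == pytest.approx(0.5)

    def test_agrees_with_independent_oracle(self):
        """1000 random matrices against the sklearn implementation."""
        r = np.random.default_rng(0)
        for _ in range(1000):
            k = int(r.integers(2, 5))
            counts = r.integers(0, 30, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            ours = cohens_kappa(ConfusionMatrix(counts))
            ref = sklearn_kappa(counts)
            if np.isnan(ref):  # degenerate marginals: we define 0
                assert ours == 0.0
            else:
                assert abs(ours - ref) < 1e-12

    def test_invariant_to_class_permutation(self, rng):
        counts = rng.integers(1, 40, size=(3, 3))
        perm = np.array([2, 0, 1])
        permuted = counts[np.ix_(perm, perm)]
        assert cohens_kappa(ConfusionMatrix(counts)) == pytest.approx(
            cohens_kappa(ConfusionMatrix(permuted)))

    def test_accuracy_kappa_chance_identity(self, rng):
        """accuracy == kappa * (1 - p_e) + p_e, exactly."""
        counts = rng.integers(1, 50, size=(4, 4))
        cm = ConfusionMatrix(counts)
        n = counts.sum()
        p_e = counts.sum(1) @ counts.sum(0) / n**2
        assert accuracy(cm) == pytest.approx(
            cohens_kappa(cm) * (1 - p_e) + p_e, abs=1e-12)


class TestKappaSignificance:
    def test_chance_matrix_gives_z_zero(self):
        counts = np.outer([10, 10], [10, 10]) // 2
        z, p = kappa_significance(ConfusionMatrix(counts))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_agreement_is_significant(self):
        cm = ConfusionMatrix(np.array([[300, 100], [100, 300]]))
        z, p = kappa_significance(cm)
        assert p < 0.01

    def test_against_permutation_oracle(self, rng):
        """The z-test p agrees with a label-permutation null within
        Monte-Carlo error."""
        y_true = rng.integers(0, 2, 120)
        y_pred = np.where(rng.random(120) < 0.7, y_true,
                          rng.integers(0, 2, 120))
        cm = confusion_matrix(y_true, y_pred, 2)
        _, p_normal = kappa_significance(cm)
        obs = cohens_kappa(cm)
        perm_stats = []
        for _ in range(10_000):
            perm = rng.permutation(y_pred)
            perm_stats.append(cohens_kappa(confusion_matrix(y_true, perm, 2)))
        p_perm = np.mean(np.abs(perm_stats) >= abs(obs) - 1e-12)
        # both should call this clearly significant, or agree closely
        if p_perm < 1e-3:
            assert p_normal < 1e-2
        else:
            assert abs(p_normal - p_perm) < 0.05

    def test_quadrupling_counts_doubles_z(self):
        counts = np.array([[25, 9], [12, 30]])
        z1, _ = kappa_significance(ConfusionMatrix(counts))
        z4, _ = kappa_significance(ConfusionMatrix(4 * counts))
        assert z4 == pytest.approx(2 * z1)


class TestDetectionAndLaterality:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10]))
        lat, det = detection_and_laterality(cm)
        assert (lat, det) == (1.0, 1.0)

    def test_all_movement_missed(self):
        counts = np.array([[0, 0, 10], [0, 0, 10], [0, 0, 10]])
        lat, det = detection_and_laterality(ConfusionMatrix(counts))
        assert det == 0.0
        assert np.isnan(lat)

    def test_worked_example(self):
        counts = np.array([[40, 5, 5], [4, 41, 5], [3, 2, 45]])
        lat, det = detection_and_laterality(ConfusionMatrix(counts))
        assert det == pytest.approx(0.90)
        assert lat == pytest.approx(81 / 90)

    def test_alternative_conditioning_flag(self):
        counts = np.array([[40, 5, 5], [4, 41, 5], [3, 2, 45]])
        lat, _ = detection_and_laterality(ConfusionMatrix(counts),
                                          condition_on_detected=False)
        assert lat == pytest.approx(81 / 100)


class TestCrossval:
    def _pipeline(self):
        from evobci.mlp import init_network, predict_class, scg_train
        from evobci.mlp import TrainConfig

        def pipeline(train_set, seed):
            X = train_set.flatten() / 10.0
            net = init_network(train_set.input_dim, [6],
                               train_set.n_classes, seed=seed)
            trained, _ = scg_train(net, X, train_set.labels,
                                   TrainConfig(max_iterations=60, seed=seed))

            class P:
                model = trained

                def __call__(self, Xrows):
                    return predict_class(trained, Xrows / 10.0)

            return P()

        return pipeline

    def test_folds_partition_the_data(self, separable_epochs):
        rep = crossval(separable_epochs, self._pipeline(), k=5, seed=0)
        all_idx = np.concatenate(rep.fold_test_indices)
        assert sorted(all_idx) == list(range(separable_epochs.n_epochs))
        assert len(set(all_idx)) == len(all_idx)
        assert len(rep.per_fold) == 5

    def test_separable_data_scores_high(self, separable_epochs):
        rep = crossval(separable_epochs, self._pipeline(), k=5, seed=0)
        assert rep.kappa_mean >= 0.9
        assert rep.p_value < 0.01

    def test_small_class_rejected(self, epochset_factory):
        es = epochset_factory(n_epochs=6, n_classes=2, seed=0)
        with pytest.raises(ValueError, match="k="):
            crossval(es, self._pipeline(), k=5, seed=0)

    def test_report_serializes_to_json(self, separable_epochs, tmp_path):
        import json

        rep = crossval(separable_epochs, self._pipeline(), k=5, seed=0)
        text = rep.to_json(tmp_path / "r.json")
        doc = json.loads(text)
        assert set(doc) >= {"kappa", "accuracy", "confusion", "p_value",
                            "per_fold", "kappa_mean"}
        assert len(doc["per_fold"]) == 5
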