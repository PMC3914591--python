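"""1-NN classification, stratified k-fold CV, and the end-to-end pipeline."""

import numpy as np
import pytest

from dpcawin import (FFPC, PCPEM, LabeledFeatureSet, evaluate_pipeline,
                     kfold_accuracy, predict_1nn)
from dpcawin.classify import _predict_batch
from dpcawin.features import FeatureVector
from dpcawin.synthetic import ClassSpec, DatasetSpec, generate_dataset

from conftest import make_signal


def fset(X, labels, scheme=FFPC):
    return LabeledFeatureSet(X=np.asarray(X, float),
                             labels=np.asarray(labels, object), scheme=scheme)


def fv(values, scheme=FFPC):
    return FeatureVector(values=np.asarray(values, float), scheme=scheme)


class TestPredict1NN:
    def test_nearest_cluster_wins(self):
        train = fset([[0, 0, 0], [10, 10, 10]], ["A", "B"])
        assert predict_1nn(train, fv([1, 0, 0])) == "A"

    def test_exact_match_returns_its_label(self):
        train = fset([[1, 2], [3, 4], [5, 6]], ["A", "B", "C"])
        assert predict_1nn(train, fv([3, 4])) == "B"

    def test_tie_breaks_to_smallest_training_index(self):
        train = fset([[1, 0], [-1, 0]], ["A", "B"])
        assert predict_1nn(train, fv([0, 0])) == "A"

    def test_dimension_mismatch_and_empty_train(self):
        train = fset([[1, 2, 3]], ["A"])
        with pytest.raises(ValueError, match="dimension"):
            predict_1nn(train, fv([1, 2]))
        empty = fset(np.empty((0, 2)), [])
        with pytest.raises(ValueError, match="empty"):
            predict_1nn(empty, fv([1, 2]))

    def test_agrees_with_exhaustive_scan(self, rng):
        """Oracle equivalence: pure-python all-pairs distance scan."""
        for _ in range(5):
            Xtr = rng.standard_normal((200, 3))
            ytr = rng.choice(["A", "B", "C"], size=200)
            Xq = rng.standard_normal((100, 3))
            pred = _predict_batch(Xtr, ytr.astype(object), Xq)
            for i, q in enumerate(Xq):
                best, best_d = None, np.inf
                for j, t in enumerate(Xtr):
                    dd = sum((q[c] - t[c]) ** 2 for c in range(3))
                    if dd < best_d:
                        best, best_d = ytr[j], dd
                assert pred[i] == best


class TestKFold:
    def test_separable_clusters_are_perfect(self, rng):
        X = np.vstack([rng.standard_normal((50, 3)),
                       rng.standard_normal((50, 3)) + 100.0])
        y = ["A"] * 50 + ["B"] * 50
        rep = kfold_accuracy(fset(X, y), k=10, seed=0)
        assert rep.mean_accuracy == 1.0
        assert rep.sd_accuracy == 0.0

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.choice(["A", "B"], size=60)
        r1 = kfold_accuracy(fset(X, y), k=5, seed=42)
        r2 = kfold_accuracy(fset(X, y), k=5, seed=42)
        assert r1.to_json() == r2.to_json()

    def test_chance_level_on_random_labels(self, rng):
        """Random labels on i.i.d. features: accuracy ~ 1/g."""
        means = []
        for rep in range(10):
            X = rng.standard_normal((500, 3))
            y = rng.choice(["A", "B"], size=500)
            means.append(kfold_accuracy(fset(X, y), k=10,
                                        seed=rep).mean_accuracy)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) < 3 * max(se, 1e-3)

    def test_mean_and_sd_recomputable(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.choice(["A", "B"], size=40)
        rep = kfold_accuracy(fset(X, y), k=4, seed=1)
        assert rep.mean_accuracy == pytest.approx(
            np.mean(rep.fold_accuracies))
        assert rep.sd_accuracy == pytest.approx(
            np.std(rep.fold_accuracies, ddof=1))
        total = sum(v["correct"] + v["incorrect"]
                    for v in rep.confusion_totals.values())
        assert total == 40

    def test_small_class_suggests_smaller_k(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = ["A"] * 4 + ["B"] * 2
        with pytest.raises(ValueError, match="smaller k"):
            kfold_accuracy(fset(X, y), k=3, seed=0)

    def test_folds_partition_and_stratify(self, rng):
        from sklearn.model_selection import StratifiedKFold
        X = rng.standard_normal((90, 2))
        y = np.array(["A"] * 60 + ["B"] * 30, dtype=object)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        seen = np.zeros(90, int)
        for _, test_idx in skf.split(X, y.astype(str)):
            seen[test_idx] += 1
            frac = np.mean(y[test_idx] == "A")
            assert abs(frac * len(test_idx) - (60 / 90) * len(test_idx)) <= 1
        assert np.all(seen == 1)


def amplitude_dataset(seed=0, n_per=6, N=2048, amp=5.0):
    """Two classes differing mainly in gain (power ratio ~= amp^2)."""
    fs = 100.0
    classes = [
        ClassSpec("baseline", center_frequency=10.0, bandwidth=4.0,
                  amplitude_scale=1.0, noise_sd=0.5),
        ClassSpec("ictal", center_frequency=4.0, bandwidth=2.0,
                  amplitude_scale=amp, noise_sd=0.5),
    ]
    return generate_dataset(DatasetSpec(classes, n_per, N, fs, seed=seed,
                                        name="amp"))


class TestPipeline:
    def test_amplitude_separated_classes_pcpem(self):
        sigs = amplitude_dataset(seed=7)
        rep = evaluate_pipeline(sigs, 256, PCPEM, k=10, seed=7)
        assert rep.mean_accuracy >= 0.95

    def test_pcpem_at_least_ffpc_on_amplitude_separation(self):
        sigs = amplitude_dataset(seed=7)
        pcpem = evaluate_pipeline(sigs, 256, PCPEM, k=10, seed=7)
        ffpc = evaluate_pipeline(sigs, 256, FFPC, k=10, seed=7)
        assert pcpem.mean_accuracy >= ffpc.mean_accuracy

    def test_single_class_rejected(self, rng):
        sigs = [make_signal(rng.standard_normal(512), label="A",
                            source_id=f"a{i}") for i in range(4)]
        with pytest.raises(ValueError, match="2 groups"):
            evaluate_pipeline(sigs, 128, FFPC, k=2, seed=0)

    def test_report_echoes_configuration(self):
        sigs = amplitude_dataset(seed=3, n_per=3, N=1024)
        rep = evaluate_pipeline(sigs, 128, PCPEM, k=3, seed=3)
        echo = rep.config_echo
        assert echo["window_length"] == 128
        assert echo["scheme"] == PCPEM
        assert echo["d"] == 3
        assert echo["truncation"] == 64
        assert echo["standardize"] is True
        assert len(rep.segment_fold_accuracies) == 3

    def test_fold_pca_independent_of_held_out_windows(self, rng):
        """Perturbing one held-out window leaves that fold's model unchanged."""
        from sklearn.model_selection import StratifiedKFold
        from dpcawin import fit_pca
        from dpcawin.types import WindowMatrix, NONOVERLAPPING
        rows = rng.standard_normal((20, 8))
        labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        train_idx, test_idx = next(iter(skf.split(rows, labels.astype(str))))
        model_a = fit_pca(WindowMatrix(rows=rows[train_idx], window_length=8,
                                       mode=NONOVERLAPPING))
        rows2 = rows.copy()
        rows2[test_idx[0]] += 100.0
        model_b = fit_pca(WindowMatrix(rows=rows2[train_idx], window_length=8,
                                       mode=NONOVERLAPPING))
        np.testing.assert_array_equal(model_a.loadings, model_b.loadings)
        np.testing.assert_array_equal(model_a.mean_vector, model_b.mean_vector)
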