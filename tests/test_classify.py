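import numpy as np
import pytest

import oracles
from orfrate.classify import (
    cosine_distance,
    ifs,
    ifs_fold_ranked,
    jackknife_accuracy,
    nna_predict,
    optimal_feature_set,
)
from orfrate.datatypes import EvalResult, FeatureMatrix, IfsCurve, LabelVector, RankedFeatures
from orfrate.errors import UnknownFeatureError, ValidationError
from orfrate.mrmr import DiscretizationRule
from orfrate.pipeline import featurize


def labels_of(names):
    return LabelVector(np.array(names, dtype=object))


class TestCosineDistance:
    def test_identical_vectors(self):
        assert cosine_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert cosine_distance([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1 - 1 / np.sqrt(2), abs=1e-9
        )

    def test_zero_vector_maximal(self):
        assert cosine_distance([0.0, 0.0], [1.0, 1.0]) == 2.0


class TestNnaPredict:
    def test_exact_training_row(self):
        train = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert nna_predict(train, np.array(["low", "high"]), np.array([0.0, 1.0])) == "high"

    def test_nearer_point_wins(self):
        train = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = np.array(["low", "high"])
        assert nna_predict(train, labels, np.array([0.1, 0.9])) == "high"

    def test_tie_goes_to_earliest_row(self):
        train = np.array([[1.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
        labels = np.array(["low", "low", "high"])
        # rows 0 and 2 are identical directions; earliest index wins
        assert nna_predict(train, labels, np.array([3.0, 3.0])) == "low"

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            d = int(rng.integers(1, 21))
            train = rng.standard_normal((n, d))
            labels = np.where(rng.random(n) < 0.5, "low", "high")
            query = rng.standard_normal(d)
            assert nna_predict(train, labels, query) == oracles.nearest_neighbor_label(
                train.tolist(), labels.tolist(), query.tolist()
            )

    def test_matches_sklearn_on_tie_free_instances(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        for _ in range(20):
            train = rng.standard_normal((30, 5))
            labels = np.where(rng.random(30) < 0.5, "low", "high")
            query = rng.standard_normal(5)
            nn = sklearn.NearestNeighbors(n_neighbors=1, metric="cosine").fit(train)
            idx = int(nn.kneighbors(query[None, :], return_distance=False)[0][0])
            assert nna_predict(train, labels, query) == labels[idx]

    def test_empty_training_set(self):
        with pytest.raises(ValidationError):
            nna_predict(np.empty((0, 2)), np.array([]), np.array([1.0, 0.0]))


class TestJackknife:
    def test_two_tight_clusters_perfect(self, examples):
        matrix = examples["nna_matrix"]
        labels = examples["nna_labels"]
        result = jackknife_accuracy(matrix, labels, scale="none")
        assert result.accuracy == 1.0
        assert (result.correct_low, result.correct_high) == (2, 2)

    def test_identical_points_opposite_labels(self):
        matrix = FeatureMatrix(["a", "b"], ["x"], np.array([[1.0], [1.0]]))
        result = jackknife_accuracy(matrix, labels_of(["low", "high"]), scale="none")
        assert result.accuracy == 0.0

    def test_deterministic(self, examples):
        matrix, labels = examples["nna_matrix"], examples["nna_labels"]
        a = jackknife_accuracy(matrix, labels)
        b = jackknife_accuracy(matrix, labels)
        assert (a.correct_high, a.correct_low) == (b.correct_high, b.correct_low)

    def test_unknown_subset_feature(self, examples):
        with pytest.raises(UnknownFeatureError):
            jackknife_accuracy(
                examples["nna_matrix"], examples["nna_labels"], ["nope"]
            )

    def test_missing_values_are_imputed_not_fatal(self, rng):
        values = rng.standard_normal((10, 3))
        mask = np.zeros_like(values, dtype=bool)
        mask[2, 1] = mask[7, 0] = True
        matrix = FeatureMatrix([f"s{i}" for i in range(10)], list("abc"), values, mask)
        labels = labels_of(["low"] * 5 + ["high"] * 5)
        result = jackknife_accuracy(matrix, labels)
        assert 0.0 <= result.accuracy <= 1.0


class TestIfs:
    @staticmethod
    def toy(rng, n=16, p=6):
        values = rng.standard_normal((n, p))
        labels = labels_of(["low"] * (n // 2) + ["high"] * (n - n // 2))
        values[:, 0] += 1.5 * labels.as_binary()  # plant one informative feature
        names = [f"f{j}" for j in range(p)]
        matrix = FeatureMatrix([f"s{i}" for i in range(n)], names, values)
        ranking = RankedFeatures(names, dict.fromkeys(names, 0.0), dict.fromkeys(names, 0.0))
        return matrix, labels, ranking

    def test_single_feature_curve(self, rng):
        matrix, labels, ranking = self.toy(rng)
        curve = ifs(matrix, labels, ranking, k_max=1)
        assert len(curve.points) == 1
        assert curve.points[0][0] == 1

    def test_curve_lengths_and_range(self, rng):
        matrix, labels, ranking = self.toy(rng)
        curve = ifs(matrix, labels, ranking, k_max=6)
        assert curve.sizes.tolist() == [1, 2, 3, 4, 5, 6]
        assert ((curve.accuracies >= 0) & (curve.accuracies <= 1)).all()

    def test_invalid_k_max(self, rng):
        matrix, labels, ranking = self.toy(rng)
        with pytest.raises(ValidationError):
            ifs(matrix, labels, ranking, k_max=0)

    def test_fold_ranked_variant_runs(self, rng):
        matrix, labels, _ = self.toy(rng, n=14, p=5)
        curve = ifs_fold_ranked(
            matrix, labels, k_max=3, rule=DiscretizationRule(alpha=0.5)
        )
        assert len(curve.points) == 3
        assert ((curve.accuracies >= 0) & (curve.accuracies <= 1)).all()
        assert curve.ranking is None


class TestOptimalFeatureSet:
    @staticmethod
    def curve_from(accs, names):
        ranking = RankedFeatures(names, dict.fromkeys(names, 0.0), dict.fromkeys(names, 0.0))
        points = []
        for k, acc in enumerate(accs, start=1):
            correct = int(round(acc * 10))
            points.append((k, EvalResult(correct, 0, 10, 0)))
        return IfsCurve(points, ranking)

    def test_tie_takes_smaller_k(self):
        curve = self.curve_from([0.6, 0.7, 0.7], ["a", "b", "c"])
        k, acc, names = optimal_feature_set(curve)
        assert (k, acc) == (2, 0.7)
        assert names == ["a", "b"]

    def test_monotone_curve_takes_k_max(self):
        curve = self.curve_from([0.1, 0.2, 0.3], ["a", "b", "c"])
        assert optimal_feature_set(curve)[0] == 3

    def test_single_point(self):
        curve = self.curve_from([0.5], ["a"])
        assert optimal_feature_set(curve) == (1, 0.5, ["a"])


class TestPlantedRecovery:
    def test_planted_features_separate_classes(self, small_dataset):
        """Jackknife on the planted informative features beats chance clearly."""
        ds = small_dataset
        matrix = featurize(ds.records, ds.network, ds.annotations)
        informative = [
            f for f in ds.truth.informative_features if f in matrix.feature_names
        ]
        result = jackknife_accuracy(matrix, ds.truth.true_labels, informative)
        n = matrix.n_samples
        upper_null = 0.5 + 1.96 * np.sqrt(0.25 / n)
        assert result.accuracy > upper_null
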