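import numpy as np
import pytest

import oracles
from orfrate.datatypes import FeatureMatrix, LabelVector
from orfrate.errors import ValidationError
from orfrate.mrmr import (
    DiscretizationRule,
    discretize,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)

BINARY_RULE = DiscretizationRule(alpha=0.0)  # preserves 0/1-valued features


def labels_of(bits):
    return LabelVector(np.array(["high" if b else "low" for b in bits], dtype=object))


class TestDiscretize:
    def test_outlier_lands_in_top_state(self):
        # mean 2.5, population sd 4.33: only the 10 exceeds mean + sd
        states = discretize(np.array([0.0, 0.0, 0.0, 10.0]), DiscretizationRule(alpha=1.0))
        assert states.tolist() == [1, 1, 1, 2]

    def test_constant_vector_all_mid(self):
        states = discretize(np.array([5.0, 5.0, 5.0]))
        assert states.tolist() == [1, 1, 1]

    def test_missing_gets_own_state(self):
        states = discretize(np.array([0.0, 1.0, np.nan, 2.0]), DiscretizationRule(alpha=0.0))
        assert states[2] == 3
        assert set(states.tolist()) <= {0, 1, 2, 3}

    def test_equal_frequency_bins(self):
        states = discretize(
            np.arange(12, dtype=float), DiscretizationRule(scheme="equal_frequency_k", k=3)
        )
        assert np.bincount(states).tolist() == [4, 4, 4]

    def test_bin_relabeling_preserves_mi(self, rng):
        """MI is invariant to monotone relabeling of the discretized states."""
        x = discretize(rng.standard_normal(60))
        y = rng.integers(0, 2, size=60)
        relabeled = np.take(np.array([10, 20, 30, 40]), x)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(relabeled, y), abs=1e-12
        )


class TestMutualInformation:
    def test_perfect_dependence_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_exact_independence_zero(self):
        assert mutual_information([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_symmetry_matches_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(0, 3, size=25)
            y = rng.integers(0, 2, size=25)
            mi = mutual_information(x, y)
            assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
            assert mi == pytest.approx(
                oracles.mutual_information(x.tolist(), y.tolist()), abs=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 2])


class TestRelevanceRedundancy:
    def test_relevance_is_label_mi(self):
        labels = labels_of([0, 0, 1, 1])
        feature = np.array([0, 0, 1, 1])
        assert relevance(feature, labels) == pytest.approx(1.0)
        assert relevance(feature, labels) == mutual_information(
            feature, labels.as_binary()
        )

    def test_self_redundancy_is_entropy(self):
        feature = np.array([0, 0, 1, 1])
        assert redundancy(feature, [feature]) == pytest.approx(1.0)

    def test_redundancy_averages(self, rng):
        feature = rng.integers(0, 2, size=20)
        a = rng.integers(0, 2, size=20)
        b = rng.integers(0, 2, size=20)
        expected = (mutual_information(feature, a) + mutual_information(feature, b)) / 2
        assert redundancy(feature, [a, b]) == pytest.approx(expected)

    def test_empty_selected_is_zero(self):
        assert redundancy(np.array([0, 1]), []) == 0.0


def random_fixture(rng, n_samples, n_features, with_duplicate=False):
    values = rng.integers(0, 2, size=(n_samples, n_features)).astype(float)
    names = [f"f{j}" for j in range(n_features)]
    if with_duplicate:
        values = np.hstack([values, values[:, :1]])
        names = names + ["f0dup"]
    bits = rng.integers(0, 2, size=n_samples)
    if bits.min() == bits.max():
        bits[0] = 1 - bits[0]
    return FeatureMatrix([f"s{i}" for i in range(n_samples)], names, values), labels_of(bits)


class TestMrmrRank:
    def test_first_selected_maximizes_relevance(self, rng):
        matrix, labels = random_fixture(rng, 12, 6)
        ranking = mrmr_rank(matrix, labels, rule=BINARY_RULE)
        best = max(
            matrix.feature_names,
            key=lambda f: (ranking.relevance[f], f),
        )
        assert ranking.relevance[ranking.order[0]] == pytest.approx(
            ranking.relevance[best]
        )

    def test_worked_fixture_matches_exhaustive_oracle(self, examples):
        matrix = examples["mrmr_matrix"]
        labels = examples["mrmr_labels"]
        ranking = mrmr_rank(matrix, labels, rule=BINARY_RULE)
        columns = {
            name: matrix.column(name)[0].tolist() for name in matrix.feature_names
        }
        expected = oracles.mrmr_order(
            columns, labels.as_binary().tolist(), matrix.n_features
        )
        assert ranking.order == expected

    def test_random_fixtures_match_exhaustive_oracle(self, rng):
        """Greedy selection re-derived from scratch each round, 50 fixtures."""
        for trial in range(50):
            n = int(rng.integers(4, 13))
            p = int(rng.integers(2, 9))
            matrix, labels = random_fixture(rng, n, p, with_duplicate=trial % 3 == 0)
            ranking = mrmr_rank(matrix, labels, rule=BINARY_RULE)
            columns = {
                name: matrix.column(name)[0].tolist()
                for name in matrix.feature_names
            }
            expected = oracles.mrmr_order(
                columns, labels.as_binary().tolist(), matrix.n_features
            )
            assert ranking.order == expected, f"fixture {trial}"

    def test_column_order_invariance(self, rng):
        matrix, labels = random_fixture(rng, 10, 6)
        permuted_names = list(np.random.default_rng(3).permutation(matrix.feature_names))
        permuted = matrix.subset(permuted_names)
        assert (
            mrmr_rank(matrix, labels, rule=BINARY_RULE).order
            == mrmr_rank(permuted, labels, rule=BINARY_RULE).order
        )

    def test_top_k_truncates(self, rng):
        matrix, labels = random_fixture(rng, 10, 6)
        ranking = mrmr_rank(matrix, labels, top_k=3, rule=BINARY_RULE)
        assert len(ranking.order) == 3

    def test_invalid_top_k(self, rng):
        matrix, labels = random_fixture(rng, 10, 4)
        with pytest.raises(ValidationError):
            mrmr_rank(matrix, labels, top_k=0)
        with pytest.raises(ValidationError):
            mrmr_rank(matrix, labels, top_k=5)
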