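import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

import genebreadth as gb
from genebreadth.errors import DomainError


def naive_mi(a, b) -> float:
    """Direct plug-in summation over the contingency table (oracle)."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    total = 0.0
    for x in np.unique(a):
        for y_ in np.unique(b):
            pxy = np.mean((a == x) & (b == y_))
            if pxy > 0:
                total += pxy * np.log(pxy / (np.mean(a == x) * np.mean(b == y_)))
    return total


def naive_mrmr(X_disc, y) -> list[int]:
    """Exhaustive greedy oracle: recompute every pairwise MI at every step."""
    n_features = len(X_disc)
    relevance = [naive_mi(y, f) for f in X_disc]
    selected: list[int] = []
    remaining = list(range(n_features))
    while remaining:
        best, best_score = None, -np.inf
        for j in remaining:
            r = (np.mean([naive_mi(X_disc[j], X_disc[s]) for s in selected])
                 if selected else 0.0)
            score = relevance[j] - r
            if score > best_score + 1e-12 or (
                    abs(score - best_score) <= 1e-12
                    and (best is None or j < best)):
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return selected


class TestDiscretize:
    def test_median_split(self):
        np.testing.assert_array_equal(
            gb.discretize([1, 2, 3, 4], 2), [0, 0, 1, 1])

    def test_constant_vector_single_bin(self):
        with pytest.warns(UserWarning):
            labels = gb.discretize([5.0] * 10, 4)
        assert set(labels) == {0}

    def test_equal_frequency_counts(self):
        rng = np.random.default_rng(1)
        labels = gb.discretize(rng.uniform(size=1000), 4)
        counts = np.bincount(labels)
        assert len(counts) == 4
        assert counts.max() - counts.min() <= 1

    def test_deterministic(self):
        v = np.random.default_rng(2).normal(size=100)
        np.testing.assert_array_equal(gb.discretize(v, 4), gb.discretize(v, 4))

    def test_too_many_bins_collapse_with_warning(self):
        with pytest.warns(UserWarning):
            labels = gb.discretize([1.0, 1.0, 2.0, 2.0], 4)
        assert len(set(labels)) == 2


class TestMutualInformation:
    def test_perfectly_dependent_balanced_binary(self):
        assert gb.mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == \
            pytest.approx(np.log(2))

    def test_empirically_independent(self):
        assert gb.mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == \
            pytest.approx(0.0, abs=1e-14)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 4, 60)
        assert gb.mutual_information(a, b) == pytest.approx(
            naive_mi(a, b), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, 200)
        b = (a + rng.integers(0, 2, 200)) % 4
        assert gb.mutual_information(a, b) == pytest.approx(
            mutual_info_score(a, b), abs=1e-12)

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 100)
        b = rng.integers(0, 3, 100)
        mi = gb.mutual_information(a, b)
        assert mi >= 0
        assert mi == pytest.approx(gb.mutual_information(b, a))

    def test_length_mismatch_error(self):
        with pytest.raises(DomainError):
            gb.mutual_information([0, 1], [0, 1, 0])


class TestMrmrRank:
    def test_single_feature(self):
        ranked = gb.mrmr_rank(np.array([[0.1], [0.9], [0.2], [0.8]]),
                              [0, 1, 0, 1])
        assert ranked.order == (0,)

    def test_duplicate_informative_column_demoted(self):
        rng = np.random.default_rng(6)
        n = 100
        y = rng.integers(0, 2, n)
        f1 = y + rng.normal(0, 0.1, n)
        f3 = rng.normal(size=n)
        X = np.column_stack([f1, f1.copy(), f3])
        ranked = gb.mrmr_rank(X, y, n_bins=4)
        assert ranked.order[0] == 0          # most relevant, lowest index
        assert ranked.order[1] == 2          # duplicate demoted by redundancy
        assert ranked.order[2] == 1

    def test_first_feature_maximizes_relevance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 6))
        y = (X[:, 3] > 0).astype(int)
        ranked = gb.mrmr_rank(X, y)
        assert ranked.order[0] == int(np.argmax(ranked.relevance))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 100, 8
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, d))
        X[:, 0] += 1.5 * y
        X[:, 1] += 1.2 * y
        ranked = gb.mrmr_rank(X, y, n_bins=4)
        disc = [gb.discretize(X[:, j], 4) for j in range(d)]
        assert list(ranked.order) == naive_mrmr(disc, y)

    def test_permutation_and_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 12))
        y = rng.integers(0, 2, 50)
        r1 = gb.mrmr_rank(X, y)
        r2 = gb.mrmr_rank(X, y)
        assert sorted(r1.order) == list(range(12))
        assert r1.order == r2.order

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(80, 5))
        y = (X[:, 0] + rng.normal(0, 0.2, 80) > 0.5).astype(int)
        X2 = X.copy()
        X2[:, 0] = np.exp(3 * X2[:, 0])     # strictly monotone, keeps bins
        assert gb.mrmr_rank(X, y).order == gb.mrmr_rank(X2, y).order

    def test_max_rank_depth_prefix_matches_full(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 2, 60)
        full = gb.mrmr_rank(X, y)
        prefix = gb.mrmr_rank(X, y, max_rank_depth=4)
        assert prefix.order[:4] == full.order[:4]
        assert sorted(prefix.order) == list(range(10))

    def test_misaligned_rows_error(self):
        with pytest.raises(DomainError):
            gb.mrmr_rank(np.zeros((5, 2)), [0, 1, 0])

    def test_typed_inputs_align_by_gene_order(self):
        fm, labels = gb.generate_feature_matrix(60, 5, 2, shift=2.5, seed=12)
        ranked = gb.mrmr_rank(fm, labels)
        assert set(ranked.top_ids(2)) == {"T00000", "T00001"}

    def test_round_trip_tsv(self, tmp_path):
        fm, labels = gb.generate_feature_matrix(40, 6, 2, shift=2.0, seed=13)
        ranked = gb.mrmr_rank(fm, labels)
        path = tmp_path / "ranked.tsv"
        ranked.write_tsv(path)
        back = gb.RankedFeatureList.read_tsv(path)
        assert back.order == ranked.order
        assert back.feature_ids == ranked.feature_ids
        np.testing.assert_allclose(back.relevance, ranked.relevance,
                                   atol=1e-9)
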