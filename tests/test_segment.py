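"""DHC-RC segmentation: correlation primitives, split oracle equivalence,
partition invariants, colour assignment and ground-truth mapping."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from lipidseg.segment import (CannotSplitError, SegmentMap,
                              UndefinedCorrelationError, WalkerConfig,
                              _standardize, assign_colors, dhc_rc_segment,
                              map_segments_to_regions, pixel_correlation,
                              resegment, split_objective, split_segment)


def brute_force_best_objective(Z):
    """Independent exhaustive bipartition search (test-local oracle)."""
    n = Z.shape[0]
    best = -np.inf
    for r in range(1, n):
        for combo in itertools.combinations(range(1, n), r):
            b = list(combo)
            a = [i for i in range(n) if i not in combo]
            o = split_objective(Z, a, b)
            if o > best:
                best = o
    return best


class TestPixelCorrelation:
    def test_identical_is_one(self):
        X = np.array([[1.0, 2, 3], [1.0, 2, 3]])
        assert pixel_correlation(X, 0, 1) == pytest.approx(1.0)

    def test_scale_invariance(self):
        X = np.array([[1.0, 2, 3], [2.0, 4, 6]])
        assert pixel_correlation(X, 0, 1) == pytest.approx(1.0)

    def test_orthogonal_centered_is_zero(self):
        X = np.array([[1.0, -1, 1, -1], [1.0, 1, -1, -1]])
        assert pixel_correlation(X, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_raises(self):
        X = np.array([[1.0, 1, 1], [1.0, 2, 3]])
        with pytest.raises(UndefinedCorrelationError):
            pixel_correlation(X, 0, 1)


class TestSplit:
    def test_two_identical_pairs_recovered(self):
        X = np.array([[1, 0, 0, 0.2], [1, 0.01, 0, 0.2],
                      [0, 1, 0.3, 0], [0.01, 1, 0.3, 0]])
        a, b = split_segment(X)
        assert set(a.tolist()) == {0, 1} and set(b.tolist()) == {2, 3}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        X = rng.normal(size=(n, 6))
        a, b = split_segment(X)
        Z = _standardize(X)
        impl = split_objective(Z, a, b)
        assert impl == pytest.approx(brute_force_best_objective(Z), abs=1e-12)

    def test_walker_heuristic_solves_block_structure(self):
        """The rank-compete walker itself (no exact enumeration) finds the
        optimal bipartition on block-structured data."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(m, 0.05, size=(10, 6))
                       for m in ([1, 0, 0, 1, 0, 0], [0, 1, 1, 0, 0, 1])])
        cfg = WalkerConfig(exact_max=0, restarts=4, seed=0)
        a, b = split_segment(X, config=cfg)
        assert set(a.tolist()) == set(range(10))
        assert set(b.tolist()) == set(range(10, 20))

    def test_single_pixel_cannot_split(self):
        with pytest.raises(CannotSplitError):
            split_segment(np.random.default_rng(0).normal(size=(5, 4)), [2])

    def test_determinism(self):
        X = np.random.default_rng(5).normal(size=(40, 8))
        cfg = WalkerConfig(seed=11)
        a1, b1 = split_segment(X, config=cfg)
        a2, b2 = split_segment(X, config=cfg)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)


class TestDHC:
    def test_single_segment_identity(self, block_features):
        X, _ = block_features
        sm = dhc_rc_segment(X, 1)
        assert sm.n_segments == 1 and (sm.labels == 0).all()

    def test_three_blocks_perfectly_recovered(self, block_features):
        X, truth = block_features
        sm = dhc_rc_segment(X, 3, WalkerConfig(seed=0))
        assert adjusted_rand_score(truth, sm.labels) == 1.0

    def test_partition_validity(self, block_features):
        X, _ = block_features
        sm = dhc_rc_segment(X, 5, WalkerConfig(seed=1))
        assert sm.n_segments == 5
        assert len(sm.labels) == len(X)
        assert set(np.unique(sm.labels)) == set(range(5))

    def test_too_many_segments_rejected(self, block_features):
        X, _ = block_features
        with pytest.raises(ValueError):
            dhc_rc_segment(X, len(X) + 1)

    def test_determinism_byte_identical(self, block_features):
        X, _ = block_features
        a = dhc_rc_segment(X, 4, WalkerConfig(seed=2))
        b = dhc_rc_segment(X, 4, WalkerConfig(seed=2))
        assert a.labels.tobytes() == b.labels.tobytes()
        assert np.array_equal(a.colors, b.colors)

    def test_row_permutation_invariance(self, block_features):
        """Permuting the pixel order permutes ids but not the partition."""
        X, _ = block_features
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        a = dhc_rc_segment(X, 3, WalkerConfig(seed=0))
        b = dhc_rc_segment(X[perm], 3, WalkerConfig(seed=0))
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_split_tree_records_history(self, block_features):
        X, _ = block_features
        sm = dhc_rc_segment(X, 3, WalkerConfig(seed=0))
        roots = [n for n in sm.tree if n["parent"] is None]
        assert len(roots) == 1
        leaves = [n for n in sm.tree if not n["children"]]
        assert len(leaves) == 3
        sizes = sum(len(n["pixels"]) for n in leaves)
        assert sizes == len(X)


class TestColors:
    def _map_from_fingerprints(self, F):
        k = len(F)
        return SegmentMap(labels=np.arange(k), coords=np.column_stack(
            [np.zeros(k, int), np.arange(k)]), shape=(1, k), mean_fingerprints=F)

    def _fingerprints_with_gram(self, C, n_features=24, seed=0):
        """Rows whose pairwise Pearson correlations equal the target Gram."""
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(len(C), n_features))
        W -= W.mean(axis=1, keepdims=True)
        Q, _ = np.linalg.qr(W.T)
        B = Q.T[:len(C)]                     # orthonormal zero-mean rows
        L = np.linalg.cholesky(C)
        return L @ B

    def test_two_segments_at_scale_ends(self):
        F = self._fingerprints_with_gram(np.array([[1.0, 0.3], [0.3, 1.0]]))
        colors = assign_colors(self._map_from_fingerprints(F))
        assert set(np.round(colors, 6)) == {0.0, 1.0}

    def test_three_segment_embedding_oracle(self):
        """corr(A,C) minimal -> A and C at the ends; with corr(A,B)=0.9 and
        corr(B,C)=0.2, B sits strictly nearer A's end."""
        C = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        F = self._fingerprints_with_gram(C)
        colors = assign_colors(self._map_from_fingerprints(F))
        assert colors[0] == 0.0 and colors[2] == 1.0
        assert 0 < colors[1] < 0.5
        # 1-D embedding oracle: position = d(A) / (d(A) + d(C))
        assert colors[1] == pytest.approx(0.1 / (0.1 + 0.8), abs=1e-6)

    def test_single_segment_convention(self):
        F = np.array([[1.0, 2.0, 3.0]])
        assert assign_colors(self._map_from_fingerprints(F))[0] == 0.5

    def test_colors_unique(self, block_features):
        X, _ = block_features
        sm = dhc_rc_segment(X, 5, WalkerConfig(seed=3))
        assert len(np.unique(sm.colors)) == 5


class TestResegment:
    def test_select_all_equals_fresh_run(self, block_features):
        X, _ = block_features
        sm = dhc_rc_segment(X, 3, WalkerConfig(seed=4))
        again = resegment(X, sm, list(range(sm.n_segments)), 3, WalkerConfig(seed=4))
        assert adjusted_rand_score(sm.labels, again.labels) == 1.0

    def test_empty_selection_rejected(self, block_features):
        X, _ = block_features
        sm = dhc_rc_segment(X, 3, WalkerConfig(seed=4))
        with pytest.raises(ValueError):
            resegment(X, sm, [], 2)

    def test_single_pixel_selection_cannot_split(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        sm = dhc_rc_segment(X, 6)
        with pytest.raises(CannotSplitError):
            resegment(X, sm, [0], 2)


class TestMapToRegions:
    def _map(self, labels, coords, shape):
        return SegmentMap(labels=np.asarray(labels), coords=np.asarray(coords),
                          shape=shape)

    def test_identical_maps_pure(self):
        raster = np.array([[1, 1, 2, 2]])
        sm = self._map([0, 0, 1, 1], [[0, 0], [0, 1], [0, 2], [0, 3]], (1, 4))
        _, purity, recall = map_segments_to_regions(sm, raster)
        assert (purity["purity"] == 1.0).all()
        assert (recall["recall"] == 1.0).all()

    def test_tie_broken_toward_lower_region_code(self):
        raster = np.array([[1, 2]])
        sm = self._map([0, 0], [[0, 0], [0, 1]], (1, 2))
        assignment, purity, _ = map_segments_to_regions(sm, raster)
        assert assignment[0] == 1
        assert purity["purity"].iloc[0] == 0.5

    def test_grid_mismatch_rejected(self):
        sm = self._map([0], [[0, 0]], (1, 1))
        with pytest.raises(ValueError):
            map_segments_to_regions(sm, np.zeros((2, 2), int))
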