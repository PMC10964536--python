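import itertools

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from habitat_rfa.habitat import (
    BLOCK_FEATURE_NAMES,
    BlockFeatureSet,
    HabitatMap,
    block_features,
    ch_score,
    cluster_habitats,
    habitat_features,
    select_k,
)
from habitat_rfa.imaging import ImageVolume, MaskVolume
from habitat_rfa.radiomics import extract_features


class TestBlockFeatures:
    def test_vector_dimension_is_77(self, preprocessed_pre):
        img, mask = preprocessed_pre
        blocks = block_features(img, mask)
        assert len(BLOCK_FEATURE_NAMES) == 77
        assert blocks.vectors.shape[1] == 77
        assert blocks.n_blocks > 0

    def test_constant_block_degenerate_conventions(self):
        img = ImageVolume(np.full((3, 3, 3), 100.0))
        mask = MaskVolume(np.ones((3, 3, 3), bool))
        blocks = block_features(img, mask)
        vec = dict(zip(BLOCK_FEATURE_NAMES, blocks.vectors[0]))
        assert vec["fo.sd"] == 0.0
        assert vec["fo.skewness"] == 0.0  # defined 0 by convention
        assert vec["hist8.entropy"] == 0.0

    def test_two_valued_block_entropy_closed_form(self):
        # 13 voxels at one extreme, 14 at the other: p = (13/27, 14/27)
        vals = np.array([0.0] * 13 + [255.0] * 14).reshape(3, 3, 3)
        img = ImageVolume(vals)
        mask = MaskVolume(np.ones((3, 3, 3), bool))
        blocks = block_features(img, mask)
        vec = dict(zip(BLOCK_FEATURE_NAMES, blocks.vectors[0]))
        p = np.array([13 / 27, 14 / 27])
        expected = float(-(p * np.log2(p)).sum())
        assert vec["hist8.entropy"] == pytest.approx(expected)
        assert vec["hist16.entropy"] == pytest.approx(expected)

    def test_blocks_require_half_roi_coverage(self):
        # a 2x2x2 ROI never fills half of any 3x3x3 block
        m = np.zeros((6, 6, 6), bool)
        m[0:2, 0:2, 0:2] = True
        with pytest.raises(ValueError):
            block_features(ImageVolume(np.zeros((6, 6, 6))), MaskVolume(m))


class TestCHScore:
    def test_pencil_and_paper_two_cluster_instance(self):
        # 6 points on a line; B and W computed by hand:
        # cluster A {0,1,2} centroid 1, cluster B {10,11,12} centroid 11
        # grand mean 6; B = 3*25 + 3*25 = 150; W = 2 + 2 = 4
        # CH = (150/1) / (4/4) = 150
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert ch_score(x, labels) == pytest.approx(150.0)

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.normal(size=(20, 4))
            labels = rng.integers(0, 3, size=20)
            if len(np.unique(labels)) < 2:
                continue
            assert ch_score(X, labels) == pytest.approx(
                calinski_harabasz_score(X, labels))

    def test_true_labels_beat_random_labels_on_separated_clouds(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        true = np.repeat([0, 1], 10)
        rand = rng.permutation(true)
        if np.array_equal(rand, true):
            rand = np.roll(true, 1)
        assert ch_score(X, true) > ch_score(X, rand)

    def test_zero_within_dispersion_is_infinite(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0], [1.0, 1.0]])
        labels = np.array([0, 0, 1, 1, 2])
        assert ch_score(X, labels) == np.inf

    def test_invalid_inputs_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            ch_score(X, np.zeros(4, dtype=int))  # single cluster
        with pytest.raises(ValueError):
            ch_score(X[:2], np.array([0, 1]))  # n <= k


class TestSelectK:
    def _mixture(self, rng, k, n_per=30, dim=77, sep=2.5):
        """Gaussian-mixture block features: components separated on every
        dimension (a texture shift moves all derived features)."""
        centers = np.zeros((k, dim))
        for i in range(k):
            centers[i] = (i - (k - 1) / 2) * sep
        return np.vstack([rng.normal(c, 1.0, size=(n_per, dim)) for c in centers])

    def test_recovers_three_planted_gaussians(self):
        hits = 0
        for seed in range(20):
            X = self._mixture(np.random.default_rng(seed), 3)
            hits += select_k(X, range(2, 7), seed=seed) == 3
        assert hits >= 19  # >= 95% of 20 seeds

    def test_recovers_two_planted_gaussians(self):
        hits = 0
        for seed in range(10):
            X = self._mixture(np.random.default_rng(seed), 2)
            hits += select_k(X, range(2, 7), seed=seed) == 2
        assert hits >= 9

    def test_single_gaussian_returns_some_k_without_crash(self):
        X = np.random.default_rng(3).normal(size=(40, 10))
        k = select_k(X, range(2, 4), seed=3)
        assert k in (2, 3)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((10, 2)), [], seed=0)


class TestClusterHabitats:
    def test_k1_labels_everything_one(self, preprocessed_pre):
        img, mask = preprocessed_pre
        blocks = block_features(img, mask)
        hmap = cluster_habitats(blocks, 1, seed=0, roi=mask)
        labels_in_roi = hmap.labels[mask.values]
        assert hmap.n_clusters == 1
        assert set(np.unique(labels_in_roi)) <= {0, 1}
        assert (labels_in_roi == 1).sum() > 0

    def test_two_blob_partition_matches_exhaustive_min_sse(self):
        # <= 12 blocks: compare with brute-force minimum-SSE 2-labelling
        rng = np.random.default_rng(5)
        img_vals = np.zeros((6, 6, 3))
        img_vals[:3] = 40 + rng.normal(0, 1.0, size=(3, 6, 3))
        img_vals[3:] = 200 + rng.normal(0, 1.0, size=(3, 6, 3))
        img = ImageVolume(img_vals)
        mask = MaskVolume(np.ones((6, 6, 3), bool))
        blocks = block_features(img, mask)
        assert blocks.n_blocks <= 12
        hmap = cluster_habitats(blocks, 2, seed=0, roi=mask)
        # brute force on standardised vectors
        X = blocks.vectors
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / np.where(sd > 1e-12, sd, 1.0)
        n = len(Xs)
        best_sse, best_assign = np.inf, None
        for bits in itertools.product([0, 1], repeat=n):
            a = np.array(bits)
            if a.min() == a.max():
                continue
            sse = sum(((Xs[a == c] - Xs[a == c].mean(0)) ** 2).sum()
                      for c in (0, 1))
            if sse < best_sse:
                best_sse, best_assign = sse, a
        # compare partitions up to label swap, via block labels
        got = []
        o = blocks.block_origin
        for (bi, bj, bk) in blocks.block_index:
            got.append(hmap.labels[o[0] + bi * 3, o[1] + bj * 3, o[2] + bk * 3])
        got = np.array(got)
        same = (got == got[0]).astype(int)
        ref = (best_assign == best_assign[0]).astype(int)
        np.testing.assert_array_equal(same, ref)

    def test_block_order_permutation_leaves_canonical_map_unchanged(
            self, preprocessed_pre):
        img, mask = preprocessed_pre
        blocks = block_features(img, mask)
        perm = np.random.default_rng(0).permutation(blocks.n_blocks)
        shuffled = BlockFeatureSet(
            block_index=blocks.block_index[perm],
            vectors=blocks.vectors[perm],
            block_origin=blocks.block_origin,
            mean_intensity=blocks.mean_intensity[perm],
        )
        a = cluster_habitats(blocks, 3, seed=11, roi=mask)
        b = cluster_habitats(shuffled, 3, seed=11, roi=mask)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_ordered_by_ascending_intensity(self, preprocessed_pre):
        img, mask = preprocessed_pre
        blocks = block_features(img, mask)
        hmap = cluster_habitats(blocks, 3, seed=2, roi=mask)
        means = []
        for lab in range(1, 4):
            m = hmap.habitat_mask(lab)
            means.append(img.values[m].mean() if m.any() else np.nan)
        finite = [m for m in means if np.isfinite(m)]
        assert finite == sorted(finite)

    def test_k_exceeding_blocks_rejected(self, preprocessed_pre):
        img, mask = preprocessed_pre
        blocks = block_features(img, mask)
        with pytest.raises(ValueError):
            cluster_habitats(blocks, blocks.n_blocks + 1, seed=0, roi=mask)


class TestHabitatFeatures:
    def test_single_habitat_equals_whole_roi_features(self, preprocessed_pre):
        img, mask = preprocessed_pre
        hmap = HabitatMap(labels=mask.values.astype(np.int64), n_clusters=1)
        feats = habitat_features(img, hmap)
        whole = extract_features(img, mask)
        for name, v in whole.items():
            assert feats[f"habitat1.{name}"] == pytest.approx(v)
            assert feats[f"habitatmean.{name}"] == pytest.approx(v)

    def test_across_habitat_mean_is_arithmetic(self):
        vals = np.zeros((6, 3, 3))
        vals[:3] = 10.0
        vals[3:] = 30.0
        img = ImageVolume(vals)
        labels = np.zeros((6, 3, 3), dtype=np.int64)
        labels[:3] = 1
        labels[3:] = 2
        hmap = HabitatMap(labels=labels, n_clusters=2)
        feats = habitat_features(img, hmap)
        assert feats["habitat1.firstorder.mean"] == pytest.approx(10.0)
        assert feats["habitat2.firstorder.mean"] == pytest.approx(30.0)
        assert feats["habitatmean.firstorder.mean"] == pytest.approx(20.0)

    def test_tiny_habitat_marked_missing_and_excluded_from_mean(self):
        vals = np.full((5, 3, 3), 10.0)
        labels = np.zeros((5, 3, 3), dtype=np.int64)
        labels[:4] = 1
        labels[4, 0, 0] = 2  # 1 voxel < 8-voxel minimum
        hmap = HabitatMap(labels=labels, n_clusters=2)
        feats = habitat_features(img := ImageVolume(vals), hmap)
        assert np.isnan(feats["habitat2.firstorder.mean"])
        assert feats["habitatmean.firstorder.mean"] == pytest.approx(10.0)
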