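import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asd_swnet import (AugmentationConfig, EigenStructure, ErosWeights,
                       augment, covariance_eigen, eros_distance,
                       eros_similarity, eros_weights, interpolate, knn_eros,
                       spca_similarity)
from asd_swnet.data_io import Dataset, PhenotypeTable, RoiTimeSeries
from asd_swnet.eros_augment import is_synthetic
from asd_swnet.errors import ConfigError, DimensionError, NumericalError

from conftest import random_eigenstructure


def eros_similarity_oracle(a, b, w):
    """Direct summation: sum_i w_i |a_i . b_i|."""
    total = 0.0
    for i in range(a.n):
        total += w.omega[i] * abs(float(
            np.dot(a.eigenvectors[:, i], b.eigenvectors[:, i])))
    return total


class TestCovarianceEigen:
    def test_identity_covariance(self, rng):
        ts = RoiTimeSeries("s", rng.standard_normal((4000, 4)))
        eig = covariance_eigen(ts)
        tol = 3.0 / np.sqrt(4000)
        np.testing.assert_allclose(eig.eigenvalues, 1.0, atol=tol * 3)

    def test_duplicated_roi_gives_zero_eigenvalue(self, rng):
        col = rng.standard_normal(50)
        ts = RoiTimeSeries("s", np.column_stack([col, col,
                                                 rng.standard_normal(50)]))
        eig = covariance_eigen(ts)
        assert eig.eigenvalues[-1] == pytest.approx(0.0, abs=1e-8)

    def test_recomposition(self, rng):
        x = rng.standard_normal((40, 5))
        eig = covariance_eigen(RoiTimeSeries("s", x))
        cov = np.cov(x, rowvar=False)
        recomposed = (eig.eigenvectors * eig.eigenvalues) @ eig.eigenvectors.T
        np.testing.assert_allclose(recomposed, cov, atol=1e-8)

    def test_constant_series_errors(self):
        ts = RoiTimeSeries("s", np.ones((10, 3)))
        with pytest.raises(NumericalError):
            covariance_eigen(ts)

    def test_descending_and_orthonormal(self, rng):
        eig = covariance_eigen(
            RoiTimeSeries("s", rng.standard_normal((30, 6))))
        assert np.all(np.diff(eig.eigenvalues) <= 1e-12)
        gram = eig.eigenvectors.T @ eig.eigenvectors
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)


class TestErosWeights:
    def test_single_subject_direct_normalization(self, rng):
        eig = EigenStructure("s", np.eye(2), np.array([3.0, 1.0]))
        w = eros_weights([eig])
        np.testing.assert_allclose(w.omega, [0.75, 0.25])

    def test_mean_then_renormalize(self):
        # normalized spectra (0.75, 0.25) and (0.25, 0.75):
        # mean (0.5, 0.5), already summing to 1
        w = eros_weights([np.array([3.0, 1.0]), np.array([1.0, 3.0])])
        np.testing.assert_allclose(w.omega, [0.5, 0.5])

    def test_sums_to_one(self, rng):
        eigs = [random_eigenstructure(5, rng, f"s{i}") for i in range(4)]
        w = eros_weights(eigs)
        assert w.omega.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w.omega >= 0)

    def test_empty_list_errors(self):
        with pytest.raises(ConfigError):
            eros_weights([])

    def test_max_min_aggregations(self, rng):
        eigs = [random_eigenstructure(4, rng, f"s{i}") for i in range(3)]
        for agg in ("max", "min"):
            w = eros_weights(eigs, aggregate=agg)
            assert w.omega.sum() == pytest.approx(1.0)


class TestErosSimilarityDistance:
    def test_self_similarity_one_distance_zero(self, rng):
        a = random_eigenstructure(6, rng)
        w = eros_weights([a])
        assert eros_similarity(a, a, w) == pytest.approx(1.0)
        assert eros_distance(a, a, w) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_pairs_give_zero_similarity(self):
        # paired eigenvectors orthogonal: a_i = e_{2i}, b_i = e_{2i+1}
        n = 4
        va = np.eye(n)[:, [0, 1, 2, 3]]
        vb = np.eye(n)[:, [1, 0, 3, 2]]
        a = EigenStructure("a", va, np.ones(n))
        b = EigenStructure("b", vb, np.ones(n))
        w = ErosWeights(np.full(n, 0.25))
        assert eros_similarity(a, b, w) == pytest.approx(0.0)
        assert eros_distance(a, b, w) == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            a = random_eigenstructure(n, rng, "a")
            b = random_eigenstructure(n, rng, "b")
            w = eros_weights([a, b])
            assert eros_similarity(a, b, w) == pytest.approx(
                eros_similarity_oracle(a, b, w), abs=1e-12)

    def test_symmetry(self, rng):
        a = random_eigenstructure(5, rng, "a")
        b = random_eigenstructure(5, rng, "b")
        w = eros_weights([a, b])
        assert eros_distance(a, b, w) == pytest.approx(
            eros_distance(b, a, w), abs=1e-12)

    def test_dimension_mismatch(self, rng):
        a = random_eigenstructure(4, rng)
        b = random_eigenstructure(5, rng)
        w = eros_weights([a])
        with pytest.raises(DimensionError):
            eros_similarity(a, b, w)

    @given(n=st.integers(2, 12), seed=st.integers(0, 100_000))
    @settings(max_examples=60, deadline=None)
    def test_ranges(self, n, seed):
        rng = np.random.default_rng(seed)
        a = random_eigenstructure(n, rng, "a")
        b = random_eigenstructure(n, rng, "b")
        w = eros_weights([a, b])
        s = eros_similarity(a, b, w)
        assert 0.0 <= s <= 1.0 + 1e-12
        d = eros_distance(a, b, w)
        assert 0.0 <= d <= np.sqrt(2.0) + 1e-12


class TestSpcaSimilarity:
    def test_self_full_rank_equals_n(self, rng):
        a = random_eigenstructure(5, rng)
        assert spca_similarity(a, a, 5) == pytest.approx(5.0)

    def test_self_one_pivot(self, rng):
        a = random_eigenstructure(5, rng)
        assert spca_similarity(a, a, 1) == pytest.approx(1.0)

    def test_brute_force(self, rng):
        a = random_eigenstructure(6, rng, "a")
        b = random_eigenstructure(6, rng, "b")
        z = 2
        expected = sum(
            float(np.dot(a.eigenvectors[:, i], b.eigenvectors[:, j])) ** 2
            for i in range(z) for j in range(z))
        assert spca_similarity(a, b, z) == pytest.approx(expected, abs=1e-12)

    def test_z_too_large(self, rng):
        a = random_eigenstructure(4, rng)
        with pytest.raises(DimensionError):
            spca_similarity(a, a, 5)


def toy_dataset(rng, n_subjects=8, n_rois=4, T=30, with_features=True):
    ids = tuple(f"s{i:02d}" for i in range(n_subjects))
    labels = np.array([i % 2 for i in range(n_subjects)])
    pheno = PhenotypeTable(ids, labels, tuple("siteA" for _ in ids))
    series = {s: RoiTimeSeries(s, rng.standard_normal((T, n_rois)))
              for s in ids}
    features = ({s: rng.standard_normal(6) for s in ids}
                if with_features else None)
    return Dataset(phenotypes=pheno, series=series, features=features)


class TestKnnEros:
    def test_exact_copy_ranked_first(self, rng):
        ds = toy_dataset(rng, n_subjects=3)
        # make s02 an exact copy of s00 (same class: labels 0,1,0)
        ds.series["s02"] = RoiTimeSeries("s02", ds.series["s00"].values.copy())
        eigs = {s: covariance_eigen(ts) for s, ts in ds.series.items()}
        w = eros_weights(list(eigs.values()))
        out = knn_eros("s00", ds, w, k=1, same_class_only=True, eigs=eigs)
        assert out == ["s02"]
        assert eros_distance(eigs["s00"], eigs["s02"], w) == pytest.approx(0.0, abs=1e-7)

    def test_k_equals_pool_returns_sorted_pool(self, rng):
        ds = toy_dataset(rng, n_subjects=8)
        eigs = {s: covariance_eigen(ts) for s, ts in ds.series.items()}
        w = eros_weights(list(eigs.values()))
        out = knn_eros("s00", ds, w, k=3, same_class_only=True, eigs=eigs)
        dists = [eros_distance(eigs["s00"], eigs[s], w) for s in out]
        assert dists == sorted(dists)
        assert len(out) == 3

    def test_matches_exhaustive_sort(self, rng):
        ds = toy_dataset(rng, n_subjects=8)
        eigs = {s: covariance_eigen(ts) for s, ts in ds.series.items()}
        w = eros_weights(list(eigs.values()))
        for query in ds.phenotypes.subject_ids:
            got = knn_eros(query, ds, w, k=2, same_class_only=False,
                           eigs=eigs)
            pool = [s for s in ds.phenotypes.subject_ids if s != query]
            expected = sorted(
                pool, key=lambda s: (eros_distance(eigs[query], eigs[s], w),
                                     s))[:2]
            assert got == expected

    def test_pool_too_small(self, rng):
        ds = toy_dataset(rng, n_subjects=4)
        eigs = {s: covariance_eigen(ts) for s, ts in ds.series.items()}
        w = eros_weights(list(eigs.values()))
        with pytest.raises(ConfigError):
            knn_eros("s00", ds, w, k=3, same_class_only=True, eigs=eigs)


class TestInterpolate:
    def test_phi_zero_returns_x(self):
        x = np.array([1.0, 2.0])
        np.testing.assert_array_equal(interpolate(x, np.array([5.0, 6.0]),
                                                  0.0), x)

    def test_phi_one_returns_neighbor(self):
        xn = np.array([5.0, 6.0])
        np.testing.assert_array_equal(
            interpolate(np.array([1.0, 2.0]), xn, 1.0), xn)

    def test_midpoint(self):
        out = interpolate(np.array([0.0, 0.0]), np.array([2.0, 4.0]), 0.5)
        np.testing.assert_array_equal(out, [1.0, 2.0])

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            interpolate(np.zeros(2), np.zeros(3), 0.5)

    def test_phi_out_of_range(self):
        with pytest.raises(ConfigError):
            interpolate(np.zeros(2), np.ones(2), 1.5)


class TestAugment:
    def test_gamma_two_doubles(self, rng):
        ds = toy_dataset(rng, n_subjects=20)
        out = augment(ds, AugmentationConfig(k=3, gamma=2, seed=0))
        assert len(out.phenotypes) == 40
        n_syn = sum(is_synthetic(s) for s in out.phenotypes.subject_ids)
        assert n_syn == 20

    def test_gamma_one_identity(self, rng):
        ds = toy_dataset(rng)
        out = augment(ds, AugmentationConfig(k=2, gamma=1, seed=0))
        assert out.phenotypes == ds.phenotypes
        assert out.features is ds.features

    def test_convexity_hull_and_label_inheritance(self, rng):
        ds = toy_dataset(rng, n_subjects=12)
        out = augment(ds, AugmentationConfig(k=3, gamma=3, seed=5))
        for sid in out.phenotypes.subject_ids:
            if not is_synthetic(sid):
                continue
            source = sid.split("__aug")[0]
            vec = out.features[sid]
            assert out.phenotypes.label_of(sid) == ds.phenotypes.label_of(source)
            assert out.phenotypes.site_of(sid) == ds.phenotypes.site_of(source)
            # hull oracle: within interval of source and SOME same-class
            # neighbour, componentwise
            src_vec = ds.features[source]
            candidates = [s for s in ds.phenotypes.subject_ids
                          if s != source and ds.phenotypes.label_of(s)
                          == ds.phenotypes.label_of(source)]
            in_hull = any(
                np.all(vec >= np.minimum(src_vec, ds.features[c]) - 1e-12)
                and np.all(vec <= np.maximum(src_vec, ds.features[c]) + 1e-12)
                for c in candidates)
            assert in_hull

    def test_class_proportions_preserved(self, rng):
        ds = toy_dataset(rng, n_subjects=14)
        before = ds.phenotypes.labels.mean()
        for gamma in (2, 3, 4):
            out = augment(ds, AugmentationConfig(k=3, gamma=gamma, seed=1))
            assert out.phenotypes.labels.mean() == pytest.approx(before)
            assert len(out.phenotypes) == gamma * 14

    def test_deterministic_under_seed(self, rng):
        ds = toy_dataset(rng, n_subjects=10)
        out1 = augment(ds, AugmentationConfig(k=3, gamma=2, seed=9))
        out2 = augment(ds, AugmentationConfig(k=3, gamma=2, seed=9))
        assert out1.phenotypes == out2.phenotypes
        for sid in out1.features:
            np.testing.assert_array_equal(out1.features[sid],
                                          out2.features[sid])

    def test_missing_features_errors(self, rng):
        ds = toy_dataset(rng, with_features=False)
        with pytest.raises(ConfigError):
            augment(ds, AugmentationConfig(k=2, gamma=2, seed=0))

    def test_pool_too_small_errors(self, rng):
        ds = toy_dataset(rng, n_subjects=6)  # 3 per class
        with pytest.raises(ConfigError):
            augment(ds, AugmentationConfig(k=3, gamma=2, seed=0))
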