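"""Receptor profiles, Euclidean distance views and SNF fusion tests."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ddifuse.biosim import (FusedSimilarity, ReceptorProfile,
                            SimilarityNetworkFusion, SimilarityView,
                            affinity_from_distance, bio_feature,
                            build_profiles, euclid_distance, snf_fuse)
from ddifuse.biosim import _p_normalize


class TestProfiles:
    def test_direct_incidence(self):
        profs = build_profiles([("A", "t1", "target"), ("B", "t1", "target"),
                                ("B", "t2", "target")], ["A", "B", "C"])
        assert len(profs) == 1
        assert np.array_equal(profs[0].matrix,
                              [[1, 0], [1, 1], [0, 0]])

    def test_empty_type_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no receptors"):
            profs = build_profiles([("A", "t1", "target")], ["A", "B"],
                                   types=["target", "carrier"])
        assert [p.function_type for p in profs] == ["target"]

    def test_duplicate_association_idempotent(self):
        profs = build_profiles([("A", "t1", "x")] * 3, ["A"])
        assert profs[0].matrix.sum() == 1

    def test_unknown_drug_listed(self):
        with pytest.raises(ValueError, match="Z1.*Z2|Z"):
            build_profiles([("Z1", "t", "x"), ("Z2", "t", "x")], ["A"])


class TestEuclid:
    def test_three_four_five(self):
        p = ReceptorProfile("t", ["a", "b"], ["r1", "r2"],
                            np.array([[0, 0], [3, 4]]))
        assert euclid_distance(p)[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        p = ReceptorProfile("t", ["a", "b"], ["r"] * 3,
                            np.array([[1, 0, 1], [1, 0, 1]]))
        assert euclid_distance(p)[0, 1] == 0.0

    def test_binary_rows_sqrt_hamming(self):
        a = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        b = a.copy()
        b[[0, 3, 5]] ^= 1   # differ in 3 positions
        p = ReceptorProfile("t", ["a", "b"], [f"r{i}" for i in range(8)],
                            np.vstack([a, b]))
        assert euclid_distance(p)[0, 1] == pytest.approx(np.sqrt(3))

    def test_metric_properties_random_binary(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            M = rng.integers(0, 2, size=(10, 8))
            p = ReceptorProfile("t", [str(i) for i in range(10)],
                                [str(j) for j in range(8)], M)
            D = euclid_distance(p)
            assert np.allclose(D, D.T)
            assert np.all(np.diag(D) == 0)
            assert np.all(D >= 0)
            # identity of indiscernibles on distinct rows
            for i in range(10):
                for j in range(i + 1, 10):
                    if not np.array_equal(M[i], M[j]):
                        assert D[i, j] > 0
            # triangle inequality, exhaustively
            for i in range(10):
                for j in range(10):
                    for k in range(10):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestSNF:
    @pytest.fixture
    def dist6(self):
        rng = np.random.default_rng(3)
        return squareform(pdist(rng.random((6, 4))))

    def test_identical_views_fixed_point(self, dist6):
        f1 = snf_fuse([SimilarityView("a", dist6.copy())], K=3, T=10)
        f3 = snf_fuse([SimilarityView(c, dist6.copy()) for c in "abc"],
                      K=3, T=10)
        assert np.abs(f1.matrix - f3.matrix).max() < 1e-8

    def test_single_view_runs(self, dist6):
        f = snf_fuse([SimilarityView("a", dist6.copy())], K=3, T=5)
        assert f.views_used == 1
        assert np.allclose(f.matrix, f.matrix.T)

    def test_block_structure_contrast(self):
        rng = np.random.default_rng(1)
        M = np.zeros((10, 8))
        M[:5, :4] = 1
        M[5:, 4:] = 1
        views = []
        for _ in range(2):
            noisy = np.abs(M - (rng.random((10, 8)) < 0.1))
            views.append(SimilarityView("v", squareform(pdist(noisy))))
        F = snf_fuse(views, K=3, T=10).matrix
        within = (F[:5, :5].sum() + F[5:, 5:].sum()
                  - np.trace(F)) / (2 * 5 * 4)
        between = F[:5, 5:].mean()
        assert within > between

    def test_symmetry_nonneg_and_row_sums(self, dist6):
        W = affinity_from_distance(dist6, K=3, mu=0.5)
        P = _p_normalize(W)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
        F = snf_fuse([SimilarityView("a", dist6.copy()),
                      SimilarityView("b", dist6.T.copy())], K=3, T=7).matrix
        assert np.allclose(F, F.T)
        assert np.all(F >= 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        D1 = squareform(pdist(rng.random((9, 5))))
        D2 = squareform(pdist(rng.random((9, 5))))
        F = snf_fuse([SimilarityView("a", D1.copy()),
                      SimilarityView("b", D2.copy())], K=4, T=8).matrix
        perm = rng.permutation(9)
        inv = np.argsort(perm)
        Fp = snf_fuse([SimilarityView("a", D1[np.ix_(perm, perm)]),
                       SimilarityView("b", D2[np.ix_(perm, perm)])],
                      K=4, T=8).matrix
        assert np.allclose(Fp[np.ix_(inv, inv)], F, atol=1e-12)

    def test_zero_views_error_and_k_clamp(self, dist6):
        with pytest.raises(ValueError, match="at least one view"):
            snf_fuse([])
        with pytest.warns(UserWarning, match="clamped"):
            snf_fuse([SimilarityView("a", dist6.copy())], K=10, T=2)


class TestBioFeature:
    @pytest.fixture
    def fused(self):
        M = np.array([[0.5, 0.3, 0.2], [0.3, 0.5, 0.1], [0.2, 0.1, 0.5]])
        return FusedSimilarity(matrix=M, drugs=["A", "B", "C"],
                               views_used=2)

    def test_row_extraction(self, fused):
        assert np.array_equal(bio_feature(fused, "B"), fused.matrix[1])

    def test_symmetry(self, fused):
        assert (bio_feature(fused, "A")[2] == bio_feature(fused, "C")[0])

    def test_unknown_drug_zero_with_warning(self, fused):
        with pytest.warns(UserWarning, match="not in fused"):
            v = bio_feature(fused, "Z")
        assert np.all(v == 0) and v.shape == (3,)


def test_estimator_wrapper_roundtrip():
    rng = np.random.default_rng(0)
    profs = build_profiles(
        [(f"D{i}", f"r{j}", "target") for i in range(6)
         for j in range(4) if rng.random() < 0.5],
        [f"D{i}" for i in range(6)])
    est = SimilarityNetworkFusion(K=3, T=5).fit(profs)
    rows = est.transform(["D0", "D3"])
    assert rows.shape == (2, 6)
    assert np.array_equal(rows[0], est.fused_.matrix[0])
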