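import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

import bactexture as bt
from bactexture.fisher import FisherVectorEncoder, normalize_fv


def naive_fv(gmm, X):
    """Per-descriptor / per-component double loop, no normalization.

    Independent oracle for the vectorized encoder: explicit posterior
    densities and statistic sums.
    """
    n, d = X.shape
    K = gmm.n_components
    first = np.zeros((K, d))
    second = np.zeros((K, d))
    for x in X:
        dens = np.array([
            gmm.weights[k]
            * np.exp(-0.5 * np.sum((x - gmm.means[k]) ** 2 / gmm.variances[k]))
            / np.sqrt((2 * np.pi) ** d * np.prod(gmm.variances[k]))
            for k in range(K)
        ])
        gamma = dens / dens.sum()
        for k in range(K):
            sig = np.sqrt(gmm.variances[k])
            first[k] += gamma[k] * (x - gmm.means[k]) / sig
            second[k] += gamma[k] * ((x - gmm.means[k]) ** 2 / gmm.variances[k] - 1)
    for k in range(K):
        first[k] /= n * np.sqrt(gmm.weights[k])
        second[k] /= n * np.sqrt(2 * gmm.weights[k])
    return np.concatenate([first.ravel(), second.ravel()])


def random_gmm(rng, K, d):
    w = rng.random(K) + 0.2
    return bt.GmmModel(weights=w / w.sum(),
                       means=rng.normal(0, 2, size=(K, d)),
                       variances=rng.random((K, d)) + 0.3)


def sample_from_gmm(gmm, n, rng):
    comps = rng.choice(gmm.n_components, size=n, p=gmm.weights)
    return gmm.means[comps] + rng.normal(size=(n, gmm.dim)) * np.sqrt(gmm.variances[comps])


class TestPca:
    def test_line_in_3d_recovered(self):
        rng = np.random.default_rng(0)
        direction = np.array([1.0, 2.0, -1.0]) / np.linalg.norm([1, 2, -1])
        X = np.outer(rng.normal(size=200), direction) + 5.0
        pca = bt.fit_pca(X, 1)
        recon = pca.project(X) @ pca.basis.T + pca.mean
        assert np.allclose(recon, X, atol=1e-8)

    def test_full_dim_preserves_pairwise_distances(self, rng):
        X = rng.normal(size=(50, 6))
        pca = bt.fit_pca(X, 6)
        P = pca.project(X)
        d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        d_proj = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
        assert np.allclose(d_orig, d_proj, atol=1e-6)

    def test_projected_variance_matches_eigenvalue_oracle(self, rng):
        X = rng.normal(size=(500, 8)) @ rng.normal(size=(8, 8))
        pca = bt.fit_pca(X, 3)
        proj_var = pca.project(X).var(axis=0, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.allclose(proj_var, eigvals[:3], rtol=1e-8)

    def test_basis_orthonormal_and_sign_deterministic(self, rng):
        X = rng.normal(size=(100, 5))
        pca = bt.fit_pca(X, 4)
        assert np.allclose(pca.basis.T @ pca.basis, np.eye(4), atol=1e-6)
        for j in range(4):
            col = pca.basis[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_overlarge_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            bt.fit_pca(rng.normal(size=(30, 4)), 5)


class TestGmmFit:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(2.0, 1.5, size=(200, 3))
        gmm = bt.fit_gmm(X, 1, seed=0)
        assert np.allclose(gmm.means[0], X.mean(axis=0), atol=1e-8)
        assert np.allclose(gmm.variances[0], X.var(axis=0), atol=1e-8)
        assert gmm.weights[0] == pytest.approx(1.0)

    def test_well_separated_means_recovered(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0.0, 0.0], [15.0, 0.0], [0.0, 15.0]])
        X = np.concatenate([c + rng.normal(0, 1.0, size=(1000, 2)) for c in centers])
        gmm = bt.fit_gmm(X, 3, seed=1)
        # best permutation match within 0.1 sigma
        for c in centers:
            dist = np.linalg.norm(gmm.means - c, axis=1).min()
            assert dist < 0.1

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(9)
        X = np.concatenate([rng.normal(0, 1, (150, 2)), rng.normal(4, 0.5, (150, 2))])
        gmm = bt.fit_gmm(X, 4, seed=2)
        ll = gmm.log_likelihood_path
        assert len(ll) >= 2
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))

    def test_seeded_fit_bit_reproducible(self, rng):
        X = rng.normal(size=(300, 4))
        a = bt.fit_gmm(X, 3, seed=7)
        b = bt.fit_gmm(X, 3, seed=7)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.variances, b.variances)
        assert np.array_equal(a.weights, b.weights)

    def test_agrees_with_reference_em_on_separated_data(self):
        """Cross-check against an independent EM implementation."""
        rng = np.random.default_rng(3)
        centers = np.array([[0.0, 0.0], [12.0, 12.0]])
        X = np.concatenate([c + rng.normal(0, 1, size=(250, 2)) for c in centers])
        ours = bt.fit_gmm(X, 2, seed=0)
        ref = GaussianMixture(2, covariance_type="diag", random_state=0).fit(X)
        order_o = np.argsort(ours.means[:, 0])
        order_r = np.argsort(ref.means_[:, 0])
        assert np.allclose(ours.means[order_o], ref.means_[order_r], atol=0.05)
        assert np.allclose(ours.weights[order_o], ref.weights_[order_r], atol=0.01)

    def test_too_few_descriptors_rejected(self, rng):
        with pytest.raises(ValueError):
            bt.fit_gmm(rng.normal(size=(25, 2)), 3, seed=0)


class TestSoftAssign:
    def test_single_component_posterior_is_one(self):
        gmm = bt.GmmModel(weights=[1.0], means=[[0.0, 0.0]], variances=[[1.0, 1.0]])
        assert bt.soft_assign(gmm, np.array([3.0, -1.0])) == pytest.approx([1.0])

    def test_descriptor_at_mean_of_separated_component(self, rng):
        gmm = bt.GmmModel(weights=[1 / 3] * 3,
                          means=[[0, 0], [20, 0], [0, 20]],
                          variances=np.ones((3, 2)))
        gamma = bt.soft_assign(gmm, np.array([20.0, 0.0]))
        assert gamma[1] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        gmm = random_gmm(rng, 5, 4)
        X = rng.normal(0, 3, size=(50, 4))
        gamma = bt.soft_assign(gmm, X)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_extreme_descriptor_no_underflow(self, rng):
        gmm = random_gmm(rng, 3, 2)
        gamma = bt.soft_assign(gmm, np.array([1e4, -1e4]))
        assert np.all(np.isfinite(gamma))
        assert gamma.sum() == pytest.approx(1.0, abs=1e-10)


class TestEncodeFv:
    def test_output_length_is_2kd(self, rng):
        gmm = random_gmm(rng, 4, 16)
        fv = bt.encode_fv(gmm, rng.normal(size=(30, 16)))
        assert len(fv.values) == 2 * 4 * 16 == 128

    @pytest.mark.parametrize("case_seed", range(20))
    def test_matches_naive_double_loop(self, case_seed):
        rng = np.random.default_rng(case_seed)
        K = int(rng.integers(1, 5))
        d = int(rng.integers(2, 17))
        n = int(rng.integers(5, 201))
        gmm = random_gmm(rng, K, d)
        X = rng.normal(0, 2, size=(n, d))
        got = bt.encode_fv(gmm, X, normalization="off", posterior_floor=0).values
        assert np.allclose(got, naive_fv(gmm, X), atol=1e-8)

    def test_single_descriptor_single_component_closed_form(self):
        gmm = bt.GmmModel(weights=[1.0], means=[[1.0, -1.0]],
                          variances=[[4.0, 0.25]])
        x = np.array([[3.0, 0.0]])
        fv = bt.encode_fv(gmm, x, normalization="off", posterior_floor=0).values
        sig = np.array([2.0, 0.5])
        expected_first = (x[0] - gmm.means[0]) / sig
        expected_second = ((x[0] - gmm.means[0]) ** 2 / sig**2 - 1) / np.sqrt(2)
        assert np.allclose(fv, np.concatenate([expected_first, expected_second]),
                           atol=1e-10)

    def test_expected_score_of_generating_model_is_zero(self):
        rng = np.random.default_rng(17)
        gmm = random_gmm(rng, 3, 8)
        n = 50_000
        X = sample_from_gmm(gmm, n, rng)
        fv = bt.encode_fv(gmm, X, normalization="off", posterior_floor=0).values
        # per-descriptor contribution std -> standard error of the mean
        single = np.stack([
            bt.encode_fv(gmm, X[i:i + 1], normalization="off",
                         posterior_floor=0).values
            for i in rng.choice(n, 2000, replace=False)])
        se = single.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(fv) <= 3 * se + 1e-12)

    def test_orderless_pooling(self, rng):
        gmm = random_gmm(rng, 3, 4)
        X = rng.normal(size=(40, 4))
        a = bt.encode_fv(gmm, X).values
        b = bt.encode_fv(gmm, X[rng.permutation(40)]).values
        assert np.allclose(a, b, atol=1e-12)

    def test_duplicating_descriptors_leaves_fv_unchanged(self, rng):
        gmm = random_gmm(rng, 2, 3)
        X = rng.normal(size=(25, 3))
        a = bt.encode_fv(gmm, X, normalization="off").values
        b = bt.encode_fv(gmm, np.concatenate([X, X]), normalization="off").values
        assert np.allclose(a, b, atol=1e-10)

    def test_pca_projection_applied_before_encoding(self, rng):
        X = rng.normal(size=(100, 6))
        pca = bt.fit_pca(X, 3)
        gmm = bt.fit_gmm(pca.project(X), 2, seed=0)
        fv = bt.encode_fv(gmm, X, pca=pca)
        assert len(fv.values) == 2 * 2 * 3

    def test_dimension_mismatch_rejected(self, rng):
        gmm = random_gmm(rng, 2, 4)
        with pytest.raises(ValueError, match="dim"):
            bt.encode_fv(gmm, rng.normal(size=(10, 3)))

    def test_normalized_fv_has_unit_norm(self, rng):
        gmm = random_gmm(rng, 3, 5)
        fv = bt.encode_fv(gmm, rng.normal(size=(30, 5)), normalization="ssr+l2")
        assert np.linalg.norm(fv.values) == pytest.approx(1.0, abs=1e-6)

    def test_ssr_normalization_is_signed_sqrt(self):
        v = np.array([4.0, -9.0, 0.0, 0.25])
        assert np.allclose(normalize_fv(v, "ssr"), [2.0, -3.0, 0.0, 0.5])
        assert np.allclose(normalize_fv(v, "off"), v)
        with pytest.raises(ValueError):
            normalize_fv(v, "bogus")


class TestFcPoolAndConcat:
    def test_zero_vector_stays_zero(self):
        fv = bt.fc_pool(np.zeros(10))
        assert np.all(fv.values == 0)

    def test_unit_vector_unchanged(self):
        v = np.zeros(8)
        v[2] = 1.0
        assert np.allclose(bt.fc_pool(v).values, v)

    def test_any_vector_normalized(self, rng):
        fv = bt.fc_pool(rng.normal(size=20))
        assert np.linalg.norm(fv.values) == pytest.approx(1.0)

    def test_single_part_concat_identity(self, rng):
        v = rng.normal(size=12)
        out = bt.concat_representations([bt.fc_pool(v)])
        assert np.allclose(out.values, v / np.linalg.norm(v))

    def test_two_orthogonal_unit_parts(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        out = bt.concat_representations([bt.fc_pool(a), bt.fc_pool(b)]).values
        assert np.linalg.norm(out) == pytest.approx(1.0)
        assert np.linalg.norm(out[:2]) == pytest.approx(1 / np.sqrt(2))
        assert np.linalg.norm(out[2:]) == pytest.approx(1 / np.sqrt(2))

    def test_output_dim_is_sum_of_part_dims(self, rng):
        dims = (5, 9, 3)
        parts = [bt.fc_pool(rng.normal(size=d)) for d in dims]
        assert len(bt.concat_representations(parts).values) == sum(dims)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            bt.concat_representations([])

    def test_tags_joined(self, rng):
        parts = [bt.fc_pool(rng.normal(size=4), source_tag="FC-M"),
                 bt.fc_pool(rng.normal(size=4), source_tag="FV-SIFT")]
        assert bt.concat_representations(parts).source_tag == "FC-M & FV-SIFT"


class TestEncoderEstimator:
    def test_fit_transform_shapes_and_determinism(self, rng):
        fields = [rng.normal(size=(60, 6)) for _ in range(5)]
        enc = FisherVectorEncoder(n_components=3, pca_dim=4, subsample=200,
                                  random_state=0)
        X1 = enc.fit_transform(fields)
        assert X1.shape == (5, 2 * 3 * 4)
        X2 = FisherVectorEncoder(n_components=3, pca_dim=4, subsample=200,
                                 random_state=0).fit_transform(fields)
        assert np.array_equal(X1, X2)

    def test_gmm_model_roundtrip(self, tmp_path, rng):
        gmm = random_gmm(rng, 3, 4)
        gmm.save(tmp_path / "gmm")
        loaded = bt.GmmModel.load(tmp_path / "gmm")
        assert np.array_equal(loaded.means, gmm.means)
        assert np.array_equal(loaded.weights, gmm.weights)
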