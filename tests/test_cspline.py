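"""CSP and LDA contracts: closed-form toy problems, brute-force projection
oracle, simultaneous diagonalization, leakage guards, permutation null."""

import numpy as np
import pytest
from scipy import optimize

from mibci.cspline import (CSPModel, MLConfig, apply_csp, csp_features, fit_csp,
                           fit_lda, predict_lda, run_ml_pipeline,
                           trial_covariances)
from mibci.simulate import EpochSet


def make_epochs(data, labels, fs=100.0):
    names = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data, np.asarray(labels), fs, names)


def gaussian_epochs(rng, covs, n_per_class, n_samples=100):
    """Trials of multichannel white noise with class-specific covariance."""
    blocks, labels = [], []
    for cls, cov in enumerate(covs):
        L = np.linalg.cholesky(cov)
        x = rng.standard_normal((n_per_class, cov.shape[0], n_samples))
        blocks.append(np.einsum("ij,tjs->tis", L, x))
        labels.extend([cls] * n_per_class)
    return make_epochs(np.concatenate(blocks), labels)


def variance_ratio(w, s0, s1):
    return (w @ s0 @ w) / (w @ s1 @ w)


def best_ratio_numerical(s0, s1, seed=0):
    """Independent oracle: dense random search + simplex polish of the
    class-variance Rayleigh ratio over unit-norm filters."""
    rng = np.random.default_rng(seed)
    cands = rng.standard_normal((4000, s0.shape[0]))
    cands /= np.linalg.norm(cands, axis=1, keepdims=True)
    vals = np.einsum("ki,ij,kj->k", cands, s0, cands) \
        / np.einsum("ki,ij,kj->k", cands, s1, cands)
    w0 = cands[np.argmax(vals)]
    res = optimize.minimize(lambda w: -np.log(variance_ratio(w, s0, s1)), w0,
                            method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 20000, "maxfev": 20000})
    return float(np.exp(-res.fun))


class TestFitCSP:
    def test_two_channel_closed_form(self):
        """diag(4,1) vs diag(1,4): top filter is the channel-1 axis and the
        generalized variance ratio is 4 (up to sampling error)."""
        rng = np.random.default_rng(0)
        epochs = gaussian_epochs(rng, [np.diag([4.0, 1.0]), np.diag([1.0, 4.0])],
                                 n_per_class=400, n_samples=200)
        model = fit_csp(epochs, m=1)
        top = model.W[0] / np.linalg.norm(model.W[0])
        assert abs(top[0]) > 0.99  # aligned with channel 1
        lam = model.eigenvalues[0]
        assert lam / (1 - lam) == pytest.approx(4.0, rel=0.15)

    def test_w_is_square_c_by_c(self, efficient_subject):
        epochs, _ = efficient_subject
        model = fit_csp(epochs, m=3)
        assert model.W.shape == (16, 16)

    def test_identical_distributions_give_unit_ratio(self):
        rng = np.random.default_rng(1)
        cov = np.eye(4)
        epochs = gaussian_epochs(rng, [cov, cov], n_per_class=1000, n_samples=50)
        model = fit_csp(epochs, m=1)
        lam = model.eigenvalues[0]
        assert lam / (1 - lam) == pytest.approx(1.0, rel=0.15)

    def test_simultaneous_diagonalization(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((4, 4))
        b = rng.standard_normal((4, 4))
        covs = [a @ a.T + 0.5 * np.eye(4), b @ b.T + 0.5 * np.eye(4)]
        epochs = gaussian_epochs(rng, covs, n_per_class=200)
        model = fit_csp(epochs, m=1)
        cov_t = trial_covariances(epochs.data)
        s0 = cov_t[epochs.labels == 0].mean(axis=0)
        s1 = cov_t[epochs.labels == 1].mean(axis=0)
        composite = model.W @ (s0 + s1) @ model.W.T
        assert np.allclose(composite, np.eye(4), atol=1e-8)
        proj0 = model.W @ s0 @ model.W.T
        off = proj0 - np.diag(np.diag(proj0))
        assert np.max(np.abs(off)) <= 1e-6

    def test_top_filter_matches_numerical_maximum(self):
        """Eigen solution equals dense numerical maximization (one problem;
        the 20-problem battery runs in the acceptance suite)."""
        rng = np.random.default_rng(3)
        a = rng.standard_normal((4, 4))
        b = rng.standard_normal((4, 4))
        covs = [a @ a.T + 0.3 * np.eye(4), b @ b.T + 0.3 * np.eye(4)]
        epochs = gaussian_epochs(rng, covs, n_per_class=100)
        model = fit_csp(epochs, m=1)
        cov_t = trial_covariances(epochs.data)
        s0 = cov_t[epochs.labels == 0].mean(axis=0)
        s1 = cov_t[epochs.labels == 1].mean(axis=0)
        r_csp = variance_ratio(model.W[0], s0, s1)
        r_num = best_ratio_numerical(s0, s1)
        assert abs(r_csp - r_num) / r_csp <= 1e-6

    def test_one_class_rejected(self):
        rng = np.random.default_rng(4)
        epochs = make_epochs(rng.standard_normal((10, 3, 50)), [0] * 10)
        with pytest.raises(ValueError):
            fit_csp(epochs, m=1)

    def test_too_many_pairs_rejected(self, efficient_subject):
        epochs, _ = efficient_subject
        with pytest.raises(ValueError):
            fit_csp(epochs, m=9)

    def test_singular_composite_rejected(self):
        data = np.zeros((8, 3, 40))
        data[:, 0, :] = np.random.default_rng(5).standard_normal((8, 40))
        epochs = make_epochs(data, [0, 1] * 4)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_csp(epochs, m=1)


class TestApplyCSP:
    def test_identity_projection(self):
        rng = np.random.default_rng(6)
        epochs = make_epochs(rng.standard_normal((5, 4, 30)), [0, 1, 0, 1, 0])
        model = CSPModel(W=np.eye(4), eigenvalues=np.ones(4),
                         selected=np.array([0, 3]))
        assert np.array_equal(apply_csp(model, epochs), epochs.data)

    def test_shape_contract(self, efficient_subject):
        epochs, _ = efficient_subject
        model = fit_csp(epochs, m=3)
        Z = apply_csp(model, epochs)
        assert Z.shape == epochs.data.shape

    def test_matches_triple_loop_product(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((3, 3))
        E = rng.standard_normal((1, 3, 5))
        model = CSPModel(W=W, eigenvalues=np.ones(3), selected=np.array([0, 2]))
        epochs = make_epochs(E, [0])
        Z = apply_csp(model, epochs)
        expected = np.zeros((3, 5))
        for i in range(3):
            for t in range(5):
                for j in range(3):
                    expected[i, t] += W[i, j] * E[0, j, t]
        assert np.allclose(Z[0], expected, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        model = CSPModel(W=np.eye(4), eigenvalues=np.ones(4),
                         selected=np.array([0, 3]))
        epochs = make_epochs(np.zeros((2, 3, 10)), [0, 1])
        with pytest.raises(ValueError):
            apply_csp(model, epochs)


class TestCSPFeatures:
    def test_offset_invariance(self):
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((20, 2, 5000)) + 1.0  # unit variance + offset
        feats = csp_features(Z, [0, 1])
        assert np.allclose(feats, 0.0, atol=0.1)

    def test_scaling_law(self):
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((4, 3, 200))
        k = 2.5
        delta = csp_features(Z * k, [0, 2]) - csp_features(Z, [0, 2])
        assert np.allclose(delta, 2 * np.log(k), atol=1e-12)

    def test_feature_length_is_2m(self):
        Z = np.random.default_rng(10).standard_normal((7, 8, 100))
        feats = csp_features(Z, [0, 1, 2, 5, 6, 7])
        assert feats.shape == (7, 6)

    def test_zero_variance_clamped_with_warning(self):
        Z = np.zeros((2, 2, 50))
        with pytest.warns(UserWarning, match="zero-variance"):
            feats = csp_features(Z, [0, 1])
        assert np.all(np.isfinite(feats))


class TestLDA:
    def test_1d_bayes_recovery(self):
        rng = np.random.default_rng(11)
        n = 10_000
        X = np.concatenate([rng.normal(-3, 1, n), rng.normal(3, 1, n)])[:, None]
        y = np.array([0] * n + [1] * n)
        model = fit_lda(X, y)
        threshold = -model.b / model.w[0]
        assert abs(threshold) < 0.1
        Xt = np.concatenate([rng.normal(-3, 1, n), rng.normal(3, 1, n)])[:, None]
        acc = np.mean(predict_lda(model, Xt) == y)
        from scipy.stats import norm
        assert abs(acc - norm.cdf(3)) < 0.01

    def test_weights_collinear_with_closed_form(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal((5, 5))
        cov = a @ a.T + np.eye(5)
        mu0, mu1 = rng.standard_normal(5), rng.standard_normal(5)
        X0 = rng.multivariate_normal(mu0, cov, size=5000)
        X1 = rng.multivariate_normal(mu1, cov, size=5000)
        X = np.vstack([X0, X1])
        y = np.array([0] * 5000 + [1] * 5000)
        model = fit_lda(X, y)
        # independent closed form on the same sample moments
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        S = ((X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)) / (len(X) - 2)
        w_ref = np.linalg.inv(S) @ (m1 - m0)
        cos = model.w @ w_ref / (np.linalg.norm(model.w) * np.linalg.norm(w_ref))
        assert cos >= 0.999

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(13)
        X = rng.standard_normal((400, 6))
        score = X[:, 0] + 0.5 * rng.standard_normal(400)
        y = (score > np.median(score)).astype(int)  # exactly balanced classes
        model = fit_lda(X, y)
        ref = sklearn.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        w_ref = ref.coef_.ravel()
        cos = model.w @ w_ref / (np.linalg.norm(model.w) * np.linalg.norm(w_ref))
        assert cos >= 0.9999
        assert np.array_equal(predict_lda(model, X), ref.predict(X))

    def test_no_information_gives_chance(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((4000, 3))
        y = rng.integers(0, 2, 4000)
        model = fit_lda(X[:2000], y[:2000])
        acc = np.mean(predict_lda(model, X[2000:]) == y[2000:])
        assert abs(acc - 0.5) < 0.03

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((5, 2)), [1] * 5)


class TestMLPipeline:
    def test_no_leakage_test_labels_cannot_change_fit(self, nosignal_subject):
        """With the partition held fixed, permuting test-fold labels leaves
        the fitted CSP and LDA parameters bit-identical."""
        from mibci import evaluate
        epochs, _ = nosignal_subject
        cfg = MLConfig(split_seed=5)
        train_idx, test_idx = evaluate.train_test_split(
            epochs.n_trials, epochs.labels, cfg.train_fraction, cfg.split_seed)
        permuted = epochs.copy()
        permuted.labels[test_idx] = permuted.labels[test_idx][::-1]

        from mibci.preprocess import apply_filter_bank
        models = []
        for eset in (epochs, permuted):
            banded = apply_filter_bank(eset, cfg.bank)[0]
            sub = EpochSet(banded.data[train_idx], banded.labels[train_idx],
                           banded.fs, tuple(banded.channel_names))
            csp = fit_csp(sub, m=cfg.m_pairs)
            feats = csp_features(apply_csp(csp, sub), csp.selected)
            lda = fit_lda(feats, sub.labels)
            models.append((csp, lda))
        (csp1, lda1), (csp2, lda2) = models
        assert np.array_equal(csp1.W, csp2.W)
        assert np.array_equal(lda1.w, lda2.w) and lda1.b == lda2.b

    def test_permutation_null_centred_on_chance(self, nosignal_subject):
        epochs, _ = nosignal_subject
        rng = np.random.default_rng(15)
        accs = []
        for i in range(50):
            shuffled = epochs.copy()
            rng.shuffle(shuffled.labels)
            res = run_ml_pipeline(shuffled, MLConfig(split_seed=i))
            accs.append(res.test_accuracy)
        assert 45.0 <= np.mean(accs) <= 55.0

    def test_strong_erd_subject_decodes_well(self, efficient_subject):
        epochs, _ = efficient_subject
        res = run_ml_pipeline(epochs, MLConfig(split_seed=3))
        assert res.test_accuracy >= 85.0

    def test_result_fields_in_range(self, inefficient_subject):
        epochs, _ = inefficient_subject
        res = run_ml_pipeline(epochs, MLConfig(split_seed=3))
        assert res.model_tag == "CSP+LDA"
        for v in (res.train_accuracy, res.test_accuracy,
                  res.f_score_left, res.f_score_right):
            assert 0.0 <= v <= 100.0
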