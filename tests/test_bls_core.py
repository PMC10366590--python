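import numpy as np
import pytest

from broadvol import (
    BLSConfig,
    BLSParams,
    ConfigurationError,
    LabelMatrix,
    NotFittedError,
    StructuralError,
    enhancement_nodes,
    feature_nodes,
    fit,
    fit_output_weights,
    predict,
    predict_proba,
    ridge_objective,
    ridge_pinv,
    sparse_autoencode_weights,
)

from oracles import dense_ridge_solution


def make_params(W_e=None, beta_e=None, W_h=None, beta_h=None, **cfg):
    p = BLSParams(config=BLSConfig(**cfg))
    p.W_e, p.beta_e, p.W_h, p.beta_h = W_e, beta_e, W_h, beta_h
    return p


class TestFeatureNodes:
    def test_identity_weights_pass_through(self, rng):
        X = rng.standard_normal((5, 3))
        p = make_params(W_e=np.eye(3), beta_e=np.zeros(3), phi="identity")
        assert np.array_equal(feature_nodes(X, p), X)

    def test_zero_input_broadcasts_bias(self):
        b = np.array([0.1, -0.2, 0.3])
        p = make_params(W_e=np.ones((4, 3)), beta_e=b, phi="tanh")
        D = feature_nodes(np.zeros((6, 4)), p)
        assert np.allclose(D, np.tanh(b)[None, :].repeat(6, axis=0))

    def test_matches_matmul_oracle(self, rng):
        X = rng.standard_normal((5, 3))
        W = rng.standard_normal((3, 7))
        b = rng.standard_normal(7)
        p = make_params(W_e=W, beta_e=b, phi="identity")
        ref = np.array([[X[i] @ W[:, j] + b[j] for j in range(7)] for i in range(5)])
        assert np.allclose(feature_nodes(X, p), ref, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        p = make_params(W_e=np.eye(3), beta_e=np.zeros(3))
        with pytest.raises(StructuralError):
            feature_nodes(rng.standard_normal((2, 4)), p)


class TestEnhancementNodes:
    def test_zero_source_zero_output_with_tanh(self):
        p = make_params(W_h=np.ones((4, 5)), beta_h=np.zeros(5), delta="tanh")
        assert np.all(enhancement_nodes(np.zeros((3, 4)), p) == 0.0)

    def test_tanh_range(self, rng):
        p = make_params(W_h=rng.standard_normal((4, 5)), beta_h=rng.standard_normal(5),
                        delta="tanh")
        E = enhancement_nodes(rng.standard_normal((20, 4)), p)
        assert np.all(E > -1.0) and np.all(E < 1.0)

    def test_matches_loop_oracle(self, rng):
        S = rng.standard_normal((6, 4))
        W = rng.standard_normal((4, 3))
        b = rng.standard_normal(3)
        p = make_params(W_h=W, beta_h=b, delta="tanh")
        ref = np.array([[np.tanh(S[i] @ W[:, j] + b[j]) for j in range(3)] for i in range(6)])
        assert np.allclose(enhancement_nodes(S, p), ref, atol=1e-10)


class TestSparseAutoencode:
    def test_zero_sparsity_reduces_to_least_squares(self, rng):
        # fewer nodes than input dims keeps Z full column rank, so the
        # normal-equations oracle is well posed
        X = rng.standard_normal((30, 5))
        W0 = rng.standard_normal((5, 4))
        W = sparse_autoencode_weights(X, W0, 0.0)
        Z = X @ W0
        ref = np.linalg.solve(Z.T @ Z, Z.T @ X)  # normal equations
        assert np.allclose(W, ref.T, atol=1e-6)

    def test_shrinkage_monotonicity(self, rng):
        X = rng.standard_normal((30, 5))
        W0 = rng.standard_normal((5, 8))
        w_dense = sparse_autoencode_weights(X, W0, 0.0)
        w_sparse = sparse_autoencode_weights(X, W0, 500.0, max_iter=500)
        assert np.linalg.norm(w_sparse) < np.linalg.norm(w_dense)

    def test_deterministic(self, rng):
        X = rng.standard_normal((20, 4))
        W0 = rng.standard_normal((4, 6))
        a = sparse_autoencode_weights(X, W0, 0.3)
        b = sparse_autoencode_weights(X, W0, 0.3)
        assert np.array_equal(a, b)

    def test_nonconvergence_warns(self, rng):
        X = rng.standard_normal((20, 4))
        W0 = rng.standard_normal((4, 6))
        with pytest.warns(RuntimeWarning, match="converge"):
            sparse_autoencode_weights(X, W0, 0.5, max_iter=1, tol=0.0)


class TestRidgePinv:
    def test_identity_closed_form(self):
        lam = 0.25
        G = np.eye(6)
        assert np.allclose(ridge_pinv(G, lam), np.eye(6) / (1 + lam))

    def test_moore_penrose_limit_orthonormal_columns(self, rng):
        A = rng.standard_normal((20, 8))
        Q, _ = np.linalg.qr(A)
        Gp = ridge_pinv(Q, 1e-12)
        assert np.allclose(Gp @ Q, np.eye(8), atol=1e-6)

    def test_matches_dense_formula(self, rng):
        G = rng.standard_normal((50, 30))
        lam = 1e-8
        ref = np.linalg.inv(lam * np.eye(30) + G.T @ G) @ G.T
        assert np.allclose(ridge_pinv(G, lam), ref, atol=1e-8)

    def test_nonfinite_rejected(self):
        G = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            ridge_pinv(G, 0.1)


class TestFitOutputWeights:
    def test_self_target_recovers_identity(self, rng):
        G = rng.standard_normal((30, 30)) + 5 * np.eye(30)
        W = fit_output_weights(G, G, 1e-10)
        assert np.allclose(W, np.eye(30), atol=1e-5)

    def test_minimizer_property(self, rng):
        G = rng.standard_normal((40, 20))
        Y = rng.standard_normal((40, 2))
        lam = 0.5
        W = fit_output_weights(G, Y, lam)
        base = ridge_objective(G, Y, W, lam)
        for _ in range(100):
            W_pert = W + rng.standard_normal(W.shape) * 0.01
            assert ridge_objective(G, Y, W_pert, lam) >= base

    def test_matches_normal_equations_oracle(self, rng):
        G = rng.standard_normal((40, 20))
        Y = rng.standard_normal((40, 2))
        ref = dense_ridge_solution(G, Y, 1e-8)
        assert np.allclose(fit_output_weights(G, Y, 1e-8), ref, atol=1e-8)

    def test_ridge_path_monotone_norm(self, rng):
        G = rng.standard_normal((30, 15))
        Y = rng.standard_normal((30, 3))
        norms = [np.linalg.norm(fit_output_weights(G, Y, lam))
                 for lam in (1e-6, 1e-3, 1e-1, 1.0, 10.0, 100.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestFitPredict:
    def test_deterministic(self, gaussian_data, default_classic_bls):
        X, y = gaussian_data
        a = fit(X, None, y, default_classic_bls)
        b = fit(X, None, y, default_classic_bls)
        assert np.array_equal(a.W_out, b.W_out)

    def test_separable_gaussians_high_training_accuracy(self, gaussian_data,
                                                        default_classic_bls):
        X, y = gaussian_data
        model = fit(X, None, y, default_classic_bls)
        _, pred = predict(model, X)
        assert (pred == y).mean() >= 0.99

    def test_permuted_labels_low_capacity_training_accuracy_near_chance(self, gaussian_data):
        """With capacity well below n, ridge cannot memorise permuted
        labels: training accuracy stays within 10 points of chance."""
        X, y = gaussian_data
        cfg = BLSConfig(mode="classic", n_feature_nodes=8, n_feature_groups=2,
                        n_enh_nodes=4, n_enh_groups=2, lam=10.0, seed=0)
        accs = []
        for ps in range(10):
            yp = np.random.default_rng(100 + ps).permutation(y)
            m = fit(X, None, yp, cfg)
            _, pred = predict(m, X)
            accs.append((pred == yp).mean())
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_predict_consistency_with_fit(self, gaussian_data, default_classic_bls):
        X, y = gaussian_data
        model = fit(X, None, y, default_classic_bls)
        s1, p1 = predict(model, X)
        s2, p2 = predict(model, X)
        assert np.array_equal(s1, s2) and np.array_equal(p1, p2)

    def test_degenerate_scores_tie_break_first_class(self, gaussian_data,
                                                     default_classic_bls):
        X, y = gaussian_data
        model = fit(X, None, y, default_classic_bls)
        model.W_out = np.zeros_like(model.W_out)
        _, pred = predict(model, X)
        assert all(p == model.class_names[0] for p in pred)

    def test_single_sample_equals_batch_row(self, gaussian_data, default_classic_bls):
        X, y = gaussian_data
        model = fit(X, None, y, default_classic_bls)
        s_batch, _ = predict(model, X)
        s_one, _ = predict(model, X[:1])
        assert np.allclose(s_one[0], s_batch[0], atol=1e-12)

    def test_unfitted_predict_raises(self):
        p = BLSParams(config=BLSConfig())
        with pytest.raises(NotFittedError):
            predict(p, np.zeros((2, 3)), np.zeros((2, 3)))

    def test_proba_rows_sum_to_one(self, gaussian_data, default_classic_bls):
        X, y = gaussian_data
        model = fit(X, None, y, default_classic_bls)
        P = predict_proba(model, X)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P >= 0)

    def test_ensemble_mode_requires_xe(self, gaussian_data):
        X, y = gaussian_data
        with pytest.raises(StructuralError):
            fit(X, None, y, BLSConfig(mode="ensemble"))


def test_classic_mode_reduction_matches_manual_wiring(rng):
    """Classic mode must equal the original BLS wiring computed by hand:
    D = phi(X We + be), E = delta(D Wh + bh), G = [D|E], W = G+ Y."""
    X = rng.standard_normal((30, 6))
    y = np.array(["A", "B"] * 15)
    cfg = BLSConfig(mode="classic", n_feature_nodes=10, n_feature_groups=2,
                    n_enh_nodes=4, n_enh_groups=2, lam=0.01, seed=7,
                    standardize=False)
    model = fit(X, None, y, cfg)
    D = X @ model.W_e + model.beta_e
    E = np.tanh(D @ model.W_h + model.beta_h)
    G = np.hstack([D, E])
    Y = LabelMatrix.from_labels(y).Y
    ref = dense_ridge_solution(G, Y, cfg.lam)
    assert np.allclose(model.W_out, ref, atol=1e-8)


def test_adding_enhancement_nodes_never_worsens_objective(rng):
    """Nested model classes: appending columns to G cannot increase the
    ridge objective at its optimum (padding with zeros is feasible)."""
    for _ in range(20):
        n, m, extra = 30, 12, 5
        G = rng.standard_normal((n, m))
        Y = rng.standard_normal((n, 2))
        lam = 0.3
        o1 = ridge_objective(G, Y, fit_output_weights(G, Y, lam), lam)
        G2 = np.hstack([G, rng.standard_normal((n, extra))])
        o2 = ridge_objective(G2, Y, fit_output_weights(G2, Y, lam), lam)
        assert o2 <= o1 + 1e-9


def test_sweep_mode_validation():
    with pytest.raises(ConfigurationError):
        BLSConfig(n_feature_nodes=200, n_feature_groups=2, sweep_mode=True)
    with pytest.raises(ConfigurationError):
        BLSConfig(n_enh_nodes=50, n_enh_groups=1, sweep_mode=True)
    with pytest.raises(ConfigurationError):
        BLSConfig(sparsity=0.9, use_sparse_autoencoder=True, sweep_mode=True)
    # fine outside sweep mode
    BLSConfig(n_feature_nodes=200, n_feature_groups=2)


def test_label_matrix_one_hot():
    lm = LabelMatrix.from_labels(["NC", "AD", "AD", "MCI"])
    assert lm.class_names == ["AD", "MCI", "NC"]
    assert lm.Y.sum() == 4
    assert np.array_equal(lm.Y.sum(axis=1), np.ones(4))
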