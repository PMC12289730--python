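"""Factorization engine: splits, pretraining, update rules, objective, stopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from dnmfdda import (
    FactorStack,
    Hyperparams,
    basic_nmf,
    convergence_check,
    fit_dnmf,
    layer_dims,
    objective,
    phi_product,
    pos_neg_split,
    pretrain_stack,
    reconstruct,
    update_H,
    update_W,
)
from dnmfdda.preprocess import FusedSimilarity, build_laplacian


def _laplacian(rng, n):
    s = rng.uniform(size=(n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    return build_laplacian(FusedSimilarity(s, [str(i) for i in range(n)], "drug"))


def _zero_laplacian(n):
    return build_laplacian(FusedSimilarity(np.eye(n), [str(i) for i in range(n)], "drug"))


def _positive_stack(rng, rows, dims, cols):
    """Strictly positive factor stack with W_l H_l ... H_1 of shape rows x cols."""
    W = [rng.uniform(0.5, 1.5, size=(rows, d)) for d in dims]
    H = [rng.uniform(0.5, 1.5, size=(dims[0], cols))]
    for i in range(1, len(dims)):
        H.append(rng.uniform(0.5, 1.5, size=(dims[i], dims[i - 1])))
    return FactorStack(list(dims), W, H)


class TestPosNegSplit:
    def test_direct_example(self):
        plus, minus = pos_neg_split(np.array([[2.0, -3.0]]))
        np.testing.assert_array_equal(plus, [[2, 0]])
        np.testing.assert_array_equal(minus, [[0, 3]])

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            array_shapes(min_dims=2, max_dims=2, max_side=6),
            elements=st.floats(-1e6, 1e6),
        )
    )
    def test_reconstruction_and_disjoint_support(self, M):
        plus, minus = pos_neg_split(M)
        assert plus.min() >= 0 and minus.min() >= 0
        np.testing.assert_array_equal(plus - minus, M)
        np.testing.assert_array_equal(plus * minus, np.zeros_like(M))


class TestBasicNMF:
    def test_recovers_rank_one_matrix(self):
        M = np.array([[1.0, 2.0], [2.0, 4.0]])
        W, H = basic_nmf(M, r=1, iters=500, seed=0)
        assert np.linalg.norm(M - W @ H) / np.linalg.norm(M) < 1e-3

    def test_deterministic(self, rng):
        M = rng.uniform(size=(6, 5))
        W1, H1 = basic_nmf(M, 3, 50, seed=42)
        W2, H2 = basic_nmf(M, 3, 50, seed=42)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_objective_nonincreasing(self, rng):
        M = rng.uniform(size=(10, 8))
        errs = []
        for iters in range(1, 30):
            W, H = basic_nmf(M, 4, iters, seed=1)
            errs.append(np.linalg.norm(M - W @ H) ** 2)
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            basic_nmf(np.array([[-1.0, 2.0]]), 1)


class TestLayerDims:
    @pytest.mark.parametrize(
        "m,n,taus,expected",
        [
            (593, 313, (0.8, 0.6), [250, 188]),
            (10, 7, (1.0,), [7]),
            (5, 4, (0.2,), [1]),
        ],
    )
    def test_rounding_and_clamp(self, m, n, taus, expected):
        assert layer_dims(m, n, taus) == expected

    def test_empty_taus(self):
        with pytest.raises(ValueError):
            layer_dims(5, 5, ())


class TestPretrain:
    def test_single_layer_reduces_to_basic_nmf(self, rng, light_params):
        from dnmfdda.dnmf_core import _layer_seed

        X = rng.uniform(size=(8, 6))
        stack = pretrain_stack(X, [3], light_params)
        W, H = basic_nmf(X, 3, light_params.pretrain_iters, _layer_seed(light_params.seed, 0))
        np.testing.assert_array_equal(stack.W[0], W)
        np.testing.assert_array_equal(stack.H[0], H)

    def test_shapes_two_layers(self, rng):
        X = rng.uniform(size=(12, 9))
        stack = pretrain_stack(X, [6, 4], Hyperparams(seed=0))
        assert stack.W[1].shape == (12, 4)
        assert stack.H[1].shape == (4, 6)
        assert stack.H[0].shape == (6, 9)

    def test_planted_product_recovered(self, rng):
        W_true = rng.uniform(size=(15, 5))
        H_true = rng.uniform(size=(5, 12))
        X = W_true @ H_true
        stack = pretrain_stack(X, [8, 5], Hyperparams(pretrain_iters=500, seed=2))
        rel = np.linalg.norm(X - reconstruct(stack)) / np.linalg.norm(X)
        assert rel < 0.05


class TestPhiProduct:
    def test_examples_and_oracle(self, rng):
        stack = _positive_stack(rng, 10, [5, 4, 3], 8)
        np.testing.assert_array_equal(phi_product(stack, 1), stack.H[0])
        np.testing.assert_allclose(phi_product(stack, 2), stack.H[1] @ stack.H[0], atol=1e-12)
        oracle = stack.H[2] @ (stack.H[1] @ stack.H[0])
        np.testing.assert_allclose(phi_product(stack, 3), oracle, atol=1e-12)
        assert phi_product(stack, 2).shape == (4, 8)

    def test_out_of_range(self, rng):
        stack = _positive_stack(rng, 4, [2], 3)
        with pytest.raises(ValueError):
            phi_product(stack, 2)


class TestUpdates:
    def _consistent_instance(self, rng):
        """Strictly positive two-layer stack with W1 = W2 H2 exactly, so
        X = W1 H1 = W2 H2 H1 is an exact factorization at every layer."""
        W2 = rng.uniform(0.5, 1.5, size=(8, 3))
        H2 = rng.uniform(0.5, 1.5, size=(3, 4))
        H1 = rng.uniform(0.5, 1.5, size=(4, 6))
        W1 = W2 @ H2
        stack = FactorStack([4, 3], [W1, W2], [H1, H2])
        return stack, reconstruct(stack)

    def test_fixed_point_W_unregularized(self, rng):
        params = Hyperparams(alpha=0, beta=0, lam=0, mu=0, taus=(0.5,))
        stack, X = self._consistent_instance(rng)
        L = _zero_laplacian(8)
        for i in (1, 2):
            new_W = update_W(stack, i, X, L, params)
            np.testing.assert_allclose(new_W, stack.W[i - 1], atol=1e-12)

    def test_fixed_point_H_unregularized(self, rng):
        params = Hyperparams(alpha=0, beta=0, lam=0, mu=0, taus=(0.5,))
        stack, X = self._consistent_instance(rng)
        for i in (1, 2):
            new_H = update_H(stack, i, X, params)
            np.testing.assert_allclose(new_H, stack.H[i - 1], atol=1e-12)

    def test_nonnegativity_preserved(self, rng):
        params = Hyperparams(seed=0)
        X = rng.uniform(size=(12, 9))
        L = _laplacian(rng, 12)
        stack = pretrain_stack(X, [6, 4], params)
        for _ in range(5):
            for i in (1, 2):
                stack.W[i - 1] = update_W(stack, i, X, L, params)
                stack.H[i - 1] = update_H(stack, i, X, params)
        assert all(w.min() >= 0 for w in stack.W)
        assert all(h.min() >= 0 for h in stack.H)

    def test_W_sweep_decreases_full_objective(self, rng):
        # regularized two-layer instance; H fixed, one full W sweep
        params = Hyperparams(alpha=0.01, beta=1, lam=1, mu=1, taus=(0.8, 0.6), seed=3)
        X = rng.uniform(size=(12, 9))
        L = _laplacian(rng, 12)
        stack = pretrain_stack(X, [6, 4], params)
        before = objective(stack, X, L, params)
        for i in (1, 2):
            stack.W[i - 1] = update_W(stack, i, X, L, params)
        assert objective(stack, X, L, params) <= before + 1e-9

    def test_H_sweep_decreases_data_term_unregularized(self, rng):
        params = Hyperparams(alpha=0, beta=0, lam=0, mu=0, taus=(0.8, 0.6), seed=4)
        X = rng.uniform(size=(12, 9))
        stack = pretrain_stack(X, [6, 4], params)
        before = np.linalg.norm(X - reconstruct(stack)) ** 2
        for i in (1, 2):
            stack.H[i - 1] = update_H(stack, i, X, params)
        assert np.linalg.norm(X - reconstruct(stack)) ** 2 <= before + 1e-9

    def test_single_layer_sweep_never_increases_error(self, rng):
        # classical multiplicative-update guarantee, unregularized, l=1
        params = Hyperparams(alpha=0, beta=0, lam=0, mu=0, taus=(0.5,))
        L = _zero_laplacian(10)
        for trial in range(100):
            trial_rng = np.random.default_rng(trial)
            X = trial_rng.uniform(size=(10, 8))
            stack = pretrain_stack(X, [4], Hyperparams(pretrain_iters=5, seed=trial))
            before = np.linalg.norm(X - reconstruct(stack)) ** 2
            stack.W[0] = update_W(stack, 1, X, L, params)
            stack.H[0] = update_H(stack, 1, X, params)
            after = np.linalg.norm(X - reconstruct(stack)) ** 2
            assert after <= before + 1e-9


class TestObjective:
    def test_zero_everything(self):
        stack = FactorStack([1], [np.zeros((2, 1))], [np.zeros((1, 3))])
        L = _zero_laplacian(2)
        assert objective(stack, np.zeros((2, 3)), L, Hyperparams()) == 0.0

    def test_unregularized_equals_reconstruction_error(self, rng):
        stack = _positive_stack(rng, 6, [3], 5)
        X = rng.uniform(size=(6, 5))
        params = Hyperparams(alpha=0, beta=0, lam=0, mu=0, taus=(0.5,))
        expected = np.linalg.norm(X - reconstruct(stack)) ** 2
        assert objective(stack, X, _zero_laplacian(6), params) == pytest.approx(expected, rel=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        params = Hyperparams(alpha=0.3, beta=0.7, lam=0.2, mu=0.9, taus=(0.8, 0.6))
        stack = _positive_stack(rng, 7, [4, 3], 6)
        X = rng.uniform(size=(7, 6))
        L = _laplacian(rng, 7)
        expected = np.linalg.norm(X - stack.W[1] @ stack.H[1] @ stack.H[0]) ** 2
        for i in range(2):
            expected += 0.3 * np.trace(stack.W[i].T @ L.values @ stack.W[i])
            expected += 0.2 * np.linalg.norm(stack.W[i]) ** 2
            expected += 0.9 * np.linalg.norm(stack.H[i]) ** 2
        expected += 0.7 * np.linalg.norm(stack.W[0] - stack.W[1] @ stack.H[1]) ** 2
        assert objective(stack, X, L, params) == pytest.approx(expected, rel=1e-9)


class TestConvergence:
    @pytest.mark.parametrize(
        "history,stop",
        [
            ([1e-5, 1e-5], True),            # both conditions met, delta 0
            ([1e-3], False),                 # too short / h above xi1
            ([4e-4, 4e-4 + 1e-6], False),    # h small but still moving
            ([], False),
            ([1e-3, 1e-5], False),           # large drop: h fine, delta too big
        ],
    )
    def test_decision_table(self, history, stop):
        params = Hyperparams(xi1=5e-4, xi2=5e-7)
        assert convergence_check(history, params) is stop


class TestFitAndReconstruct:
    def test_max_iter_zero_returns_pretrained(self, rng):
        X = rng.uniform(size=(10, 8))
        L = _laplacian(rng, 10)
        params = Hyperparams(max_iter=0, pretrain_iters=30, seed=5, taus=(0.5, 0.4))
        stack = fit_dnmf(X, L, params)
        pre = pretrain_stack(X, [4, 3], params)
        for a, b in zip(stack.W + stack.H, pre.W + pre.H):
            np.testing.assert_array_equal(a, b)

    def test_refinement_improves_on_pretraining(self, rng):
        W_true = rng.uniform(size=(12, 3))
        H_true = rng.uniform(size=(3, 10))
        X = W_true @ H_true
        L = _zero_laplacian(12)
        params = Hyperparams(
            alpha=0, beta=0, lam=0, mu=0, taus=(0.3,), max_iter=100,
            pretrain_iters=20, seed=6,
        )
        pre_err = np.linalg.norm(X - reconstruct(pretrain_stack(X, [3], params)))
        fit_err = np.linalg.norm(X - reconstruct(fit_dnmf(X, L, params, dims=[3])))
        assert fit_err <= pre_err

    def test_bit_identical_given_seed(self, rng):
        X = rng.uniform(size=(9, 7))
        L = _laplacian(rng, 9)
        params = Hyperparams(max_iter=20, pretrain_iters=20, seed=11, taus=(0.5,))
        s1 = fit_dnmf(X, L, params)
        s2 = fit_dnmf(X, L, params)
        for a, b in zip(s1.W + s1.H, s2.W + s2.H):
            np.testing.assert_array_equal(a, b)

    def test_reconstruct_oracle_and_degenerate(self, rng):
        stack = _positive_stack(rng, 6, [4, 3, 2], 5)
        oracle = stack.W[2]
        for H in (stack.H[2], stack.H[1], stack.H[0]):
            oracle = oracle @ H
        np.testing.assert_allclose(reconstruct(stack), oracle, rtol=1e-10)
        stack.W[2] = np.zeros_like(stack.W[2])
        np.testing.assert_array_equal(reconstruct(stack), np.zeros((6, 5)))
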