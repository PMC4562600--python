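"""Factorization core: loss, scatter, updates, and the full fit."""

import numpy as np
import pytest
from sklearn.base import clone

import oracles
from conftest import random_factors
from dnmfrank import (
    DiscriminantNMF,
    class_seed_H,
    class_statistics,
    fit_dnmf,
    initialize_factors,
    kl_divergence,
    objective,
    update_H,
    update_W,
)
from dnmfrank.dnmf import _h_quadratic_coefficients


class TestKLDivergence:
    def test_zero_at_exact_factorization(self, rng):
        W, H = random_factors(rng, 6, 2, 4)
        assert kl_divergence(W @ H, W, H) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_case_matches_closed_form(self):
        # V=2 against WH=1: 2 ln 2 - 2 + 1
        val = kl_divergence([[2.0]], [[1.0]], [[1.0]])
        assert val == pytest.approx(2 * np.log(2) - 1, abs=1e-12)

    def test_zero_entry_contributes_reconstruction_only(self):
        # 0*ln0 convention: cell with V=0, WH=x contributes exactly x
        V = np.array([[0.0, 3.0]])
        W = np.array([[1.0]])
        H = np.array([[0.7, 3.0]])
        assert kl_divergence(V, W, H) == pytest.approx(0.7, abs=1e-12)

    def test_matches_direct_summation(self, rng):
        W, H = random_factors(rng, 8, 3, 5)
        V = rng.uniform(0.1, 4.0, size=(8, 5))
        assert kl_divergence(V, W, H) == pytest.approx(
            oracles.kl_direct(V, W @ H), rel=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="conform"):
            kl_divergence(np.ones((2, 2)), np.ones((3, 1)), np.ones((1, 2)))

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            kl_divergence(np.ones((1, 1)), [[-1.0]], [[1.0]])


class TestClassStatistics:
    def test_identical_columns_within_class_zero_Sw(self):
        H = np.array([[1.0, 1.0, 5.0, 5.0], [2.0, 2.0, 3.0, 3.0]])
        stats = class_statistics(H, np.array([0, 0, 1, 1]))
        assert np.allclose(stats.Sw, 0.0)

    def test_single_class_scatter_hand_computed(self):
        stats = class_statistics(np.array([[1.0, 3.0]]), np.array([0, 0]))
        assert stats.class_means[0, 0] == pytest.approx(2.0)
        assert stats.Sw[0, 0] == pytest.approx(2.0)

    def test_between_class_scatter_hand_computed(self):
        H = np.array([[0.0, 2.0, 2.0, 4.0]])  # class means 1 and 3, grand mean 2
        stats = class_statistics(H, np.array([0, 0, 1, 1]))
        assert stats.grand_mean[0] == pytest.approx(2.0)
        assert stats.Sb[0, 0] == pytest.approx(4.0)

    def test_equal_class_means_zero_Sb(self):
        H = np.array([[1.0, 3.0, 0.0, 4.0]])
        stats = class_statistics(H, np.array([0, 0, 1, 1]))
        assert np.allclose(stats.Sb, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_scatter_matches_double_summation(self, seed):
        r = np.random.default_rng(seed)
        H = r.uniform(0.0, 5.0, size=(3, 12))
        idx = np.repeat([0, 1, 2], 4)
        stats = class_statistics(H, idx)
        Sw, Sb = oracles.scatter_direct(H, idx)
        assert np.allclose(stats.Sw, Sw, atol=1e-12)
        assert np.allclose(stats.Sb, Sb, atol=1e-12)

    def test_scatter_matrices_are_psd(self, rng):
        H = rng.uniform(size=(3, 9))
        stats = class_statistics(H, np.repeat([0, 1, 2], 3))
        for S in (stats.Sw, stats.Sb):
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() >= -1e-12


class TestObjective:
    def test_reduces_to_kl_without_penalty(self, small_instance, rng):
        V, labels = small_instance
        W, H = random_factors(rng, 20, 2, 6)
        assert objective(V, W, H, labels, 0.0, 0.0) == pytest.approx(
            kl_divergence(V, W, H)
        )

    def test_exact_reconstruction_leaves_penalty(self, rng):
        W, H = random_factors(rng, 10, 2, 6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        val = objective(W @ H, W, H, labels, 0.3, 0.05)
        stats = class_statistics(H, labels)
        assert val == pytest.approx(
            0.3 * np.trace(stats.Sw) - 0.05 * np.trace(stats.Sb), abs=1e-10
        )

    def test_matches_direct_summation_oracle(self, rng):
        V = rng.uniform(0.5, 3.0, size=(2, 4))
        W, H = random_factors(rng, 2, 2, 4)
        labels = np.array([0, 0, 1, 1])
        assert objective(V, W, H, labels, 0.1, 1e-4) == pytest.approx(
            oracles.objective_direct(V, W, H, labels, 0.1, 1e-4), abs=1e-12
        )


class TestInitialization:
    def test_seeding_rule_on_unit_matrix(self):
        H = np.ones((2, 4))
        seeded = class_seed_H(H, np.array([0, 0, 1, 1]))
        assert seeded.tolist() == [[9, 9, 1, 1], [1, 1, 9, 9]]

    def test_each_row_dominates_its_own_class(self, rng):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        W, H = initialize_factors(15, labels, 2, rng)
        for k in range(2):
            own = H[k, labels == k].mean()
            other = H[k, labels != k].mean()
            assert own > other

    def test_same_seed_bitwise_identical(self):
        labels = np.array([0, 0, 1, 1])
        a = initialize_factors(8, labels, 2, np.random.default_rng(5))
        b = initialize_factors(8, labels, 2, np.random.default_rng(5))
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_W_columns_normalized_and_positive(self, rng):
        W, H = initialize_factors(30, np.array([0, 0, 1, 1]), 2, rng)
        assert W.sum(axis=0) == pytest.approx([1.0, 1.0])
        assert (W > 0).all() and (H > 0).all()

    def test_seeding_requires_one_metagene_per_class(self, rng):
        with pytest.raises(ValueError, match="per class"):
            initialize_factors(10, np.array([0, 0, 1, 1]), 3, rng)


class TestUpdateH:
    def test_fixed_point_without_penalty(self, rng):
        W, H = random_factors(rng, 12, 2, 6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        Hn = update_H(W @ H, W, H, labels, 0.0, 0.0, eps=0.0)
        assert np.allclose(Hn, H, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_penalty_free_matches_leeseung(self, seed):
        r = np.random.default_rng(seed)
        W, H = random_factors(r, 4, 2, 3)
        V = r.uniform(0.2, 3.0, size=(4, 3))
        ours = update_H(V, W, H, np.array([0, 0, 1]), 0.0, 0.0, eps=0.0)
        ref = oracles.leeseung_update_H(V, W, H)
        assert np.allclose(ours, ref, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_returned_roots_satisfy_their_quadratic(self, seed):
        r = np.random.default_rng(seed)
        W, H = random_factors(r, 3, 2, 4)
        V = r.uniform(0.2, 3.0, size=(3, 4))
        labels = np.array([0, 0, 1, 1])
        a, b, c = _h_quadratic_coefficients(V, W, H, labels, 0.1, 1e-4, 0.0)
        Hn = update_H(V, W, H, labels, 0.1, 1e-4, eps=0.0)
        residual = a * Hn**2 + b * Hn + c
        assert np.abs(residual).max() < 1e-10

    def test_output_nonnegative_and_finite(self, rng):
        W, H = random_factors(rng, 10, 2, 8)
        V = rng.uniform(0.0, 5.0, size=(10, 8))
        Hn = update_H(V, W, H, np.repeat([0, 1], 4), 0.5, 0.01)
        assert (Hn >= 0).all() and np.isfinite(Hn).all()


class TestUpdateW:
    def test_fixed_point_at_exact_reconstruction(self, rng):
        W, H = random_factors(rng, 9, 2, 5)
        Wn = update_W(W @ H, W, H, eps=0.0)
        assert np.allclose(Wn, W, rtol=1e-12)

    def test_columns_sum_to_one(self, rng):
        W, H = random_factors(rng, 14, 3, 6)
        V = rng.uniform(0.1, 2.0, size=(14, 6))
        Wn = update_W(V, W, H)
        assert Wn.sum(axis=0) == pytest.approx([1.0] * 3, abs=1e-12)

    def test_single_step_matches_hand_computation(self):
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.full((2, 2), 0.5)
        H = np.ones((2, 2))
        Wn = update_W(V, W, H, eps=0.0)
        ref = oracles.column_normalize(
            np.full((2, 2), 0.5) * ((V / (W @ H)) @ H.T)
        )
        assert np.allclose(Wn, ref, atol=1e-12)

    def test_collapsed_column_raises(self):
        V = np.array([[1.0, 1.0], [1.0, 1.0]])
        W = np.array([[0.5, 0.5], [0.5, 0.5]])
        H = np.array([[1.0, 1.0], [0.0, 0.0]])  # metagene 2 silent everywhere
        with pytest.raises(FloatingPointError, match="collapsed"):
            update_W(V, W, H, eps=0.0)


class TestFit:
    def test_same_seed_identical_factors(self, small_instance):
        V, labels = small_instance
        a = fit_dnmf(V, labels, max_iter=50, random_state=3)
        b = fit_dnmf(V, labels, max_iter=50, random_state=3)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_objective_nonincreasing_with_defaults(self, rng):
        V = rng.uniform(0.5, 8.0, size=(100, 10))
        labels = np.repeat([0, 1], 5)
        _, _, trace = fit_dnmf(V, labels, max_iter=150, tol=0.0, random_state=1,
                               ensure_orientation=False)
        obj = np.asarray(trace.objective_per_iteration)
        rel = np.diff(obj) / np.abs(obj[:-1])
        assert rel.max() <= 1e-9

    def test_single_class_rejected(self, rng):
        V = rng.uniform(0.5, 2.0, size=(6, 4))
        with pytest.raises(ValueError, match="two sample classes"):
            fit_dnmf(V, np.zeros(4, dtype=int))

    def test_factors_stay_nonnegative(self, small_instance):
        V, labels = small_instance
        W, H, _ = fit_dnmf(V, labels, max_iter=60, random_state=2)
        assert (W >= 0).all() and (H >= 0).all()
        assert W.sum(axis=0) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_penalty_free_trajectory_matches_leeseung(self, rng):
        """gamma = delta = 0 reduces the iteration to plain KL-NMF.

        The model fixes the column-sum-one gauge on W (its normalization
        step), so the independently coded Lee-Seung iteration is run in
        the same gauge: LS W update, column normalization, LS H update.
        """
        V = rng.uniform(0.5, 6.0, size=(20, 6))
        labels = np.array([0, 0, 0, 1, 1, 1])
        rng_init = np.random.default_rng(0)
        W0, H0 = initialize_factors(20, labels, 2, rng_init)
        W, H = W0.copy(), H0.copy()
        Wr, Hr = W0.copy(), H0.copy()
        for _ in range(50):
            W = update_W(V, W, H, eps=0.0)
            H = update_H(V, W, H, labels, 0.0, 0.0, eps=0.0)
            Wr = oracles.column_normalize(oracles.leeseung_update_W(V, Wr, Hr))
            Hr = oracles.leeseung_update_H(V, Wr, Hr)
        assert np.allclose(W, Wr, rtol=1e-8)
        assert np.allclose(H, Hr, rtol=1e-8)

    def test_fisher_penalty_raises_scatter_ratio(self):
        """On class-structured data the penalty should enlarge tr(Sb)/tr(Sw)."""
        r = np.random.default_rng(42)
        base = r.uniform(1.0, 5.0, size=(60, 1))
        shift = np.concatenate([np.zeros(5), np.full(5, 1.5)])
        V = base + shift[None, :] * r.uniform(0.0, 1.0, size=(60, 1)) + \
            r.uniform(0.0, 0.5, size=(60, 10))
        labels = np.repeat([0, 1], 5)

        def ratio(gamma, delta):
            _, H, _ = fit_dnmf(V, labels, gamma=gamma, delta=delta,
                               max_iter=300, random_state=7,
                               ensure_orientation=False)
            stats = class_statistics(H, labels)
            return np.trace(stats.Sb) / np.trace(stats.Sw)

        assert ratio(0.1, 1e-4) > ratio(0.0, 0.0)


class TestEstimator:
    def test_fit_sets_sklearn_style_attributes(self, small_instance):
        V, labels = small_instance
        est = DiscriminantNMF(max_iter=40, random_state=0)
        est.fit(V.T, labels)
        assert est.W_.shape == (20, 2)
        assert est.H_.shape == (2, 6)
        assert est.components_.shape == (2, 20)
        assert est.n_iter_ == est.trace_.iterations_run
        assert est.classes_.tolist() == [0, 1]

    def test_clone_and_get_params_roundtrip(self):
        est = DiscriminantNMF(gamma=0.2, delta=1e-3, max_iter=10)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_transform_returns_sample_coefficients(self, small_instance):
        V, labels = small_instance
        est = DiscriminantNMF(max_iter=40, random_state=0)
        Ht = est.fit_transform(V.T, labels)
        assert Ht.shape == (6, 2)
        assert (Ht == est.H_.T).all()
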