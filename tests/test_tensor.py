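"""Tests for unfoldings, the tensor GSVD, HOSVD and special-case reductions."""

import numpy as np
import pytest
from scipy import linalg

from tensorgsvd import (
    RankDeficiencyError,
    TensorGSVD,
    ThirdOrderTensor,
    fold_row,
    hosvd,
    matrix_gsvd,
    pattern_angular_distance,
    significance,
    tensor_angular_distance,
    tensor_gsvd,
    unfold_row,
    unfold_x,
    unfold_y,
)

QUARTER_PI = np.pi / 4


def numbered_tensor():
    """2x2x2 tensor with T[k,l,m] = 100(k+1) + 10(l+1) + (m+1)."""
    k, l, m = np.meshgrid([1, 2], [1, 2], [1, 2], indexing="ij")
    return (100 * k + 10 * l + m).astype(float)


class TestUnfoldings:
    def test_row_unfolding_column_order_m_fastest(self):
        t = numbered_tensor()
        np.testing.assert_array_equal(unfold_row(t)[0], [111, 112, 121, 122])
        np.testing.assert_array_equal(unfold_row(t)[1], [211, 212, 221, 222])

    def test_x_unfolding_stacks_platform_within_probe(self):
        t = numbered_tensor()
        # column l stacks (T[1,l,1], T[1,l,2], T[2,l,1], T[2,l,2])
        np.testing.assert_array_equal(unfold_x(t)[:, 0], [111, 112, 211, 212])
        np.testing.assert_array_equal(unfold_x(t)[:, 1], [121, 122, 221, 222])

    def test_y_unfolding_stacks_patient_within_probe(self):
        t = numbered_tensor()
        np.testing.assert_array_equal(unfold_y(t)[:, 0], [111, 121, 211, 221])

    def test_fold_row_inverts_unfold_row(self, rng):
        t = rng.normal(size=(5, 3, 2))
        np.testing.assert_array_equal(fold_row(unfold_row(t), t.shape), t)

    def test_identical_patient_slices_give_rank_one_x_unfolding(self):
        slice_ = np.arange(8.0).reshape(4, 2)
        t = np.stack([slice_, slice_, slice_], axis=1)
        assert np.linalg.matrix_rank(unfold_x(t)) == 1


class TestTensorGSVD:
    def test_reconstruction_of_random_pairs(self, random_tensor_pair):
        d1, d2 = random_tensor_pair
        r = tensor_gsvd(d1, d2)
        for d, which in ((d1, 1), (d2, 2)):
            err = np.linalg.norm(d - r.reconstruct(which)) / np.linalg.norm(d)
            assert err < 1e-8

    def test_kronecker_unfolding_identity(self, random_tensor_pair):
        d1, _ = random_tensor_pair
        r = tensor_gsvd(*random_tensor_pair)
        lhs = r.U1 @ unfold_row(r.R1) @ np.kron(r.Vx.T, r.Vy.T)
        np.testing.assert_allclose(lhs, unfold_row(d1), atol=1e-9)

    def test_theta_equals_row_mode_theta_everywhere_defined(self, random_tensor_pair):
        r = tensor_gsvd(*random_tensor_pair)
        dev = np.abs(r.theta - r.theta_row[:, None, None])
        assert np.nanmax(dev) < 1e-10
        assert np.nanmax(np.abs(r.theta)) <= QUARTER_PI + 1e-12

    def test_core_cross_product_identity(self, random_tensor_pair):
        # R1 * sigma2 == R2 * sigma1 element-wise (valid at zeros too)
        r = tensor_gsvd(*random_tensor_pair)
        lhs = r.R1 * r.sigma_row2[:, None, None]
        rhs = r.R2 * r.sigma_row1[:, None, None]
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_identical_tensors_have_zero_theta(self, rng):
        d = rng.normal(size=(30, 3, 2))
        r = tensor_gsvd(d, d)
        assert np.nanmax(np.abs(r.theta)) < 1e-8
        sel = r.select_significant_subtensor(1)
        assert abs(sel.theta) < 1e-8

    def test_orthonormal_arraylets_unit_probelets(self, random_tensor_pair):
        r = tensor_gsvd(*random_tensor_pair)
        lm = r.U1.shape[1]
        assert np.abs(r.U1.T @ r.U1 - np.eye(lm)).max() < 1e-10
        assert np.abs(r.U2.T @ r.U2 - np.eye(lm)).max() < 1e-10
        np.testing.assert_allclose(np.linalg.norm(r.Vx.T, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(r.Vy.T, axis=1), 1.0, atol=1e-12)

    def test_single_subtensor_reconstruction(self, random_tensor_pair):
        r = tensor_gsvd(*random_tensor_pair)
        a, b, c = 2, 1, 2
        expected = r.R1[a - 1, b - 1, c - 1] * np.einsum(
            "k,l,m->klm", r.U1[:, a - 1], r.Vx[:, b - 1], r.Vy[:, c - 1]
        )
        np.testing.assert_allclose(r.subtensor(1, a, b, c), expected)

    def test_patient_permutation_equivariance(self, random_tensor_pair):
        d1, d2 = random_tensor_pair
        perm = np.array([2, 0, 3, 1])
        r = tensor_gsvd(d1, d2)
        rp = tensor_gsvd(d1[:, perm, :], d2[:, perm, :])
        # same ratios; Vx rows permuted (up to the +-1 phase freedom)
        np.testing.assert_allclose(
            rp.sigma_x1 / rp.sigma_x2, r.sigma_x1 / r.sigma_x2, atol=1e-8
        )
        cos = np.abs(np.einsum("lb,lb->b", rp.Vx, r.Vx[perm]))
        np.testing.assert_allclose(cos, 1.0, atol=1e-8)

    def test_dimension_mismatch_and_rank_errors(self, rng):
        with pytest.raises(ValueError, match="match"):
            TensorGSVD(rng.normal(size=(20, 3, 2)), rng.normal(size=(20, 4, 2)))
        with pytest.raises(ValueError, match="L\\*M"):
            TensorGSVD(rng.normal(size=(5, 3, 2)), rng.normal(size=(20, 3, 2)))
        flat = np.ones((20, 3, 2)) + 0.0
        with pytest.raises(RankDeficiencyError, match="unfolding"):
            tensor_gsvd(rng.normal(size=(20, 3, 2)), flat)


class TestSpecialCases:
    def test_order_two_reduces_to_matrix_gsvd(self, rng):
        a1, a2 = rng.normal(size=(12, 5)), rng.normal(size=(11, 5))
        r = tensor_gsvd(a1[:, :, None], a2[:, :, None])
        f = matrix_gsvd(a1, a2)
        np.testing.assert_allclose(r.sigma_row1, f.sigma1, atol=1e-8)
        np.testing.assert_allclose(r.sigma_row2, f.sigma2, atol=1e-8)
        sgn = np.sign(np.einsum("ka,ka->a", r.U1, f.U1))
        np.testing.assert_allclose(r.U1 * sgn, f.U1, atol=1e-8)
        np.testing.assert_allclose(r.U2 * sgn, f.U2, atol=1e-8)
        cos = np.abs(np.einsum("lb,lb->b", r.Vx, f.V))
        np.testing.assert_allclose(cos, 1.0, atol=1e-8)

    def test_identity_first_tensor_reduces_to_hosvd(self, rng):
        l, m = 4, 2
        lm = l * m
        d1 = np.eye(lm).reshape(lm, l, m)
        d2 = rng.normal(size=(30, l, m))
        r = tensor_gsvd(d1, d2)
        h = hosvd(d2)
        # mode singular values agree after sorting (GSVD orders by ratio)
        np.testing.assert_allclose(
            np.sort(r.sigma_row2)[::-1], linalg.svdvals(unfold_row(d2)), atol=1e-8
        )
        np.testing.assert_allclose(
            np.sort(r.sigma_x2)[::-1], linalg.svdvals(unfold_x(d2)), atol=1e-8
        )
        np.testing.assert_allclose(
            np.sort(r.sigma_y2)[::-1], linalg.svdvals(unfold_y(d2)), atol=1e-8
        )
        # factor vectors match pairwise up to sign (principal angles ~ 0)
        order = np.argsort(-r.sigma_row2)
        cos_u = [abs(r.U2[:, order[j]] @ h.factors[0][:, j]) for j in range(lm)]
        assert min(cos_u) > 1 - 1e-6
        order_x = np.argsort(-r.sigma_x2)
        cos_x = [abs(r.Vx[:, order_x[j]] @ h.factors[1][:, j]) for j in range(l)]
        assert min(cos_x) > 1 - 1e-6


class TestHosvd:
    def test_rank_one_tensor_core(self):
        u = np.array([3.0, 4.0])
        v = np.array([1.0, 2.0, 2.0])
        w = np.array([2.0, 0.0])
        # K >= L*M not needed for the HOSVD itself
        t = np.einsum("k,l,m->klm", u, v, w)
        h = hosvd(t)
        mags = np.abs(h.core)
        assert mags.max() == pytest.approx(
            np.linalg.norm(u) * np.linalg.norm(v) * np.linalg.norm(w)
        )
        assert np.sum(mags > 1e-10) == 1

    def test_reconstruction(self, rng):
        t = rng.normal(size=(8, 4, 2))
        h = hosvd(t)
        assert np.linalg.norm(t - h.reconstruct()) / np.linalg.norm(t) < 1e-10

    def test_mode1_factor_spans_row_unfolding_column_space(self, rng):
        t = rng.normal(size=(8, 3, 2))
        h = hosvd(t)
        proj = h.factors[0] @ h.factors[0].T
        d = unfold_row(t)
        np.testing.assert_allclose(proj @ d, d, atol=1e-10)


class TestSignificanceAndTheta:
    def test_single_nonzero_entry(self):
        r = np.zeros((4, 2, 2))
        r[1, 0, 1] = -3.0
        p = significance(r)
        assert p[1, 0, 1] == 1.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_magnitude_opposite_sign(self):
        r = np.zeros((2, 1, 1))
        r[0, 0, 0], r[1, 0, 0] = 2.0, -2.0
        np.testing.assert_allclose(significance(r).ravel(), [0.5, 0.5])

    def test_all_zero_core_errors(self):
        with pytest.raises(ValueError):
            significance(np.zeros((2, 2, 2)))

    def test_undefined_entries_flagged_not_zero(self):
        r1 = np.zeros((2, 1, 1))
        r2 = np.zeros((2, 1, 1))
        r1[0, 0, 0], r2[0, 0, 0] = 1.0, 1.0
        theta, _, defined = tensor_angular_distance(r1, r2)
        assert defined[0, 0, 0] and not defined[1, 0, 0]
        assert np.isnan(theta[1, 0, 0])
        assert theta[0, 0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_equal_cores_give_zero_theta(self, rng):
        r = rng.normal(size=(4, 2, 2))
        theta, _, defined = tensor_angular_distance(r, r)
        assert np.all(defined)
        np.testing.assert_allclose(theta, 0.0, atol=1e-14)


class TestSelection:
    def test_dominant_entry_selected_with_exclusivity(self, rng):
        d1, d2 = rng.normal(size=(40, 4, 2)), rng.normal(size=(50, 4, 2))
        r = tensor_gsvd(d1, d2)
        sel = r.select_significant_subtensor(1)
        p = r.significance1
        assert p[sel.a - 1, sel.b - 1, sel.c - 1] == p.max()
        assert sel.most_exclusive == (sel.a == 1)

    def test_tie_returns_lexicographically_smallest_with_warning(self):
        # symmetric construction: two exactly tied core entries
        r1 = np.zeros((2, 2, 1))
        r1[0, 0, 0] = r1[1, 1, 0] = 2.0
        from tensorgsvd.tensor import TensorGSVDResults, TensorGSVD as TG

        d = np.random.default_rng(0).normal(size=(4, 2, 1))
        res = TensorGSVDResults(
            model=TG(d, d),
            U1=np.eye(4)[:, :2],
            U2=np.eye(4)[:, :2],
            Vx=np.eye(2),
            Vy=np.eye(1),
            R1=r1,
            R2=r1.copy(),
            sigma_row1=np.ones(2),
            sigma_row2=np.ones(2),
            sigma_x1=np.ones(2),
            sigma_x2=np.ones(2),
            sigma_y1=np.ones(1),
            sigma_y2=np.ones(1),
            theta_row=np.zeros(2),
        )
        with pytest.warns(UserWarning, match="tie"):
            sel = res.select_significant_subtensor(1)
        assert (sel.a, sel.b, sel.c) == (1, 1, 1)


class TestSerialization:
    def test_round_trip_preserves_factors_and_reconstruction(self, tmp_path, rng):
        d1 = ThirdOrderTensor(rng.normal(size=(12, 3, 2)))
        d2 = ThirdOrderTensor(rng.normal(size=(14, 3, 2)))
        r = TensorGSVD(d1, d2).fit()
        r.save(tmp_path / "fac")
        from tensorgsvd import load_factorization

        r2 = load_factorization(tmp_path / "fac")
        np.testing.assert_allclose(r2.U1, r.U1, atol=1e-14)
        np.testing.assert_allclose(r2.R1, r.R1, atol=1e-14)
        np.testing.assert_allclose(r2.theta_row, r.theta_row, atol=1e-14)
        err = np.linalg.norm(d1.values - r2.reconstruct(1)) / np.linalg.norm(d1.values)
        assert err < 1e-8


def test_pattern_angular_distance_matches_factorized_theta_when_noiseless():
    # a pattern planted only in dataset 1 and probed at its own direction
    rng = np.random.default_rng(3)
    shape = np.zeros(60)
    shape[10:30] = 0.5
    carriers = np.zeros(6)
    carriers[[1, 4]] = 1.0
    w = np.array([1.0, 1.0])
    signal = np.einsum("k,l,m->klm", shape, carriers, w)
    noise1 = 0.02 * rng.normal(size=(60, 6, 2))
    noise2 = 0.02 * rng.normal(size=(60, 6, 2))
    th = pattern_angular_distance(signal + noise1, noise2, carriers, w)
    assert th > QUARTER_PI - 0.05
    common = pattern_angular_distance(signal + noise1, signal + noise2, carriers, w)
    assert abs(common) < 0.05
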