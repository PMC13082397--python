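"""Contrastive, adversarial and attention couplings between branches."""

import autograd
import autograd.numpy as anp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from duast import ModelConfig
from duast.interactions import (aam_loss, afm_loss, attention_fuse,
                                bilinear_score, decode_expression,
                                grad_reverse, lgcm_loss, local_summaries,
                                permute_negatives)
from duast.model import init_params

LOG2 = float(np.log(2.0))


class TestLocalSummaries:
    def test_identical_rows(self, rng):
        Z = np.tile(rng.normal(size=(1, 3)), (5, 1))
        nbrs = [np.array([1, 2]), np.array([0]), np.array([0, 3, 4]),
                np.array([2]), np.array([2])]
        np.testing.assert_allclose(local_summaries(Z, nbrs), Z)

    def test_two_node_path(self, rng):
        Z = rng.normal(size=(2, 4))
        C = local_summaries(Z, [np.array([1]), np.array([0])])
        np.testing.assert_allclose(C, Z[::-1])

    def test_star_hub_mean_of_leaves(self, rng):
        Z = rng.normal(size=(4, 3))
        nbrs = [np.array([1, 2, 3]), np.array([0]), np.array([0]),
                np.array([0])]
        C = local_summaries(Z, nbrs)
        np.testing.assert_allclose(C[0], Z[1:].mean(axis=0))

    def test_empty_neighbor_set_errors(self, rng):
        with pytest.raises(ValueError):
            local_summaries(rng.normal(size=(2, 2)), [np.array([1]), np.array([])])


class TestPermuteNegatives:
    def test_identity_permutation_injected(self, rng):
        Z = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(
            permute_negatives(Z, permutation=np.arange(6)), Z)

    def test_seed_determinism(self, rng):
        Z = rng.normal(size=(10, 2))
        np.testing.assert_array_equal(permute_negatives(Z, 42),
                                      permute_negatives(Z, 42))

    def test_row_multiset_preserved(self, rng):
        Z = rng.normal(size=(20, 4))
        Zn = permute_negatives(Z, 7)
        np.testing.assert_allclose(np.sort(Z, axis=0)[np.lexsort(Z.T[::-1])].shape,
                                   Zn.shape)
        # sort rows lexicographically and compare
        key = lambda M: M[np.lexsort(M.T)]
        np.testing.assert_array_equal(key(Z), key(Zn))


class TestLgcmLoss:
    def test_zero_discriminator_analytic_anchor(self, rng):
        N, d = 7, 4
        Z_sa, Z_ns, C, Z_neg = (rng.normal(size=(N, d)) for _ in range(4))
        loss = lgcm_loss(Z_sa, Z_ns, C, Z_neg, np.zeros((d, d)))
        assert float(loss) == pytest.approx(4 * LOG2, rel=1e-12)

    def test_identity_matrix_is_dot_product(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        np.testing.assert_allclose(bilinear_score(a, b, np.eye(3)),
                                   np.sum(a * b, axis=1))

    def test_perfect_discrimination_limit(self):
        # one latent dim; positives hugely positive, negatives hugely negative
        Z_sa = np.full((4, 1), 100.0)
        C = np.full((4, 1), 1.0)
        Z_ns = np.full((4, 1), 1.0)
        Z_neg = np.full((4, 1), -1.0)
        loss = lgcm_loss(Z_sa, Z_ns, C, Z_neg, np.eye(1))
        assert float(loss) == pytest.approx(0.0, abs=1e-6)


class TestGradReverse:
    def test_forward_is_identity_bitwise(self, rng):
        x = rng.normal(size=(5, 3))
        out = grad_reverse(x, 0.7)
        assert out is x or np.array_equal(out, x)

    def test_backward_negates_and_scales(self):
        g = autograd.grad(lambda x: anp.sum(grad_reverse(x, 1.0) ** 2))
        # d/dx of x^2 after reversal at x=3 is -6
        np.testing.assert_allclose(g(np.array([3.0])), [-6.0])
        g2 = autograd.grad(lambda x: anp.sum(grad_reverse(x, 2.5) * anp.array([1.0, -2.0])))
        np.testing.assert_allclose(g2(np.array([5.0, 5.0])), [-2.5, 5.0])

    def test_lambda_zero_blocks_gradient(self):
        g = autograd.grad(lambda x: anp.sum(grad_reverse(x, 0.0) ** 2))
        np.testing.assert_allclose(g(np.array([3.0])), [0.0])


class TestAamLoss:
    @pytest.fixture()
    def zero_disc_params(self):
        return {"dm_W1": np.zeros((3, 4)), "dm_b1": np.zeros(4),
                "dm_W2": np.zeros((4, 1)), "dm_b2": np.zeros(1)}

    def test_chance_level_analytic_anchor(self, rng, zero_disc_params):
        Z_sa = rng.normal(size=(6, 3))
        Z_ns = rng.normal(size=(6, 3))
        loss = aam_loss(Z_sa, Z_ns, zero_disc_params, grl_lambda=1.0)
        assert float(loss) == pytest.approx(2 * LOG2, rel=1e-12)

    def test_discriminator_win_limit(self):
        # hand-build a discriminator that outputs +big for positive inputs
        p = {"dm_W1": np.array([[1.0]]), "dm_b1": np.zeros(1),
             "dm_W2": np.array([[100.0]]), "dm_b2": np.array([-50.0])}
        Z_sa = np.full((3, 1), 1.0)   # logit +50 -> prob ~ 1
        Z_ns = np.full((3, 1), 0.0)   # logit -50 -> prob ~ 0
        assert float(aam_loss(Z_sa, Z_ns, p)) == pytest.approx(0.0, abs=1e-6)

    def test_swapping_branches_swaps_terms(self, rng):
        p = {"dm_W1": rng.normal(size=(3, 4)), "dm_b1": rng.normal(size=4),
             "dm_W2": rng.normal(size=(4, 1)), "dm_b2": rng.normal(size=1)}
        Z1 = rng.normal(size=(5, 3))
        Z2 = rng.normal(size=(5, 3))
        from duast.interactions import modality_probability

        l12 = float(aam_loss(Z1, Z2, p))
        p1 = np.clip(modality_probability(Z1, p), 1e-7, 1 - 1e-7)
        p2 = np.clip(modality_probability(Z2, p), 1e-7, 1 - 1e-7)
        swapped_expected = -np.mean(np.log(p2)) - np.mean(np.log(1 - p1))
        assert float(aam_loss(Z2, Z1, p)) == pytest.approx(swapped_expected)
        assert l12 == pytest.approx(-np.mean(np.log(p1)) - np.mean(np.log(1 - p2)))


class TestAttentionFuse:
    def test_zero_scorer_gives_equal_weights(self, rng):
        Z_sa = rng.normal(size=(6, 4))
        Z_ns = rng.normal(size=(6, 4))
        alphas, Z_att = attention_fuse(Z_sa, Z_ns, np.zeros(4))
        np.testing.assert_allclose(alphas, 0.5)
        np.testing.assert_allclose(Z_att, (Z_sa + Z_ns) / 2)

    def test_equal_branches_fixed_point(self, rng):
        Z = rng.normal(size=(5, 3))
        _, Z_att = attention_fuse(Z, Z, rng.normal(size=3))
        np.testing.assert_allclose(Z_att, Z, atol=1e-12)

    def test_softmax_closed_form(self):
        # logits (log 3, 0) -> weights (0.75, 0.25)
        Z_sa = np.array([[np.log(3.0)]])
        Z_ns = np.array([[0.0]])
        alphas, _ = attention_fuse(Z_sa, Z_ns, np.array([1.0]))
        np.testing.assert_allclose(alphas, [[0.75, 0.25]], rtol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, (4, 3), elements=st.floats(-50, 50)),
           arrays(np.float64, (4, 3), elements=st.floats(-50, 50)),
           arrays(np.float64, (3,), elements=st.floats(-5, 5)))
    def test_rows_sum_to_one_property(self, Z_sa, Z_ns, w):
        alphas, _ = attention_fuse(Z_sa, Z_ns, w)
        np.testing.assert_allclose(np.asarray(alphas).sum(axis=1), 1.0,
                                   atol=1e-6)
        assert np.all(np.asarray(alphas) >= 0)


class TestAfmLoss:
    def test_perfect_reconstruction(self):
        # decoder with identity-like weights on a 1-d latent
        p = {"dec_W1": np.array([[1.0]]), "dec_b1": np.zeros(1),
             "dec_W2": np.array([[1.0]]), "dec_b2": np.zeros(1)}
        Z = np.array([[2.0], [3.0]])
        loss, X_hat = afm_loss(Z, p, Z.copy())
        assert float(loss) == pytest.approx(0.0)
        np.testing.assert_allclose(X_hat, Z)

    def test_constant_offset(self):
        p = {"dec_W1": np.array([[1.0]]), "dec_b1": np.zeros(1),
             "dec_W2": np.array([[1.0]]), "dec_b2": np.array([1.0])}
        Z = np.array([[2.0], [3.0]])
        loss, _ = afm_loss(Z, p, Z.copy())
        assert float(loss) == pytest.approx(1.0)

    def test_hand_decode(self):
        p = {"dec_W1": np.array([[1.0, -1.0]]), "dec_b1": np.array([0.0, 0.0]),
             "dec_W2": np.array([[1.0], [2.0]]), "dec_b2": np.array([0.5])}
        Z = np.array([[1.0], [-1.0]])
        # row0: h=[1,0] -> 1*1+0*2+0.5 = 1.5 ; row1: h=[0,1] -> 2+0.5 = 2.5
        np.testing.assert_allclose(decode_expression(Z, p), [[1.5], [2.5]])
        X = np.array([[1.0], [2.0]])
        loss, _ = afm_loss(Z, p, X)
        assert float(loss) == pytest.approx(((1.5 - 1) ** 2 + (2.5 - 2) ** 2) / 2)
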