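"""Focal loss, trio valid degree and MCVLoss against closed forms and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trionet.genotype_space import MISMATCH_TABLE, build_beta_table
from trionet.losses import (
    LossConfig,
    combined_loss,
    focal_grad_logits,
    focal_loss,
    mcv_grad_probs,
    mcv_loss,
    softmax,
    trio_valid_degree,
)

BETA = build_beta_table(1e-8)


def one_hot(i):
    p = np.zeros(21)
    p[i] = 1.0
    return p


def brute_force_valid_degree(pc, p1, p2, beta):
    """Direct 9261-term sum, independent of the grouped computation."""
    outer = pc[:, None, None] * p1[None, :, None] * p2[None, None, :]
    return float((beta.values * outer).sum())


def _rand_dists(rng, n):
    x = rng.gamma(1.0, size=(n, 21))
    return x / x.sum(axis=1, keepdims=True)


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        assert focal_loss(np.array([3]), one_hot(3)[None, :]) == pytest.approx(0.0, abs=1e-8)

    def test_gamma_zero_is_cross_entropy(self):
        probs = np.array([[0.7] + [0.3 / 20] * 20])
        assert focal_loss(np.array([0]), probs, gamma=0.0) == pytest.approx(
            -math.log(0.7), rel=1e-6
        )

    def test_closed_form_at_half_mass(self):
        probs = np.array([[0.5] + [0.5 / 20] * 20])
        assert focal_loss(np.array([0]), probs, gamma=2.0) == pytest.approx(
            0.25 * math.log(2.0), rel=1e-6
        )

    def test_zero_true_class_probability_is_capped(self):
        probs = np.array([[0.0, 1.0] + [0.0] * 19])
        val = focal_loss(np.array([0]), probs, gamma=2.0, epsilon=1e-9)
        assert np.isfinite(val) and val == pytest.approx(-math.log(1e-9), rel=1e-6)

    def test_one_hot_labels_accepted(self):
        probs = np.array([[0.5] + [0.5 / 20] * 20])
        labels = np.zeros((1, 21))
        labels[0, 0] = 1.0
        assert focal_loss(labels, probs) == focal_loss(np.array([0]), probs)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(4, 21))
        labels = np.array([0, 5, 20, 13])
        grad = focal_grad_logits(labels, softmax(logits))
        eps = 1e-6
        for b, i in [(0, 0), (1, 5), (2, 2), (3, 20)]:
            up, dn = logits.copy(), logits.copy()
            up[b, i] += eps
            dn[b, i] -= eps
            num = (
                focal_loss(labels, softmax(up)) - focal_loss(labels, softmax(dn))
            ) / (2 * eps)
            assert grad[b, i] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestValidDegree:
    def test_single_consistent_triple(self):
        p = one_hot(0)
        assert trio_valid_degree(p, p, p, BETA) == pytest.approx((1 - 1e-8) ** 2)

    def test_single_two_mismatch_triple(self):
        # child hom-alt C/C from two hom-ref A/A parents
        assert trio_valid_degree(one_hot(6), one_hot(0), one_hot(0), BETA) == pytest.approx(
            1e-16
        )

    def test_uniform_distributions_closed_form(self):
        u = np.full(21, 1 / 21)
        expected = (1281 * (1 - 1e-8) ** 2 + 5130 * 1e-8 + 2850 * 1e-16) / 9261
        assert trio_valid_degree(u, u, u, BETA) == pytest.approx(expected, rel=1e-12)

    def test_grouped_equals_direct_sum(self, rng):
        dists = _rand_dists(rng, 3 * 50)
        for k in range(50):
            pc, p1, p2 = dists[3 * k], dists[3 * k + 1], dists[3 * k + 2]
            direct = brute_force_valid_degree(pc, p1, p2, BETA)
            assert abs(trio_valid_degree(pc, p1, p2, BETA) - direct) <= 1e-12

    def test_rejects_unnormalized_input(self):
        bad = np.full(21, 0.1)
        with pytest.raises(ValueError):
            trio_valid_degree(bad, one_hot(0), one_hot(0), BETA)

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        pc, p1, p2 = _rand_dists(r, 3)
        v = trio_valid_degree(pc, p1, p2, BETA)
        assert 0.0 < v < 1.0

    def test_product_distribution_normalizes(self, rng):
        pc, p1, p2 = _rand_dists(rng, 3)
        outer = pc[:, None, None] * p1[None, :, None] * p2[None, None, :]
        assert outer.sum() == pytest.approx(1.0, abs=1e-9)


class TestMcvLoss:
    def test_alpha_zero_disables_the_penalty(self, rng):
        pc, p1, p2 = _rand_dists(rng, 3)
        assert mcv_loss(pc, p1, p2, LossConfig(alpha=0.0)) == 0.0

    def test_two_mismatch_mass_hits_the_epsilon_cap(self):
        cfg = LossConfig(alpha=1.0, epsilon=1e-9, mu=1e-8)
        val = mcv_loss(one_hot(6), one_hot(0), one_hot(0), cfg)
        assert val == pytest.approx(-math.log(1e-16 + 1e-9), rel=1e-9)

    def test_consistent_mass_is_near_zero(self):
        cfg = LossConfig(alpha=1.0)
        val = mcv_loss(one_hot(0), one_hot(0), one_hot(0), cfg)
        assert val == pytest.approx(-math.log((1 - 1e-8) ** 2 + 1e-9))
        assert abs(val) < 1e-6

    def test_parent_swap_invariance(self, rng):
        pc, p1, p2 = _rand_dists(rng, 3)
        cfg = LossConfig(alpha=2.5)
        assert mcv_loss(pc, p1, p2, cfg) == pytest.approx(mcv_loss(pc, p2, p1, cfg))

    def test_mass_transfer_to_consistent_strictly_decreases(self, rng):
        # with concentrated parents the child classes map one-to-one onto trio
        # triples, so this is a transfer from a violating to a consistent triple
        cfg = LossConfig(alpha=1.0)
        for _ in range(20):
            j, k = rng.integers(0, 21, size=2)
            p1, p2 = np.zeros(21), np.zeros(21)
            p1[j] = p2[k] = 1.0
            pc = _rand_dists(rng, 1)[0]
            consistent = int(np.flatnonzero(MISMATCH_TABLE[:, j, k] == 0)[0])
            violating = int(np.flatnonzero(MISMATCH_TABLE[:, j, k] == 2)[0])
            delta = 0.5 * pc[violating] + 1e-6
            moved = pc.copy()
            moved[violating] -= delta
            moved[consistent] += delta
            assert mcv_loss(moved, p1, p2, cfg) < mcv_loss(pc, p1, p2, cfg)

    def test_projected_gradient_signs(self):
        # under the probability-simplex constraint, the descent direction moves
        # child mass towards consistent classes and away from two-mismatch ones
        cfg = LossConfig(alpha=1.0)
        u = np.full((1, 21), 1 / 21)
        hot = one_hot(0)[None, :]  # both parents confidently A/A
        gc, _, _ = mcv_grad_probs(u, hot, hot, cfg)
        projected = u * (gc - (gc * u).sum(axis=1, keepdims=True))
        assert projected[0, 0] < 0  # A/A child: the only consistent class
        assert projected[0, 6] > 0  # C/C child: two-mismatch class


class TestCombinedLoss:
    def test_reduces_to_focal_terms_without_penalties(self, rng):
        dists = _rand_dists(rng, 9).reshape(3, 3, 21)
        labels = tuple(np.array([0, 4, 20]) for _ in range(3))
        cfg = LossConfig(alpha=0.0, l2_weight=0.0)
        total = combined_loss(tuple(dists), labels, cfg)
        expected = sum(focal_loss(l, d) for l, d in zip(labels, dists))
        assert total == pytest.approx(expected, rel=1e-12)

    def test_perfect_consistent_predictions_leave_only_the_floor(self):
        probs = tuple(one_hot(0)[None, :] for _ in range(3))
        labels = tuple(np.array([0]) for _ in range(3))
        total = combined_loss(probs, labels, LossConfig(alpha=1.0))
        assert total == pytest.approx(-math.log((1 - 1e-8) ** 2 + 1e-9), abs=1e-8)

    def test_misaligned_batches_rejected(self, rng):
        d = _rand_dists(rng, 2)
        with pytest.raises(ValueError):
            combined_loss(
                (d, d, d[:1]), tuple(np.array([0, 1]) for _ in range(3)), LossConfig()
            )
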