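"""The contrastive core: kernel, world representations, triplet loss, EMA.

Oracles here are deliberately independent of the implementation: explicit
exp/loop arithmetic rather than calls back into the library.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contrawr import (
    ContrastiveConfig,
    batch_loss,
    batch_loss_and_grad,
    ema_update,
    gaussian_similarity,
    instance_aware_world_representation,
    knn_topx_negative,
    max_similarity_gap,
    triplet_loss,
    world_representation,
)
from helpers import numeric_grad


def unit_rows(rng, m, d):
    v = rng.standard_normal((m, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# -- Gaussian kernel -----------------------------------------------------


class TestGaussianSimilarity:
    def test_identical_vectors_give_one(self, rng):
        a = unit_rows(rng, 1, 6)[0]
        assert gaussian_similarity(a, a, sigma=0.7) == 1.0

    def test_antipodal_closed_form(self):
        a = np.array([1.0, 0.0, 0.0])
        val = gaussian_similarity(a, -a, sigma=2.0)
        assert val == pytest.approx(math.exp(-0.5), abs=1e-12)
        assert round(float(val), 4) == 0.6065

    def test_symmetry_and_range(self, rng):
        a, b = unit_rows(rng, 2, 8)
        s = gaussian_similarity(a, b, 1.3)
        assert s == gaussian_similarity(b, a, 1.3)
        assert 0.0 < s <= 1.0

    def test_monotone_in_distance_and_cosine(self):
        a = np.array([1.0, 0.0])
        angles = np.linspace(0, np.pi, 50)
        pts = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        sims = gaussian_similarity(np.tile(a, (50, 1)), pts, sigma=2.0)
        assert np.all(np.diff(sims) < 0)  # decreasing as cosine decreases

    def test_large_sigma_flattens(self, rng):
        a, b, c = unit_rows(rng, 3, 5)
        wide = gaussian_similarity(a, b, 1e4) - gaussian_similarity(a, c, 1e4)
        assert abs(wide) < 1e-6

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_similarity(np.ones(3), np.ones(3), 0.0)

    def test_similarity_gap_bound(self):
        closed, numeric = max_similarity_gap(sigma=2.0, n_restarts=16, seed=0)
        assert closed == pytest.approx(1.0 - math.exp(-0.5), abs=1e-12)
        assert round(closed, 4) == 0.3935
        assert numeric == pytest.approx(closed, abs=1e-6)


# -- world representations -----------------------------------------------


class TestWorldRepresentation:
    def test_antipodal_pair_averages_to_zero(self):
        z = np.array([[0.0, 1.0], [0.0, -1.0]])
        np.testing.assert_array_equal(world_representation(z), [0.0, 0.0])

    def test_identical_batch_is_fixed_point(self, rng):
        z = np.tile(unit_rows(rng, 1, 4), (5, 1))
        np.testing.assert_allclose(world_representation(z), z[0], atol=1e-12)

    def test_matches_summation_oracle(self, rng):
        z = unit_rows(rng, 8, 5)
        oracle = np.zeros(5)
        for row in z:
            oracle += row
        oracle /= 8
        np.testing.assert_allclose(world_representation(z), oracle, atol=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            world_representation(np.empty((0, 3)))

    @given(st.integers(2, 12), st.integers(2, 6), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mean_stays_in_unit_ball(self, m, d, seed):
        z = unit_rows(np.random.default_rng(seed), m, d)
        assert np.linalg.norm(world_representation(z)) <= 1.0 + 1e-12


class TestInstanceAwareWorld:
    def test_high_temperature_recovers_uniform_mean(self, rng):
        z = unit_rows(rng, 10, 6)
        zw = instance_aware_world_representation(z[0], z, temperature=1e9)
        np.testing.assert_allclose(zw, world_representation(z), atol=1e-6)

    def test_low_temperature_selects_nearest(self, rng):
        z = unit_rows(rng, 10, 6)
        anchor = z[3] + 0.01 * rng.standard_normal(6)
        anchor /= np.linalg.norm(anchor)
        zw = instance_aware_world_representation(anchor, z, temperature=1e-9)
        nearest = z[np.argmax(z @ anchor)]
        np.testing.assert_allclose(zw, nearest, atol=1e-6)

    def test_matches_hand_coded_softmax_mean(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        anchor = np.array([1.0, 0.0])
        T = 2.0
        w = [math.exp(np.dot(row, anchor) / T) for row in z]
        total = sum(w)
        oracle = sum((wi / total) * row for wi, row in zip(w, z))
        zw = instance_aware_world_representation(anchor, z, temperature=T)
        np.testing.assert_allclose(zw, oracle, atol=1e-10)

    def test_invalid_temperature_rejected(self, rng):
        z = unit_rows(rng, 4, 3)
        with pytest.raises(ValueError, match="temperature"):
            instance_aware_world_representation(z[0], z, temperature=0.0)

    @given(st.integers(2, 10), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_weights_proper_and_monotone(self, m, seed):
        rng = np.random.default_rng(seed)
        z = unit_rows(rng, m, 4)
        anchor = unit_rows(rng, 1, 4)[0]
        T = 1.7
        logits = z @ anchor / T
        w = np.exp(logits - logits.max())
        w /= w.sum()
        assert np.all(w > 0) and w.sum() == pytest.approx(1.0)
        order = np.argsort(z @ anchor)
        assert np.all(np.diff(w[order]) >= -1e-15)  # larger inner product, larger weight
        zw = instance_aware_world_representation(anchor, z, T)
        np.testing.assert_allclose(zw, w @ z, atol=1e-12)
        assert np.linalg.norm(zw) <= 1.0 + 1e-12


class TestKnnTopX:
    def test_full_batch_equals_uniform_world(self, rng):
        z = unit_rows(rng, 6, 4)
        np.testing.assert_array_equal(
            knn_topx_negative(z[0], z, topx=6), world_representation(z)
        )

    def test_top1_is_nearest_member(self, rng):
        z = unit_rows(rng, 7, 4)
        anchor = unit_rows(rng, 1, 4)[0]
        d2 = ((z - anchor) ** 2).sum(axis=1)
        np.testing.assert_array_equal(
            knn_topx_negative(anchor, z, topx=1), z[d2.argmin()]
        )

    def test_top2_matches_sort_and_average_oracle(self, rng):
        z = unit_rows(rng, 4, 3)
        anchor = unit_rows(rng, 1, 3)[0]
        d2 = ((z - anchor) ** 2).sum(axis=1)
        idx = np.argsort(d2)[:2]
        oracle = z[np.sort(idx)].mean(axis=0)
        np.testing.assert_allclose(
            knn_topx_negative(anchor, z, topx=2), oracle, atol=1e-12
        )

    def test_ties_break_toward_lower_index(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, -1.0], [1.0, 0.0]])
        anchor = np.array([0.0, 1.0])
        # members 0 and 3 are equidistant from the anchor; X=2 takes {1, 0}
        np.testing.assert_allclose(
            knn_topx_negative(anchor, z, topx=2), (z[0] + z[1]) / 2, atol=1e-12
        )

    def test_topx_out_of_range_rejected(self, rng):
        z = unit_rows(rng, 3, 2)
        with pytest.raises(ValueError, match="topx"):
            knn_topx_negative(z[0], z, topx=4)


# -- triplet loss --------------------------------------------------------


class TestTripletLoss:
    def test_positive_equal_to_world_hinges_at_margin(self, rng):
        z = unit_rows(rng, 2, 5)
        assert triplet_loss(z[0], z[1], z[1], sigma=2.0, delta=0.2) == pytest.approx(0.2)

    def test_perfect_positive_far_world_is_zero(self):
        a = np.array([1.0, 0.0])
        assert triplet_loss(a, a, -a, sigma=2.0, delta=0.2) == 0.0

    def test_worst_case_equals_margin(self):
        a = np.array([1.0, 0.0])
        val = triplet_loss(a, -a, -a, sigma=2.0, delta=0.2)
        assert val == pytest.approx(0.2, abs=1e-12)

    def test_batch_loss_matches_per_anchor_loop(self, rng):
        for m in (4, 9, 16):
            anchors = unit_rows(rng, m, 6)
            positives = unit_rows(rng, m, 6)
            for mode, extra in (
                ("contrawr", {}),
                ("contrawr_plus", {}),
                ("avg_knn_topx", {"topx": 3}),
            ):
                cfg = ContrastiveConfig(batch_size=m, mode=mode, **extra)
                expected = 0.0
                for i in range(m):
                    if mode == "contrawr":
                        zw = positives.mean(axis=0)
                    elif mode == "contrawr_plus":
                        logits = positives @ anchors[i] / cfg.temperature
                        w = np.exp(logits - logits.max())
                        w /= w.sum()
                        zw = w @ positives
                    else:
                        d2 = ((positives - anchors[i]) ** 2).sum(axis=1)
                        zw = positives[np.sort(np.argsort(d2, kind="stable")[:3])].mean(axis=0)
                    s_w = math.exp(-((anchors[i] - zw) ** 2).sum() / (2 * cfg.sigma**2))
                    s_p = math.exp(
                        -((anchors[i] - positives[i]) ** 2).sum() / (2 * cfg.sigma**2)
                    )
                    expected += max(0.0, s_w + cfg.delta - s_p)
                expected /= m
                assert batch_loss(anchors, positives, cfg) == pytest.approx(
                    expected, abs=1e-10
                )

    def test_knn_full_batch_equals_contrawr_bitwise(self, rng):
        anchors = unit_rows(rng, 8, 5)
        positives = unit_rows(rng, 8, 5)
        a = batch_loss(anchors, positives, ContrastiveConfig(batch_size=8, mode="contrawr"))
        b = batch_loss(
            anchors, positives, ContrastiveConfig(batch_size=8, mode="avg_knn_topx", topx=8)
        )
        assert a == b

    def test_zero_loss_when_positive_dominates(self):
        # antipodal anchors/positives: world mean is the origin; at sigma=1
        # the positive similarity (1.0) beats sim to the origin by > delta
        anchors = np.array([[1.0, 0.0], [-1.0, 0.0]])
        cfg = ContrastiveConfig(batch_size=2, sigma=1.0, delta=0.2, mode="contrawr")
        assert batch_loss(anchors, anchors.copy(), cfg) == 0.0

    def test_per_anchor_loss_bounded_by_similarity_gap(self, rng):
        cfg = ContrastiveConfig(batch_size=16, mode="contrawr")
        bound = (1.0 - math.exp(-(2.0**2) / (2 * cfg.sigma**2))) + cfg.delta
        for seed in range(5):
            r = np.random.default_rng(seed)
            loss = batch_loss(unit_rows(r, 16, 8), unit_rows(r, 16, 8), cfg)
            assert 0.0 <= loss <= bound

    def test_misaligned_batch_rejected(self, rng):
        cfg = ContrastiveConfig(batch_size=4)
        with pytest.raises(ValueError, match="aligned"):
            batch_loss(unit_rows(rng, 4, 3), unit_rows(rng, 5, 3), cfg)

    def test_anchor_gradient_matches_numeric(self, rng):
        anchors = unit_rows(rng, 5, 4)
        positives = unit_rows(rng, 5, 4)
        for mode, extra in (("contrawr", {}), ("avg_knn_topx", {"topx": 2})):
            cfg = ContrastiveConfig(batch_size=5, mode=mode, **extra)
            _, grad = batch_loss_and_grad(anchors, positives, cfg)
            gn = numeric_grad(lambda: batch_loss(anchors, positives, cfg), anchors)
            np.testing.assert_allclose(grad, gn, rtol=1e-5, atol=1e-8)

    def test_exclude_self_changes_the_reference(self, rng):
        anchors = unit_rows(rng, 6, 4)
        positives = unit_rows(rng, 6, 4)
        inc = ContrastiveConfig(batch_size=6, mode="contrawr")
        exc = ContrastiveConfig(batch_size=6, mode="contrawr", exclude_self=True)
        assert batch_loss(anchors, positives, inc) != batch_loss(anchors, positives, exc)


# -- EMA -----------------------------------------------------------------


class TestEmaUpdate:
    def test_boundary_identities(self, rng):
        theta = [rng.standard_normal((3, 2)), rng.standard_normal(4)]
        phi = [rng.standard_normal((3, 2)), rng.standard_normal(4)]
        keep = [p.copy() for p in phi]
        ema_update(theta, phi, lam=1.0)
        for a, b in zip(phi, keep):
            np.testing.assert_array_equal(a, b)
        ema_update(theta, phi, lam=0.0)
        for a, b in zip(phi, theta):
            np.testing.assert_array_equal(a, b)

    def test_scalar_arithmetic(self):
        phi = [np.array([0.0])]
        ema_update([np.array([1.0])], phi, lam=0.9)
        assert phi[0][0] == pytest.approx(0.1, abs=1e-15)

    def test_geometric_decay_toward_constant_theta(self):
        theta = [np.full(5, 2.0)]
        phi = [np.zeros(5)]
        lam = 0.8
        prev = np.linalg.norm(phi[0] - theta[0])
        for _ in range(20):
            ema_update(theta, phi, lam)
            cur = np.linalg.norm(phi[0] - theta[0])
            assert cur == pytest.approx(lam * prev, abs=1e-12)
            prev = cur

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_update([np.zeros(3)], [np.zeros(3), np.zeros(2)], 0.5)
        with pytest.raises(ValueError, match="shape"):
            ema_update([np.zeros(3)], [np.zeros(4)], 0.5)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            ema_update([np.zeros(2)], [np.zeros(2)], 1.5)


# -- configuration -------------------------------------------------------


class TestContrastiveConfig:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(sigma=0.0), "sigma"),
            (dict(delta=0.0), "delta"),
            (dict(temperature=-1.0), "temperature"),
            (dict(ema_lambda=1.5), "ema_lambda"),
            (dict(batch_size=1), "batch_size"),
            (dict(mode="simclr"), "mode"),
            (dict(mode="avg_knn_topx"), "topx"),
            (dict(mode="avg_knn_topx", topx=300, batch_size=256), "topx"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            ContrastiveConfig(**kwargs)

    def test_small_margin_at_sigma_two_warns(self):
        with pytest.warns(UserWarning, match="0.3935"):
            ContrastiveConfig(sigma=2.0, delta=0.05)
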