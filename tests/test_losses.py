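"""Loss functions versus independent scalar-loop oracles and closed forms."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cslearn.autodiff import Tensor
from cslearn.embedding import PrototypeSet
from cslearn.losses import (
    LossWeights,
    cluster_penalty,
    csr_loss,
    cycle_loss,
    dce_loss,
    ksi_loss,
    prototype_loss,
    separation_loss,
)

# ---------------------------------------------------------------------------
# scalar-loop oracles (kept deliberately naive and independent of the
# vectorized implementations)


def sq_dist_oracle(a, b):
    return sum((float(x) - float(y)) ** 2 for x, y in zip(a, b))


def dce_oracle(z, k, M, gamma):
    dists = [sq_dist_oracle(z, m) for m in M]
    weights = [math.exp(-gamma * (d - min(dists))) for d in dists]
    return -math.log(weights[k] / sum(weights))


def separation_oracle(M, eps):
    mu = [sum(col) / len(M) for col in zip(*M)]
    return max(-math.log(max(sq_dist_oracle(m, mu), eps)) for m in M)


def cluster_oracle(z, M, gamma):
    mu = [sum(col) / len(M) for col in zip(*M)]
    d_all = [sq_dist_oracle(z, mu)] + [sq_dist_oracle(z, m) for m in M]
    weights = [math.exp(-gamma * (d - min(d_all))) for d in d_all]
    return -math.log(weights[0] / sum(weights))


def _protos(rng, k=3, d=4, scale=2.0):
    return PrototypeSet(scale * rng.standard_normal((k, d)))


# ---------------------------------------------------------------------------


class TestDceLoss:
    def test_uniform_distances_give_log_k(self, rng):
        """Any gamma: equidistant prototypes produce the maximum-entropy loss."""
        for k in (2, 3, 7):
            for gamma in (0.1, 1.0, 5.0):
                protos = PrototypeSet(np.eye(k))  # all rows unit distance from any scaled-center z
                z = np.full(k, 1.0 / k)  # equidistant from every e_i
                val = dce_loss(z, 0, protos, gamma).item()
                assert val == pytest.approx(math.log(k), rel=1e-9)

    @pytest.mark.parametrize(
        "label,expected",
        [(0, math.log(1 + math.exp(-2))), (1, 2 + math.log(1 + math.exp(-2)))],
    )
    def test_two_prototype_closed_form(self, label, expected):
        """d(z,m1)=0, d(z,m2)=2 at gamma=1: hand-derived softmax values."""
        protos = PrototypeSet(np.array([[0.0, 0.0], [math.sqrt(2), 0.0]]))
        z = np.zeros(2)
        assert dce_loss(z, label, protos, 1.0).item() == pytest.approx(expected, rel=1e-9)

    def test_matches_scalar_oracle_on_random_instances(self, rng):
        for _ in range(100):
            k, d = rng.integers(2, 6), rng.integers(1, 6)
            protos = _protos(rng, k, d)
            z = rng.standard_normal(d)
            label = int(rng.integers(k))
            gamma = float(rng.uniform(0.1, 3.0))
            expected = dce_oracle(z, label, protos.matrix, gamma)
            assert dce_loss(z, label, protos, gamma).item() == pytest.approx(expected, rel=1e-5)

    def test_nonnegative_and_label_validation(self, rng):
        protos = _protos(rng)
        assert dce_loss(rng.standard_normal(4), 0, protos).item() >= 0
        with pytest.raises(ValueError):
            dce_loss(rng.standard_normal(4), 99, protos)
        with pytest.raises(ValueError):
            dce_loss(rng.standard_normal(4), 0, protos, gamma=-1.0)

    def test_extreme_distances_stay_finite(self):
        protos = PrototypeSet(np.array([[0.0, 0.0], [100.0, 0.0]]))
        val = dce_loss(np.zeros(2), 0, protos, gamma=10.0).item()
        assert np.isfinite(val) and val >= 0


class TestPrototypeLoss:
    def test_zero_iff_on_prototype(self, rng):
        protos = _protos(rng)
        assert prototype_loss(protos.matrix[1], 1, protos).item() == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five(self):
        protos = PrototypeSet(np.array([[0.0, 0.0], [10.0, 10.0]]))
        assert prototype_loss(np.array([3.0, 4.0]), 0, protos).item() == pytest.approx(25.0)

    def test_matches_oracle(self, rng):
        for _ in range(100):
            protos = _protos(rng, 4, 8)
            z = rng.standard_normal(8)
            k = int(rng.integers(4))
            assert prototype_loss(z, k, protos).item() == pytest.approx(
                sq_dist_oracle(z, protos.matrix[k]), rel=1e-5
            )


class TestSeparationLoss:
    def test_unit_sphere_prototypes_give_zero(self):
        protos = PrototypeSet(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert separation_loss(protos).item() == pytest.approx(0.0, abs=1e-12)

    def test_prototype_at_center_activates_clamp(self):
        protos = PrototypeSet(np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]]))
        eps = 1e-8
        assert separation_loss(protos, eps).item() == pytest.approx(-math.log(eps))

    def test_hand_computed_asymmetric_case(self):
        # mu = (1, 0); both prototypes at squared distance 1 from mu
        protos = PrototypeSet(np.array([[2.0, 0.0], [0.0, 0.0]]))
        assert separation_loss(protos).item() == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(100):
            protos = _protos(rng, int(rng.integers(2, 6)), 3)
            expected = separation_oracle(protos.matrix, 1e-8)
            assert separation_loss(protos).item() == pytest.approx(expected, rel=1e-5)

    def test_moving_nearest_prototype_outward_decreases_loss(self, rng):
        """Radially moving the argmin prototype away from mu lowers the max."""
        protos = PrototypeSet(np.array([[2.0, 0.0], [-2.0, 0.1], [0.4, 0.0]]))
        base = separation_loss(protos).item()
        mu = protos.center_numpy()
        i = np.argmin(np.linalg.norm(protos.matrix - mu, axis=1))
        shifted = protos.matrix.copy()
        shifted[i] = mu + 1.3 * (shifted[i] - mu)
        moved = separation_loss(PrototypeSet(shifted)).item()
        assert moved < base

    def test_needs_two_prototypes(self):
        with pytest.raises(ValueError):
            separation_loss(PrototypeSet(np.ones((1, 2))))


class TestKsiLoss:
    def test_zero_weights_reduce_to_dce(self, rng):
        protos = _protos(rng, 3, 4)
        z = rng.standard_normal((6, 4))
        labels = rng.integers(0, 3, 6)
        w = LossWeights(alpha1=0.0, beta1=0.0)
        assert ksi_loss(z, labels, protos, w).item() == pytest.approx(
            dce_loss(z, labels, protos, w.gamma).item(), rel=1e-12
        )

    def test_equals_weighted_sum_of_components(self, rng):
        protos = _protos(rng, 3, 4)
        z = rng.standard_normal((5, 4))
        labels = rng.integers(0, 3, 5)
        w = LossWeights(alpha1=0.3, beta1=0.7)
        expected = (
            dce_loss(z, labels, protos, w.gamma).item()
            + 0.3 * prototype_loss(z, labels, protos).item()
            + 0.7 * separation_loss(protos, w.epsilon).item()
        )
        assert ksi_loss(z, labels, protos, w).item() == pytest.approx(expected, rel=1e-10)

    def test_mean_reduction_invariant_to_batch_duplication(self, rng):
        protos = _protos(rng, 3, 4)
        z = rng.standard_normal((4, 4))
        labels = rng.integers(0, 3, 4)
        w = LossWeights()
        single = ksi_loss(z, labels, protos, w).item()
        doubled = ksi_loss(np.vstack([z, z]), np.concatenate([labels, labels]), protos, w).item()
        assert doubled == pytest.approx(single, rel=1e-12)


class TestCycleLoss:
    def test_identical_latents_give_zero(self, rng):
        f = rng.standard_normal((3, 8))
        assert cycle_loss(f, f.copy()).item() == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five_is_unsquared(self):
        assert cycle_loss(np.zeros(2), np.array([3.0, 4.0])).item() == pytest.approx(5.0)

    def test_matches_sqrt_of_sum_oracle(self, rng):
        for _ in range(100):
            f = rng.standard_normal(8)
            f2 = rng.standard_normal(8)
            assert cycle_loss(f, f2).item() == pytest.approx(
                math.sqrt(sq_dist_oracle(f, f2)), rel=1e-5
            )

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            cycle_loss(rng.standard_normal(4), rng.standard_normal(5))


class TestClusterPenalty:
    def test_full_symmetry_gives_log_k_plus_one(self):
        """z equidistant to the center and every prototype: uniform softmax.

        A derived centroid is always strictly closer to z than the
        prototypes are (parallelogram law), so exact symmetry is realized
        through the explicit center override: center and prototypes all at
        unit distance from z.
        """
        protos = PrototypeSet(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        center = Tensor(np.array([0.0, 1.0]))
        for gamma in (0.5, 1.0, 2.0):
            val = cluster_penalty(np.zeros(2), protos, gamma=gamma, center=center).item()
            assert val == pytest.approx(math.log(3), rel=1e-9)

    def test_anchor_at_center_with_distant_prototypes(self):
        protos = PrototypeSet(np.array([[math.sqrt(10), 0.0], [-math.sqrt(10), 0.0]]))
        val = cluster_penalty(np.zeros(2), protos, gamma=1.0).item()
        assert val == pytest.approx(math.log(1 + 2 * math.exp(-10)), rel=1e-9)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            protos = _protos(rng, int(rng.integers(2, 5)), 3)
            z = rng.standard_normal(3)
            gamma = float(rng.uniform(0.2, 2.0))
            assert cluster_penalty(z, protos, gamma).item() == pytest.approx(
                cluster_oracle(z, protos.matrix, gamma), rel=1e-5
            )

    def test_literal_mode_telescopes(self):
        """The literal printed ratio reduces to -gamma * sum of prototype distances."""
        protos = PrototypeSet(np.array([[1.0, 0.0], [0.0, -math.sqrt(2)]]))
        z = np.zeros(2)  # d(z,m1)=1, d(z,m2)=2
        assert cluster_penalty(z, protos, gamma=1.0, mode="literal").item() == pytest.approx(-3.0)

    def test_monotone_decrease_along_segment_to_center(self, rng):
        """Sliding an anchor from a prototype toward mu lowers the penalty."""
        protos = _protos(rng, 4, 3)
        mu = protos.center_numpy()
        start = protos.matrix[2]
        vals = [
            cluster_penalty(start + t * (mu - start), protos, gamma=1.0).item()
            for t in np.linspace(0, 1, 11)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_penalty(rng.standard_normal(3), _protos(rng, 2, 3), mode="bogus")


class TestCsrLoss:
    def test_theta_zero_reduces_to_stage1_form(self, rng):
        protos = _protos(rng, 3, 4)
        z = rng.standard_normal((5, 4))
        labels = rng.integers(0, 3, 5)
        anchors = rng.standard_normal((5, 4))
        w = LossWeights(alpha2=0.4, beta2=0.2, theta=0.0)
        w_equiv = LossWeights(alpha1=0.4, beta1=0.2)
        assert csr_loss(z, labels, anchors, protos, w).item() == pytest.approx(
            ksi_loss(z, labels, protos, w_equiv).item(), rel=1e-10
        )

    def test_equals_weighted_component_sum_at_published_weights(self, rng):
        protos = _protos(rng, 3, 4)
        z = rng.standard_normal((5, 4))
        labels = rng.integers(0, 3, 5)
        anchors = rng.standard_normal((6, 4))
        w = LossWeights(alpha2=0.1, beta2=0.01, theta=0.1)
        expected = (
            dce_loss(z, labels, protos, w.gamma).item()
            + 0.1 * prototype_loss(z, labels, protos).item()
            + 0.01 * separation_loss(protos, w.epsilon).item()
            + 0.1 * cluster_penalty(anchors, protos, w.gamma).item()
        )
        assert csr_loss(z, labels, anchors, protos, w).item() == pytest.approx(expected, rel=1e-10)

    def test_anchors_at_center_leave_stage1_value(self, rng):
        protos = PrototypeSet(10.0 * np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]]))
        z = rng.standard_normal((4, 2))
        labels = rng.integers(0, 4, 4)
        anchors = np.tile(protos.center_numpy(), (4, 1))
        w = LossWeights()
        with_anchor = csr_loss(z, labels, anchors, protos, w).item()
        without = ksi_loss(z, labels, protos, LossWeights(alpha1=w.alpha2, beta1=w.beta2)).item()
        assert with_anchor == pytest.approx(without, abs=1e-6)

    def test_cluster_gradient_stops_at_prototypes(self, rng):
        """Prototype gradients are identical with and without the cluster term."""
        protos = _protos(rng, 3, 4)
        z = Tensor(rng.standard_normal((5, 4)))
        labels = rng.integers(0, 3, 5)
        anchors = rng.standard_normal((5, 4))

        protos.M.grad = None
        csr_loss(z, labels, anchors, protos, LossWeights(theta=0.0)).backward()
        g_without = protos.M.grad.copy()
        protos.M.grad = None
        csr_loss(z, labels, anchors, protos, LossWeights(theta=5.0)).backward()
        g_with = protos.M.grad.copy()
        np.testing.assert_allclose(g_with, g_without, rtol=1e-12)


# ---------------------------------------------------------------------------
# gradient checks


def central_difference(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "loss_name",
    ["dce", "prototype", "separation", "ksi", "cycle", "cluster", "csr"],
)
def test_analytic_gradients_match_finite_differences(loss_name, rng):
    """Backward pass of every loss agrees with central differences to 1e-4."""
    k, d, n = 3, 4, 5
    protos = _protos(rng, k, d)
    z = Tensor(rng.standard_normal((n, d)), requires_grad=True)
    labels = rng.integers(0, k, n)
    z2 = Tensor(rng.standard_normal((n, d)), requires_grad=True)
    w = LossWeights(alpha1=0.3, beta1=0.2, alpha2=0.1, beta2=0.05, theta=0.4)

    builders = {
        "dce": lambda: dce_loss(z, labels, protos, 0.7),
        "prototype": lambda: prototype_loss(z, labels, protos),
        "separation": lambda: separation_loss(protos),
        "ksi": lambda: ksi_loss(z, labels, protos, w),
        "cycle": lambda: cycle_loss(z, z2),
        "cluster": lambda: cluster_penalty(z, protos, 0.7),
        "csr": lambda: csr_loss(z, labels, z2, protos, w, cluster_grad_to_prototypes=True),
    }
    f = builders[loss_name]
    for leaf in (z, z2, protos.M):
        leaf.grad = None
    out = f()
    out.backward()
    for leaf, data in (("z", z), ("z2", z2), ("M", protos.M)):
        if data.grad is None:
            continue
        numeric = central_difference(lambda: f().item(), data.data)
        np.testing.assert_allclose(
            data.grad, numeric, rtol=1e-4, atol=1e-6, err_msg=f"{loss_name} grad wrt {leaf}"
        )
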