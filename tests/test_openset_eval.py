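"""Open-set decision rule, AUROC and F-measure against exhaustive oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cslearn.embedding import PrototypeSet
from cslearn.openset_eval import (
    UNKNOWN_LABEL,
    classify_open_set,
    compute_auroc,
    compute_f_measure,
    evaluate_open_set,
    select_threshold,
    unknown_score,
)


def auroc_oracle(scores, flags):
    """Exhaustive pairwise comparison, ties counted 1/2."""
    pos = [s for s, f in zip(scores, flags) if f]
    neg = [s for s, f in zip(scores, flags) if not f]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestUnknownScore:
    def test_zero_at_prototype(self):
        protos = PrototypeSet(np.array([[1.0, 2.0], [-1.0, 0.0]]))
        assert unknown_score(protos.matrix[0], protos)[0] == pytest.approx(0.0, abs=1e-9)

    def test_center_of_unit_sphere_scores_one(self):
        protos = PrototypeSet(np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]))
        assert unknown_score(np.zeros(2), protos)[0] == pytest.approx(1.0)

    def test_matches_exhaustive_min(self, rng):
        protos = PrototypeSet(rng.standard_normal((4, 3)))
        z = rng.standard_normal((10, 3))
        got = unknown_score(z, protos)
        expected = np.min(np.linalg.norm(z[:, None, :] - protos.matrix[None], axis=2), axis=1)
        np.testing.assert_allclose(got, expected, rtol=1e-9)


class TestSelectThreshold:
    def test_boundary_percentiles(self, rng):
        protos = PrototypeSet(rng.standard_normal((3, 2)))
        z = rng.standard_normal((20, 2))
        scores = unknown_score(z, protos)
        assert select_threshold(z, protos, 100) == pytest.approx(scores.max())
        assert select_threshold(z, protos, 0) == pytest.approx(scores.min())

    def test_higher_order_statistic_convention(self):
        """Scores 1..100 at the 95th percentile give exactly 95."""
        protos = PrototypeSet(np.zeros((1, 1)))
        z = np.arange(1.0, 101.0).reshape(-1, 1)
        assert select_threshold(z, protos, 95) == pytest.approx(95.0)

    def test_monotone_in_percentile(self, rng):
        protos = PrototypeSet(rng.standard_normal((3, 2)))
        z = rng.standard_normal((50, 2))
        ts = [select_threshold(z, protos, p) for p in (10, 50, 90, 99)]
        assert ts == sorted(ts)

    def test_empty_input_rejected(self):
        protos = PrototypeSet(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            select_threshold(np.empty((0, 2)), protos)


class TestClassifyOpenSet:
    def test_infinite_threshold_never_rejects(self, rng):
        protos = PrototypeSet(rng.standard_normal((3, 2)))
        preds = classify_open_set(rng.standard_normal((10, 2)), protos, np.inf)
        assert UNKNOWN_LABEL not in preds

    def test_zero_threshold_rejects_everything_off_prototype(self, rng):
        protos = PrototypeSet(rng.standard_normal((3, 2)))
        preds = classify_open_set(rng.standard_normal((10, 2)) + 10, protos, 0.0)
        assert (preds == UNKNOWN_LABEL).all()

    def test_hand_constructed_geometry(self):
        protos = PrototypeSet(np.array([[0.0, 0.0], [10.0, 0.0]]))
        latents = np.array(
            [[0.1, 0.0], [0.0, 0.2], [9.9, 0.1], [10.2, 0.0], [5.0, 0.0], [0.0, 7.0]]
        )
        preds = classify_open_set(latents, protos, threshold=1.0)
        np.testing.assert_array_equal(preds, [0, 0, 1, 1, UNKNOWN_LABEL, UNKNOWN_LABEL])


class TestAuroc:
    def test_perfect_separation(self):
        assert compute_auroc([1, 2, 8, 9], [False, False, True, True]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auroc([3.0] * 6, [True, False] * 3) == 0.5

    def test_hand_counted_example(self):
        scores = [3, 4, 1, 2, 5]
        flags = [True, True, False, False, False]
        assert compute_auroc(scores, flags) == pytest.approx(4 / 6)

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        """Exact agreement with pairwise counting for every instance <= 50 samples."""
        for _ in range(50):
            n = int(rng.integers(2, 51))
            scores = rng.choice([0.0, 0.5, 1.0, 2.5, 7.0], size=n)
            flags = rng.integers(0, 2, n).astype(bool)
            if flags.all() or not flags.any():
                flags[0] = ~flags[0]
            assert compute_auroc(scores, flags) == pytest.approx(
                auroc_oracle(scores, flags), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(40)
        flags = rng.integers(0, 2, 40).astype(bool)
        flags[0], flags[1] = True, False
        assert compute_auroc(scores, flags) == pytest.approx(roc_auc_score(flags, scores))

    @settings(deadline=None, max_examples=50)
    @given(
        # integer grid: strictly monotone transforms cannot create new
        # floating-point ties between distinct scores
        st.lists(st.integers(min_value=-50, max_value=50).map(float), min_size=4, max_size=30),
        st.data(),
    )
    def test_invariant_under_monotone_transforms(self, scores, data):
        flags = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if all(flags) or not any(flags):
            flags[0] = not flags[0]
        scores = np.array(scores)
        flags = np.array(flags)
        base = compute_auroc(scores, flags)
        for transform in (lambda s: 3 * s + 7, np.exp, lambda s: s**3):
            assert compute_auroc(transform(scores), flags) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([1, 2], [True, True])


class TestFMeasure:
    def test_perfect_predictions(self):
        preds = np.array([UNKNOWN_LABEL, UNKNOWN_LABEL, 0, 1])
        flags = np.array([True, True, False, False])
        assert compute_f_measure(preds, flags) == 1.0

    def test_zero_recall_gives_zero(self):
        preds = np.array([0, 1, 2])
        flags = np.array([True, True, False])
        assert compute_f_measure(preds, flags) == 0.0

    def test_hand_confusion_matrix(self):
        """TP=8, FP=2, FN=4: P=0.8, R=2/3, F1=8/11."""
        preds = np.array([UNKNOWN_LABEL] * 10 + [0] * 4 + [1] * 6)
        flags = np.array([True] * 8 + [False] * 2 + [True] * 4 + [False] * 6)
        assert compute_f_measure(preds, flags) == pytest.approx(8 / 11)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import f1_score

        preds = rng.choice([UNKNOWN_LABEL, 0, 1], size=60)
        flags = rng.integers(0, 2, 60).astype(bool)
        got = compute_f_measure(preds, flags)
        expected = f1_score(flags, preds == UNKNOWN_LABEL, zero_division=0)
        assert got == pytest.approx(expected)


class TestThresholdConsistency:
    def test_raising_threshold_never_increases_unknown_recall(self, rng):
        protos = PrototypeSet(rng.standard_normal((3, 4)))
        latents = rng.standard_normal((60, 4)) * 2
        flags = rng.integers(0, 2, 60).astype(bool)
        recalls = []
        for t in (0.5, 1.0, 2.0, 4.0, 8.0):
            preds = classify_open_set(latents, protos, t)
            pred_unknown = preds == UNKNOWN_LABEL
            recalls.append((pred_unknown & flags).sum() / max(flags.sum(), 1))
        assert all(b <= a for a, b in zip(recalls, recalls[1:]))


class TestEvaluateOpenSet:
    def test_report_fields_and_ranges(self, rng):
        protos = PrototypeSet(rng.standard_normal((3, 4)) * 3)
        train = protos.matrix[rng.integers(0, 3, 30)] + 0.1 * rng.standard_normal((30, 4))
        val = protos.matrix[[0, 1, 2] * 4] + 0.1 * rng.standard_normal((12, 4))
        unknown = rng.standard_normal((8, 4)) * 0.2  # near the center, far from prototypes
        report = evaluate_open_set(train, val, np.array([0, 1, 2] * 4), unknown, protos)
        assert 0 <= report.auroc <= 1
        assert 0 <= report.f_measure <= 1
        assert report.closed_set_accuracy == pytest.approx(1.0)
        assert report.n_known == 12 and report.n_unknown == 8
        text = report.to_json()
        assert '"auroc"' in text
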