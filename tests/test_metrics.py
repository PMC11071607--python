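import math

import numpy as np
import pytest

from labelrefine import CANONICAL_SCHEME, class_overlap, evaluate_set, generate_phantom

RNG = np.random.default_rng(321)


class TestClassOverlap:
    def test_identity(self):
        labels = RNG.integers(0, 4, size=(8, 8))
        labels[0, 0] = 1  # make sure the class is present
        assert class_overlap(labels, labels, 1) == (100.0, 100.0, 0.0)

    def test_disjoint(self):
        pred = np.zeros((4, 4), dtype=int)
        truth = np.zeros((4, 4), dtype=int)
        pred[0, :] = 1
        truth[1, :] = 1
        iou, dsc, rvd = class_overlap(pred, truth, 1)
        assert iou == 0.0 and dsc == 0.0 and rvd == 0.0

    def test_textbook_fixture(self):
        # |P| = 2, |T| = 2, |P ∩ T| = 1 on a 2x2 map
        pred = np.array([[1, 1], [0, 0]])
        truth = np.array([[1, 0], [1, 0]])
        iou, dsc, rvd = class_overlap(pred, truth, 1)
        assert iou == pytest.approx(100 / 3)
        assert dsc == pytest.approx(50.0)
        assert rvd == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=int)
        assert class_overlap(z, z, 3) == (100.0, 100.0, 0.0)

    def test_truth_empty_pred_not(self):
        truth = np.zeros((4, 4), dtype=int)
        pred = np.ones((4, 4), dtype=int)
        iou, dsc, rvd = class_overlap(pred, truth, 1)
        assert iou == 0.0 and dsc == 0.0 and math.isnan(rvd)

    def test_background_index_rejected(self):
        z = np.zeros((4, 4), dtype=int)
        with pytest.raises(ValueError):
            class_overlap(z, z, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            class_overlap(np.zeros((4, 4), dtype=int), np.zeros((5, 5), dtype=int), 1)

    def test_dsc_iou_identity_on_random_maps(self):
        for _ in range(50):
            pred = RNG.integers(0, 4, size=(16, 16))
            truth = RNG.integers(0, 4, size=(16, 16))
            for cls in (1, 2, 3):
                iou, dsc, _ = class_overlap(pred, truth, cls)
                assert dsc == pytest.approx(2 * iou / (1 + iou / 100), abs=1e-9)
                assert dsc >= iou


class TestEvaluateSet:
    def test_single_perfect_sample(self):
        truth = generate_phantom(seed=0, height=32, width=32)
        report = evaluate_set([truth.with_labels(truth.labels)], [truth],
                              CANONICAL_SCHEME)
        for stats in report.per_class.values():
            assert stats.dsc_mean == 100.0 and stats.dsc_sd == 0.0
            assert stats.rvd_mean == 0.0

    def test_two_value_aggregation(self):
        truth = generate_phantom(seed=1, height=32, width=32)
        perfect = truth.with_labels(truth.labels)
        t2 = generate_phantom(seed=2, height=32, width=32)
        report = evaluate_set(
            [perfect, t2.with_labels(np.zeros_like(t2.labels))],
            [truth, t2], CANONICAL_SCHEME)
        stats = report.per_class["muscle"]
        # per-sample DSCs are 100 and 0: mean 50, sample SD of (100, 0)
        assert stats.dsc_mean == pytest.approx(50.0)
        assert stats.dsc_sd == pytest.approx(np.std([100.0, 0.0], ddof=1))

    def test_report_ordering_follows_scheme(self):
        truth = generate_phantom(seed=3, height=32, width=32)
        report = evaluate_set([truth.with_labels(truth.labels)], [truth],
                              CANONICAL_SCHEME)
        assert list(report.per_class) == [
            "muscle", "subcutaneous_adipose", "visceral_adipose"
        ]
        assert list(report.to_frame()["class_name"]) == list(report.per_class)

    def test_revision_suffix_matching(self):
        truth = generate_phantom(seed=4, height=32, width=32)
        pred = truth.with_labels(truth.labels, sample_id=truth.sample_id + "-weak")
        report = evaluate_set([pred], [truth], CANONICAL_SCHEME)
        assert report.n_samples == 1

    def test_count_mismatch_rejected(self):
        truth = generate_phantom(seed=5, height=32, width=32)
        with pytest.raises(ValueError):
            evaluate_set([], [truth], CANONICAL_SCHEME)

    def test_unmatched_id_rejected(self):
        truth = generate_phantom(seed=6, height=32, width=32)
        stray = truth.with_labels(truth.labels, sample_id="unrelated")
        with pytest.raises(ValueError, match="unmatched"):
            evaluate_set([stray], [truth], CANONICAL_SCHEME)

    def test_to_dict_round_trips_means(self):
        truth = generate_phantom(seed=7, height=32, width=32)
        report = evaluate_set([truth.with_labels(truth.labels)], [truth],
                              CANONICAL_SCHEME)
        d = report.to_dict()
        assert d["n_samples"] == 1
        assert d["per_class"]["muscle"]["dsc"][0] == 100.0
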