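"""Detection matching, PR/AUPRC, Dice, splits, trial statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbguide import evaluation as ev
from nbguide.types import Box, Detection, TrialRecord


def brute_force_ap(scored, n_truth):
    """Envelope-rule average precision by explicit enumeration of cuts."""
    order = sorted(scored, key=lambda s: -s[0])
    points = []
    tp = fp = 0
    for _, hit in order:
        tp += hit
        fp += not hit
        points.append((tp / n_truth, tp / (tp + fp)))
    area = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        env = max(p for _, p in points[k:])
        area += (r - prev_r) * env
        prev_r = r
    return area


def brute_force_dice(a, b):
    inter = both = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            inter += bool(a[r, c]) and bool(b[r, c])
            both += bool(a[r, c]) + bool(b[r, c])
    return 2 * inter / both


class TestMatchDetections:
    def test_exact_match_is_true_positive(self, dets):
        d = dets("FA", (0, 0, 10, 10), 0.9)
        res = ev.match_detections([[d]], [[dets("FA", (0, 0, 10, 10), 1.0)]])
        assert res["FA"].scored == [(0.9, True)]
        assert res["FA"].n_truth == 1

    def test_low_iou_is_fp_and_fn(self, dets):
        pred = dets("FA", (0, 0, 10, 10), 0.9)
        truth = dets("FA", (8, 8, 18, 18), 1.0)   # IOU = 4/196 < 0.5
        res = ev.match_detections([[pred]], [[truth]])
        assert res["FA"].scored == [(0.9, False)]
        assert res["FA"].n_truth == 1

    def test_one_to_one_matching_is_greedy_by_confidence(self, dets):
        truth = [dets("FA", (0, 0, 10, 10), 1.0)]
        preds = [dets("FA", (0, 0, 10, 10), 0.6),
                 dets("FA", (0, 1, 10, 11), 0.9)]
        res = ev.match_detections([preds], [truth])
        assert sorted(res["FA"].scored) == [(0.6, False), (0.9, True)]

    def test_classes_do_not_cross_match(self, dets):
        res = ev.match_detections(
            [[dets("FV", (0, 0, 10, 10), 0.9)]],
            [[dets("FA", (0, 0, 10, 10), 1.0)]])
        assert res["FA"].scored == [] and res["FA"].n_truth == 1
        assert res["FV"].scored == [(0.9, False)] and res["FV"].n_truth == 0

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_conservation_of_counts(self, data):
        n_p = data.draw(st.integers(0, 6))
        n_t = data.draw(st.integers(1, 6))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        frame_p = [Detection("FA", Box(*_rand_box(rng)), float(rng.random()))
                   for _ in range(n_p)]
        frame_t = [Detection("FA", Box(*_rand_box(rng)), 1.0)
                   for _ in range(n_t)]
        res = ev.match_detections([frame_p], [frame_t])["FA"]
        tp = sum(hit for _, hit in res.scored)
        fp = sum(not hit for _, hit in res.scored)
        assert tp + fp == n_p
        assert tp <= min(n_p, n_t)
        assert res.n_truth == n_t


def _rand_box(rng):
    r0, c0 = rng.integers(0, 30, size=2)
    return float(r0), float(c0), float(r0 + rng.integers(1, 12)), \
        float(c0 + rng.integers(1, 12))


class TestAveragePrecision:
    def test_all_true_positives_is_one(self):
        match = ev.MatchResult([(0.2, True), (0.9, True)], n_truth=2)
        assert ev.pr_curve_and_auprc(match)[2] == 1.0

    def test_all_false_positives_is_zero(self):
        match = ev.MatchResult([(0.9, False), (0.8, False)], n_truth=3)
        assert ev.pr_curve_and_auprc(match)[2] == 0.0

    def test_tp_fp_tp_ranking(self):
        match = ev.MatchResult([(0.9, True), (0.8, False), (0.7, True)],
                               n_truth=2)
        # envelope: 0.5 recall at precision 1, then 0.5 more at 2/3
        assert ev.pr_curve_and_auprc(match)[2] == pytest.approx(5 / 6)
        assert ev.pr_curve_and_auprc(match)[2] == pytest.approx(
            brute_force_ap(match.scored, match.n_truth))

    def test_zero_truth_is_an_error(self):
        with pytest.raises(ValueError):
            ev.pr_curve_and_auprc(ev.MatchResult([(0.5, False)], n_truth=0))

    def test_invariant_under_monotone_confidence_rescaling(self):
        rng = np.random.default_rng(1)
        scored = [(float(c), bool(h)) for c, h in
                  zip(rng.random(40), rng.random(40) < 0.6)]
        match = ev.MatchResult(scored, n_truth=30)
        base = ev.pr_curve_and_auprc(match)[2]
        for f in (lambda c: c ** 3, lambda c: 0.1 + 0.9 * c, np.tanh):
            rescaled = ev.MatchResult([(float(f(c)), h) for c, h in scored],
                                      n_truth=30)
            assert ev.pr_curve_and_auprc(rescaled)[2] == pytest.approx(base)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 10))
            n_truth = int(rng.integers(1, 10))
            scored = [(float(rng.random()), bool(rng.random() < 0.5))
                      for _ in range(n)]
            tp_total = 0
            capped = []
            for c, h in scored:   # keep TP count consistent with n_truth
                if h and tp_total < n_truth:
                    capped.append((c, True))
                    tp_total += 1
                else:
                    capped.append((c, False))
            match = ev.MatchResult(capped, n_truth)
            assert ev.pr_curve_and_auprc(match)[2] == pytest.approx(
                brute_force_ap(capped, n_truth))

    def test_trapezoid_alternative_close_but_distinct(self):
        match = ev.MatchResult([(0.9, True), (0.8, False), (0.7, True)],
                               n_truth=2)
        env = ev.pr_curve_and_auprc(match, "envelope")[2]
        trap = ev.pr_curve_and_auprc(match, "trapezoid")[2]
        assert trap <= env

    def test_macro_is_unweighted_mean(self):
        matches = {"FA": ev.MatchResult([(0.9, True)], 1),
                   "FV": ev.MatchResult([(0.9, False)], 1)}
        assert ev.macro_auprc(matches) == pytest.approx(0.5)


class TestDice:
    def test_identity_disjoint_and_partial(self):
        a = np.zeros((20, 20), dtype=bool)
        a[:10] = True
        b = np.zeros((20, 20), dtype=bool)
        b[10:] = True
        assert ev.dice(a, a) == 1.0
        assert ev.dice(a, b) == 0.0

    def test_counting_example(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[20:120] = True   # |A|=|B|=100, overlap 80
        assert ev.dice(a, b) == pytest.approx(0.8)

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError):
            ev.dice(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))

    @settings(max_examples=150, deadline=None)
    @given(seed=st.integers(0, 10_000), size=st.integers(2, 32))
    def test_matches_brute_force_and_symmetry(self, seed, size):
        rng = np.random.default_rng(seed)
        a = rng.random((size, size)) < 0.4
        b = rng.random((size, size)) < 0.4
        if not (a.any() or b.any()):
            a[0, 0] = True
        val = ev.dice(a, b)
        assert val == pytest.approx(brute_force_dice(a, b))
        assert val == pytest.approx(ev.dice(b, a))
        assert 0.0 <= val <= 1.0


class TestDiceSummary:
    def test_perfect_masks(self):
        s = ev.dice_summary([1.0, 1.0, 1.0])
        assert s["mean"] == 1.0 and s["fraction_above_threshold"] == 1.0

    def test_mixed_values(self):
        s = ev.dice_summary([1.0, 0.8, 0.0])
        assert s["mean"] == pytest.approx(0.6)
        assert s["median"] == pytest.approx(0.8)

    def test_threshold_counting(self):
        s = ev.dice_summary([0.95, 0.91, 0.5, 0.89], threshold=0.9)
        assert s["fraction_above_threshold"] == pytest.approx(0.5)


class TestSubjectSplit:
    def test_twenty_subjects_split_14_2_4(self):
        split = ev.subject_split([f"s{i}" for i in range(20)], seed=0)
        sizes = [len(split.subjects(n)) for n in ("train", "validation",
                                                  "test")]
        assert sizes == [14, 2, 4]

    def test_ten_subjects_split_7_1_2(self):
        split = ev.subject_split(list(range(10)), seed=3)
        assert [len(split.subjects(n))
                for n in ("train", "validation", "test")] == [7, 1, 2]

    def test_three_subjects_pinned_one_per_split(self):
        split = ev.subject_split(
            ["ex1", "ex2", "ex3"],
            pinned={"ex1": "train", "ex2": "validation", "ex3": "test"})
        assert split.assignment == {"ex1": "train", "ex2": "validation",
                                    "ex3": "test"}

    def test_partition_is_exhaustive_and_disjoint(self):
        ids = [f"pig{i}" for i in range(13)]
        split = ev.subject_split(ids, seed=5)
        all_assigned = (split.subjects("train") + split.subjects("validation")
                        + split.subjects("test"))
        assert sorted(all_assigned) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = list(range(12))
        assert ev.subject_split(ids, seed=9).assignment == \
            ev.subject_split(ids, seed=9).assignment

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ev.subject_split(["a", "b"])


def _records(successes, attempts, round_label="", condition="normovolemic",
             times=None):
    out = []
    for i in range(attempts):
        t = times[i] if times else None
        out.append(TrialRecord(success=i < successes, elapsed_s=t,
                               round_label=round_label, condition=condition))
    return out


class TestTrialStatistics:
    def test_success_rate_to_one_decimal(self):
        stats = ev.trial_statistics(_records(28, 38))
        assert stats["overall"]["success_rate_pct"] == 73.7

    def test_in_vivo_success_rate(self):
        stats = ev.trial_statistics(_records(59, 60))
        assert stats["overall"]["success_rate_pct"] == 98.3

    def test_grouping_by_round(self):
        recs = _records(2, 9, "round-1") + _records(28, 38, "round-2")
        stats = ev.trial_statistics(recs)
        assert stats["by_round_label"]["round-1"]["success_rate_pct"] == 22.2
        assert stats["by_round_label"]["round-2"]["success_rate_pct"] == 73.7

    def test_cap_values_enter_time_statistics(self):
        recs = _records(1, 2, times=[30.0, 180.0])
        stats = ev.trial_statistics(recs)
        assert stats["overall"]["time_mean_s"] == pytest.approx(105.0)

    def test_pooled_mean_of_condition_means(self):
        assert round(ev.pooled_mean([45.7, 33.2], [35, 25]), 1) == 40.5


class TestLetterbox:
    def test_square_input_pure_scale(self):
        frame = np.arange(600 * 600, dtype=np.uint8).reshape(600, 600)
        out, tf = ev.letterbox_resize(frame, 640)
        assert out.shape == (640, 640)
        assert tf.pad_top == 0 and tf.pad_left == 0
        assert tf.scale == pytest.approx(640 / 600)

    def test_portrait_input_pads_columns(self):
        frame = np.zeros((600, 400), dtype=np.uint8) + 50
        out, tf = ev.letterbox_resize(frame, 640)
        assert out.shape == (640, 640)
        assert tf.scale == pytest.approx(640 / 600)
        new_w = round(400 * 640 / 600)
        assert tf.pad_left == (640 - new_w) // 2
        # padding is zero, content is not
        assert out[:, :int(tf.pad_left)].max() == 0
        assert out[320, 320] == 50

    def test_box_round_trip_is_identity(self):
        frame = np.zeros((600, 400), dtype=np.uint8)
        _, tf = ev.letterbox_resize(frame, 640)
        box = Box(12.5, 40.25, 300.0, 399.0)
        back = tf.invert_box(tf.apply_box(box))
        assert np.allclose(back, box, atol=1e-9)
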