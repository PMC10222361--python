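import numpy as np
import pytest

from videofm.evaluation import (
    Annotation,
    MatchCounts,
    acc_from_ppv_sen,
    bland_altman,
    f1_from_ppv_sen,
    match_events,
    metrics,
)
from videofm.fm_events import FMEvent


def events(*ivals):
    return [FMEvent(a, b, 1) for a, b in ivals]


class TestMatchEvents:
    def test_identical_sets(self):
        labels = Annotation([(0, 2), (10, 12), (30, 31)])
        c = match_events(events((0, 2), (10, 12), (30, 31)), labels)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_disjoint_sets(self):
        labels = Annotation([(0, 2), (10, 12)])
        c = match_events(events((50, 51), (60, 62)), labels)
        assert (c.tp, c.fp, c.fn) == (0, 2, 2)

    def test_partial_overlap(self):
        labels = Annotation([(9, 11), (30, 33)])
        c = match_events(events((10, 12)), labels)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_one_prediction_validates_two_labels(self):
        labels = Annotation([(0, 2), (3, 5)])
        c = match_events(events((1, 4)), labels)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_tp_plus_fn_equals_tme(self):
        labels = Annotation([(0, 1), (5, 6), (9, 10)])
        c = match_events(events((0.5, 0.8), (20, 21)), labels)
        assert c.tp + c.fn == labels.tme

    def test_overlapping_labels_rejected(self):
        with pytest.raises(ValueError):
            Annotation([(0, 5), (3, 8)])


class TestMetrics:
    def test_worked_arithmetic(self):
        rep = metrics(MatchCounts(tp=2, fp=1, fn=2), tme=4)
        assert rep.tdr == pytest.approx(50.0)
        assert rep.ppv == pytest.approx(66.67, abs=0.01)
        assert rep.sen == pytest.approx(50.0)
        assert rep.acc == pytest.approx(40.0)
        assert rep.f1 == pytest.approx(57.14, abs=0.01)

    def test_published_f1_identity(self):
        assert f1_from_ppv_sen(95.26, 95.75) == pytest.approx(95.50, abs=0.005)
        assert f1_from_ppv_sen(75.00, 77.22) == pytest.approx(76.09, abs=0.005)

    def test_published_acc_identity(self):
        assert acc_from_ppv_sen(95.26, 95.75) == pytest.approx(91.40, abs=0.005)
        assert acc_from_ppv_sen(75.00, 77.22) == pytest.approx(61.41, abs=0.005)

    def test_tdr_equals_sen_by_construction(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = MatchCounts(*rng.integers(0, 20, 3))
            rep = metrics(c)
            if not np.isnan(rep.tdr):
                assert rep.tdr == pytest.approx(rep.sen)

    def test_f1_between_ppv_and_sen(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = MatchCounts(int(rng.integers(1, 20)), *rng.integers(0, 20, 2))
            rep = metrics(c)
            assert min(rep.ppv, rep.sen) - 1e-9 <= rep.f1 <= max(rep.ppv, rep.sen) + 1e-9

    def test_zero_denominators_flagged(self):
        rep = metrics(MatchCounts(tp=0, fp=0, fn=5), tme=5)
        assert rep.tdr == 0.0 and np.isnan(rep.ppv) and np.isnan(rep.f1)

    def test_agrees_with_bruteforce_from_raw_events(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n_lab, n_pred = rng.integers(1, 8), rng.integers(0, 8)
            # labels spaced so intervals cannot overlap
            starts = np.cumsum(rng.uniform(5, 40, n_lab))
            labels = Annotation([(s, s + rng.uniform(0.5, 3)) for s in starts])
            pred = events(*[(s, s + rng.uniform(0.5, 3))
                            for s in np.sort(rng.uniform(0, 300, n_pred))])
            rep = metrics(match_events(pred, labels), tme=labels.tme)
            # brute force straight from the interval lists
            hit = [any(p.start_s <= b and a <= p.end_s for p in pred)
                   for a, b in labels.labeled_events]
            tp = sum(hit)
            fp = sum(not any(a <= p.end_s and p.start_s <= b
                             for a, b in labels.labeled_events) for p in pred)
            fn = labels.tme - tp
            assert rep.tdr == pytest.approx(tp / labels.tme * 100)
            if tp + fp:
                assert rep.ppv == pytest.approx(tp / (tp + fp) * 100)
            if tp + fp + fn:
                assert rep.acc == pytest.approx(tp / (tp + fp + fn) * 100)


class TestBlandAltman:
    def test_identical_pairs(self):
        r = bland_altman(np.arange(5.0), np.arange(5.0))
        assert r.mean_diff == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        p2 = np.arange(4.0)
        r = bland_altman(p2 + 3.0, p2)
        assert r.mean_diff == pytest.approx(3.0)
        assert r.loa_low == pytest.approx(3.0) and r.loa_high == pytest.approx(3.0)

    def test_hand_computed_limits(self):
        r = bland_altman(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))
        assert r.mean_diff == pytest.approx(0.0)
        assert r.loa_low == pytest.approx(-1.96)
        assert r.loa_high == pytest.approx(1.96)
        np.testing.assert_allclose(r.means, [1.5, 2.0, 2.5])

    def test_limits_bracket_mean(self):
        rng = np.random.default_rng(8)
        r = bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert r.loa_low <= r.mean_diff <= r.loa_high

    def test_gaussian_coverage_near_95(self):
        rng = np.random.default_rng(12)
        p2 = rng.normal(size=1000)
        p1 = p2 + rng.normal(0.3, 1.0, size=1000)
        r = bland_altman(p1, p2)
        assert r.coverage() == pytest.approx(0.95, abs=0.02)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones(3), np.ones(4))
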