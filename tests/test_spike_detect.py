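import numpy as np
import pytest

from videofm.fm_events import merge_spikes
from videofm.spike_detect import (
    detect_spikes,
    first_diff,
    second_diff,
    threshold_th1,
    threshold_th2,
)

FS = 25.0


def bump_signal(n_bumps=5, fs=FS, spacing_s=12.0, noise=0.01, seed=0):
    """Baseline noise plus isolated amplitude-1 biphasic spikes.

    Each spike is an up-down sample pair — the shape a high-passed FM
    transient takes — giving the differential thresholds a wide margin
    over the noise floor.
    """
    rng = np.random.default_rng(seed)
    n = int((n_bumps * spacing_s + spacing_s) * fs)
    x = noise * rng.normal(size=n)
    centers = (spacing_s * (np.arange(n_bumps) + 1) * fs).astype(int)
    for k in centers:
        x[k] += 1.0
        x[k + 1] -= 1.0
    return x, centers / fs, 2


class TestDifferences:
    def test_first_diff_example(self):
        np.testing.assert_array_equal(first_diff([0.0, 1.0, 3.0]), [1.0, 2.0])

    def test_first_diff_constant_and_ramp(self):
        assert not first_diff(np.full(5, 2.0)).any()
        np.testing.assert_allclose(first_diff(3.0 * np.arange(6.0)), np.full(5, 3.0))

    def test_second_diff_ramp_zero(self):
        np.testing.assert_allclose(second_diff(2.5 * np.arange(8.0)), np.zeros(6))

    def test_second_diff_impulse_response(self):
        np.testing.assert_array_equal(
            second_diff([0.0, 0.0, 1.0, 0.0, 0.0]), [1.0, -2.0, 1.0]
        )

    def test_second_diff_quadratic(self):
        np.testing.assert_allclose(second_diff(np.arange(10.0) ** 2), np.full(8, 2.0))

    def test_too_short(self):
        with pytest.raises(ValueError):
            first_diff([1.0])
        with pytest.raises(ValueError):
            second_diff([1.0, 2.0])


class TestTh1:
    def test_mean_of_local_minima(self):
        th1, deg = threshold_th1(np.array([0.0, -2.0, 0.0, -4.0, 0.0]))
        assert th1 == pytest.approx(-3.0) and not deg

    def test_monotone_degenerate(self):
        th1, deg = threshold_th1(np.arange(5.0))
        assert th1 == 0.0 and deg

    def test_single_minimum(self):
        th1, deg = threshold_th1(np.array([1.0, 0.0, 1.0]))
        assert th1 == 0.0 and not deg


class TestTh2:
    def test_worked_example(self):
        y3, th2 = threshold_th2(np.array([1.0, 2.0]), np.array([3.0]), a=0.02)
        np.testing.assert_array_equal(y3, [11.0])  # 2*1 + 3*3
        assert th2 == pytest.approx(0.22)

    def test_all_zero(self):
        y3, th2 = threshold_th2(np.zeros(4), np.zeros(3), a=0.03)
        assert not y3.any() and th2 == 0.0

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        for c in (2.0, 7.5):
            _, th2 = threshold_th2(first_diff(x), second_diff(x), a=0.03)
            _, th2c = threshold_th2(first_diff(c * x), second_diff(c * x), a=0.03)
            assert th2c == pytest.approx(c**2 * th2)


class TestDetectSpikes:
    def test_all_zero_no_spikes(self):
        assert len(detect_spikes(np.zeros(50), a=0.03)) == 0

    def test_five_bumps_recovered_exactly(self):
        x, centers, width = bump_signal()
        train = detect_spikes(x, a=0.03, fs=FS)
        assert 5 <= len(train) <= 5 * width
        events = merge_spikes(train, gap_s=6.0)
        assert len(events) == 5
        for ev, c in zip(events, centers):
            assert abs(ev.start_s - c) < 0.5

    @pytest.mark.parametrize("mode", ["signal", "y3"])
    def test_monotone_nonincreasing_in_a(self, mode):
        x, _, _ = bump_signal(noise=0.02, seed=3)
        counts = [len(detect_spikes(x, a=a, compare_on=mode))
                  for a in np.linspace(0.01, 0.05, 9)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_detected_spikes_satisfy_inequalities(self):
        # post-hoc literal re-check of both threshold conditions
        x, _, _ = bump_signal(seed=5)
        train = detect_spikes(x, a=0.02, fs=FS)
        xn = x / np.abs(x).max()
        assert len(train) > 0
        for n in train.spike_indices:
            assert xn[n] > train.th1 and xn[n] > train.th2

    def test_scale_invariance_with_normalization(self):
        x, _, _ = bump_signal(seed=7)
        base = detect_spikes(x, a=0.03).spike_indices
        for c in (1e-3, 50.0):
            np.testing.assert_array_equal(
                detect_spikes(c * x, a=0.03).spike_indices, base
            )

    def test_time_reversal_symmetric_signal(self):
        x, _, _ = bump_signal(noise=0.0)
        sym = x + x[::-1]
        a_count = len(detect_spikes(sym, a=0.03))
        b_count = len(detect_spikes(sym[::-1], a=0.03))
        assert a_count == b_count

    def test_spike_indices_within_common_range(self):
        x, _, _ = bump_signal(seed=9)
        train = detect_spikes(x, a=0.01)
        assert train.spike_indices.max() <= len(x) - 3

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(10), compare_on="nope")
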