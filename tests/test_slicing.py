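"""Slice stacks: alignment, framing, cross-slice statistics, rank order."""

import numpy as np
import pytest

from spikekit import (
    RateMatrix,
    SpikeTrainSet,
    align_to_events,
    aligned_mean_rate,
    binned_rates,
    frames,
    gen_poisson_population,
    rank_order_correlation,
    slice_to_slice_time_corr,
    slice_to_slice_unit_corr,
    unit_timing_per_slice,
)
from spikekit.slicing import SliceStack


def rate_stack(arrays, bin_ms=1.0, provenance="events"):
    slices = [
        RateMatrix(np.asarray(a, dtype=float), bin_ms, list(range(len(a))))
        for a in arrays
    ]
    return SliceStack(slices=slices, provenance=provenance)


class TestAlignToEvents:
    def test_window_geometry(self):
        s = gen_poisson_population(4, 10_000.0, 5.0, seed=0)
        stack = align_to_events(s, [1000.0, 5000.0], pre_ms=250.0, post_ms=500.0)
        assert len(stack) == 2
        assert stack[0].duration_ms == 750.0
        assert stack.window == (250.0, 500.0)

    def test_event_near_edge_dropped(self):
        s = gen_poisson_population(2, 10_000.0, 5.0, seed=1)
        stack = align_to_events(s, [100.0, 5000.0, 9900.0], pre_ms=250.0, post_ms=500.0)
        assert len(stack) == 1
        assert stack.meta["n_dropped"] == 2

    def test_spike_time_becomes_relative(self):
        s = SpikeTrainSet([0], [[1000.0]], 10_000.0)
        stack = align_to_events(s, [1000.0], pre_ms=250.0, post_ms=500.0)
        np.testing.assert_array_equal(stack[0].trains[0], [250.0])

    def test_no_survivors_warns(self):
        s = SpikeTrainSet([0], [[50.0]], 1000.0)
        with pytest.warns(UserWarning):
            stack = align_to_events(s, [100.0], pre_ms=500.0, post_ms=600.0)
        assert len(stack) == 0


class TestFrames:
    def test_frame_count(self):
        s = gen_poisson_population(3, 600_000.0, 1.0, seed=2)
        stack = frames(s, window_ms=120_000.0, step_ms=10_000.0)
        assert len(stack) == 49

    def test_window_equals_duration_single_frame(self):
        s = gen_poisson_population(2, 50_000.0, 1.0, seed=3)
        assert len(frames(s, 50_000.0, 10_000.0)) == 1

    def test_consecutive_overlap(self):
        s = gen_poisson_population(2, 400_000.0, 1.0, seed=4)
        stack = frames(s, window_ms=120_000.0, step_ms=10_000.0)
        starts = stack.alignment_times_ms
        assert 120_000.0 - (starts[1] - starts[0]) == 110_000.0

    def test_oversized_window_warns_empty(self):
        s = gen_poisson_population(2, 10_000.0, 1.0, seed=5)
        with pytest.warns(UserWarning):
            assert len(frames(s, 20_000.0, 1_000.0)) == 0

    def test_rate_matrix_frames(self):
        s = gen_poisson_population(3, 10_000.0, 10.0, seed=6)
        r = binned_rates(s, 10.0)
        stack = frames(r, window_ms=2_000.0, step_ms=1_000.0)
        assert len(stack) == 9
        assert stack[0].n_bins == 200


class TestAlignedMeanRate:
    def test_identical_slices_zero_sem(self):
        a = np.random.default_rng(0).random((3, 50))
        mean, sem = aligned_mean_rate(rate_stack([a, a, a]))
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, a.sum(axis=0))

    def test_two_hand_traces(self):
        a = np.array([[1.0, 2.0]])
        b = np.array([[3.0, 6.0]])
        mean, sem = aligned_mean_rate(rate_stack([a, b]))
        np.testing.assert_allclose(mean, [2.0, 4.0])
        assert np.all(sem > 0)

    def test_slice_order_invariant(self):
        rng = np.random.default_rng(1)
        arrays = [rng.random((2, 30)) for _ in range(4)]
        m1, _ = aligned_mean_rate(rate_stack(arrays))
        m2, _ = aligned_mean_rate(rate_stack(arrays[::-1]))
        np.testing.assert_allclose(m1, m2)

    def test_psth_equivalence_with_direct_windowing(self):
        """Event alignment + per-slice mean reproduces direct windowed averaging."""
        s = gen_poisson_population(5, 60_000.0, 10.0, seed=7)
        events = [10_000.0, 20_000.0, 30_000.0]
        stack = align_to_events(s, events, pre_ms=250.0, post_ms=500.0)
        rstack = SliceStack(
            [binned_rates(sl, 10.0) for sl in stack], provenance="events"
        )
        psth, _ = aligned_mean_rate(rstack)
        direct = np.mean(
            [
                binned_rates(s.subtime(e - 250.0, e + 500.0), 10.0).values.sum(axis=0)
                for e in events
            ],
            axis=0,
        )
        np.testing.assert_allclose(psth, direct, atol=1e-9)


class TestSliceToSliceCorr:
    def test_identical_slices_all_one(self):
        a = np.random.default_rng(2).random((4, 60))
        m = slice_to_slice_unit_corr(rate_stack([a, a, a]))
        np.testing.assert_allclose(m, 1.0)

    def test_unit_corr_null_near_zero(self):
        rng = np.random.default_rng(3)
        arrays = [rng.random((50, 750)) for _ in range(4)]
        m = slice_to_slice_unit_corr(rate_stack(arrays))
        off = m[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_unit_corr_symmetric(self):
        rng = np.random.default_rng(4)
        arrays = [rng.random((3, 40)) for _ in range(3)]
        m = slice_to_slice_unit_corr(rate_stack(arrays))
        np.testing.assert_array_equal(m, m.T)

    def test_time_corr_identical_slices(self):
        a = np.random.default_rng(5).random((10, 30))
        trace, detail = slice_to_slice_time_corr(rate_stack([a, a]))
        np.testing.assert_allclose(trace, 1.0)
        assert trace.size == 30

    def test_time_corr_shuffled_units_near_zero(self):
        rng = np.random.default_rng(6)
        a = rng.random((50, 40))
        b = a[rng.permutation(50)]
        trace, _ = slice_to_slice_time_corr(rate_stack([a, b]))
        assert np.nanmean(np.abs(trace)) < 0.25
        assert abs(np.nanmean(trace)) < 0.1

    def test_time_corr_needs_two_units(self):
        with pytest.raises(ValueError):
            slice_to_slice_time_corr(rate_stack([np.ones((1, 10)), np.ones((1, 10))]))


class TestUnitTiming:
    def test_single_spike_timing(self):
        s = SpikeTrainSet([0], [[100.0]], 750.0)
        stack = SliceStack([s], provenance="events")
        timing = unit_timing_per_slice(stack, sigma_ms=10.0)
        assert timing[0, 0] == pytest.approx(100.0, abs=10.0)

    def test_silent_unit_nan(self):
        s = SpikeTrainSet([0, 1], [[100.0], []], 750.0)
        stack = SliceStack([s], provenance="events")
        timing = unit_timing_per_slice(stack)
        assert np.isnan(timing[1, 0])

    def test_identical_slices_identical_columns(self):
        s = SpikeTrainSet([0, 1], [[100.0, 110.0], [300.0]], 750.0)
        stack = SliceStack([s, s], provenance="events")
        timing = unit_timing_per_slice(stack)
        np.testing.assert_array_equal(timing[:, 0], timing[:, 1])

    def test_median_spike_method(self):
        s = SpikeTrainSet([0], [[100.0, 200.0, 600.0]], 750.0)
        stack = SliceStack([s], provenance="events")
        timing = unit_timing_per_slice(stack, method="median_spike")
        assert timing[0, 0] == 200.0


class TestRankOrder:
    def _stack_from_timing(self, timing_cols, duration=750.0):
        slices = []
        n_units = len(timing_cols[0])
        for col in timing_cols:
            trains = [np.array([t]) for t in col]
            slices.append(SpikeTrainSet(list(range(n_units)), trains, duration))
        return SliceStack(slices, provenance="events")

    def test_identical_ordering_spearman_one(self):
        col = list(np.linspace(50, 700, 20))
        stack = self._stack_from_timing([col, col])
        rho, _ = rank_order_correlation(stack, n_shuffles=50, seed=0)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_reversed_ordering_minus_one(self):
        col = list(np.linspace(50, 700, 20))
        stack = self._stack_from_timing([col, col[::-1]])
        rho, _ = rank_order_correlation(stack, n_shuffles=50, seed=0)
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_independent_timings_z_near_zero(self):
        rng = np.random.default_rng(8)
        cols = [list(rng.uniform(10, 700, 50)) for _ in range(6)]
        stack = self._stack_from_timing(cols)
        _, z = rank_order_correlation(stack, n_shuffles=100, seed=1)
        mean_z = np.nanmean(z[np.triu_indices(6, 1)])
        assert abs(mean_z) < 0.5

    def test_too_few_common_units_nan(self):
        stack = self._stack_from_timing([[100.0, 200.0], [150.0, 250.0]])
        rho, z = rank_order_correlation(stack, n_shuffles=20, seed=2)
        assert np.isnan(rho[0, 1]) and np.isnan(z[0, 1])

    def test_single_slice_rejected(self):
        stack = self._stack_from_timing([[100.0, 200.0, 300.0]])
        with pytest.raises(ValueError):
            rank_order_correlation(stack)


class TestStackCompositionality:
    def test_single_set_ops_apply_per_slice(self):
        s = gen_poisson_population(6, 30_000.0, 5.0, seed=9)
        stack = frames(s, 10_000.0, 5_000.0)
        rates = stack.map(lambda sl: sl.mean_firing_rates())
        assert len(rates) == len(stack)
        assert all(r.shape == (6,) for r in rates)

    def test_mismatched_slices_rejected(self):
        a = SpikeTrainSet([0], [[10.0]], 100.0)
        b = SpikeTrainSet([0], [[10.0]], 200.0)
        with pytest.raises(ValueError):
            SliceStack([a, b], provenance="events")
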