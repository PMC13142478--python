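"""Pairwise matrices: STTC vs a brute-force oracle, lagged correlation, graphs."""

import networkx as nx
import numpy as np
import pytest

from spikekit import (
    PairwiseMatrix,
    RateMatrix,
    SpikeTrainSet,
    fr_correlation,
    gen_coupled_pair,
    mean_weighted_degree,
    sttc,
    sttc_pair,
    threshold_matrix,
    to_weighted_graph,
)
from conftest import random_spike_set


def sttc_bruteforce(a, b, delta, duration):
    """Literal tiling-definition oracle: interval sweep + double loop."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.nan

    def tiling(t):
        covered = 0.0
        grid_edges = sorted({0.0, duration} | {max(x - delta, 0) for x in t}
                            | {min(x + delta, duration) for x in t})
        for lo, hi in zip(grid_edges[:-1], grid_edges[1:]):
            mid = (lo + hi) / 2
            if any(abs(mid - x) <= delta for x in t):
                covered += hi - lo
        return covered / duration

    def prop_within(x, y):
        return np.mean([any(abs(xi - yi) <= delta for yi in y) for xi in x])

    ta, tb = tiling(a), tiling(b)
    pa, pb = prop_within(a, b), prop_within(b, a)
    if 1 - pa * tb == 0 or 1 - pb * ta == 0:
        return np.nan
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


class TestSttc:
    def test_identical_trains_one(self):
        t = np.array([100.0, 300.0, 700.0])
        assert sttc_pair(t, t, 20.0, 1000.0) == pytest.approx(1.0)

    def test_hand_value(self):
        assert sttc_pair(np.array([100.0]), np.array([500.0]), 20.0, 1000.0) == \
            pytest.approx(-0.04, abs=1e-12)

    def test_empty_train_undefined(self):
        assert np.isnan(sttc_pair(np.array([100.0]), np.empty(0), 20.0, 1000.0))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            s = random_spike_set(rng, max_units=3, max_spikes=60, duration_ms=1500.0)
            delta = rng.uniform(5, 40)
            m = sttc(s, delta_ms=delta)
            for i in range(s.n_units):
                for j in range(i + 1, s.n_units):
                    oracle = sttc_bruteforce(s.trains[i], s.trains[j], delta,
                                             s.duration_ms)
                    got = m.values[i, j]
                    if np.isnan(oracle):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_nan_diagonal(self, poisson_set):
        m = sttc(poisson_set)
        np.testing.assert_array_equal(m.values, m.values.T)
        assert np.all(np.isnan(np.diag(m.values)))

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(5)
        t1 = np.sort(rng.uniform(100, 800, 30))
        t2 = np.sort(rng.uniform(100, 800, 30))
        base = sttc_pair(t1, t2, 20.0, 1000.0)
        shifted = sttc_pair(t1 + 100, t2 + 100, 20.0, 1000.0)
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_monotone_in_copy_probability(self):
        means = []
        for p in (0.0, 0.5, 1.0):
            vals = [
                sttc(gen_coupled_pair(5.0, p, 3.0, 2.0, 60_000.0, seed=s)).values[0, 1]
                for s in range(30)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_pair_count_formula(self):
        s = SpikeTrainSet(list(range(12)), [[float(i + 1)] for i in range(12)], 100.0)
        m = sttc(s)
        assert m.unique_pair_values().size == 12 * 11 // 2


class TestFrCorrelation:
    def _rm(self, values, bin_ms=1.0):
        return RateMatrix(np.asarray(values, dtype=float), bin_ms,
                          list(range(len(values))))

    def test_identical_traces(self):
        x = np.abs(np.sin(np.linspace(0, 10, 500))) + 0.1
        m = fr_correlation(self._rm([x, x]), max_lag_ms=50.0)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_shifted_trace_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.random(2000)
        y = np.roll(x, 100)
        m = fr_correlation(self._rm([x, y]), max_lag_ms=350.0)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_constant_trace_undefined(self):
        x = np.ones(100)
        y = np.abs(np.sin(np.linspace(0, 5, 100)))
        m = fr_correlation(self._rm([x, y]), max_lag_ms=10.0)
        assert np.isnan(m.values[0, 1])

    def test_zero_lag_equals_pearson(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(300), rng.random(300)
        m = fr_correlation(self._rm([a, b]), max_lag_ms=0.0)
        assert m.values[0, 1] == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_lag_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            fr_correlation(self._rm([np.arange(10.0), np.arange(10.0)]), max_lag_ms=20.0)

    def test_exactly_symmetric(self):
        rng = np.random.default_rng(3)
        m = fr_correlation(self._rm(rng.random((5, 400))), max_lag_ms=30.0)
        np.testing.assert_array_equal(m.values, m.values.T)


class TestMatrixOps:
    @pytest.fixture
    def hand_matrix(self):
        v = np.array(
            [[np.nan, 0.9, 0.5], [0.9, np.nan, 0.2], [0.5, 0.2, np.nan]]
        )
        return PairwiseMatrix(v, ["a", "b", "c"], "sttc", {"delta_ms": 20.0})

    def test_threshold(self, hand_matrix):
        out = threshold_matrix(hand_matrix, 0.8)
        assert out.values[0, 1] == 0.9
        assert out.values[0, 2] == 0.0 and out.values[1, 2] == 0.0
        assert out.params["threshold_cutoff"] == 0.8

    def test_threshold_noop_below_min(self, hand_matrix):
        out = threshold_matrix(hand_matrix, 0.0)
        np.testing.assert_array_equal(
            out.unique_pair_values(), hand_matrix.unique_pair_values()
        )

    def test_graph_export(self, hand_matrix):
        g = to_weighted_graph(hand_matrix, threshold=0.8,
                              node_attrs={"x": [0, 1, 2]})
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["weight"] == 0.9
        assert g.nodes["c"]["x"] == 2

    def test_graph_all_edges_and_none(self, hand_matrix):
        assert to_weighted_graph(hand_matrix, threshold=0.1).number_of_edges() == 3
        assert to_weighted_graph(hand_matrix, threshold=1.0).number_of_edges() == 0

    def test_graph_feeds_standard_metrics(self, hand_matrix):
        g = to_weighted_graph(hand_matrix, threshold=0.1)
        # delegated graph metrics work on the export
        assert nx.average_clustering(g, weight="weight") > 0

    def test_mean_weighted_degree(self, hand_matrix):
        out = mean_weighted_degree(hand_matrix)
        np.testing.assert_allclose(out, [0.7, 0.55, 0.35])

    def test_mean_weighted_degree_permutation(self, hand_matrix):
        perm = [2, 0, 1]
        v = hand_matrix.values[np.ix_(perm, perm)]
        m2 = PairwiseMatrix(v, ["c", "a", "b"], "sttc")
        np.testing.assert_allclose(
            mean_weighted_degree(m2), mean_weighted_degree(hand_matrix)[perm]
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            PairwiseMatrix(np.array([[np.nan, 1.0], [0.5, np.nan]]), [0, 1], "x")

    def test_long_csv_roundtrip(self, hand_matrix, tmp_path):
        import pandas as pd

        p = tmp_path / "m.csv"
        hand_matrix.to_csv(p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["unit_a", "unit_b", "value"]
        assert len(df) == 3
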