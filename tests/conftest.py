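import numpy as np
import pytest

from spikekit import SpikeTrainSet, gen_poisson_population


@pytest.fixture
def tiny_set():
    """Three hand-built units over a 1 s recording."""
    return SpikeTrainSet(
        unit_ids=["a", "b", "c"],
        trains=[[5.0, 10.0, 15.0], [10.0, 500.0], []],
        duration_ms=1000.0,
        unit_meta={"x_um": [0.0, 10.0, 20.0]},
    )


@pytest.fixture
def poisson_set():
    """Small seeded Poisson population."""
    return gen_poisson_population(8, 20000.0, 5.0, seed=42)


def random_spike_set(rng, max_units=6, max_spikes=200, duration_ms=2000.0):
    """Random fixture for oracle comparisons (<=200 spikes per unit)."""
    n_units = rng.integers(2, max_units + 1)
    trains = []
    for _ in range(n_units):
        n = rng.integers(0, max_spikes + 1)
        trains.append(np.sort(rng.uniform(0, duration_ms, size=n)))
    return SpikeTrainSet(list(range(n_units)), trains, duration_ms)
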