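"""Seeded generators for synthetic spike data with planted structure.

Three generators cover the statistical structure the analyses assume:
stationary Poisson background firing, planted population bursts (Gaussian
rate gain with per-unit timing offsets and participation probabilities), and
spike-coupled unit pairs (copy probability plus Gaussian jitter).  Each
returns its ground truth so that detection, coupling, and sequence analyses
can be scored against it.  All generators are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpikeTrainSet


@dataclass
class BurstPlan:
    """Ground truth for planted population bursts.

    ``gain`` multiplies each unit's base rate at burst centre; ``offsets_ms``
    shifts each unit's burst response (the planted sequence); ``participation``
    is the per-unit probability of joining any given burst.
    """

    burst_times_ms: np.ndarray
    width_ms: float
    gain: np.ndarray
    offsets_ms: np.ndarray
    participation: np.ndarray
    engaged: np.ndarray | None = None  # units x bursts Bernoulli draws (filled in)

    def __post_init__(self):
        self.burst_times_ms = np.asarray(self.burst_times_ms, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.offsets_ms = np.asarray(self.offsets_ms, dtype=float)
        self.participation = np.asarray(self.participation, dtype=float)
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if np.any((self.participation < 0) | (self.participation > 1)):
            raise ValueError("participation must lie in [0, 1]")

    @classmethod
    def uniform(
        cls,
        n_units: int,
        n_bursts: int,
        duration_ms: float,
        width_ms: float = 50.0,
        gain: float = 8.0,
        offsets_ms=0.0,
        participation: float = 1.0,
        margin_ms: float = 2000.0,
    ) -> "BurstPlan":
        """Evenly spaced bursts with shared gain/participation per unit."""
        times = np.linspace(margin_ms, duration_ms - margin_ms, n_bursts)
        offs = np.broadcast_to(np.asarray(offsets_ms, dtype=float), (n_units,)).copy()
        return cls(
            burst_times_ms=times,
            width_ms=width_ms,
            gain=np.full(n_units, float(gain)),
            offsets_ms=offs,
            participation=np.full(n_units, float(participation)),
        )


def gen_poisson_population(
    n_units: int, duration_ms: float, rates_hz, seed: int | None = None
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains at the requested rates."""
    rates = np.broadcast_to(np.asarray(rates_hz, dtype=float), (n_units,))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    trains = []
    for r in rates:
        n = rng.poisson(r * duration_ms / 1000.0)
        trains.append(np.sort(rng.uniform(0, duration_ms, size=n)))
    return SpikeTrainSet(
        unit_ids=list(range(n_units)),
        trains=trains,
        duration_ms=duration_ms,
        recording_meta={"generator": "poisson", "seed": seed},
    )


def gen_bursting_population(
    n_units: int,
    duration_ms: float,
    base_rates_hz,
    plan: BurstPlan,
    seed: int | None = None,
):
    """Inhomogeneous Poisson population with planted Gaussian-gain bursts.

    The per-unit rate is
    ``base * (1 + gain * sum_b engaged[u,b] * exp(-(t - t_b - delta_u)^2 / 2 w^2))``
    sampled exactly by thinning.  Returns (spikes, plan) with the plan's
    per-burst participation draws filled in.
    """
    base = np.broadcast_to(np.asarray(base_rates_hz, dtype=float), (n_units,))
    rng = np.random.default_rng(seed)
    engaged = (
        rng.random((n_units, plan.burst_times_ms.size)) < plan.participation[:, None]
    )
    trains = []
    w2 = 2.0 * plan.width_ms**2
    for u in range(n_units):
        rate_max = base[u] * (1.0 + plan.gain[u] * max(engaged[u].sum(), 1))
        n_cand = rng.poisson(rate_max * duration_ms / 1000.0)
        cand = np.sort(rng.uniform(0, duration_ms, size=n_cand))
        if cand.size:
            centres = plan.burst_times_ms[engaged[u]] + plan.offsets_ms[u]
            bump = np.zeros(cand.size)
            for c in centres:
                bump += np.exp(-((cand - c) ** 2) / w2)
            lam = base[u] * (1.0 + plan.gain[u] * bump)
            keep = rng.random(cand.size) < lam / rate_max
            cand = cand[keep]
        trains.append(cand)
    plan.engaged = engaged
    spikes = SpikeTrainSet(
        unit_ids=list(range(n_units)),
        trains=trains,
        duration_ms=duration_ms,
        recording_meta={"generator": "bursting", "seed": seed},
    )
    return spikes, plan


def gen_population_with_coupled_unit(
    n_background: int,
    duration_ms: float,
    background_rate_hz: float,
    copy_frac: float = 0.15,
    jitter_ms: float = 5.0,
    extra_rate_hz: float = 1.0,
    seed: int | None = None,
) -> SpikeTrainSet:
    """Poisson background plus one population-coupled unit and one matched control.

    The ``coupled`` unit copies a fraction of the pooled background spikes
    (with Gaussian jitter) plus an independent Poisson train; the ``control``
    unit is an independent Poisson train at the coupled unit's realised rate.
    Ground truth for population-coupling (stPR) recovery tests.
    """
    rng = np.random.default_rng(seed)
    pop = gen_poisson_population(n_background, duration_ms, background_rate_hz, seed=seed)
    pooled = np.sort(np.concatenate(pop.trains)) if pop.n_spikes else np.empty(0)
    keep = rng.random(pooled.size) < copy_frac
    copied = np.clip(pooled[keep] + rng.normal(0, jitter_ms, int(keep.sum())), 0, duration_ms)
    n_extra = rng.poisson(extra_rate_hz * duration_ms / 1000.0)
    coupled = np.sort(
        np.concatenate([copied, rng.uniform(0, duration_ms, size=n_extra)])
    )
    n_ctrl = rng.poisson(max(coupled.size, 1))
    control = np.sort(rng.uniform(0, duration_ms, size=n_ctrl))
    return SpikeTrainSet(
        unit_ids=pop.unit_ids + ["coupled", "control"],
        trains=pop.trains + [coupled, control],
        duration_ms=duration_ms,
        recording_meta={"generator": "population_with_coupled_unit", "seed": seed},
    )


def gen_coupled_pair(
    parent_rate_hz: float,
    p_copy: float,
    jitter_ms: float,
    indep_rate_hz: float,
    duration_ms: float,
    seed: int | None = None,
) -> SpikeTrainSet:
    """Two units: a Poisson parent A and a child B that copies A's spikes.

    Each A spike is copied into B with probability ``p_copy`` plus Gaussian
    jitter; B additionally fires an independent Poisson train at
    ``indep_rate_hz``.
    """
    if not 0 <= p_copy <= 1:
        raise ValueError("p_copy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = rng.poisson(parent_rate_hz * duration_ms / 1000.0)
    a = np.sort(rng.uniform(0, duration_ms, size=n))
    copied = a[rng.random(a.size) < p_copy]
    if jitter_ms > 0:
        copied = copied + rng.normal(0, jitter_ms, size=copied.size)
    m = rng.poisson(indep_rate_hz * duration_ms / 1000.0)
    extra = rng.uniform(0, duration_ms, size=m)
    b = np.sort(np.clip(np.concatenate([copied, extra]), 0, duration_ms))
    return SpikeTrainSet(
        unit_ids=["parent", "child"],
        trains=[a, b],
        duration_ms=duration_ms,
        recording_meta={"generator": "coupled_pair", "seed": seed, "p_copy": p_copy},
    )
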