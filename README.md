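# spikekit

Composable analysis of spike-sorted extracellular recordings — the kind of
data produced by Neuropixels probes, Utah arrays, and high-density
microelectrode arrays after spike sorting. The package is aimed at systems
and in-vitro electrophysiologists who need the standard downstream analyses
(single-unit statistics, population bursts, pairwise functional
connectivity, population coupling, burst-aligned sequence structure) as
tested, reusable building blocks rather than per-project scripts.

All spike times are milliseconds, all windows are half-open `[t0, t1)`, and
every analysis consumes or produces one of a small set of containers:

- `SpikeTrainSet` — per-unit non-decreasing spike times plus metadata; the
  universal input. Sliceable in time (`subtime`) and by unit (`subset`).
- `RateMatrix` — units × time-bins instantaneous firing rates (Hz) with
  estimator provenance (binned, Gaussian-smoothed, or ISI-reciprocal).
- `BurstSet` — detected population bursts (refined peaks plus edges).
- `PairwiseMatrix` / `PairwiseMatrixStack` — symmetric n × n comparison
  matrices (STTC, lagged rate correlation) with NaN diagonals.
- `SliceStack` — equal-duration, unit-aligned segments from event alignment,
  sliding frames, or surrogate generation; any single-recording operation
  applies unchanged per slice.
- `Workspace` — an HDF5 store of results addressed by `(namespace, key)`,
  with caching and a no-silent-overwrite rule.

## The core statistics

**Spike time tiling coefficient (STTC).** For trains A, B and a coincidence
half-width Δ,

    STTC = ½ [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ]

where T_X is the fraction of the recording covered by ∪[t−Δ, t+Δ] around X's
spikes and P_X is the fraction of X's spikes within Δ of any partner spike.
It is symmetric, bounded in [−1, 1], and insensitive to firing rate. The
implementation is checked against a literal brute-force evaluation of the
definition to 1e-12.

**Population-burst detection.** The 1 ms population spike count is smoothed
twice (coarse trace: 20 ms boxcar then σ = 100 ms Gaussian; high-resolution
trace: 8 ms / 8 ms). Peaks of the coarse trace above
`multiplier × RMS(coarse)` are pruned greedily to a 1000 ms minimum
inter-burst interval; edges are found by walking out from each peak to where
the trace drops below `baseline + 0.2 × (peak − baseline)` (baseline = the
higher flanking trough), and the peak is refined to the high-resolution
maximum inside the edges.

**Spike-triggered population coupling (stPR).** Per unit, the leave-one-out
population rate is low-pass filtered (zero-phase Butterworth, 20 Hz),
baseline-subtracted, averaged around the unit's spikes over ±80 ms, and
normalised by the summed mean rate of all other units. Zero-lag and peak
coupling are reported per unit.

**Degree-preserving surrogates.** A checkerboard-swap shuffle of the binary
raster that exactly preserves each unit's occupied-bin count and each bin's
population count, used to calibrate z-scores
(`z = (obs − mean(shuffles)) / sd(shuffles)`; near-zero shuffle spread gives
NaN, never a clamped value).

**Burst-aligned sequence statistics.** Burst-aligned slice stacks yield
per-unit activation times, slice-to-slice unit/time correlations, and
Spearman rank-order correlations of activation sequences z-scored against
unit-permutation nulls.

## Worked example

```python
import numpy as np
import spikekit as sk

# synthetic population: 50 units, 2 Hz background, 10 planted bursts
plan = sk.BurstPlan.uniform(50, 10, 120_000.0, width_ms=50.0, gain=8.0)
rec, plan = sk.gen_bursting_population(50, 120_000.0, 2.0, plan, seed=7)

b = sk.detect_bursts(rec, rms_multiplier=2.5)
print(f"{b.n_bursts} bursts, first peak at {b.peaks_ms[0]:.1f} ms")

m = sk.sttc(rec, delta_ms=20.0)
pairs = m.unique_pair_values()
print(f"{pairs.size} unique pairs, mean STTC {np.nanmean(pairs):.3f}")

stack = sk.align_to_events(rec, b.peaks_ms, pre_ms=250.0, post_ms=500.0)
rho, z = sk.rank_order_correlation(stack, n_shuffles=100, seed=7)
iu = np.triu_indices(len(stack), 1)
print(f"median rank-order z across burst pairs: {np.nanmedian(z[iu]):.2f}")
```

Output:

```
10 bursts, first peak at 2007.5 ms
1225 unique pairs, mean STTC 0.025
median rank-order z across burst pairs: 0.10
```

Ten of ten planted bursts are recovered; 50 units give 50·49/2 = 1225 unique
pairs; the mildly positive mean STTC reflects shared burst participation;
and because this plan plants no per-unit timing offsets, burst-to-burst
sequences are uncorrelated (median z near 0 — planting offsets drives it
above 3, see the tests).

A CLI mirrors the library for shell pipelines
(`spikekit simulate|bursts|burst-sensitivity|sttc|fr-corr|coupling|shuffle-z|align|frames|rank-order|workspace {ls,merge}`);
run `spikekit --help`.

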