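# Methods

This note documents the models and procedures spikekit implements, the
parameters that matter, the numerical choices made where a definition was
genuinely open, and what the synthetic test conditions do and do not
establish about real recordings.

## Conventions

Spike times are milliseconds throughout; nothing else is ever stored. Time
windows are half-open `[t0, t1)`, so adjacent windows partition a recording
without double counting; a spike exactly at the right edge belongs to the
next window. Binned series keep the partial trailing bin (`n_bins =
ceil(duration/bin)`); its count is genuine but its rate conversion uses the
full bin width, a documented bias that is negligible at 1 ms. Equal spike
times within a unit are permitted (trains are non-decreasing, not strictly
increasing), as millisecond rounding of sorted data can produce ties.
Undefined quantities are always NaN, never 0 or a clamped value: the ISI
coefficient of variation with fewer than two spikes, an STTC involving an
empty train, a z-score against degenerate surrogates, the symmetric
normalised change `(x′ − x0′)/(x′ + x0′)` when both clamped values are zero.

## Rate estimation

Three estimators share the same output shape for the same (duration, bin)
and stamp their parameters into the result's provenance.

- **Binned**: counts per bin divided by the bin width in seconds.
- **Gaussian**: binned counts convolved with a unit-area Gaussian kernel,
  truncated at ±4σ with zero padding. Interior spikes contribute unit
  integral; within 4σ of the edges mass leaks out (deterministic, documented
  edge bias rather than renormalisation that would distort interior values).
- **ISI-reciprocal** (default for instantaneous rates, 1 ms bins, 10 ms
  Gaussian smoothing): the rate inside an inter-spike interval
  `[t_i, t_{i+1})` is `1000/ISI` Hz, held piecewise constant, then smoothed.
  Piecewise-constant holding was chosen over interpolation between
  per-spike anchors because it reads the reciprocal-interval idea literally
  and preserves the ordering of interval rates; zero is used outside the
  span of a unit's spikes (no rate is invented where no interval exists),
  and units with fewer than two spikes yield an all-zero row.

## Population-burst detection

The detector operates on the 1 ms binned population spike count:

1. Coarse trace: 20 ms boxcar, then σ = 100 ms Gaussian (boxcar first).
2. Threshold θ = multiplier × RMS of the coarse trace, with RMS read
   literally as the uncentred `sqrt(mean(x²))`. On a baseline-dominated
   trace this is close to, and slightly above, the centred standard
   deviation, making the threshold marginally more conservative.
3. Candidate peaks are local maxima above θ; the minimum inter-burst
   interval (default 1000 ms) is enforced greedily in descending amplitude,
   which is deterministic and favours dominant events.
4. Flanking troughs are the coarse-trace minima between the peak and its
   neighbouring retained peak (or the recording edge); the baseline is the
   **higher** trough, and the edge level is
   `baseline + edge_frac × (peak − baseline)` with `edge_frac = 0.2`.
   Edges are the first bins, walking outward, below that level; the walk
   stops at recording boundaries, so a burst may abut an edge.
5. The reported peak is the maximum of a high-resolution trace (8 ms boxcar,
   σ = 8 ms Gaussian) inside the edges, at bin-centre time.

The threshold-sensitivity sweep (multiplier 1.0–5.0) reports bursts per
minute per multiplier; counts are non-increasing in the multiplier on every
synthetic condition tested, which is the qualitative signature the sweep is
meant to expose.

Burst participation metrics: `frac_active` is the per-unit fraction of
bursts containing at least `min_spikes` (default 2) of that unit's spikes in
`[start, end)`; `frac_spikes_in_burst` is the per-unit fraction of spikes
inside any burst window. A unit is classified *backbone* when its
`frac_active` reaches 1.0 in at least one condition, *non-rigid* otherwise;
conditions with no bursts (NaN) never qualify.

## Spike time tiling coefficient

`STTC = ½[(P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A)]` with a
default ±20 ms window. Tiling fractions clip coincidence windows to the
recording and merge overlaps exactly (sorted-interval sweep); `P` values use
nearest-neighbour distances via binary search. Pairs with an empty train, or
a zero denominator in either term, are NaN. The diagonal of every pairwise
matrix is NaN rather than 1, so summaries over "unique unit pairs" are
unambiguous. An independent brute-force oracle (literal interval sweep plus
double loop over spikes) is kept in the test suite; the optimised path
agrees with it to 1e-12 on randomized fixtures.

## Lagged firing-rate correlation

For every pair, the Pearson correlation is evaluated at every integer-bin
lag in ±350 ms on the overlapping segment (truncation, no wrap-around or
padding, per-lag renormalisation); the reported value is the maximum
*signed* correlation over lags — the signed maximum, not |r|, so
anti-correlated pairs are not inflated. Zero-variance traces give NaN.
Exact matrix symmetry follows from evaluating lag −k as the transpose of
lag +k.

## Population coupling (stPR)

Per unit: the leave-one-out population rate (1 ms bins, Hz) is low-pass
filtered with a zero-phase (forward–backward) Butterworth filter, order 3,
cutoff 20 Hz; the baseline is the time mean of the filtered trace; the lag
curve is the spike-triggered average of the baseline-subtracted trace over
±80 ms, divided by the summed mean rate of all other units (dimensionless).
Choices the definition left open: filter order 3 and zero-phase application
(avoids lag-curve asymmetry from filter delay); baseline = mean of the
filtered trace; spikes within 80 ms of either recording edge do not trigger
(no partial windows). Because filtering is linear, filtering the total
population rate once and subtracting each unit's filtered own-rate is
identical to filtering each leave-one-out sum, and is how it is computed.
The sliding-window variant uses 120 s windows with 10 s steps (110 s
overlap) and masks units with fewer than 12 spikes in a window.

## Slice stacks and sequence statistics

Slice-internal times are relative to the window start (preserving the
non-negativity invariant); for event-aligned stacks the event sits at
`t = pre_ms` and the offset is stored so plots can relabel t = 0. Events
whose window exceeds the recording are dropped and counted. Framing yields
`floor((T − W)/step) + 1` slices; the trailing partial window is discarded.

Cross-slice statistics on rate stacks: the slice-to-slice *unit* correlation
is the mean over units of each unit's temporal Pearson correlation between
two slices (zero-variance units excluded per pair); the slice-to-slice
*time* correlation is, per time bin, the across-unit Pearson correlation
between two slices' rate vectors, averaged over unordered slice pairs. Unit
activation timing per slice is the argmax of the Gaussian-smoothed rate
(earliest bin on ties; median spike time available as an option; NaN for
silent units). Rank-order correlation is the Spearman correlation of two
slices' timing vectors over units defined in both (NaN below 3 common
units), z-scored against 100 seeded permutations of one vector's unit
assignment; since Spearman is Pearson on tie-averaged ranks, the null is
computed by permuting rank vectors, which is exact and fast.

## Degree-preserving surrogates

The shuffle binarises the raster at a chosen resolution (default 1 ms;
multiple same-bin spikes clip to one, so conservation is defined on the
binary raster) and repeatedly samples two occupied entries `(i, a)` and
`(j, b)`; when the 2×2 submatrix on those rows and columns is a checkerboard
the two spikes trade bins. Both margins — per-unit occupied-bin counts and
per-bin population counts — are preserved exactly by construction. Sampling
occupied entries rather than uniform unit/bin pairs keeps the proposal
acceptance rate high on sparse rasters without changing the stationary
behaviour of the swap chain. The stopping rule is a budget of
`swaps_per_entry × occupied` *successful* swaps (default 10 per entry), a
deterministic, seed-reproducible choice in preference to mixing diagnostics;
a proposal cap guards degenerate rasters with no legal swaps.
Reconstructed spikes sit at bin centres (unbiased within-bin placement
without invented jitter). One structural caveat: with exactly two units the
margins pin every coincidence, so a two-unit shuffle cannot destroy pairwise
structure — shuffle-based nulls need the pair embedded in a population.

Shuffle z-scores are `(obs − mean)/sd` over surrogates, NaN when the
surrogate spread is below 1e-12 — an explicit flag of unreliable estimation,
never clamped.

## Latent-state statistics and PCA

Latent-model fitting is consumed, not implemented: any bins × states
posterior with rows summing to 1 is accepted, with an optional per-bin burst
label. Per-burst entropy is the Shannon entropy (base 2) of the *mean*
within-burst posterior (mean-then-entropy; the alternative
mean-of-entropies measures within-burst uncertainty rather than the
diversity of states visited, which is the quantity of interest here).
Occupancy is the mean posterior over selected bins. Transition matrices use
the per-bin argmax state (lowest index on ties), count a step only when both
bins share a burst id (cross-burst boundaries excluded), and leave
unvisited-state rows all-zero rather than imputing. PCA of a rate matrix
treats bins as observations, centres (optionally standardises) per unit, and
reports at least five explained-variance ratios when the rank allows.

## Synthetic conditions and their scope

The generators are exact and seed-reproducible: homogeneous Poisson trains
(counts Poisson, times uniform-sorted); inhomogeneous Poisson bursts by
thinning under the rate
`base·(1 + gain·Σ_b engaged·exp(−(t − t_b − δ_u)²/2w²))` with per-burst
Bernoulli participation; coupled pairs by Bernoulli spike copying with
Gaussian jitter plus an independent component; and a population-embedded
coupled/control unit pair for coupling recovery.

Fixture conditions used by the tests and the acceptance script, chosen once
as representative of dense in-vitro population recordings: burst recovery
uses 50 units × 2 Hz × 120 s with 10 planted bursts (gain 8, width 50 ms,
detector multiplier 2.5); sequence recovery uses 50 units × 5 Hz × 240 s
with 20 bursts (gain 15, width 30 ms) and planted offsets spanning ±60 ms —
the higher rate and gain ensure units contribute several spikes per burst,
without which a planted sequence is simply not expressed in the spikes;
coupling recovery uses a 12-unit 3 Hz background with a 15% copy fraction
and 5 ms jitter over 60 s; oracle and conservation checks use randomized
fixtures of up to 6 units × 200 spikes.

What passing these conditions shows: the implementations compute their
definitions correctly, conserve what they must exactly, and recover planted
structure at realistic signal strengths. What they do not show: robustness
to non-Poisson firing (bursty single-unit ISI statistics, refractoriness),
non-stationary baselines, electrode drift, or spike-sorting contamination —
all properties of real recordings that these stationary generative models
deliberately omit.

## Known limitations

- Burst-edge behaviour at recording boundaries uses the available flank
  only; the first/last burst's trough definition is one-sided.
- The ISI-reciprocal estimator holds intervals constant rather than
  interpolating spike-anchored values; both readings exist in the field.
- `fr_correlation` scans all lags densely; for very long traces at 1 ms
  resolution prefer coarser bins (the default analyses use smoothed rates
  where this is immaterial).
- The workspace stores a fixed set of container types plus arrays and
  data-frame tables; arbitrary objects are rejected rather than pickled, by
  design (language-neutral files).
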