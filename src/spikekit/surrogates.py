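"""Degree-preserving raster shuffles and shuffle-calibrated z-scores.

The shuffle operates on the binary raster at a user-chosen bin resolution and
exactly preserves both margins: each unit's occupied-bin count and each
bin's population count.  It repeatedly samples two occupied raster entries
(i, a) and (j, b); when the 2x2 submatrix on rows {i, j} and columns {a, b}
is a checkerboard ([[1,0],[0,1]] or its mirror) the entries are swapped.
This destroys pairwise timing structure while leaving the margins intact.
Multiple same-bin spikes are clipped to one by rasterization; reconstructed
spikes are placed at bin centres.
"""

from __future__ import annotations

import numpy as np

from .containers import SpikeTrainSet
from .slicing import SliceStack


def raster_shuffle(
    s: SpikeTrainSet,
    bin_ms: float = 1.0,
    swaps_per_entry: float = 10.0,
    seed: int | None = None,
) -> SpikeTrainSet:
    """Margin-preserving shuffle of the binary raster.

    Stops after ``swaps_per_entry x (occupied entries)`` successful swaps (a
    deterministic, seed-reproducible budget).  A single-unit input is
    returned unchanged (no legal swaps exist).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    raster = s.raster(bin_ms, binary=True).astype(np.int8)
    n_units, n_bins = raster.shape
    units, bins_ = np.nonzero(raster)
    n_occ = units.size
    if n_units < 2 or n_occ < 2:
        return SpikeTrainSet(
            list(s.unit_ids),
            [t.copy() for t in s.trains],
            s.duration_ms,
            dict(s.unit_meta),
            dict(s.recording_meta),
        )
    rng = np.random.default_rng(seed)
    target = int(swaps_per_entry * n_occ)
    done = 0
    # cap total proposals so pathological rasters cannot spin forever
    max_proposals = 200 * target + 1000
    proposals = 0
    while done < target and proposals < max_proposals:
        # draw proposals in blocks to amortise RNG overhead
        block = min(4 * (target - done) + 64, 1 << 16)
        ks = rng.integers(0, n_occ, size=block)
        ls = rng.integers(0, n_occ, size=block)
        for k, l in zip(ks, ls):
            proposals += 1
            i, a = units[k], bins_[k]
            j, b = units[l], bins_[l]
            if i == j or a == b:
                continue
            if raster[i, b] == 0 and raster[j, a] == 0:
                raster[i, a] = 0
                raster[j, b] = 0
                raster[i, b] = 1
                raster[j, a] = 1
                bins_[k] = b
                bins_[l] = a
                done += 1
                if done >= target:
                    break
        if proposals >= max_proposals:
            break
    trains = []
    for i in range(n_units):
        occ = np.flatnonzero(raster[i])
        trains.append(np.minimum((occ + 0.5) * bin_ms, s.duration_ms))
    meta = dict(s.recording_meta)
    meta["surrogate"] = {"method": "raster_shuffle", "bin_ms": bin_ms, "seed": seed}
    return SpikeTrainSet(list(s.unit_ids), trains, s.duration_ms, dict(s.unit_meta), meta)


def shuffle_stack(
    s: SpikeTrainSet, n: int, bin_ms: float = 1.0, seed: int | None = None, **kwargs
) -> SliceStack:
    """Stack of ``n`` independent margin-preserving surrogates.

    Per-surrogate seeds are spawned deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    slices = [
        raster_shuffle(s, bin_ms=bin_ms, seed=int(cs), **kwargs) for cs in child_seeds
    ]
    return SliceStack(slices=slices, provenance="surrogates", meta={"seed": seed, "n": n})


def zscore_vs_shuffles(observed, surrogate_values, tol: float = 1e-12):
    """z = (observed - mean(surrogates)) / sd(surrogates), elementwise.

    Where the surrogate spread is below ``tol`` the z-score is NaN — an
    explicit flag of unreliable estimation, never a clamped value.
    """
    surr = np.asarray(surrogate_values, dtype=float)
    if surr.shape[0] < 2:
        raise ValueError("need at least 2 surrogate values")
    mean = surr.mean(axis=0)
    sd = surr.std(axis=0)
    obs = np.asarray(observed, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd >= tol, (obs - mean) / np.where(sd >= tol, sd, 1.0), np.nan)
    if z.ndim == 0:
        return float(z)
    return z
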