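"""Slice stacks: event alignment, sliding frames, and cross-slice statistics.

A :class:`SliceStack` is an ordered collection of equal-duration,
unit-aligned segments (each a full :class:`SpikeTrainSet` or
:class:`RateMatrix`), built by aligning to events, tiling a recording with
overlapping frames, or generating surrogates.  Because every slice is a full
container, any single-recording operation applies unchanged per slice.

Slice-internal times are relative to the window start; for event-aligned
stacks the event sits at ``t = pre_ms``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import RateMatrix, SpikeTrainSet
from .rates import gaussian_rates


@dataclass
class SliceStack:
    """Aligned, equal-duration slices with provenance."""

    slices: list
    provenance: str  # "events" | "frames" | "surrogates"
    alignment_times_ms: np.ndarray | None = None
    window: tuple | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.slices:
            ref = self.slices[0]
            for sl in self.slices[1:]:
                if list(sl.unit_ids) != list(ref.unit_ids):
                    raise ValueError("all slices must share unit_ids")
                if not np.isclose(sl.duration_ms, ref.duration_ms):
                    raise ValueError("all slices must share duration")
        if self.provenance == "events" and self.alignment_times_ms is not None:
            if len(self.alignment_times_ms) != len(self.slices):
                raise ValueError("one alignment time per slice required")

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i):
        return self.slices[i]

    def __iter__(self):
        return iter(self.slices)

    @property
    def unit_ids(self):
        return list(self.slices[0].unit_ids) if self.slices else []

    def map(self, fn):
        """Apply ``fn`` to every slice, returning the list of results."""
        return [fn(sl) for sl in self.slices]


def align_to_events(data, event_times_ms, pre_ms: float, post_ms: float) -> SliceStack:
    """Slice ``[e - pre, e + post)`` around each event; event sits at t=pre.

    Events whose window falls outside the recording are dropped and counted
    in ``meta['n_dropped']``.
    """
    if pre_ms < 0 or post_ms < 0 or pre_ms + post_ms <= 0:
        raise ValueError("pre/post must be non-negative with positive total")
    slices, kept = [], []
    dropped = 0
    for e in np.asarray(event_times_ms, dtype=float):
        t0, t1 = e - pre_ms, e + post_ms
        if t0 < 0 or t1 > data.duration_ms:
            dropped += 1
            continue
        slices.append(data.subtime(t0, t1))
        kept.append(e)
    if not slices:
        warnings.warn("no events survived the window bounds; empty stack")
    return SliceStack(
        slices=slices,
        provenance="events",
        alignment_times_ms=np.asarray(kept),
        window=(pre_ms, post_ms),
        meta={"n_dropped": dropped},
    )


def frames(data, window_ms: float, step_ms: float) -> SliceStack:
    """Overlapping frames at offsets 0, step, 2*step, ...; trailing partial
    window discarded.  Frame count = floor((T - W)/step) + 1."""
    if step_ms <= 0:
        raise ValueError("step must be positive")
    if window_ms > data.duration_ms:
        warnings.warn("window longer than recording; empty stack")
        return SliceStack([], "frames", window=(window_ms, step_ms))
    n = int(np.floor((data.duration_ms - window_ms) / step_ms)) + 1
    starts = np.arange(n) * step_ms
    slices = [data.subtime(t0, t0 + window_ms) for t0 in starts]
    return SliceStack(
        slices=slices,
        provenance="frames",
        alignment_times_ms=starts,
        window=(window_ms, step_ms),
    )


def _rate_stack_values(stack: SliceStack) -> np.ndarray:
    """slices x units x bins array from a stack of RateMatrix slices."""
    if not stack.slices:
        raise ValueError("empty stack")
    if not isinstance(stack.slices[0], RateMatrix):
        raise TypeError("operation requires a stack of RateMatrix slices")
    return np.stack([sl.values for sl in stack.slices])


def aligned_mean_rate(stack: SliceStack, per_unit: bool = False):
    """Mean rate trace and SEM across slices (the peri-event histogram).

    With ``per_unit=False`` the population (unit-summed) trace is averaged;
    otherwise per-unit traces are.  SEM = sd/sqrt(n_slices); 0 for one slice.
    """
    v = _rate_stack_values(stack)
    data = v if per_unit else v.sum(axis=1)  # slices x (units x) bins
    mean = data.mean(axis=0)
    if data.shape[0] > 1:
        sem = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
    else:
        sem = np.zeros_like(mean)
    return mean, sem


def slice_to_slice_unit_corr(stack: SliceStack) -> np.ndarray:
    """Slices x slices matrix: mean over units of per-unit temporal Pearson r.

    Units with zero variance in either slice of a pair are excluded from that
    pair's mean.  Diagonal is 1.
    """
    v = _rate_stack_values(stack)
    n_s, n_u, n_b = v.shape
    if n_s < 2 or n_b < 2:
        raise ValueError("need >=2 slices and >=2 time bins")
    z = v - v.mean(axis=2, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=2))
    out = np.eye(n_s)
    for a in range(n_s):
        for b in range(a + 1, n_s):
            ok = (norm[a] > 0) & (norm[b] > 0)
            if not ok.any():
                out[a, b] = out[b, a] = np.nan
                continue
            r = (z[a, ok] * z[b, ok]).sum(axis=1) / (norm[a, ok] * norm[b, ok])
            out[a, b] = out[b, a] = r.mean()
    return out


def slice_to_slice_time_corr(stack: SliceStack):
    """Per-time-bin across-unit similarity between slices.

    At each bin, the Pearson correlation across units between two slices'
    instantaneous rate vectors; the returned trace is the mean over all
    unordered slice pairs.  Also returns the full pairs x bins detail.
    """
    v = _rate_stack_values(stack)
    n_s, n_u, n_b = v.shape
    if n_u < 2:
        raise ValueError("need at least 2 units")
    if n_s < 2:
        raise ValueError("need at least 2 slices")
    z = v - v.mean(axis=1, keepdims=True)  # centre across units per bin
    norm = np.sqrt((z**2).sum(axis=1))  # slices x bins
    detail = []
    for a in range(n_s):
        for b in range(a + 1, n_s):
            denom = norm[a] * norm[b]
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (z[a] * z[b]).sum(axis=0) / denom
            r[denom == 0] = np.nan
            detail.append(r)
    detail = np.asarray(detail)
    defined = np.isfinite(detail)
    cnt = defined.sum(axis=0)
    trace = np.where(
        cnt > 0, np.where(defined, detail, 0.0).sum(axis=0) / np.maximum(cnt, 1), np.nan
    )
    return trace, detail


def unit_timing_per_slice(
    stack: SliceStack, method: str = "rate_peak", sigma_ms: float = 10.0, bin_ms: float = 1.0
) -> np.ndarray:
    """Units x slices matrix of activation times (ms from window start).

    ``rate_peak``: time of the maximum of the Gaussian-smoothed rate trace
    (earliest bin on ties).  ``median_spike``: median spike time.  NaN where
    the unit is silent in the slice.
    """
    if not stack.slices:
        raise ValueError("empty stack")
    n_u = len(stack.unit_ids)
    out = np.full((n_u, len(stack.slices)), np.nan)
    for j, sl in enumerate(stack.slices):
        if isinstance(sl, RateMatrix):
            active = sl.values.max(axis=1) > 0
            idx = sl.values.argmax(axis=1)
            out[active, j] = sl.times_ms()[idx[active]]
        elif method == "median_spike":
            for i, t in enumerate(sl.trains):
                if t.size:
                    out[i, j] = float(np.median(t))
        else:
            rm = gaussian_rates(sl, bin_ms=bin_ms, sigma_ms=sigma_ms)
            active = np.array([t.size > 0 for t in sl.trains])
            idx = rm.values.argmax(axis=1)
            out[active, j] = rm.times_ms()[idx[active]]
    return out


def rank_order_correlation(
    stack: SliceStack,
    n_shuffles: int = 100,
    seed: int | None = None,
    timing: np.ndarray | None = None,
    min_common: int = 3,
    **timing_kwargs,
):
    """Spearman rank-order correlation of unit activation sequences.

    For every slice pair the Spearman correlation of the two timing vectors
    is computed over units defined in both (NaN if fewer than ``min_common``),
    and z-scored against ``n_shuffles`` permutations of one vector's unit
    assignment.  Near-zero null spread yields NaN, never a clamped z.

    Returns (spearman, zscores), both slices x slices with NaN diagonals.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 slices")
    if timing is None:
        timing = unit_timing_per_slice(stack, **timing_kwargs)
    rng = np.random.default_rng(seed)
    n_s = timing.shape[1]
    rho = np.full((n_s, n_s), np.nan)
    z = np.full((n_s, n_s), np.nan)
    for a in range(n_s):
        for b in range(a + 1, n_s):
            ok = np.isfinite(timing[:, a]) & np.isfinite(timing[:, b])
            n_ok = int(ok.sum())
            if n_ok < min_common:
                continue
            # Spearman = Pearson on (tie-averaged) ranks; rank once, then the
            # permutation null is a plain dot product of permuted ranks
            ra = stats.rankdata(timing[ok, a])
            rb = stats.rankdata(timing[ok, b])
            za = ra - ra.mean()
            zb = rb - rb.mean()
            sa = np.sqrt((za**2).sum())
            sb = np.sqrt((zb**2).sum())
            if sa == 0 or sb == 0:
                continue
            obs = float(za @ zb) / (sa * sb)
            rho[a, b] = rho[b, a] = obs
            perms = np.stack([rng.permutation(zb) for _ in range(n_shuffles)])
            null = (perms @ za) / (sa * sb)
            sd = null.std()
            if sd > 1e-12:
                zv = (obs - null.mean()) / sd
                z[a, b] = z[b, a] = zv
    return rho, z
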