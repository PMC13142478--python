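"""Population-burst detection and burst-participation metrics.

A population burst is a transient, network-wide elevation of the summed
firing rate.  Detection thresholds a heavily smoothed population-count trace
at a multiple of its RMS, prunes peaks closer than a minimum inter-burst
interval (keeping the largest), finds burst edges by walking out from each
peak to where the trace drops below a fraction of the peak-to-baseline
height, and refines the peak time on a lightly smoothed high-resolution
trace within those edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import SpikeTrainSet, smooth_trace


@dataclass
class BurstSet:
    """Detected population bursts: refined peak times and (start, end) edges.

    ``threshold`` is the absolute value applied to the coarse trace; ``params``
    records the detection settings that produced the set.
    """

    peaks_ms: np.ndarray
    edges_ms: np.ndarray  # shape (n, 2)
    threshold: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peaks_ms = np.asarray(self.peaks_ms, dtype=float).ravel()
        self.edges_ms = np.asarray(self.edges_ms, dtype=float).reshape(-1, 2)
        if self.edges_ms.shape[0] != self.peaks_ms.size:
            raise ValueError("peaks and edges must have equal length")
        for p, (a, b) in zip(self.peaks_ms, self.edges_ms):
            if not (a <= p <= b):
                raise ValueError("each peak must lie within its edges")
        if self.peaks_ms.size > 1 and np.any(np.diff(self.peaks_ms) <= 0):
            raise ValueError("peaks must be strictly increasing")

    @property
    def n_bursts(self) -> int:
        return int(self.peaks_ms.size)

    def widths_ms(self) -> np.ndarray:
        return self.edges_ms[:, 1] - self.edges_ms[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_ms": self.edges_ms[:, 0],
                "peak_ms": self.peaks_ms,
                "end_ms": self.edges_ms[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_bursts(
    s: SpikeTrainSet,
    rms_multiplier: float,
    min_ibi_ms: float = 1000.0,
    edge_frac: float = 0.2,
    coarse=(20.0, 100.0),
    hires=(8.0, 8.0),
    bin_ms: float = 1.0,
) -> BurstSet:
    """Detect population bursts on the smoothed population count.

    Parameters
    ----------
    rms_multiplier : float
        Threshold = multiplier x RMS (uncentred, sqrt(mean(x^2))) of the
        coarse trace.
    min_ibi_ms : float
        Minimum peak separation; enforced greedily, largest peaks first.
    edge_frac : float
        Edge level = baseline + edge_frac x (peak - baseline), where the
        baseline is the higher of the two flanking troughs.
    coarse, hires : (boxcar_ms, sigma_ms)
        Smoothing of the coarse (peak/edge finding) and high-resolution
        (peak refinement) traces.
    """
    if rms_multiplier <= 0:
        raise ValueError("rms_multiplier must be positive")
    counts = s.population_rate(bin_ms=bin_ms)
    params = {
        "rms_multiplier": rms_multiplier,
        "min_ibi_ms": min_ibi_ms,
        "edge_frac": edge_frac,
        "coarse": tuple(coarse),
        "hires": tuple(hires),
        "bin_ms": bin_ms,
    }
    if counts.sum() == 0:
        return BurstSet(np.empty(0), np.empty((0, 2)), threshold=0.0, params=params)
    c = smooth_trace(counts, bin_ms, *coarse)
    h = smooth_trace(counts, bin_ms, *hires)
    theta = rms_multiplier * float(np.sqrt(np.mean(c**2)))

    cand, _ = find_peaks(c)
    cand = cand[c[cand] > theta]
    # greedy pruning, descending amplitude, enforcing the minimum IBI
    order = cand[np.argsort(c[cand])[::-1]]
    kept: list[int] = []
    min_ibi_bins = min_ibi_ms / bin_ms
    for i in order:
        if all(abs(i - k) >= min_ibi_bins for k in kept):
            kept.append(i)
    kept.sort()

    peaks, edges = [], []
    n = c.size
    for k, i in enumerate(kept):
        left_bound = kept[k - 1] if k > 0 else 0
        right_bound = kept[k + 1] if k + 1 < len(kept) else n - 1
        left_trough = c[left_bound : i + 1].min() if i > left_bound else c[i]
        right_trough = c[i : right_bound + 1].min() if right_bound > i else c[i]
        baseline = max(left_trough, right_trough)
        level = baseline + edge_frac * (c[i] - baseline)
        a = i
        while a > 0 and c[a] >= level:
            a -= 1
        if c[a] < level:
            a += 1
        b = i
        while b < n - 1 and c[b] >= level:
            b += 1
        if c[b] < level:
            b -= 1
        refined = a + int(np.argmax(h[a : b + 1]))
        peaks.append((refined + 0.5) * bin_ms)
        edges.append((a * bin_ms, (b + 1) * bin_ms))

    peaks = np.asarray(peaks)
    edges = np.asarray(edges).reshape(-1, 2)
    order = np.argsort(peaks)
    return BurstSet(peaks[order], edges[order], threshold=theta, params=params)


def burst_sensitivity(
    s: SpikeTrainSet,
    mult_lo: float = 1.0,
    mult_hi: float = 5.0,
    step: float = 0.1,
    min_ibi_ms: float = 1000.0,
    edge_frac: float = 0.2,
    **kwargs,
) -> pd.DataFrame:
    """Sweep the RMS multiplier and report bursts per minute at each value."""
    if step <= 0:
        raise ValueError("step must be positive")
    mults = np.arange(mult_lo, mult_hi + step / 2, step)
    minutes = s.duration_ms / 60000.0
    rows = []
    for m in mults:
        b = detect_bursts(s, float(m), min_ibi_ms=min_ibi_ms, edge_frac=edge_frac, **kwargs)
        rows.append({"multiplier": float(m), "bursts_per_min": b.n_bursts / minutes})
    return pd.DataFrame(rows)


def frac_active(s: SpikeTrainSet, b: BurstSet, min_spikes: int = 2) -> np.ndarray:
    """Per unit, the fraction of bursts containing >= min_spikes of its spikes.

    Burst windows are half-open ``[start, end)``.  NaN per unit when the
    burst set is empty.
    """
    if b.n_bursts == 0:
        return np.full(s.n_units, np.nan)
    out = np.zeros(s.n_units)
    for i, t in enumerate(s.trains):
        hits = 0
        for a, e in b.edges_ms:
            n_in = np.searchsorted(t, e, side="left") - np.searchsorted(t, a, side="left")
            if n_in >= min_spikes:
                hits += 1
        out[i] = hits / b.n_bursts
    return out


def frac_spikes_in_burst(s: SpikeTrainSet, b: BurstSet) -> np.ndarray:
    """Per unit, the fraction of its spikes inside any burst window.

    NaN for units with zero spikes.
    """
    out = np.full(s.n_units, np.nan)
    for i, t in enumerate(s.trains):
        if t.size == 0:
            continue
        inside = np.zeros(t.size, dtype=bool)
        for a, e in b.edges_ms:
            inside |= (t >= a) & (t < e)
        out[i] = inside.mean()
    return out


def classify_backbone(frac_active_per_condition, min_frac: float = 1.0) -> np.ndarray:
    """Label units 'backbone' or 'non_rigid' from per-condition participation.

    A unit is backbone if its fraction of bursts with >=2 spikes reaches
    ``min_frac`` (default 1.0, i.e. every burst) in at least one condition.
    NaN fractions (no bursts in a condition) never qualify.
    """
    if len(frac_active_per_condition) == 0:
        raise ValueError("at least one condition is required")
    mat = np.vstack([np.asarray(v, dtype=float) for v in frac_active_per_condition])
    with np.errstate(invalid="ignore"):
        hit = np.any(np.nan_to_num(mat, nan=-1.0) >= min_frac, axis=0)
    return np.where(hit, "backbone", "non_rigid")
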