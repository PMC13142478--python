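"""Spike-triggered population coupling (stPR).

For each unit the leave-one-out population rate is low-pass filtered
(zero-phase Butterworth), baseline-subtracted (baseline = its time mean) and
averaged around the unit's spikes over a +/-max_lag window, then normalised
by the sum of the mean firing rates of all other units.  The zero-lag value
measures how tied the unit's firing is to network activity; the curve's
maximum and its lag are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.signal import butter, filtfilt

from .containers import SpikeTrainSet
from .rates import binned_rates


@dataclass
class CouplingResult:
    """Per-unit stPR lag curves plus zero-lag and peak summaries."""

    lags_ms: np.ndarray
    curves: np.ndarray  # units x lags, dimensionless
    unit_ids: list
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (len(self.unit_ids), self.lags_ms.size):
            raise ValueError("curves must be units x lags")

    @property
    def center(self) -> int:
        return int(np.argmin(np.abs(self.lags_ms)))

    @property
    def zero_lag(self) -> np.ndarray:
        return self.curves[:, self.center]

    @property
    def peak(self):
        """(value, lag_ms) of each unit's curve maximum; NaN rows stay NaN."""
        vals = np.full(len(self.unit_ids), np.nan)
        lags = np.full(len(self.unit_ids), np.nan)
        for i, row in enumerate(self.curves):
            if np.all(np.isnan(row)):
                continue
            k = int(np.nanargmax(row))
            vals[i] = row[k]
            lags[i] = self.lags_ms[k]
        return vals, lags

    def to_frame(self):
        import pandas as pd

        pv, pl = self.peak
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "zero_lag": self.zero_lag,
                "peak_value": pv,
                "peak_lag_ms": pl,
            }
        )


def spike_triggered_pop_rate(
    s: SpikeTrainSet,
    max_lag_ms: float = 80.0,
    lowpass_hz: float = 20.0,
    bin_ms: float = 1.0,
    filter_order: int = 3,
) -> CouplingResult:
    """Spike-triggered leave-one-out population rate coupling per unit.

    Spikes within ``max_lag_ms`` of either recording edge do not trigger.
    Units with no (usable) spikes, or whose complement population is silent,
    yield NaN rows.
    """
    if s.n_units < 2:
        raise ValueError("need at least 2 units")
    if s.duration_ms <= 2 * max_lag_ms:
        raise ValueError("recording shorter than twice the maximum lag")
    rm = binned_rates(s, bin_ms)
    rates_hz = rm.values
    total = rates_hz.sum(axis=0)
    fs = 1000.0 / bin_ms
    sos_b, sos_a = butter(filter_order, lowpass_hz, fs=fs)
    # filtering is linear: filter the total once and each unit's own trace once
    ftotal = filtfilt(sos_b, sos_a, total)
    fown = filtfilt(sos_b, sos_a, rates_hz, axis=1)
    mean_rates = s.mean_firing_rates()

    lag_bins = int(round(max_lag_ms / bin_ms))
    lags = np.arange(-lag_bins, lag_bins + 1)
    n_bins = rates_hz.shape[1]
    curves = np.full((s.n_units, lags.size), np.nan)
    for i, t in enumerate(s.trains):
        norm = mean_rates.sum() - mean_rates[i]
        if norm <= 0:
            continue
        p = ftotal - fown[i]
        baseline = p.mean()
        usable = t[(t >= max_lag_ms) & (t <= s.duration_ms - max_lag_ms)]
        if usable.size == 0:
            continue
        centers = np.minimum((usable / bin_ms).astype(int), n_bins - 1)
        idx = centers[:, None] + lags[None, :]
        idx = np.clip(idx, 0, n_bins - 1)
        curves[i] = (p[idx].mean(axis=0) - baseline) / norm
    return CouplingResult(
        lags_ms=lags * bin_ms,
        curves=curves,
        unit_ids=list(s.unit_ids),
        params={
            "max_lag_ms": max_lag_ms,
            "lowpass_hz": lowpass_hz,
            "bin_ms": bin_ms,
            "filter_order": filter_order,
        },
    )


def sliding_window_coupling(
    s: SpikeTrainSet,
    window_s: float = 120.0,
    step_s: float = 10.0,
    min_spikes: int = 12,
    **stpr_kwargs,
):
    """Zero-lag stPR per unit in overlapping sliding windows.

    Returns (frame_starts_ms, frames x units matrix).  Entries are NaN where
    the unit fired fewer than ``min_spikes`` in the window.  An empty result
    (with a warning) is returned when the recording is shorter than one
    window.
    """
    w = window_s * 1000.0
    step = step_s * 1000.0
    if s.duration_ms < w:
        warnings.warn("recording shorter than one window; empty result")
        return np.empty(0), np.empty((0, s.n_units))
    n_frames = int(np.floor((s.duration_ms - w) / step)) + 1
    starts = np.arange(n_frames) * step
    out = np.full((n_frames, s.n_units), np.nan)
    for f, t0 in enumerate(starts):
        sub = s.subtime(t0, t0 + w)
        res = spike_triggered_pop_rate(sub, **stpr_kwargs)
        counts = np.array([t.size for t in sub.trains])
        row = res.zero_lag.copy()
        row[counts < min_spikes] = np.nan
        out[f] = row
    return starts, out
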