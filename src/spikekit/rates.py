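"""Instantaneous firing-rate estimators producing :class:`RateMatrix`.

Three estimators are provided: plain binned counts, Gaussian-smoothed counts,
and the ISI-reciprocal estimator (rate inside an inter-spike interval equals
1000/ISI Hz, piecewise constant, then Gaussian smoothed).  All estimators
produce the same shape for the same (duration, bin) and stamp their name and
parameters into ``estimator_meta``.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import RateMatrix, SpikeTrainSet


def binned_rates(s: SpikeTrainSet, bin_ms: float) -> RateMatrix:
    """Spike counts per bin converted to Hz (count / bin width in s)."""
    counts = s.raster(bin_ms)
    return RateMatrix(
        values=counts / (bin_ms / 1000.0),
        bin_ms=bin_ms,
        unit_ids=list(s.unit_ids),
        estimator_meta={"estimator": "binned", "bin_ms": bin_ms},
    )


def gaussian_rates(s: SpikeTrainSet, bin_ms: float, sigma_ms: float) -> RateMatrix:
    """Binned counts convolved with a unit-area Gaussian kernel, in Hz.

    The kernel is truncated at +/-4 sigma with zero padding, so each interior
    spike contributes unit integral to its rate trace.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    counts = s.raster(bin_ms).astype(float)
    smoothed = gaussian_filter1d(
        counts, sigma_ms / bin_ms, axis=1, mode="constant", truncate=4.0
    )
    return RateMatrix(
        values=np.maximum(smoothed, 0.0) / (bin_ms / 1000.0),
        bin_ms=bin_ms,
        unit_ids=list(s.unit_ids),
        estimator_meta={"estimator": "gaussian", "bin_ms": bin_ms, "sigma_ms": sigma_ms},
    )


def isi_rates(s: SpikeTrainSet, bin_ms: float = 1.0, sigma_ms: float = 10.0) -> RateMatrix:
    """ISI-reciprocal rates: 1000/ISI Hz inside each interval, smoothed.

    The rate at time t in ``[t_i, t_{i+1})`` is the reciprocal of that
    interval (in seconds); zero outside the span of the unit's spikes.  Units
    with fewer than two spikes yield an all-zero row.  A Gaussian smoothing of
    ``sigma_ms`` is applied afterwards (pass 0 to skip).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(np.ceil(s.duration_ms / bin_ms))
    centres = (np.arange(n_bins) + 0.5) * bin_ms
    values = np.zeros((s.n_units, n_bins))
    for i, t in enumerate(s.trains):
        if t.size < 2:
            continue
        isi = np.diff(t)
        # interval index for each bin centre inside [first, last) spike
        pos = np.searchsorted(t, centres, side="right") - 1
        inside = (pos >= 0) & (pos < isi.size)
        iv = isi[pos[inside]]
        row = np.zeros(n_bins)
        with np.errstate(divide="ignore"):
            row[inside] = np.where(iv > 0, 1000.0 / np.where(iv > 0, iv, 1.0), 0.0)
        values[i] = row
    if sigma_ms > 0:
        values = gaussian_filter1d(
            values, sigma_ms / bin_ms, axis=1, mode="constant", truncate=4.0
        )
        values = np.maximum(values, 0.0)
    return RateMatrix(
        values=values,
        bin_ms=bin_ms,
        unit_ids=list(s.unit_ids),
        estimator_meta={"estimator": "isi", "bin_ms": bin_ms, "sigma_ms": sigma_ms},
    )
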