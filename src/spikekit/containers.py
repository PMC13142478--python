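"""Core containers for spike-train analysis.

All spike times are stored and processed in milliseconds.  Time windows are
half-open ``[t0, t1)`` everywhere, so adjacent windows partition a recording
without double counting.  A :class:`SpikeTrainSet` holds one non-decreasing
spike-time array per sorted unit plus metadata; a :class:`RateMatrix` holds a
units x time-bins instantaneous firing-rate matrix in Hz with provenance of
the estimator that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d


class InvalidWindowError(ValueError):
    """Requested time window is empty or outside the recording."""


class MissingUnitError(KeyError):
    """A requested unit id is not present in the set."""


def _as_train(t) -> np.ndarray:
    a = np.asarray(t, dtype=float).ravel()
    return a


@dataclass
class SpikeTrainSet:
    """Spike times for a population of sorted units.

    Parameters
    ----------
    unit_ids : sequence
        Unique, ordered unit labels (any hashable; stored as given).
    trains : sequence of array-like
        Per-unit spike times in milliseconds, non-decreasing, within
        ``[0, duration_ms]``.
    duration_ms : float
        Positive recording length in milliseconds.
    unit_meta : dict, optional
        Per-unit metadata (e.g. x/y position in um, quality label, region),
        keyed by field name, one value per unit.
    recording_meta : dict, optional
        Free-form provenance (source path, sampling rate, notes).
    """

    unit_ids: list
    trains: list
    duration_ms: float
    unit_meta: dict = field(default_factory=dict)
    recording_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.unit_ids = list(self.unit_ids)
        self.trains = [_as_train(t) for t in self.trains]
        self.duration_ms = float(self.duration_ms)
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if len(self.trains) != len(self.unit_ids):
            raise ValueError("trains and unit_ids must have equal length")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")
        for uid, t in zip(self.unit_ids, self.trains):
            if t.size:
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"train for unit {uid!r} is not non-decreasing")
                if t[0] < 0 or t[-1] > self.duration_ms:
                    raise ValueError(
                        f"unit {uid!r} has spikes outside [0, {self.duration_ms}] ms"
                    )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def _index_of(self, uid) -> int:
        try:
            return self.unit_ids.index(uid)
        except ValueError:
            raise MissingUnitError(uid) from None

    # ------------------------------------------------------------------
    # slicing / subsetting
    # ------------------------------------------------------------------
    def subtime(self, t0_ms: float, t1_ms: float) -> "SpikeTrainSet":
        """Return the half-open window ``[t0, t1)`` re-referenced to 0.

        All units are retained (possibly with empty trains); spikes exactly at
        ``t1`` are excluded.  Metadata is carried over.
        """
        if not (0 <= t0_ms < t1_ms <= self.duration_ms):
            raise InvalidWindowError(
                f"window [{t0_ms}, {t1_ms}) invalid for duration {self.duration_ms} ms"
            )
        trains = []
        for t in self.trains:
            lo = np.searchsorted(t, t0_ms, side="left")
            hi = np.searchsorted(t, t1_ms, side="left")
            trains.append(t[lo:hi] - t0_ms)
        return SpikeTrainSet(
            unit_ids=list(self.unit_ids),
            trains=trains,
            duration_ms=t1_ms - t0_ms,
            unit_meta=dict(self.unit_meta),
            recording_meta=dict(self.recording_meta),
        )

    def subset(self, ids: Sequence) -> "SpikeTrainSet":
        """Return the units in ``ids`` in the requested order; duration kept."""
        idx = [self._index_of(u) for u in ids]
        meta = {
            k: [list(v)[i] for i in idx] for k, v in self.unit_meta.items()
        }
        return SpikeTrainSet(
            unit_ids=[self.unit_ids[i] for i in idx],
            trains=[self.trains[i].copy() for i in idx],
            duration_ms=self.duration_ms,
            unit_meta=meta,
            recording_meta=dict(self.recording_meta),
        )

    # ------------------------------------------------------------------
    # elementary statistics
    # ------------------------------------------------------------------
    def mean_firing_rates(self) -> np.ndarray:
        """Per-unit mean rate in Hz: spike count / duration in seconds."""
        counts = np.array([t.size for t in self.trains], dtype=float)
        return counts / (self.duration_ms / 1000.0)

    def interspike_intervals(self):
        """Per-unit ISI arrays (ms) and ISI coefficient of variation.

        Returns
        -------
        isis : list of ndarray
            Successive spike-time differences per unit; empty for units with
            fewer than two spikes.
        cv : ndarray
            ``std(ISI)/mean(ISI)`` per unit; NaN where undefined (<2 spikes).
        """
        isis = [np.diff(t) if t.size >= 2 else np.empty(0) for t in self.trains]
        cv = np.full(self.n_units, np.nan)
        for i, d in enumerate(isis):
            if d.size >= 1:
                m = d.mean()
                cv[i] = d.std() / m if m > 0 else np.nan
        return isis, cv

    def population_rate(
        self, bin_ms: float = 1.0, boxcar_ms: float = 0.0, sigma_ms: float = 0.0
    ) -> np.ndarray:
        """Binned population spike count per bin, optionally smoothed.

        Smoothing order is boxcar first, then Gaussian (truncated at 4 sigma,
        zero-padded edges).  Without smoothing the series sums exactly to the
        total spike count.
        """
        if bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if boxcar_ms < 0 or sigma_ms < 0:
            raise ValueError("smoothing widths must be non-negative")
        n_bins = int(np.ceil(self.duration_ms / bin_ms))
        counts = np.zeros(n_bins)
        for t in self.trains:
            if t.size:
                idx = np.minimum((t / bin_ms).astype(int), n_bins - 1)
                counts += np.bincount(idx, minlength=n_bins)
        return smooth_trace(counts, bin_ms, boxcar_ms, sigma_ms)

    def raster(self, bin_ms: float, binary: bool = False) -> np.ndarray:
        """Units x bins spike-count matrix (or 0/1 if ``binary``)."""
        if bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        n_bins = int(np.ceil(self.duration_ms / bin_ms))
        out = np.zeros((self.n_units, n_bins), dtype=int)
        for i, t in enumerate(self.trains):
            if t.size:
                idx = np.minimum((t / bin_ms).astype(int), n_bins - 1)
                out[i] = np.bincount(idx, minlength=n_bins)
        if binary:
            out = (out > 0).astype(int)
        return out


def smooth_trace(
    x: np.ndarray, bin_ms: float, boxcar_ms: float = 0.0, sigma_ms: float = 0.0
) -> np.ndarray:
    """Boxcar then Gaussian smoothing of a binned trace (both optional).

    The boxcar kernel is normalised to unit sum; the Gaussian kernel is
    truncated at +/-4 sigma with zero padding, so total mass is conserved
    away from the edges.
    """
    y = np.asarray(x, dtype=float)
    if boxcar_ms > 0:
        w = max(int(round(boxcar_ms / bin_ms)), 1)
        kernel = np.ones(w) / w
        y = np.convolve(y, kernel, mode="same")
    if sigma_ms > 0:
        y = gaussian_filter1d(y, sigma_ms / bin_ms, mode="constant", truncate=4.0)
    return y


def normalized_change(x, x0):
    """Symmetric normalised change N = (x' - x0') / (x' + x0'), x' = max(x, 0).

    Bounded in [-1, 1]; NaN where both clamped values are zero.  Works
    elementwise on arrays.
    """
    xp = np.maximum(np.asarray(x, dtype=float), 0.0)
    x0p = np.maximum(np.asarray(x0, dtype=float), 0.0)
    denom = xp + x0p
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (xp - x0p) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class RateMatrix:
    """Units x time-bins instantaneous firing rates in Hz.

    ``t0_ms`` is the left edge of the first bin in the coordinate frame of
    the recording the matrix was estimated from.  ``estimator_meta`` records
    the producing estimator's name and parameters.
    """

    values: np.ndarray
    bin_ms: float
    unit_ids: list
    t0_ms: float = 0.0
    estimator_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (units x bins)")
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length must match values rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rate values must be finite")
        if np.any(self.values < 0):
            raise ValueError("rate values must be non-negative")
        self.unit_ids = list(self.unit_ids)
        self.bin_ms = float(self.bin_ms)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_bins * self.bin_ms

    def times_ms(self) -> np.ndarray:
        """Bin-centre times in the matrix's own frame (0 = first bin edge)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_ms

    def subtime(self, t0_ms: float, t1_ms: float) -> "RateMatrix":
        """Bins whose left edge falls in ``[t0, t1)``, re-referenced to 0."""
        if not (0 <= t0_ms < t1_ms <= self.duration_ms + self.bin_ms * 0.5):
            raise InvalidWindowError(f"window [{t0_ms}, {t1_ms}) invalid")
        lo = int(np.ceil(t0_ms / self.bin_ms - 1e-9))
        hi = int(np.ceil(t1_ms / self.bin_ms - 1e-9))
        return RateMatrix(
            values=self.values[:, lo:hi].copy(),
            bin_ms=self.bin_ms,
            unit_ids=list(self.unit_ids),
            t0_ms=0.0,
            estimator_meta=dict(self.estimator_meta),
        )

    def subset(self, ids: Sequence) -> "RateMatrix":
        index = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            idx = [index[u] for u in ids]
        except KeyError as e:
            raise MissingUnitError(e.args[0]) from None
        return RateMatrix(
            values=self.values[idx].copy(),
            bin_ms=self.bin_ms,
            unit_ids=list(ids),
            t0_ms=self.t0_ms,
            estimator_meta=dict(self.estimator_meta),
        )
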