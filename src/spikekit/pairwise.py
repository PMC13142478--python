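"""Pairwise comparison matrices: STTC, lagged rate correlation, graph export.

The spike time tiling coefficient (STTC) is a firing-rate-insensitive
pairwise spike-timing correlation:

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

where T_X is the fraction of the recording covered by the union of
coincidence windows [t - delta, t + delta] around X's spikes (clipped to the
recording), and P_X is the fraction of X's spikes falling within delta of any
spike of the partner.

Matrices are symmetric with NaN on the diagonal, so distributional summaries
over unique unit pairs are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import RateMatrix, SpikeTrainSet


@dataclass
class PairwiseMatrix:
    """Symmetric n x n comparison matrix with method metadata."""

    values: np.ndarray
    unit_ids: list
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.unit_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n matching unit_ids")
        if not np.array_equal(self.values, self.values.T, equal_nan=True):
            raise ValueError("values must be symmetric")
        self.unit_ids = list(self.unit_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def unique_pair_values(self) -> np.ndarray:
        """Upper-triangle (i < j) values, one per unique unit pair."""
        iu = np.triu_indices(self.n_units, k=1)
        return self.values[iu]

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_units, k=1)
        return pd.DataFrame(
            {
                "unit_a": [self.unit_ids[a] for a in i],
                "unit_b": [self.unit_ids[b] for b in j],
                "value": self.values[i, j],
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


@dataclass
class PairwiseMatrixStack:
    """Labelled matrices sharing unit ids and method (e.g. one per condition)."""

    matrices: list
    labels: list

    def __post_init__(self):
        if len(self.matrices) != len(self.labels):
            raise ValueError("matrices and labels must align")
        if self.matrices:
            ref = self.matrices[0]
            for m in self.matrices[1:]:
                if m.unit_ids != ref.unit_ids or m.method != ref.method:
                    raise ValueError("stack members must share unit_ids and method")

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, i):
        return self.matrices[i]


def _tiling_fraction(t: np.ndarray, delta: float, duration: float) -> float:
    """Fraction of [0, duration] covered by the union of +/-delta windows."""
    if t.size == 0:
        return 0.0
    starts = np.clip(t - delta, 0.0, duration)
    ends = np.clip(t + delta, 0.0, duration)
    total = ends[0] - starts[0]
    cursor = ends[0]
    for a, b in zip(starts[1:], ends[1:]):
        if b <= cursor:
            continue
        total += b - max(a, cursor)
        cursor = b
    return total / duration


def _frac_within(a: np.ndarray, b: np.ndarray, delta: float) -> float:
    """Fraction of spikes in ``a`` within delta of any spike in ``b``."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    return float(np.mean(np.minimum(left, right) <= delta))


def sttc_pair(a: np.ndarray, b: np.ndarray, delta_ms: float, duration_ms: float) -> float:
    """STTC for a single pair of sorted spike trains; NaN when undefined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.nan
    ta = _tiling_fraction(a, delta_ms, duration_ms)
    tb = _tiling_fraction(b, delta_ms, duration_ms)
    pa = _frac_within(a, b, delta_ms)
    pb = _frac_within(b, a, delta_ms)
    da = 1.0 - pa * tb
    db = 1.0 - pb * ta
    if da == 0.0 or db == 0.0:
        return np.nan
    return 0.5 * ((pa - tb) / da + (pb - ta) / db)


def sttc(s: SpikeTrainSet, delta_ms: float = 20.0) -> PairwiseMatrix:
    """STTC for all unit pairs with a +/-delta coincidence window."""
    if delta_ms <= 0:
        raise ValueError("delta_ms must be positive")
    n = s.n_units
    tilings = np.array(
        [_tiling_fraction(t, delta_ms, s.duration_ms) for t in s.trains]
    )
    values = np.full((n, n), np.nan)
    for i in range(n):
        a = s.trains[i]
        if a.size == 0:
            continue
        for j in range(i + 1, n):
            b = s.trains[j]
            if b.size == 0:
                continue
            pa = _frac_within(a, b, delta_ms)
            pb = _frac_within(b, a, delta_ms)
            da = 1.0 - pa * tilings[j]
            db = 1.0 - pb * tilings[i]
            if da == 0.0 or db == 0.0:
                continue
            v = 0.5 * ((pa - tilings[j]) / da + (pb - tilings[i]) / db)
            values[i, j] = values[j, i] = v
    return PairwiseMatrix(values, list(s.unit_ids), "sttc", {"delta_ms": delta_ms})


def fr_correlation(r: RateMatrix, max_lag_ms: float = 350.0) -> PairwiseMatrix:
    """Max signed Pearson correlation over integer-bin lags in [-L, +L].

    Lagged overlaps are truncated (no wrap-around or padding) and the
    correlation is renormalised per lag on the overlapping segment.  Pairs
    involving a zero-variance trace are NaN.
    """
    if max_lag_ms < 0:
        raise ValueError("max_lag_ms must be non-negative")
    if r.n_bins < 2:
        raise ValueError("need at least 2 time bins")
    L = int(round(max_lag_ms / r.bin_ms))
    if L >= r.n_bins:
        raise ValueError("max lag exceeds trace length")
    x = r.values
    n = r.n_units
    best = np.full((n, n), -np.inf)

    def corr_at(k: int) -> np.ndarray:
        a = x[:, k:] if k > 0 else x
        b = x[:, : x.shape[1] - k] if k > 0 else x
        m = a.shape[1]
        za = a - a.mean(axis=1, keepdims=True)
        zb = b - b.mean(axis=1, keepdims=True)
        sa = np.sqrt((za**2).sum(axis=1))
        sb = np.sqrt((zb**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (za @ zb.T) / np.outer(sa, sb)
        c[~np.isfinite(c)] = -np.inf
        return c

    for k in range(L + 1):
        c = corr_at(k)
        # lag +k: row leads by k; lag -k is the transpose
        best = np.fmax(best, c)
        best = np.fmax(best, c.T)
    values = np.where(np.isfinite(best), best, np.nan)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, np.nan)
    values = np.fmax(values, values.T)  # exact symmetry
    return PairwiseMatrix(
        values, list(r.unit_ids), "fr_correlation", {"max_lag_ms": max_lag_ms}
    )


def threshold_matrix(m: PairwiseMatrix, cutoff: float) -> PairwiseMatrix:
    """Zero out off-diagonal values below ``cutoff``; records the cutoff."""
    values = m.values.copy()
    off = ~np.eye(m.n_units, dtype=bool)
    sub = values[off]
    sub[sub < cutoff] = 0.0
    values[off] = sub
    params = dict(m.params)
    params["threshold_cutoff"] = cutoff
    return PairwiseMatrix(values, list(m.unit_ids), m.method, params)


def to_weighted_graph(
    m: PairwiseMatrix, threshold: float = -np.inf, node_attrs: dict | None = None
) -> nx.Graph:
    """Weighted undirected graph with edges where value > threshold.

    ``node_attrs`` maps attribute name -> per-unit values (e.g. x/y position).
    The graph can be written with :func:`networkx.write_weighted_edgelist`.
    """
    g = nx.Graph()
    for i, u in enumerate(m.unit_ids):
        attrs = {k: list(v)[i] for k, v in (node_attrs or {}).items()}
        g.add_node(u, **attrs)
    iu, ju = np.triu_indices(m.n_units, k=1)
    for i, j in zip(iu, ju):
        v = m.values[i, j]
        if np.isfinite(v) and v > threshold:
            g.add_edge(m.unit_ids[i], m.unit_ids[j], weight=float(v))
    return g


def mean_weighted_degree(m: PairwiseMatrix) -> np.ndarray:
    """Per-unit mean of off-diagonal row values, ignoring NaNs.

    NaN for a unit whose whole row is undefined.
    """
    if m.n_units < 2:
        raise ValueError("need at least 2 units")
    values = m.values.copy()
    np.fill_diagonal(values, np.nan)
    defined = np.isfinite(values)
    cnt = defined.sum(axis=1)
    total = np.where(defined, values, 0.0).sum(axis=1)
    return np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
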