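"""PCA manifolds of rate matrices and statistics over latent-state posteriors.

Latent-state model *fitting* is consumed, not implemented: any time-bins x
states posterior (for instance from a GP latent-variable model or a toy HMM)
is accepted as a :class:`StatePosterior`, optionally with a per-bin burst
membership label so that burst-resolved statistics (per-burst entropy,
within-burst transition matrices) can exclude cross-burst boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .containers import RateMatrix


@dataclass
class StatePosterior:
    """Per-time-bin posterior over latent population states.

    ``burst_id`` assigns each bin to a burst (negative or NaN = outside any
    burst); required for the burst-resolved statistics.
    """

    probs: np.ndarray  # bins x states
    bin_ms: float
    burst_id: np.ndarray | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be bins x states")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("posterior rows must sum to 1 (within 1e-6)")
        if self.burst_id is not None:
            self.burst_id = np.asarray(self.burst_id, dtype=float).ravel()
            if self.burst_id.size != self.probs.shape[0]:
                raise ValueError("burst_id must have one label per bin")

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]

    def burst_labels(self) -> np.ndarray:
        """Sorted unique non-negative finite burst ids."""
        if self.burst_id is None:
            raise ValueError("burst_id is not set")
        b = self.burst_id
        return np.unique(b[np.isfinite(b) & (b >= 0)])


def pca_manifold(r: RateMatrix, n_components: int = 2, center: bool = True,
                 standardize: bool = False):
    """PCA of a rate matrix over time bins (observations = bins).

    Returns (embedding bins x k, loadings k x units, explained-variance
    ratios).  The ratio vector reports at least 5 components when the data
    rank allows, regardless of ``n_components``.
    """
    if r.n_bins < 2 or r.n_units < 1:
        raise ValueError("need >=2 bins and >=1 unit")
    x = r.values.T.astype(float)  # bins x units
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    elif center:
        x = x - x.mean(axis=0)
    if np.allclose(x, 0):
        raise ValueError("degenerate (constant) rate matrix")
    k_fit = min(max(n_components, 5), min(x.shape))
    pca = PCA(n_components=k_fit)
    emb = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    return emb[:, :n_components], pca.components_[:n_components], ratios


def state_occupancy(p: StatePosterior, mask=None) -> np.ndarray:
    """Mean posterior over the selected bins; a length-n_states simplex vector."""
    if mask is None:
        mask = np.ones(p.probs.shape[0], dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype != bool:
        idx = mask
        sel = p.probs[idx]
    else:
        sel = p.probs[mask]
    if sel.shape[0] == 0:
        raise ValueError("mask selects no bins")
    return sel.mean(axis=0)


def burst_state_entropy(p: StatePosterior) -> dict:
    """Shannon entropy (bits) of the mean within-burst posterior, per burst."""
    out = {}
    for b in p.burst_labels():
        rows = p.probs[p.burst_id == b]
        pm = rows.mean(axis=0)
        nz = pm[pm > 0]
        out[float(b)] = float(-(nz * np.log2(nz)).sum())
    return out


def within_burst_transitions(p: StatePosterior) -> np.ndarray:
    """Row-stochastic state transition matrix counting only within-burst steps.

    States are the per-bin argmax (lowest index on ties); a step t -> t+1 is
    counted only when both bins share the same burst id.  Rows with no
    observed transitions are left all-zero.
    """
    if p.burst_id is None:
        raise ValueError("burst_id is required")
    states = np.argmax(p.probs, axis=1)
    k = p.n_states
    counts = np.zeros((k, k))
    b = p.burst_id
    same = (
        np.isfinite(b[:-1])
        & np.isfinite(b[1:])
        & (b[:-1] >= 0)
        & (b[1:] >= 0)
        & (b[:-1] == b[1:])
    )
    for s0, s1 in zip(states[:-1][same], states[1:][same]):
        counts[s0, s1] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row > 0, counts / np.where(row > 0, row, 1.0), 0.0)
    return out
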