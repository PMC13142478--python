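"""HDF5-backed analysis workspace.

Results are addressed by ``(namespace, key)`` pairs — one HDF5 group per
namespace, one subgroup per key — and carry attributes (method name,
parameters, timestamp, free-text annotations).  Existing keys are never
overwritten unless ``overwrite=True`` is passed explicitly, and a cached
entry short-circuits recomputation via :meth:`Workspace.cached`.

Layout notes: ragged spike trains are stored as one flat time array plus a
per-unit offset index; dict-valued metadata is stored as JSON strings.  The
schema is deliberately portable and language-neutral.
"""

from __future__ import annotations

import json
import time
from typing import Callable

import h5py
import numpy as np
import pandas as pd

from .bursts import BurstSet
from .containers import RateMatrix, SpikeTrainSet
from .coupling import CouplingResult
from .latent import StatePosterior
from .pairwise import PairwiseMatrix, PairwiseMatrixStack
from .slicing import SliceStack


class KeyExistsError(KeyError):
    """Refusal to overwrite an existing (namespace, key) entry."""


class EntryNotFoundError(KeyError):
    """No entry at the requested (namespace, key)."""


class MergeConflictError(ValueError):
    """Conflicting (namespace, key) during a merge under the 'error' policy."""


def _dump_json(group, name, obj):
    group.attrs[name] = json.dumps(obj, default=str)


def _load_json(group, name, default=None):
    if name in group.attrs:
        return json.loads(group.attrs[name])
    return default


def _store_ids(group, unit_ids):
    _dump_json(group, "unit_ids", list(unit_ids))


def _load_ids(group):
    return _load_json(group, "unit_ids", [])


def _write_spikes(group, s: SpikeTrainSet):
    flat = np.concatenate([t for t in s.trains]) if s.trains else np.empty(0)
    offsets = np.cumsum([0] + [t.size for t in s.trains])
    group.create_dataset("times_ms", data=flat)
    group.create_dataset("offsets", data=offsets)
    group.attrs["duration_ms"] = s.duration_ms
    _store_ids(group, s.unit_ids)
    _dump_json(group, "unit_meta", s.unit_meta)
    _dump_json(group, "recording_meta", s.recording_meta)


def _read_spikes(group) -> SpikeTrainSet:
    flat = group["times_ms"][...]
    offsets = group["offsets"][...]
    trains = [flat[offsets[i] : offsets[i + 1]] for i in range(offsets.size - 1)]
    return SpikeTrainSet(
        unit_ids=_load_ids(group),
        trains=trains,
        duration_ms=float(group.attrs["duration_ms"]),
        unit_meta=_load_json(group, "unit_meta", {}),
        recording_meta=_load_json(group, "recording_meta", {}),
    )


def _write_rates(group, r: RateMatrix):
    group.create_dataset("values", data=r.values)
    group.attrs["bin_ms"] = r.bin_ms
    group.attrs["t0_ms"] = r.t0_ms
    _store_ids(group, r.unit_ids)
    _dump_json(group, "estimator_meta", r.estimator_meta)


def _read_rates(group) -> RateMatrix:
    return RateMatrix(
        values=group["values"][...],
        bin_ms=float(group.attrs["bin_ms"]),
        unit_ids=_load_ids(group),
        t0_ms=float(group.attrs["t0_ms"]),
        estimator_meta=_load_json(group, "estimator_meta", {}),
    )


def _write_bursts(group, b: BurstSet):
    group.create_dataset("peaks_ms", data=b.peaks_ms)
    group.create_dataset("edges_ms", data=b.edges_ms)
    group.attrs["threshold"] = b.threshold
    _dump_json(group, "params", b.params)


def _read_bursts(group) -> BurstSet:
    return BurstSet(
        peaks_ms=group["peaks_ms"][...],
        edges_ms=group["edges_ms"][...],
        threshold=float(group.attrs["threshold"]),
        params=_load_json(group, "params", {}),
    )


def _write_pairwise(group, m: PairwiseMatrix):
    group.create_dataset("values", data=m.values)
    group.attrs["method"] = m.method
    _store_ids(group, m.unit_ids)
    _dump_json(group, "params", m.params)


def _read_pairwise(group) -> PairwiseMatrix:
    return PairwiseMatrix(
        values=group["values"][...],
        unit_ids=_load_ids(group),
        method=str(group.attrs["method"]),
        params=_load_json(group, "params", {}),
    )


def _write_pairwise_stack(group, st: PairwiseMatrixStack):
    _dump_json(group, "labels", list(st.labels))
    for i, m in enumerate(st.matrices):
        _write_pairwise(group.create_group(f"m{i}"), m)


def _read_pairwise_stack(group) -> PairwiseMatrixStack:
    labels = _load_json(group, "labels", [])
    mats = [_read_pairwise(group[f"m{i}"]) for i in range(len(labels))]
    return PairwiseMatrixStack(mats, labels)


def _write_slice_stack(group, st: SliceStack):
    group.attrs["provenance"] = st.provenance
    _dump_json(group, "meta", st.meta)
    if st.window is not None:
        group.attrs["window"] = list(st.window)
    if st.alignment_times_ms is not None:
        group.create_dataset("alignment_times_ms", data=np.asarray(st.alignment_times_ms))
    group.attrs["n_slices"] = len(st.slices)
    for i, sl in enumerate(st.slices):
        sub = group.create_group(f"s{i}")
        _write_payload(sub, sl)


def _read_slice_stack(group) -> SliceStack:
    n = int(group.attrs["n_slices"])
    slices = [_read_payload(group[f"s{i}"]) for i in range(n)]
    window = tuple(group.attrs["window"]) if "window" in group.attrs else None
    align = (
        group["alignment_times_ms"][...] if "alignment_times_ms" in group else None
    )
    return SliceStack(
        slices=slices,
        provenance=str(group.attrs["provenance"]),
        alignment_times_ms=align,
        window=window,
        meta=_load_json(group, "meta", {}),
    )


def _write_coupling(group, c: CouplingResult):
    group.create_dataset("lags_ms", data=c.lags_ms)
    group.create_dataset("curves", data=c.curves)
    _store_ids(group, c.unit_ids)
    _dump_json(group, "params", c.params)


def _read_coupling(group) -> CouplingResult:
    return CouplingResult(
        lags_ms=group["lags_ms"][...],
        curves=group["curves"][...],
        unit_ids=_load_ids(group),
        params=_load_json(group, "params", {}),
    )


def _write_posterior(group, p: StatePosterior):
    group.create_dataset("probs", data=p.probs)
    group.attrs["bin_ms"] = p.bin_ms
    if p.burst_id is not None:
        group.create_dataset("burst_id", data=p.burst_id)


def _read_posterior(group) -> StatePosterior:
    return StatePosterior(
        probs=group["probs"][...],
        bin_ms=float(group.attrs["bin_ms"]),
        burst_id=group["burst_id"][...] if "burst_id" in group else None,
    )


def _write_frame(group, df: pd.DataFrame):
    _dump_json(group, "columns", list(df.columns))
    for col in df.columns:
        vals = df[col].to_numpy()
        if vals.dtype == object:
            vals = np.asarray([str(v) for v in vals], dtype=h5py.string_dtype())
        group.create_dataset(f"col_{col}", data=vals)


def _read_frame(group) -> pd.DataFrame:
    cols = _load_json(group, "columns", [])
    data = {}
    for col in cols:
        vals = group[f"col_{col}"][...]
        if vals.dtype.kind in ("S", "O"):
            vals = np.asarray([v.decode() if isinstance(v, bytes) else v for v in vals])
        data[col] = vals
    return pd.DataFrame(data)


_WRITERS = {
    "SpikeTrainSet": _write_spikes,
    "RateMatrix": _write_rates,
    "BurstSet": _write_bursts,
    "PairwiseMatrix": _write_pairwise,
    "PairwiseMatrixStack": _write_pairwise_stack,
    "SliceStack": _write_slice_stack,
    "CouplingResult": _write_coupling,
    "StatePosterior": _write_posterior,
    "DataFrame": _write_frame,
}
_READERS = {
    "SpikeTrainSet": _read_spikes,
    "RateMatrix": _read_rates,
    "BurstSet": _read_bursts,
    "PairwiseMatrix": _read_pairwise,
    "PairwiseMatrixStack": _read_pairwise_stack,
    "SliceStack": _read_slice_stack,
    "CouplingResult": _read_coupling,
    "StatePosterior": _read_posterior,
    "DataFrame": _read_frame,
}


def _type_name(payload) -> str:
    if isinstance(payload, np.ndarray):
        return "ndarray"
    if isinstance(payload, pd.DataFrame):
        return "DataFrame"
    name = type(payload).__name__
    if name in _WRITERS:
        return name
    raise TypeError(f"unsupported payload type: {type(payload)!r}")


def _write_payload(group, payload):
    name = _type_name(payload)
    group.attrs["spikekit_type"] = name
    if name == "ndarray":
        group.create_dataset("values", data=np.asarray(payload))
    else:
        _WRITERS[name](group, payload)


def _read_payload(group):
    name = str(group.attrs["spikekit_type"])
    if name == "ndarray":
        return group["values"][...]
    return _READERS[name](group)


class Workspace:
    """HDF5-backed store of analysis results addressed by (namespace, key)."""

    def __init__(self, path, mode: str = "a"):
        self.path = str(path)
        self._h5 = h5py.File(self.path, mode)

    # -- lifecycle -----------------------------------------------------
    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- core API ------------------------------------------------------
    def store(
        self,
        namespace: str,
        key: str,
        payload,
        annotations: dict | None = None,
        overwrite: bool = False,
    ) -> None:
        ns = self._h5.require_group(namespace)
        if key in ns:
            if not overwrite:
                raise KeyExistsError(
                    f"({namespace}, {key}) already exists; pass overwrite=True to replace"
                )
            del ns[key]
        group = ns.create_group(key)
        group.attrs["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _dump_json(group, "annotations", annotations or {})
        _write_payload(group, payload)
        self._h5.flush()

    def load(self, namespace: str, key: str):
        try:
            group = self._h5[namespace][key]
        except KeyError:
            raise EntryNotFoundError(f"({namespace}, {key}) not found") from None
        return _read_payload(group)

    def annotations(self, namespace: str, key: str) -> dict:
        try:
            group = self._h5[namespace][key]
        except KeyError:
            raise EntryNotFoundError(f"({namespace}, {key}) not found") from None
        return _load_json(group, "annotations", {})

    def __contains__(self, addr) -> bool:
        namespace, key = addr
        return namespace in self._h5 and key in self._h5[namespace]

    def keys(self):
        """All (namespace, key) pairs in the workspace."""
        out = []
        for ns in self._h5:
            for key in self._h5[ns]:
                out.append((ns, key))
        return out

    def cached(self, namespace: str, key: str, compute: Callable, annotations=None):
        """Load the entry if present, else compute, store, and return it."""
        if (namespace, key) in self:
            return self.load(namespace, key)
        result = compute()
        self.store(namespace, key, result, annotations=annotations)
        return result


def ws_merge(a: Workspace, b: Workspace, out_path, on_conflict: str = "error") -> Workspace:
    """Union of two workspaces into a new one at ``out_path``.

    Conflicting (namespace, key) pairs are handled per policy: ``error``
    (raise, naming the key), ``keep_a``, or ``keep_b``.
    """
    if on_conflict not in ("error", "keep_a", "keep_b"):
        raise ValueError("on_conflict must be 'error', 'keep_a' or 'keep_b'")
    out = Workspace(out_path, mode="w")
    keys_a = set(a.keys())
    keys_b = set(b.keys())
    conflicts = keys_a & keys_b
    if conflicts and on_conflict == "error":
        ns, key = sorted(conflicts)[0]
        out.close()
        raise MergeConflictError(f"conflicting entry ({ns}, {key})")
    for ns, key in sorted(keys_a):
        if (ns, key) in conflicts and on_conflict == "keep_b":
            continue
        out.store(ns, key, a.load(ns, key), annotations=a.annotations(ns, key))
    for ns, key in sorted(keys_b):
        if (ns, key) in conflicts and on_conflict == "keep_a":
            continue
        out.store(ns, key, b.load(ns, key), annotations=b.annotations(ns, key))
    return out
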