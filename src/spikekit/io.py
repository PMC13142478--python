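"""Loaders and exporters for spike-train files.

Supported formats: a documented HDF5 schema (the same layout the workspace
uses), CSV spike lists with header ``unit_id,time_ms``, and KiloSort/Phy
output directories (spike sample indices divided by the sorter's sampling
rate).  Times are milliseconds everywhere.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SpikeTrainSet


class SpikeFileError(ValueError):
    """Malformed or incomplete spike data file."""


def save_spikes(s: SpikeTrainSet, path, format: str = None) -> None:
    """Write a SpikeTrainSet to HDF5 or CSV (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        from .workspace import _write_spikes

        with h5py.File(path, "w") as f:
            group = f.create_group("spikes")
            _write_spikes(group, s)
    elif fmt == "csv":
        rows = []
        for uid, t in zip(s.unit_ids, s.trains):
            for v in t:
                rows.append((uid, v))
        df = pd.DataFrame(rows, columns=["unit_id", "time_ms"])
        header = f"# duration_ms={s.duration_ms}\n"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_spikes(path, format: str | None = None, **options) -> SpikeTrainSet:
    """Load a SpikeTrainSet from HDF5, CSV, or a KiloSort/Phy directory.

    Options (phy): ``good_only=True`` keeps only clusters labelled 'good' in
    ``cluster_group.tsv``; ``duration_ms`` overrides the inferred duration.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "phy"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "hdf5"
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv":
        return _load_csv(path, **options)
    if format == "phy":
        return _load_phy(path, **options)
    raise ValueError(f"unknown format {format!r}")


def _load_hdf5(path) -> SpikeTrainSet:
    from .workspace import _read_spikes

    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise SpikeFileError(f"{path}: missing 'spikes' group")
        return _read_spikes(f["spikes"])


def _load_csv(path, duration_ms: float | None = None) -> SpikeTrainSet:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        meta_duration = None
        if first.startswith("#"):
            m = re.search(r"duration_ms=([0-9.eE+-]+)", first)
            if m:
                meta_duration = float(m.group(1))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    for col in ("unit_id", "time_ms"):
        if col not in df.columns:
            raise SpikeFileError(f"{path}: missing column '{col}'")
    if len(df) and not np.issubdtype(df["time_ms"].dtype, np.number):
        raise SpikeFileError(f"{path}: non-numeric values in 'time_ms'")
    duration = duration_ms or meta_duration
    if duration is None:
        duration = float(df["time_ms"].max()) + 1.0 if len(df) else 1000.0
    unit_ids = list(pd.unique(df["unit_id"]))
    trains = [
        np.sort(df.loc[df["unit_id"] == u, "time_ms"].to_numpy(dtype=float))
        for u in unit_ids
    ]
    return SpikeTrainSet(
        unit_ids=unit_ids,
        trains=trains,
        duration_ms=duration,
        recording_meta={"source": str(path), "format": "csv"},
    )


def _phy_sampling_rate(dirpath: Path) -> float:
    params = dirpath / "params.py"
    if not params.exists():
        raise SpikeFileError(f"{dirpath}: params.py with sample_rate is required")
    text = params.read_text(encoding="utf-8")
    m = re.search(r"sample_rate\s*=\s*([0-9.eE+-]+)", text)
    if not m:
        raise SpikeFileError(f"{dirpath}: no sample_rate in params.py")
    return float(m.group(1))


def _load_phy(
    dirpath, good_only: bool = False, duration_ms: float | None = None
) -> SpikeTrainSet:
    dirpath = Path(dirpath)
    fs = _phy_sampling_rate(dirpath)
    try:
        samples = np.load(dirpath / "spike_times.npy").ravel()
        clusters = np.load(dirpath / "spike_clusters.npy").ravel()
    except FileNotFoundError as e:
        raise SpikeFileError(f"{dirpath}: missing {Path(e.filename).name}") from None
    if samples.size != clusters.size:
        raise SpikeFileError(f"{dirpath}: spike_times/spike_clusters length mismatch")
    times_ms = samples.astype(float) / fs * 1000.0
    unit_ids = sorted(np.unique(clusters).tolist())
    if good_only:
        tsv = dirpath / "cluster_group.tsv"
        if tsv.exists():
            labels = pd.read_csv(tsv, sep="\t")
            good = set(labels.loc[labels.iloc[:, 1] == "good", labels.columns[0]])
            unit_ids = [u for u in unit_ids if u in good]
    duration = duration_ms or (float(times_ms.max()) + 1.0 if times_ms.size else 1000.0)
    trains = [np.sort(times_ms[clusters == u]) for u in unit_ids]
    return SpikeTrainSet(
        unit_ids=unit_ids,
        trains=trains,
        duration_ms=duration,
        recording_meta={"source": str(dirpath), "format": "phy", "sample_rate": fs},
    )
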