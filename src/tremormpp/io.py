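"""Plain-text trace and manifest file formats.

One trace file per animal-epoch: two whitespace-delimited columns
(time_s, force) plus a ``.meta`` sidecar of ``key: value`` lines carrying
the trace metadata.  Manifests and MPP tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .signal_model import MotionTrace

_META_KEYS = ("animal_id", "genotype", "drug", "dose", "epoch", "sample_rate_hz", "seed")


def trace_basename(trace: MotionTrace) -> str:
    return f"{trace.animal_id}_{trace.epoch}"


def write_trace(trace: MotionTrace, directory: Path | str) -> Path:
    """Write one trace as <animal>_<epoch>.txt (+ .meta sidecar); returns the data path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / trace_basename(trace)
    t = np.arange(trace.n_samples) / trace.sample_rate_hz
    np.savetxt(
        base.with_suffix(".txt"),
        np.column_stack([t, trace.samples]),
        fmt="%.6f %.10g",
        header="time_s force",
    )
    meta = dict(
        animal_id=trace.animal_id,
        genotype=trace.genotype,
        drug=trace.drug,
        dose=trace.dose,
        epoch=trace.epoch,
        sample_rate_hz=trace.sample_rate_hz,
        seed=trace.seed,
    )
    with open(base.with_suffix(".meta"), "w") as fh:
        for k in _META_KEYS:
            fh.write(f"{k}: {meta[k]}\n")
    return base.with_suffix(".txt")


def read_trace(data_path: Path | str) -> MotionTrace:
    """Read one trace file written by :func:`write_trace` (or hand-made in the same format)."""
    data_path = Path(data_path)
    meta_path = data_path.with_suffix(".meta")
    if not meta_path.exists():
        raise DataError(f"missing sidecar metadata file {meta_path}")
    meta: dict[str, str] = {}
    for line in meta_path.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    arr = np.loadtxt(data_path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError(f"{data_path} is not a two-column (time_s, force) file")
    return MotionTrace(
        sample_rate_hz=float(meta["sample_rate_hz"]),
        samples=arr[:, 1],
        animal_id=meta.get("animal_id", ""),
        genotype=meta.get("genotype", ""),
        drug=meta.get("drug", ""),
        dose=float(meta.get("dose", 0.0)),
        epoch=meta.get("epoch", ""),
        seed=meta.get("seed", ""),
    )


def read_traces_dir(directory: Path | str) -> list[MotionTrace]:
    """Read every *.txt trace (with sidecar) in a directory, sorted by filename."""
    directory = Path(directory)
    return [read_trace(p) for p in sorted(directory.glob("*.txt"))]


def write_manifest(manifest: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)
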