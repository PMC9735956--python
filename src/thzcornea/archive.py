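"""Scan-archive and table I/O.

Primary format is a single HDF5 file:

    /time_ps                      [N] float64
    /reference/trace              [N] float64
    /samples/{id}/frames/{k}/traces   [rows x cols x N] float32
    /samples/{id}/frames/{k}          attrs: t_min, iop_mmHg
    /meta                         JSON string (protocol, seed, config hash)

A plain-directory CSV dialect (one trace per file plus a manifest JSON)
is accepted as an alternative input for small archives; both are read
through the same functions.  Datasets are written with
``track_times=False`` so archives produced from the same seed and
configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FrameRecord",
    "write_archive",
    "write_archive_csvdir",
    "read_meta",
    "read_time_axis",
    "read_reference",
    "sample_ids",
    "iter_frames",
    "write_labels_csv",
    "read_labels_csv",
    "write_table_csv",
    "read_table_csv",
]

_MANIFEST = "manifest.json"


@dataclass
class FrameRecord:
    """One scan frame: the full pixel grid of traces plus annotations."""

    sample_id: str
    frame_index: int
    t_min: float
    iop_mmhg: float
    traces: np.ndarray  # (rows, cols, N)


def _is_csvdir(path) -> bool:
    return Path(path).is_dir()


def write_archive(path, frames: Iterable[FrameRecord], time_ps, reference_trace, meta: dict):
    """Stream frame records into an HDF5 scan archive."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_ps", data=np.asarray(time_ps, float), track_times=False)
        h5.create_dataset(
            "reference/trace", data=np.asarray(reference_trace, float), track_times=False
        )
        h5.create_dataset(
            "meta", data=json.dumps(meta, sort_keys=True), track_times=False
        )
        for fr in frames:
            grp = h5.create_group(f"samples/{fr.sample_id}/frames/{fr.frame_index}")
            grp.attrs["t_min"] = float(fr.t_min)
            grp.attrs["iop_mmHg"] = float(fr.iop_mmhg)
            grp.create_dataset(
                "traces", data=np.asarray(fr.traces, np.float32), track_times=False
            )


def write_archive_csvdir(path, frames: Iterable[FrameRecord], time_ps, reference_trace, meta: dict):
    """Write the plain-directory CSV dialect (one trace per file).

    Intended for small archives and interchange; the HDF5 layout is the
    primary format.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    np.savetxt(root / "time_ps.csv", np.asarray(time_ps, float))
    np.savetxt(root / "reference.csv", np.asarray(reference_trace, float))
    manifest = {"meta": meta, "samples": {}}
    for fr in frames:
        fdir = root / "samples" / fr.sample_id / f"frame{fr.frame_index:04d}"
        fdir.mkdir(parents=True, exist_ok=True)
        rows, cols, _ = fr.traces.shape
        for i in range(rows):
            for j in range(cols):
                np.savetxt(fdir / f"r{i}c{j}.csv", np.asarray(fr.traces[i, j], float))
        manifest["samples"].setdefault(fr.sample_id, []).append(
            {
                "frame_index": int(fr.frame_index),
                "t_min": float(fr.t_min),
                "iop_mmHg": float(fr.iop_mmhg),
                "rows": rows,
                "cols": cols,
                "dir": str(fdir.relative_to(root)),
            }
        )
    with open(root / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)


def read_meta(path) -> dict:
    if _is_csvdir(path):
        with open(Path(path) / _MANIFEST) as fh:
            return json.load(fh)["meta"]
    with h5py.File(path, "r") as h5:
        return json.loads(h5["meta"][()].decode())


def read_time_axis(path) -> np.ndarray:
    if _is_csvdir(path):
        return np.loadtxt(Path(path) / "time_ps.csv")
    with h5py.File(path, "r") as h5:
        return np.asarray(h5["time_ps"])


def read_reference(path) -> np.ndarray:
    if _is_csvdir(path):
        return np.loadtxt(Path(path) / "reference.csv")
    with h5py.File(path, "r") as h5:
        return np.asarray(h5["reference/trace"])


def sample_ids(path) -> list[str]:
    if _is_csvdir(path):
        with open(Path(path) / _MANIFEST) as fh:
            return sorted(json.load(fh)["samples"].keys())
    with h5py.File(path, "r") as h5:
        return sorted(h5["samples"].keys())


def iter_frames(path) -> Iterator[FrameRecord]:
    """Yield frames sample by sample in ascending frame order."""
    if _is_csvdir(path):
        root = Path(path)
        with open(root / _MANIFEST) as fh:
            manifest = json.load(fh)
        for sid in sorted(manifest["samples"]):
            for entry in sorted(manifest["samples"][sid], key=lambda e: e["frame_index"]):
                fdir = root / entry["dir"]
                traces = np.stack(
                    [
                        np.stack(
                            [np.loadtxt(fdir / f"r{i}c{j}.csv") for j in range(entry["cols"])]
                        )
                        for i in range(entry["rows"])
                    ]
                )
                yield FrameRecord(
                    sid, entry["frame_index"], entry["t_min"], entry["iop_mmHg"], traces
                )
        return
    with h5py.File(path, "r") as h5:
        for sid in sorted(h5["samples"].keys()):
            frames = h5[f"samples/{sid}/frames"]
            for k in sorted(frames.keys(), key=int):
                grp = frames[k]
                yield FrameRecord(
                    sid,
                    int(k),
                    float(grp.attrs["t_min"]),
                    float(grp.attrs["iop_mmHg"]),
                    np.asarray(grp["traces"]),
                )


def write_labels_csv(labels: pd.DataFrame, path, config_hash: Optional[str] = None):
    """Write the per-sample label table (sample_id, group_mmHg, ecd_cells_per_mm2)."""
    required = ["sample_id", "group_mmHg", "ecd_cells_per_mm2"]
    missing = [c for c in required if c not in labels.columns]
    if missing:
        raise ValueError(f"labels table missing columns: {missing}")
    write_table_csv(labels[required], path, config_hash=config_hash)


def read_labels_csv(path) -> pd.DataFrame:
    df = read_table_csv(path)
    required = ["sample_id", "group_mmHg", "ecd_cells_per_mm2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"labels CSV {path} missing columns: {missing}")
    return df


def write_table_csv(table: pd.DataFrame, path, config_hash: Optional[str] = None):
    """CSV writer that embeds the run's config hash as a leading comment."""
    with open(path, "w", newline="") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, index=False)


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_config_hash(path) -> Optional[str]:
    """Return the config hash embedded in a CSV written by this package."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        return first.strip().split("=", 1)[1]
    return None
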