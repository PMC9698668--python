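"""Readers, writers and run configuration.

Matrices travel as CSV with a header row and an index column of region
labels; absent entries are empty fields (read back as NaN). Time series are
CSV with the region label in the first column and one sample per remaining
column, or an ``.npz`` container with ``data``, ``fs`` and ``labels`` keys.
Avalanches are JSON-lines, one record per avalanche.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .delays import DelayMatrix, TractLengthMatrix
from .raster import Avalanche, SourceTimeSeries

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries_csv",
    "read_matrix",
    "write_matrix",
    "read_lesion_mask",
    "write_avalanches_jsonl",
    "read_avalanches_jsonl",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; the defaults are the headline settings (z threshold
    3, bin width 3, all avalanches, onset events, bin-resolution delays,
    1000 permutations) and every replication variant (thresholds 2.5/3.5,
    bins 1-5, avalanche-size filters, sample-resolution delays, occupancy
    events, directed matrices) is reachable by configuration alone.

    ``min_avalanche_size`` is counted in bins (the size->duration filter);
    set e.g. 10 or 15 to restrict delay estimation to long avalanches.
    """

    fs: float = 512.0
    threshold: float = 3.0
    bin_width: int = 3
    min_avalanche_size: int | None = None
    event_mode: str = "onset"
    delay_resolution: str = "bin"
    n_perm: int = 1000
    seed: int = 0
    directed: bool = False
    null_pool: str = "all"
    side: str = "greater"
    n_percentile_bins: int = 100
    velocity_threshold: float = 15.0
    target_fs: float | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.threshold <= 0:
            raise ValueError("fs and threshold must be positive")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.event_mode not in ("onset", "occupancy"):
            raise ValueError("event_mode must be 'onset' or 'occupancy'")
        if self.delay_resolution not in ("bin", "sample"):
            raise ValueError("delay_resolution must be 'bin' or 'sample'")
        if self.null_pool not in ("all", "nonlesioned"):
            raise ValueError("null_pool must be 'all' or 'nonlesioned'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def read_timeseries(path: str | Path, fs: float | None = None) -> SourceTimeSeries:
    """Read a regional time series from CSV (first column = region label,
    no header) or from an ``.npz`` container (keys data/fs/labels)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return SourceTimeSeries(
                z["data"], float(z["fs"]), tuple(str(x) for x in z["labels"])
            )
    if fs is None:
        raise ValueError("fs is required for delimited time-series input")
    df = pd.read_csv(path, header=None)
    labels = tuple(str(x) for x in df.iloc[:, 0])
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return SourceTimeSeries(data, fs, labels)


def write_timeseries_csv(ts: SourceTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data)
    df.insert(0, "label", list(ts.region_labels))
    df.to_csv(path, header=False, index=False, float_format="%.5f")


def _read_labelled_square(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    # round_trip parsing keeps write->read bit-identical
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = tuple(str(x) for x in df.columns)
    row_labels = tuple(str(x) for x in df.index)
    if labels != row_labels:
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), labels


def read_matrix(
    path: str | Path, kind: str, labels: Sequence[str] | None = None
):
    """Strictly validated matrix reader.

    ``kind``: 'lengths' (symmetric, positive; returns TractLengthMatrix),
    'lesions' (symmetric 0/1; returns a boolean array + labels), or
    'delays' (positive where present; returns DelayMatrix with counts=1).
    Empty fields / NaN mark absent entries. If ``labels`` is given the file
    labels must match it exactly.
    """
    path = Path(path)
    m, file_labels = _read_labelled_square(path)
    if labels is not None and tuple(labels) != file_labels:
        raise ValueError(
            f"{path}: labels do not match the configured parcellation"
        )
    if kind == "lengths":
        neg = np.argwhere(~np.isnan(m) & (m < 0))
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"{path}: negative length at ({file_labels[i]}, {file_labels[j]})"
            )
        try:
            return TractLengthMatrix(m, file_labels)
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from e
    if kind == "lesions":
        m = np.where(np.isnan(m), 0.0, m)
        bad = np.argwhere(~np.isin(m, (0.0, 1.0)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: lesion value {m[i, j]} at "
                f"({file_labels[i]}, {file_labels[j]}) is not 0/1"
            )
        mask = m.astype(bool)
        if not np.array_equal(mask, mask.T):
            raise ValueError(f"{path}: lesion mask is not symmetric")
        return mask, file_labels
    if kind == "delays":
        counts = (~np.isnan(m)).astype(np.int64)
        np.fill_diagonal(m, np.nan)
        try:
            return DelayMatrix(m, counts, file_labels)
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from e
    raise ValueError("kind must be 'lengths', 'lesions' or 'delays'")


def write_matrix(
    m: np.ndarray, labels: Sequence[str], path: str | Path
) -> None:
    """Write a labelled square matrix; NaN becomes an empty field."""
    pd.DataFrame(np.asarray(m), index=list(labels), columns=list(labels)).to_csv(
        path, na_rep=""
    )


def read_lesion_mask(
    path: str | Path, labels: Sequence[str] | None = None
) -> np.ndarray:
    mask, _ = read_matrix(path, "lesions", labels=labels)
    return mask


def write_avalanches_jsonl(
    avalanches: Sequence[Avalanche],
    labels: Sequence[str],
    path: str | Path,
    subject: str = "",
) -> None:
    labels = list(labels)
    with open(path, "w") as fh:
        for a in avalanches:
            rec = {
                "subject": subject,
                "start_bin": a.start_bin,
                "frames": [sorted(labels[r] for r in f) for f in a.frames],
            }
            fh.write(json.dumps(rec) + "\n")


def read_avalanches_jsonl(
    path: str | Path, labels: Sequence[str]
) -> list[Avalanche]:
    index = {lab: i for i, lab in enumerate(labels)}
    out: list[Avalanche] = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            frames = tuple(
                frozenset(index[lab] for lab in f) for f in rec["frames"]
            )
            out.append(
                Avalanche(
                    start_bin=int(rec["start_bin"]),
                    frames=frames,
                    n_regions=len(labels),
                )
            )
    return out
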