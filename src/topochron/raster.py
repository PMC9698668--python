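"""Discretization of regional time series and neuronal-avalanche statistics.

A continuous source-space recording (regions x samples) is z-scored per
region, thresholded at ``|z| > threshold`` (both polarities count as
activations), and binned. A *neuronal avalanche* is a maximal run of
consecutive non-empty time bins, bounded by bins in which no region is
suprathreshold. The branching parameter sigma — the geometric-mean ratio of
event counts in consecutive bins, geometrically averaged over avalanches —
is used to select the bin width: near-critical dynamics have sigma ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SourceTimeSeries",
    "BinnedRaster",
    "Avalanche",
    "BranchingResult",
    "BranchingUndefinedError",
    "zscore_timeseries",
    "downsample",
    "binarize",
    "bin_raster",
    "segment_avalanches",
    "branching_parameter",
    "cohort_branching",
    "select_bin_width",
]


@dataclass(frozen=True)
class SourceTimeSeries:
    """Regional time series: ``data`` is (n_regions, n_samples), ``fs`` in Hz."""

    data: np.ndarray
    fs: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", tuple(str(l) for l in self.region_labels))
        if data.ndim != 2:
            raise ValueError("data must be 2-D (regions x samples)")
        if data.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be > 0")
        if len(self.region_labels) != data.shape[0]:
            raise ValueError("region_labels length does not match data rows")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region_labels must be unique")
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite values in time series")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BinnedRaster:
    """Boolean activation raster.

    ``occupancy[r, b]`` — region r is suprathreshold somewhere in bin b;
    ``onsets[r, b]`` — bin b is the first bin of a contiguous suprathreshold
    run of region r. ``bin_width`` is in samples of the parent recording.
    """

    occupancy: np.ndarray
    onsets: np.ndarray
    bin_width: int
    fs: float
    threshold: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        ons = np.asarray(self.onsets, dtype=bool)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "onsets", ons)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if occ.shape != ons.shape:
            raise ValueError("occupancy and onsets shapes differ")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if np.any(ons & ~occ):
            raise ValueError("onset without occupancy")

    @property
    def n_regions(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_bins(self) -> int:
        return self.occupancy.shape[1]


@dataclass(frozen=True)
class Avalanche:
    """One avalanche: ``frames[k]`` is the set of region indices recruited
    (event onsets) in the k-th bin after ``start_bin``. In the default onset
    event mode a mid-avalanche frame may be empty (continuing excursions)."""

    start_bin: int
    frames: tuple[frozenset[int], ...]
    n_regions: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(frozenset(f) for f in self.frames))
        if len(self.frames) < 1:
            raise ValueError("avalanche must have at least one frame")
        if not self.frames[0]:
            raise ValueError("first frame of an avalanche cannot be empty")

    @property
    def n_bins(self) -> int:
        return len(self.frames)

    @property
    def n_events_per_bin(self) -> list[int]:
        return [len(f) for f in self.frames]

    @property
    def size(self) -> int:
        """Total number of events (activations) in the avalanche."""
        return sum(len(f) for f in self.frames)

    def recruitment_times(self) -> dict[int, int]:
        """First frame index at which each region appears."""
        t: dict[int, int] = {}
        for k, frame in enumerate(self.frames):
            for r in frame:
                if r not in t:
                    t[r] = k
        return t


@dataclass(frozen=True)
class BranchingResult:
    sigma_per_avalanche: tuple[float, ...]
    sigma: float
    n_avalanches_used: int


class BranchingUndefinedError(ValueError):
    """sigma_i is undefined (single-bin avalanche or a zero event count)."""


def zscore_timeseries(ts: SourceTimeSeries) -> SourceTimeSeries:
    """Z-score each region over the full segment (population denominator).

    Raises ValueError naming the region if any region has zero variance
    (a flat or dead channel).
    """
    mean = ts.data.mean(axis=1, keepdims=True)
    std = ts.data.std(axis=1, keepdims=True)  # ddof=0
    dead = np.flatnonzero(std[:, 0] == 0)
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead)
        raise ValueError(f"zero variance region(s): {names}")
    return SourceTimeSeries((ts.data - mean) / std, ts.fs, ts.region_labels)


def downsample(ts: SourceTimeSeries, target_fs: float) -> SourceTimeSeries:
    """Integer decimation (keep every k-th sample).

    Anti-alias filtering is assumed to have happened upstream. Non-integer
    fs/target_fs ratios are rejected.
    """
    if target_fs > ts.fs:
        raise ValueError("target_fs must not exceed fs")
    ratio = ts.fs / target_fs
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9:
        raise ValueError(
            f"fs={ts.fs} is not an integer multiple of target_fs={target_fs}; "
            "resample upstream before ingestion"
        )
    if k == 1:
        return ts
    n_out = ts.n_samples // k
    return SourceTimeSeries(ts.data[:, ::k][:, :n_out], target_fs, ts.region_labels)


def _onsets_from_occupancy(occ: np.ndarray) -> np.ndarray:
    """First bin of each contiguous True run, per row."""
    prev = np.zeros_like(occ)
    prev[:, 1:] = occ[:, :-1]
    return occ & ~prev


def binarize(ts: SourceTimeSeries, threshold: float = 3.0) -> BinnedRaster:
    """Threshold a z-scored series at strict ``|z| > threshold``.

    Positive and negative excursions both count. Returns a bin_width=1
    raster; onsets mark the first sample of each contiguous excursion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    occ = np.abs(ts.data) > threshold
    return BinnedRaster(
        occupancy=occ,
        onsets=_onsets_from_occupancy(occ),
        bin_width=1,
        fs=ts.fs,
        threshold=threshold,
        region_labels=ts.region_labels,
    )


def bin_raster(r: BinnedRaster, bin_width: int) -> BinnedRaster:
    """OR-reduce a sample-resolution raster into bins of ``bin_width`` samples.

    The trailing partial bin is dropped; onsets are recomputed on the binned
    occupancy (first bin of each binned run).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if r.bin_width != 1:
        raise ValueError("bin_raster expects a sample-resolution (bin_width=1) raster")
    if bin_width == 1:
        return r
    n = (r.n_bins // bin_width) * bin_width
    occ = r.occupancy[:, :n].reshape(r.n_regions, -1, bin_width).any(axis=2)
    return BinnedRaster(
        occupancy=occ,
        onsets=_onsets_from_occupancy(occ),
        bin_width=bin_width,
        fs=r.fs,
        threshold=r.threshold,
        region_labels=r.region_labels,
    )


def segment_avalanches(r: BinnedRaster, event_mode: str = "onset") -> list[Avalanche]:
    """Cut the raster into avalanches: maximal runs of non-empty bins.

    An avalanche begins when at least one region is suprathreshold and ends
    when all regions are below threshold (an empty bin). Runs touching the
    first or last bin of the recording are discarded — their true start or
    end is unobservable. ``frames`` record, per bin, the regions whose event
    falls there: excursion onsets by default (``event_mode="onset"``), or
    every occupied bin (``event_mode="occupancy"``).
    """
    if event_mode not in ("onset", "occupancy"):
        raise ValueError("event_mode must be 'onset' or 'occupancy'")
    active = r.occupancy.any(axis=0)
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    events = r.onsets if event_mode == "onset" else r.occupancy
    out: list[Avalanche] = []
    for s, e in zip(starts, ends):
        if s == 0 or e == r.n_bins:
            continue  # truncated by the recording boundary
        frames = [frozenset(np.flatnonzero(events[:, b])) for b in range(s, e)]
        if not frames[0]:
            # onset mode: run starts with occupancy carried in from ... cannot
            # happen for interior runs (an empty bin precedes s), kept as guard
            frames[0] = frozenset(np.flatnonzero(r.occupancy[:, s]))
        out.append(Avalanche(start_bin=int(s), frames=tuple(frames), n_regions=r.n_regions))
    return out


def branching_parameter(a: Avalanche) -> float:
    """sigma_i: geometric mean of descendant/ancestor event-count ratios.

    The product over consecutive-bin ratios telescopes, so
    sigma_i = (n_last / n_first) ** (1 / (Nbin - 1)). Undefined for
    single-bin avalanches and whenever a bin has zero events.
    """
    counts = a.n_events_per_bin
    if a.n_bins < 2:
        raise BranchingUndefinedError("sigma undefined for a single-bin avalanche")
    if any(c == 0 for c in counts):
        raise BranchingUndefinedError("sigma undefined: a bin with zero events")
    log_ratios = np.diff(np.log(np.asarray(counts, dtype=float)))
    return float(np.exp(log_ratios.mean()))


def cohort_branching(avalanches: Sequence[Avalanche]) -> BranchingResult:
    """sigma: geometric mean of sigma_i over all eligible avalanches.

    Avalanches for which sigma_i is undefined (single-bin, zero-event bins)
    are excluded; the number actually used is reported.
    """
    sigmas: list[float] = []
    for a in avalanches:
        try:
            sigmas.append(branching_parameter(a))
        except BranchingUndefinedError:
            continue
    if not sigmas:
        raise ValueError("no avalanche with a defined branching parameter")
    sigma = float(np.exp(np.mean(np.log(sigmas))))
    return BranchingResult(tuple(sigmas), sigma, len(sigmas))


def select_bin_width(
    ts: SourceTimeSeries,
    candidates: Sequence[int] = (1, 2, 3, 4, 5),
    threshold: float = 3.0,
    event_mode: str = "onset",
) -> tuple[int, dict[int, float]]:
    """Pick the bin width whose cohort sigma is closest to 1.

    The series is z-scored and thresholded once; each candidate width is
    binned, segmented and scored. Ties break toward the smaller width.
    Returns ``(best_width, {width: sigma})``.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    base = binarize(zscore_timeseries(ts), threshold)
    table: dict[int, float] = {}
    for w in sorted(set(int(c) for c in candidates)):
        avalanches = segment_avalanches(bin_raster(base, w), event_mode=event_mode)
        table[w] = cohort_branching(avalanches).sigma
    best = min(table, key=lambda w: (abs(table[w] - 1.0), w))
    return best, table
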