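"""Recruitment delays, delay/velocity matrices and length-percentile profiles.

Within an avalanche, the delay from region i to region j is the time between
their first activations. Per-avalanche delay matrices are sparse; subject
matrices average them entrywise over the avalanches in which the ordered
pair was observed (absent entries are never treated as zero), and group
matrices average subject matrices the same way. Dividing tract lengths (mm)
by delays (s) on structurally connected pairs gives conduction velocities
(m/s) — the "topochronic map".

Units are fixed package-wide: lengths mm, delays s, velocities m/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import Avalanche, BinnedRaster

__all__ = [
    "TractLengthMatrix",
    "DelayMatrix",
    "VelocityMatrix",
    "PercentileProfile",
    "avalanche_delays",
    "accumulate_delays",
    "subject_delay_matrix",
    "group_delay_matrix",
    "symmetrize_delays",
    "complete_coverage_edges",
    "velocity_matrix",
    "percentile_profile",
    "constant_velocity_expectation",
    "fast_edge_subgraph",
]

MM_PER_M = 1000.0


def _check_labels(a: Sequence[str], b: Sequence[str]) -> None:
    if tuple(a) != tuple(b):
        raise ValueError("region labels are not aligned")


@dataclass(frozen=True)
class TractLengthMatrix:
    """Symmetric streamline lengths in mm; NaN marks absent tracts."""

    lengths: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        L = np.array(self.lengths, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("lengths must be square")
        if len(self.labels) != L.shape[0]:
            raise ValueError("labels length mismatch")
        np.fill_diagonal(L, np.nan)  # self-tracts are meaningless
        L[L == 0] = np.nan  # zero encodes "no tract"
        present = ~np.isnan(L)
        if not np.array_equal(present, present.T) or not np.allclose(
            L[present], L.T[present], rtol=0, atol=1e-9, equal_nan=True
        ):
            raise ValueError("length matrix is not symmetric")
        if np.any(L[present] <= 0):
            raise ValueError("present tract lengths must be strictly positive")
        L.setflags(write=False)
        object.__setattr__(self, "lengths", L)

    @property
    def n_regions(self) -> int:
        return self.lengths.shape[0]

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.lengths)


@dataclass(frozen=True)
class DelayMatrix:
    """Mean recruitment delays in seconds with per-entry contribution counts.

    ``mean_delay`` is NaN exactly where ``counts`` is 0 — absence is never
    silently zero. Counts are contributing avalanches (subject level) or
    contributing subjects (group level).
    """

    mean_delay: np.ndarray
    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.array(self.mean_delay, dtype=float)
        c = np.array(self.counts, dtype=np.int64)
        object.__setattr__(self, "labels", tuple(self.labels))
        if d.shape != c.shape or d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("mean_delay and counts must be matching square matrices")
        if len(self.labels) != d.shape[0]:
            raise ValueError("labels length mismatch")
        np.fill_diagonal(d, np.nan)
        np.fill_diagonal(c, 0)
        present = ~np.isnan(d)
        if not np.array_equal(present, c > 0):
            raise ValueError("mean_delay present iff counts > 0 violated")
        if np.any(d[present] <= 0):
            raise ValueError("present delays must be strictly positive")
        d.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "mean_delay", d)
        object.__setattr__(self, "counts", c)

    @property
    def n_regions(self) -> int:
        return self.mean_delay.shape[0]

    @property
    def present(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class VelocityMatrix:
    """Conduction velocities in m/s, present only where a structural tract
    and a delay estimate coexist."""

    velocity: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.array(self.velocity, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("velocity must be square")
        present = ~np.isnan(v)
        if np.any(v[present] <= 0):
            raise ValueError("present velocities must be strictly positive")
        v.setflags(write=False)
        object.__setattr__(self, "velocity", v)

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.velocity)


@dataclass(frozen=True)
class PercentileProfile:
    """Edge values averaged within equal-count tract-length bins."""

    percentile_edges: np.ndarray  # length boundaries, len n_bins + 1
    mean_value_per_bin: np.ndarray
    n_bins: int


def avalanche_delays(
    a: Avalanche, bin_width: int, fs: float
) -> dict[tuple[int, int], float]:
    """Directed recruitment delays of one avalanche, in seconds.

    Each region's recruitment time is the index of the first frame containing
    it (later re-activations are ignored). For every ordered pair (i, j) with
    t_j > t_i the delay (t_j - t_i) * bin_width / fs is emitted; simultaneous
    recruitment emits nothing.
    """
    t = a.recruitment_times()
    scale = bin_width / fs
    out: dict[tuple[int, int], float] = {}
    for i, ti in t.items():
        for j, tj in t.items():
            if tj > ti:
                out[(i, j)] = (tj - ti) * scale
    return out


def accumulate_delays(
    avalanches: Iterable[Avalanche],
    n_regions: int,
    bin_width: int,
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sum/count accumulation of directed delays over avalanches.

    Returns (sums, counts) as (n_regions, n_regions) arrays, delays in
    seconds. This is the fast path behind subject matrices and surrogates.
    """
    sums = np.zeros((n_regions, n_regions))
    counts = np.zeros((n_regions, n_regions), dtype=np.int64)
    scale = bin_width / fs
    for a in avalanches:
        t = a.recruitment_times()
        if len(t) < 2:
            continue
        idx = np.fromiter(t.keys(), dtype=np.intp, count=len(t))
        tt = np.fromiter(t.values(), dtype=float, count=len(t))
        diff = tt[None, :] - tt[:, None]  # diff[i, j] = t_j - t_i
        mask = diff > 0
        ii, jj = np.nonzero(mask)
        np.add.at(sums, (idx[ii], idx[jj]), diff[mask] * scale)
        np.add.at(counts, (idx[ii], idx[jj]), 1)
    return sums, counts


def subject_delay_matrix(
    avalanches: Sequence[Avalanche],
    labels: Sequence[str],
    bin_width: int,
    fs: float,
) -> DelayMatrix:
    """Average per-avalanche delay matrices entrywise, disregarding absences.

    An ordered pair's mean is taken only over the avalanches in which it was
    observed; pairs never observed stay absent (NaN), never zero.
    """
    if not avalanches:
        raise ValueError("need at least one avalanche")
    n = len(labels)
    sums, counts = accumulate_delays(avalanches, n, bin_width, fs)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DelayMatrix(mean, counts, tuple(labels))


def group_delay_matrix(subjects: Sequence[DelayMatrix]) -> DelayMatrix:
    """Entrywise mean over subjects with a present estimate (absences
    discarded); counts record the number of contributing subjects."""
    if not subjects:
        raise ValueError("need at least one subject")
    labels = subjects[0].labels
    n = subjects[0].n_regions
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for s in subjects:
        _check_labels(s.labels, labels)
        p = s.present
        sums[p] += s.mean_delay[p]
        counts += p
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DelayMatrix(mean, counts, labels)


def symmetrize_delays(d: DelayMatrix) -> DelayMatrix:
    """Count-weighted mean of the two directions of each pair.

    Tract lengths are symmetric, so velocities are computed on symmetrized
    delays by default; the directed matrices remain available upstream.
    """
    sums = np.where(d.present, d.mean_delay * d.counts, 0.0)
    tot = sums + sums.T
    cnt = d.counts + d.counts.T
    mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return DelayMatrix(mean, cnt, d.labels)


def complete_coverage_edges(
    controls: Sequence[DelayMatrix], directed: bool = False
) -> list[tuple[int, int]]:
    """Edges with a delay estimate in *every* control subject.

    With ``directed=False`` (default) each control is symmetrized first and
    undirected edges (i < j) are returned; otherwise ordered pairs.
    """
    if not controls:
        raise ValueError("need at least one control")
    labels = controls[0].labels
    mats = controls if directed else [symmetrize_delays(c) for c in controls]
    common = np.ones((len(labels), len(labels)), dtype=bool)
    for m in mats:
        _check_labels(m.labels, labels)
        common &= m.present
    if not directed:
        common &= np.triu(np.ones_like(common), k=1)
    ii, jj = np.nonzero(common)
    return [(int(i), int(j)) for i, j in zip(ii, jj)]


def velocity_matrix(
    d: DelayMatrix, L: TractLengthMatrix, directed: bool = False
) -> VelocityMatrix:
    """v_ij = (L_ij / 1000) / delay_ij, only where a direct structural
    connection and a delay estimate are both present."""
    _check_labels(d.labels, L.labels)
    dm = d if directed else symmetrize_delays(d)
    both = dm.present & L.present
    v = np.full_like(L.lengths, np.nan)
    v[both] = (L.lengths[both] / MM_PER_M) / dm.mean_delay[both]
    return VelocityMatrix(v, L.labels)


def _paired_edges(
    values: DelayMatrix | VelocityMatrix, L: TractLengthMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (length, value) pairs present in both matrices.

    DelayMatrix inputs are symmetrized so that each undirected edge
    contributes once.
    """
    _check_labels(values.labels, L.labels)
    if isinstance(values, DelayMatrix):
        vm = symmetrize_delays(values).mean_delay
    else:
        vm = values.velocity
    mask = ~np.isnan(vm) & L.present & np.triu(np.ones_like(L.present), k=1)
    return L.lengths[mask], vm[mask]


def percentile_profile(
    values: DelayMatrix | VelocityMatrix,
    L: TractLengthMatrix,
    n_bins: int = 100,
) -> PercentileProfile:
    """Average edge values within equal-count percentile bins of tract length.

    Edges are ranked by length and split into ``n_bins`` near-equal chunks;
    the mean of the value over each chunk is returned together with the
    length boundaries.
    """
    lengths, vals = _paired_edges(values, L)
    if lengths.size < n_bins:
        raise ValueError(
            f"only {lengths.size} edges for {n_bins} bins; use a smaller n_bins"
        )
    order = np.argsort(lengths, kind="stable")
    chunks = np.array_split(order, n_bins)
    means = np.array([vals[c].mean() for c in chunks])
    edges = np.array(
        [lengths[chunks[0]].min()] + [lengths[c].max() for c in chunks]
    )
    return PercentileProfile(edges, means, n_bins)


def constant_velocity_expectation(
    L: TractLengthMatrix, v: float
) -> DelayMatrix:
    """Delays expected if conduction velocity were homogeneous at v m/s."""
    if v <= 0:
        raise ValueError("velocity must be > 0")
    d = (L.lengths / MM_PER_M) / v
    return DelayMatrix(d, L.present.astype(np.int64), L.labels)


def fast_edge_subgraph(
    V: VelocityMatrix,
    threshold: float = 15.0,
    hemisphere_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Undirected edges faster than ``threshold`` m/s, hemisphere-tagged.

    Returns a DataFrame (region_a, region_b, velocity, hemisphere_tag) with
    tag 'iso' or 'cross' from the region->hemisphere map; untagged (with a
    warning) if no map is given. Default 15 m/s mirrors the glass-brain
    display rule for the fastest tracts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if hemisphere_map is None:
        warnings.warn("no hemisphere map: edges returned untagged", stacklevel=2)
    mask = V.present & (V.velocity > threshold) & np.triu(
        np.ones_like(V.present), k=1
    )
    rows = []
    for i, j in zip(*np.nonzero(mask)):
        la, lb = V.labels[i], V.labels[j]
        if hemisphere_map is None:
            tag = ""
        else:
            tag = "iso" if hemisphere_map[la] == hemisphere_map[lb] else "cross"
        rows.append((la, lb, float(V.velocity[i, j]), tag))
    return pd.DataFrame(
        rows, columns=["region_a", "region_b", "velocity", "hemisphere_tag"]
    )
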