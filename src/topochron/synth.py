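"""Ground-truthed synthetic cohorts for the topochronic pipeline.

The generator states a world with the qualitative features the estimation
pipeline is built for: a connected structural connectome whose tract
lengths follow a fat-tailed (log-normal) distribution; per-edge conduction
velocities growing with tract length as v = a * L**b (b = 0 is the
homogeneous-velocity null, b = 1 the homogeneous-delay regime); rare
intermittent cascades that spread along structural edges with a fixed
transmission probability per edge; and "patients" whose lesioned edges are
slowed by a multiplicative factor.

Cascades use first-arrival semantics: each region is recruited at most once,
by whichever neighbor reaches it first, mirroring the single-onset delay
definition of the estimation side. Cascade recruitment times are therefore
shortest-arrival times through the delayed network, not necessarily the
direct-edge delays — the network effect the estimation inherits.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .delays import TractLengthMatrix, MM_PER_M
from .raster import Avalanche, SourceTimeSeries

__all__ = [
    "CascadeParams",
    "GroundTruth",
    "SubjectData",
    "CohortBundle",
    "synth_connectome",
    "critical_transmission_p",
    "assign_velocities",
    "simulate_cascades",
    "synthesize_timeseries",
    "apply_lesions",
    "make_cohort",
]


@dataclass(frozen=True)
class CascadeParams:
    """Knobs of the synthetic world. Defaults state a 60-region connectome
    of tractography-like sparsity (density 0.12, mean degree ~7) with
    log-normal tract lengths (median ~60 mm), velocities ~2-30 m/s rising
    with length (b = 0.8), a 512 Hz recording, and rare small cascades
    (``transmission_p`` ~ 0.4 / mean degree, branching ratio R0 ~ 0.4).

    The sub-critical default matters: the delay estimator attributes
    co-activation lags to region pairs, so it reads out true per-edge
    conduction delays only when co-recruitment is dominated by direct
    single-hop transmission. Larger, near-critical cascades pool in
    common-source and multi-hop lags, which are nearly length-independent
    and flatten the recovered delay-length relation (see docs/methods.md).

    ``bin_width`` is the simulation time step in samples: 1 by default so
    that ground-truth delays of a few milliseconds stay representable
    (at 512 Hz a width-3 bin is 5.9 ms, coarser than most edge delays).
    """

    n_regions: int = 60
    edge_density: float = 0.12
    length_median_mm: float = 60.0
    length_sigma: float = 0.55
    min_length_mm: float = 3.0
    velocity_a: float = 0.3
    velocity_b: float = 0.8
    transmission_p: float = 0.057
    n_avalanches: int = 200
    fs: float = 512.0
    bin_width: int = 1
    noise_sd: float = 1.0
    pulse_amplitude: float = 12.0
    gap_bins: int = 10
    horizon_bins: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.transmission_p <= 1:
            raise ValueError("transmission_p must be in (0, 1]")
        if self.velocity_a <= 0 or self.velocity_b < 0:
            raise ValueError("velocity law requires a > 0 and b >= 0")
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if self.n_avalanches < 1 or self.fs <= 0 or self.bin_width < 1:
            raise ValueError("counts, fs and bin_width must be positive")
        if self.gap_bins < 2:
            raise ValueError("gap_bins must be >= 2 to separate avalanches")


@dataclass(frozen=True)
class GroundTruth:
    """The stated world: structural lengths, per-edge velocities and delays
    (delay * velocity = length / 1000 where present), hemisphere labels, and
    — for patients — the lesion mask and its delay slowdown factor."""

    lengths: TractLengthMatrix
    velocity_gt: np.ndarray  # m/s, NaN off-tract
    delay_gt: np.ndarray  # s, NaN off-tract
    hemisphere_map: dict[str, str]
    lesion_mask: np.ndarray | None = None
    slowdown: float = 1.0

    @property
    def labels(self) -> tuple[str, ...]:
        return self.lengths.labels

    @property
    def present(self) -> np.ndarray:
        return self.lengths.present


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    group: str  # "control" | "patient"
    timeseries: SourceTimeSeries
    avalanches: tuple[Avalanche, ...]
    ground_truth: GroundTruth  # lesioned variant for patients
    seed: int


@dataclass(frozen=True)
class CohortBundle:
    params: CascadeParams
    ground_truth: GroundTruth  # healthy (control) world
    subjects: tuple[SubjectData, ...]

    @property
    def controls(self) -> list[SubjectData]:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def patients(self) -> list[SubjectData]:
        return [s for s in self.subjects if s.group == "patient"]


def _region_labels(n: int) -> tuple[str, ...]:
    half = n // 2
    return tuple(
        f"L{i:02d}" if i < half else f"R{i - half:02d}" for i in range(n)
    )


def assign_velocities(
    lengths: TractLengthMatrix, a: float, b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity law v = a * L**b (L in mm, v in m/s) and the implied delays.

    b = 0 gives the constant-velocity null; b = 1 makes every ground-truth
    delay equal to 1/(1000 a) s (the homogeneous-delay regime).
    """
    if a <= 0 or b < 0:
        raise ValueError("require a > 0 and b >= 0")
    L = lengths.lengths
    with np.errstate(invalid="ignore"):
        v = a * L**b
        d = (L / MM_PER_M) / v
    return v, d


def synth_connectome(params: CascadeParams) -> GroundTruth:
    """Draw a connected symmetric connectome with log-normal tract lengths.

    Hemispheres are assigned half/half by region order. Disconnected draws
    are retried with an incremented sub-seed (bounded), then rejected.
    """
    n = params.n_regions
    labels = _region_labels(n)
    for attempt in range(64):
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 17, attempt])
        )
        upper = np.triu(rng.random((n, n)) < params.edge_density, k=1)
        adj = upper | upper.T
        if nx.is_connected(nx.from_numpy_array(adj)):
            break
    else:
        raise RuntimeError(
            "could not draw a connected connectome; increase edge_density"
        )
    raw = rng.lognormal(
        mean=np.log(params.length_median_mm), sigma=params.length_sigma, size=(n, n)
    )
    raw = np.maximum(np.triu(raw, k=1), params.min_length_mm)
    Lm = np.where(upper, raw, np.nan)
    Lm = np.where(np.isnan(Lm.T), Lm, Lm.T)  # symmetrize the upper draw
    lengths = TractLengthMatrix(Lm, labels)
    v, d = assign_velocities(lengths, params.velocity_a, params.velocity_b)
    hemis = {lab: ("L" if lab.startswith("L") else "R") for lab in labels}
    return GroundTruth(lengths, v, d, hemis)


def apply_lesions(
    gt: GroundTruth, fraction: float, slowdown: float, seed: int
) -> GroundTruth:
    """Flag a random fraction of structural edges as lesioned and multiply
    their ground-truth delays (not lengths) by ``slowdown``."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if slowdown <= 1:
        raise ValueError("slowdown must be > 1")
    rng = np.random.default_rng(seed)
    triu = np.triu(gt.present, k=1)
    ii, jj = np.nonzero(triu)
    k = int(round(fraction * ii.size))
    pick = rng.choice(ii.size, size=k, replace=False)
    mask = np.zeros_like(triu)
    mask[ii[pick], jj[pick]] = True
    mask |= mask.T
    delay = gt.delay_gt.copy()
    delay[mask] *= slowdown
    with np.errstate(invalid="ignore"):
        velocity = (gt.lengths.lengths / MM_PER_M) / delay
    return GroundTruth(
        gt.lengths, velocity, delay, gt.hemisphere_map, mask, slowdown
    )


def critical_transmission_p(gt: GroundTruth) -> float:
    """Transmission probability putting the cascade branching ratio near 1:
    p_t = 1 / mean structural degree (R0 = p_t * mean degree)."""
    deg = gt.present.sum(axis=0)
    return float(1.0 / deg.mean())


def _delay_bins(gt: GroundTruth, params: CascadeParams) -> np.ndarray:
    """Per-edge transmission delay in simulation bins (rounded)."""
    db = np.rint(gt.delay_gt * params.fs / params.bin_width)
    bad = gt.present & (db < 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"edge ({gt.labels[i]}, {gt.labels[j]}) rounds to a zero-bin delay; "
            "use a finer fs/bin_width or larger delays"
        )
    return np.where(gt.present, db, 0).astype(np.int64)


def simulate_cascades(
    gt: GroundTruth,
    params: CascadeParams,
    n_cascades: int | None = None,
    seed: int | None = None,
) -> list[Avalanche]:
    """Simulate avalanche-like cascades on the delayed connectome.

    Each cascade starts at a uniformly random seed region at bin 0. When a
    region is recruited at bin t it attempts, independently with probability
    ``transmission_p`` per structural edge, to recruit each neighbor at
    t + (rounded edge delay in bins); the earliest successful arrival wins
    and regions are recruited at most once. Cascades whose span would exceed
    ``horizon_bins`` are discarded and redrawn (bounded retries).
    """
    n_casc = params.n_avalanches if n_cascades is None else n_cascades
    rng = np.random.default_rng(params.seed if seed is None else seed)
    db = _delay_bins(gt, params)
    n = params.n_regions
    neighbors = [np.flatnonzero(gt.present[u]) for u in range(n)]
    out: list[Avalanche] = []
    attempts = 0
    while len(out) < n_casc:
        attempts += 1
        if attempts > 20 * n_casc:
            raise RuntimeError("too many cascades exceeded the horizon")
        seed_region = int(rng.integers(n))
        arrival: dict[int, int] = {}
        heap: list[tuple[int, int]] = [(0, seed_region)]
        overran = False
        while heap:
            t, u = heapq.heappop(heap)
            if u in arrival:
                continue
            if t > params.horizon_bins:
                overran = True
                break
            arrival[u] = t
            nbrs = neighbors[u]
            hit = nbrs[rng.random(nbrs.size) < params.transmission_p]
            for w in hit:
                if int(w) not in arrival:
                    heapq.heappush(heap, (t + int(db[u, w]), int(w)))
        if overran:
            continue
        t_max = max(arrival.values())
        frames = [set() for _ in range(t_max + 1)]
        for r, t in arrival.items():
            frames[t].add(r)
        out.append(
            Avalanche(
                start_bin=0,
                frames=tuple(frozenset(f) for f in frames),
                n_regions=n,
            )
        )
    return out


def synthesize_timeseries(
    avalanches: Sequence[Avalanche],
    params: CascadeParams,
    seed: int | None = None,
) -> SourceTimeSeries:
    """Continuous time series whose suprathreshold excursions reproduce the
    cascades exactly.

    Background noise is a clipped (+-2.5 SD) Gaussian, so after z-scoring no
    noise sample can cross a |z| > 3 threshold — detected excursions are
    cascade pulses and nothing else. Each recruited region's excursion
    starts at its recruitment sample and is sustained until the cascade's
    *next* recruitment bin, which keeps the avalanche's bin span gap-free
    (one onset per region, single-recruitment semantics) while keeping the
    per-region duty cycle low. Cascades are laid out sequentially with
    >= ``gap_bins`` empty bins between them and at both boundaries, and the
    recording is padded with quiet bins so that no region is suprathreshold
    in more than ~4% of samples — beyond a ~10% duty cycle, z-scoring
    inflates the per-region SD enough that no amplitude can clear |z| > 3.
    """
    if params.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    w = params.bin_width
    # layout: (region, absolute start bin, absolute end bin) excursions
    excursions: list[tuple[int, int, int]] = []
    active_bins = np.zeros(params.n_regions, dtype=np.int64)
    cursor = params.gap_bins
    for a in avalanches:
        times = a.recruitment_times()
        distinct = sorted(set(times.values()))
        nxt = {t: distinct[k + 1] if k + 1 < len(distinct) else t + 1
               for k, t in enumerate(distinct)}
        for r, t in times.items():
            b0, b1 = cursor + t, cursor + nxt[t]
            excursions.append((r, b0, b1))
            active_bins[r] += b1 - b0
        cursor += a.n_bins + params.gap_bins
    max_duty = 0.04
    total_bins = max(cursor + 1, int(np.ceil(active_bins.max(initial=0) / max_duty)))
    n_samples = total_bins * w
    rng = np.random.default_rng(params.seed if seed is None else seed)
    data = rng.normal(0.0, params.noise_sd, size=(params.n_regions, n_samples))
    np.clip(data, -2.5 * params.noise_sd, 2.5 * params.noise_sd, out=data)
    amp = params.pulse_amplitude
    for r, b0, b1 in excursions:
        data[r, b0 * w : b1 * w] = amp
    labels = _region_labels(params.n_regions)
    return SourceTimeSeries(data, params.fs, labels)


def make_cohort(
    params: CascadeParams,
    n_controls: int,
    n_patients: int = 0,
    lesion_fraction: float = 0.2,
    lesion_slowdown: float = 1.5,
    out_dir: str | Path | None = None,
) -> CohortBundle:
    """Generate a full cohort on one shared connectome.

    Controls share the healthy ground truth; each patient gets an
    independent lesion mask (same fraction and slowdown) applied to the
    shared connectome. Every subject is an independent cascade realization
    with its own derived seed; the bundle is byte-reproducible from
    ``params.seed``. If ``out_dir`` is given the on-disk layout consumed by
    the CLI (manifest.csv, lengths.csv, per-subject time series and lesion
    masks, ground_truth.json) is written.
    """
    if n_controls < 1 or n_patients < 0:
        raise ValueError("need at least one control")
    gt = synth_connectome(params)
    ss = np.random.SeedSequence([params.seed, 1001])
    child = ss.spawn(n_controls + 2 * n_patients)
    subjects: list[SubjectData] = []
    for c in range(n_controls):
        sub_seed = int(child[c].generate_state(1)[0] % (2**31))
        av = simulate_cascades(gt, params, seed=sub_seed)
        ts = synthesize_timeseries(av, params, seed=sub_seed + 1)
        subjects.append(
            SubjectData(f"C{c:02d}", "control", ts, tuple(av), gt, sub_seed)
        )
    for p in range(n_patients):
        mseed = int(child[n_controls + 2 * p].generate_state(1)[0] % (2**31))
        sub_seed = int(
            child[n_controls + 2 * p + 1].generate_state(1)[0] % (2**31)
        )
        pgt = apply_lesions(gt, lesion_fraction, lesion_slowdown, mseed)
        av = simulate_cascades(pgt, params, seed=sub_seed)
        ts = synthesize_timeseries(av, params, seed=sub_seed + 1)
        subjects.append(
            SubjectData(f"P{p:02d}", "patient", ts, tuple(av), pgt, sub_seed)
        )
    bundle = CohortBundle(params, gt, tuple(subjects))
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: CohortBundle, out_dir: Path) -> None:
    from . import io as tio  # local import to avoid a cycle

    out_dir.mkdir(parents=True, exist_ok=True)
    gt = bundle.ground_truth
    tio.write_matrix(gt.lengths.lengths, gt.labels, out_dir / "lengths.csv")
    rows = []
    for s in bundle.subjects:
        ts_path = out_dir / f"timeseries_{s.subject_id}.csv"
        tio.write_timeseries_csv(s.timeseries, ts_path)
        lesion_path = ""
        if s.group == "patient" and s.ground_truth.lesion_mask is not None:
            lesion_path = f"lesions_{s.subject_id}.csv"
            tio.write_matrix(
                s.ground_truth.lesion_mask.astype(int),
                gt.labels,
                out_dir / lesion_path,
            )
        rows.append(
            {
                "subject": s.subject_id,
                "group": s.group,
                "timeseries": ts_path.name,
                "lengths": "lengths.csv",
                "lesions": lesion_path,
                "seed": s.seed,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    truth = {
        "labels": list(gt.labels),
        "hemisphere_map": gt.hemisphere_map,
        "velocity_gt": _matrix_to_json(gt.velocity_gt),
        "delay_gt": _matrix_to_json(gt.delay_gt),
        "params": {
            k: (v if not isinstance(v, (np.integer, np.floating)) else v.item())
            for k, v in vars(bundle.params).items()
        },
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))


def _matrix_to_json(m: np.ndarray) -> list[list[float | None]]:
    return [[None if np.isnan(x) else float(x) for x in row] for row in m]
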