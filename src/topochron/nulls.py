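"""Surrogate nulls and permutation statistics for topochronic maps.

Time-shuffled surrogates permute the frame order of each avalanche while
leaving every frame's recruited-region set intact: the spatial structure of
recruitment survives, the temporal structure is destroyed. Recomputing
delay matrices on the shuffled avalanches yields per-edge surrogate delay
distributions against which the observed length-delay coupling is tested.
Group differences use the two-sample Kolmogorov-Smirnov test; the effect of
structural lesions is assessed with a subset-resampling permutation test on
edgewise patient-minus-control delay differences.

All empirical p-values use the add-one (permutation-inclusive) estimator
p = (1 + #{null at least as extreme}) / (1 + n_perm), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .delays import (
    DelayMatrix,
    TractLengthMatrix,
    _check_labels,
    symmetrize_delays,
)
from .raster import Avalanche

__all__ = [
    "SurrogateEnsemble",
    "KSResult",
    "LesionTestResult",
    "ConvergenceResult",
    "shuffle_avalanche",
    "surrogate_delay_ensemble",
    "length_delay_correlation",
    "correlation_null_test",
    "ks_compare_groups",
    "edgewise_differences",
    "lesion_permutation_test",
    "convergence_curve",
]


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Per-permutation surrogate mean-delay matrices.

    ``delays`` has shape (n_perm, n_regions, n_regions) with NaN for absent
    entries; matrices are symmetrized (count-weighted) unless built with
    ``directed=True``.
    """

    delays: np.ndarray
    n_perm: int
    seed: int
    labels: tuple[str, ...]

    def per_edge_delays(self, i: int, j: int) -> np.ndarray:
        """Surrogate mean delays of edge (i, j); NaN where unobserved."""
        return self.delays[:, i, j]


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    cdf_control: pd.DataFrame
    cdf_patient: pd.DataFrame


@dataclass(frozen=True)
class LesionTestResult:
    observed_mean: float
    null_distribution: np.ndarray
    pvalue: float
    n_perm: int
    seed: int
    n_lesioned: int
    side: str
    null_pool: str


@dataclass(frozen=True)
class ConvergenceResult:
    """``curves[o, k]`` = mean |delta| between cumulative group means over
    the first k+2 and k+1 subjects of ordering o."""

    curves: np.ndarray  # (n_orders, n_subjects - 1)
    mean_curve: np.ndarray
    median_curve: np.ndarray
    sample_sizes: np.ndarray  # x = 2 .. n_subjects


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_avalanche(a: Avalanche, rng_seed: int | np.random.Generator) -> Avalanche:
    """Uniformly permute an avalanche's frame order, contents untouched."""
    rng = _rng(rng_seed)
    perm = rng.permutation(a.n_bins)
    frames = [a.frames[k] for k in perm]
    # an Avalanche's first frame must be non-empty; rotate a non-empty frame
    # to the front is NOT allowed (it would bias the shuffle) — instead the
    # surrogate keeps the raw permuted order and bypasses that check.
    out = object.__new__(Avalanche)
    object.__setattr__(out, "start_bin", a.start_bin)
    object.__setattr__(out, "frames", tuple(frames))
    object.__setattr__(out, "n_regions", a.n_regions)
    return out


def _avalanche_events(a: Avalanche) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(frame index, local region index, global region index) triplets for
    every frame membership, for vectorized surrogate recomputation."""
    frames_idx: list[int] = []
    regions: list[int] = []
    for k, frame in enumerate(a.frames):
        for r in frame:
            frames_idx.append(k)
            regions.append(r)
    regs = np.asarray(regions, dtype=np.intp)
    uniq, local = np.unique(regs, return_inverse=True)
    return np.asarray(frames_idx, dtype=np.intp), local, uniq


def surrogate_delay_ensemble(
    avalanches: Sequence[Avalanche],
    labels: Sequence[str],
    n_perm: int,
    seed: int,
    bin_width: int,
    fs: float,
    directed: bool = False,
) -> SurrogateEnsemble:
    """Shuffle every avalanche independently, n_perm times, and recompute
    the subject delay matrix for each permutation.

    Per-permutation RNG streams are spawned deterministically from the root
    seed, so the ensemble is bit-reproducible from (seed, n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = tuple(labels)
    n = len(labels)
    scale = bin_width / fs
    prep = [_avalanche_events(a) for a in avalanches]
    n_frames = [a.n_bins for a in avalanches]
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_perm)]
    out = np.full((n_perm, n, n), np.nan)
    for p, rng in enumerate(streams):
        sums = np.zeros((n, n))
        counts = np.zeros((n, n), dtype=np.int64)
        for (fidx, local, uniq), nb in zip(prep, n_frames):
            if uniq.size < 2:
                continue
            perm = rng.permutation(nb)
            pos = np.empty(nb, dtype=np.intp)
            pos[perm] = np.arange(nb)
            t = np.full(uniq.size, np.iinfo(np.int64).max, dtype=np.int64)
            np.minimum.at(t, local, pos[fidx])
            diff = t[None, :] - t[:, None]
            mask = diff > 0
            ii, jj = np.nonzero(mask)
            np.add.at(sums, (uniq[ii], uniq[jj]), diff[mask] * scale)
            np.add.at(counts, (uniq[ii], uniq[jj]), 1)
        if not directed:
            sums = sums + sums.T
            counts = counts + counts.T
        with np.errstate(invalid="ignore"):
            out[p] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SurrogateEnsemble(out, n_perm, seed, labels)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(r), float(p)


def length_delay_correlation(
    d: DelayMatrix, L: TractLengthMatrix, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between tract length and mean delay over edges present in
    both matrices (delays symmetrized; undirected edges counted once)."""
    _check_labels(d.labels, L.labels)
    dm = symmetrize_delays(d).mean_delay
    mask = ~np.isnan(dm) & L.present & np.triu(np.ones_like(L.present), k=1)
    if mask.sum() < 3:
        raise ValueError("need at least 3 edges with both length and delay")
    return _corr(L.lengths[mask], dm[mask], method)


def correlation_null_test(
    observed_r: float,
    ensemble: SurrogateEnsemble,
    L: TractLengthMatrix,
    side: str = "greater",
    method: str = "spearman",
) -> tuple[float, np.ndarray]:
    """Empirical p of the observed length-delay correlation against the
    correlations obtained from each surrogate delay matrix.

    ``side="greater"`` tests whether the observed coupling exceeds the
    surrogate ones. Returns (p, surrogate r values). Undefined surrogate
    correlations (e.g. constant delays) count as extreme (conservative).
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    _check_labels(ensemble.labels, L.labels)
    triu = np.triu(np.ones_like(L.present), k=1)
    rs = np.empty(ensemble.n_perm)
    for p in range(ensemble.n_perm):
        dm = ensemble.delays[p]
        mask = ~np.isnan(dm) & L.present & triu
        if mask.sum() < 3:
            rs[p] = np.nan
            continue
        rs[p], _ = _corr(L.lengths[mask], dm[mask], method)
    if side == "greater":
        extreme = np.isnan(rs) | (rs >= observed_r)
    else:
        extreme = np.isnan(rs) | (rs <= observed_r)
    pval = (1 + int(extreme.sum())) / (1 + ensemble.n_perm)
    return pval, rs


def _ecdf(x: np.ndarray) -> pd.DataFrame:
    xs = np.sort(np.asarray(x, dtype=float))
    return pd.DataFrame(
        {"value": xs, "cdf": np.arange(1, xs.size + 1) / xs.size}
    )


def ks_compare_groups(
    control_delays: Sequence[float], patient_delays: Sequence[float]
) -> KSResult:
    """Two-sample KS test on per-edge (or per-percentile) mean delays,
    returning the statistic, asymptotic p, and both empirical CDFs."""
    c = np.asarray(control_delays, dtype=float)
    p = np.asarray(patient_delays, dtype=float)
    if c.size == 0 or p.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(c, p, method="asymp" if min(c.size, p.size) > 25 else "auto")
    return KSResult(float(res.statistic), float(res.pvalue), _ecdf(c), _ecdf(p))


def edgewise_differences(
    patients: Sequence[DelayMatrix],
    controls_mean: DelayMatrix,
    coverage: Sequence[tuple[int, int]],
    masks: Sequence[np.ndarray],
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Patient-minus-control delay differences on complete-coverage edges.

    One record per (patient, coverage edge) where the patient has an
    estimate; each record carries the patient's lesioned flag for that edge.
    Patient matrices are symmetrized to match the undirected coverage set.
    Returns a DataFrame (patient, i, j, difference, lesioned).
    """
    if not coverage:
        raise ValueError("coverage edge set is empty")
    if len(masks) != len(patients):
        raise ValueError("one lesion mask per patient required")
    if patient_ids is None:
        patient_ids = [f"P{k:02d}" for k in range(len(patients))]
    edges = np.asarray(coverage, dtype=np.intp)
    ei, ej = edges[:, 0], edges[:, 1]
    cm = symmetrize_delays(controls_mean)
    if np.any(~cm.present[ei, ej]):
        raise ValueError("control mean is absent on a coverage edge")
    cvals = cm.mean_delay[ei, ej]
    frames = []
    for pid, pat, mask in zip(patient_ids, patients, masks):
        _check_labels(pat.labels, controls_mean.labels)
        pm = symmetrize_delays(pat)
        have = pm.present[ei, ej]
        mask = np.asarray(mask, dtype=bool)
        frames.append(
            pd.DataFrame(
                {
                    "patient": pid,
                    "i": ei[have],
                    "j": ej[have],
                    "difference": pm.mean_delay[ei, ej][have] - cvals[have],
                    "lesioned": mask[ei, ej][have],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def lesion_permutation_test(
    diffs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    null_pool: str = "all",
    side: str = "greater",
) -> LesionTestResult:
    """Do lesioned edges slow down more than expected by chance?

    Observed statistic: mean delay difference over lesioned records. Null:
    means of ``n_perm`` uniformly drawn (without replacement) subsets of the
    same size, from all records (``null_pool="all"``) or from non-lesioned
    records only (``"nonlesioned"``, the stricter variant). One-sided
    ``side="greater"`` tests the "lesioned edges slowed more" hypothesis.
    """
    if null_pool not in ("all", "nonlesioned"):
        raise ValueError("null_pool must be 'all' or 'nonlesioned'")
    if side not in ("greater", "less", "two-sided"):
        raise ValueError("side must be 'greater', 'less' or 'two-sided'")
    lesioned = diffs.loc[diffs["lesioned"], "difference"].to_numpy(dtype=float)
    healthy = diffs.loc[~diffs["lesioned"], "difference"].to_numpy(dtype=float)
    if lesioned.size == 0:
        raise ValueError("no lesioned records")
    if healthy.size == 0:
        raise ValueError("no non-lesioned records")
    pool = (
        diffs["difference"].to_numpy(dtype=float) if null_pool == "all" else healthy
    )
    if lesioned.size > pool.size:
        raise ValueError("null pool smaller than the number of lesioned records")
    observed = float(lesioned.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    k = lesioned.size
    for t in range(n_perm):
        null[t] = pool[rng.choice(pool.size, size=k, replace=False)].mean()
    if side == "greater":
        extreme = null >= observed
    elif side == "less":
        extreme = null <= observed
    else:
        extreme = np.abs(null - null.mean()) >= abs(observed - null.mean())
    p = (1 + int(extreme.sum())) / (1 + n_perm)
    return LesionTestResult(
        observed, null, p, n_perm, seed, int(k), side, null_pool
    )


def convergence_curve(
    subjects: Sequence[DelayMatrix],
    n_orders: int = 10,
    seed: int = 0,
) -> ConvergenceResult:
    """Stability of the group delay matrix as subjects accumulate.

    For each of ``n_orders`` random subject orderings and each x = 2..N, the
    mean over edges of |group mean over the first x subjects - group mean
    over the first x-1| is computed, over the edges already present at x-1.
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    labels = subjects[0].labels
    for s in subjects:
        _check_labels(s.labels, labels)
    n_sub = len(subjects)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_orders, n_sub - 1))
    for o in range(n_orders):
        order = rng.permutation(n_sub)
        first = subjects[order[0]]
        sums = np.where(first.present, first.mean_delay * 1.0, 0.0)
        counts = first.present.astype(np.int64)
        prev = np.where(counts > 0, sums, np.nan)
        for k, si in enumerate(order[1:]):
            s = subjects[si]
            p = s.present
            sums = sums + np.where(p, s.mean_delay, 0.0)
            counts = counts + p
            cur = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            shared = ~np.isnan(prev)
            curves[o, k] = float(np.abs(cur[shared] - prev[shared]).mean())
            prev = cur
    return ConvergenceResult(
        curves=curves,
        mean_curve=curves.mean(axis=0),
        median_curve=np.median(curves, axis=0),
        sample_sizes=np.arange(2, n_sub + 1),
    )
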