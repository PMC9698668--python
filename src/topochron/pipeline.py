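"""End-to-end orchestration: time series in, topochronic report out.

Per subject: z-score, threshold, bin, segment avalanches (optionally
filtered by minimum duration), estimate the delay and velocity matrices.
Per group: group matrices, length-percentile profiles, the length-delay
correlation with its time-shuffle surrogate null, the patient-control KS
comparison, the lesioned-edge permutation test, and the convergence curve.
Subject failures are isolated: a subject that yields no usable avalanches
is dropped with a logged reason rather than aborting the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import delays as D
from . import nulls as N
from . import raster as R
from .io import RunConfig, write_matrix

logger = logging.getLogger("topochron")

__all__ = ["SubjectRecord", "SubjectResult", "PipelineResults", "run_pipeline", "report", "write_report"]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "patient"
    timeseries: R.SourceTimeSeries
    lengths: D.TractLengthMatrix | None = None
    lesion_mask: np.ndarray | None = None


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    n_avalanches: int
    n_boundary_discarded: int
    n_single_bin: int
    sigma: float | None
    delay_matrix: D.DelayMatrix
    velocity_matrix: D.VelocityMatrix | None
    fs: float
    avalanches: list[R.Avalanche] = field(repr=False, default_factory=list)


@dataclass
class PipelineResults:
    config: RunConfig
    subjects: list[SubjectResult]
    failed_subjects: dict[str, str]
    group_delays: dict[str, D.DelayMatrix]
    group_lengths: D.TractLengthMatrix | None
    coverage_edges: list[tuple[int, int]]
    correlation: dict | None
    surrogate_tests: list[dict]
    delay_profile: D.PercentileProfile | None
    velocity_profile: D.PercentileProfile | None
    ks: N.KSResult | None
    edgewise: pd.DataFrame | None
    lesion_test: N.LesionTestResult | None
    convergence: N.ConvergenceResult | None


def _count_boundary_runs(raster: R.BinnedRaster) -> int:
    active = raster.occupancy.any(axis=0)
    if not active.any():
        return 0
    return int(active[0]) + int(active[-1] and not (active[0] and active.all()))


def _sample_resolution_matrix(
    raster1: R.BinnedRaster,
    avalanches: Sequence[R.Avalanche],
    bin_width: int,
    labels: Sequence[str],
) -> D.DelayMatrix:
    """Delays at raw-sample resolution: recruitment time of a region is its
    first onset *sample* inside the avalanche's bin span."""
    n = len(labels)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    onsets = raster1.onsets
    for a in avalanches:
        lo, hi = a.start_bin * bin_width, (a.start_bin + a.n_bins) * bin_width
        regions = sorted(set().union(*a.frames))
        t = {}
        for r in regions:
            hits = np.flatnonzero(onsets[r, lo:hi])
            if hits.size:
                t[r] = int(hits[0])
        idx = np.fromiter(t.keys(), dtype=np.intp, count=len(t))
        tt = np.fromiter(t.values(), dtype=float, count=len(t))
        if idx.size < 2:
            continue
        diff = tt[None, :] - tt[:, None]
        mask = diff > 0
        ii, jj = np.nonzero(mask)
        np.add.at(sums, (idx[ii], idx[jj]), diff[mask] / raster1.fs)
        np.add.at(counts, (idx[ii], idx[jj]), 1)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return D.DelayMatrix(mean, counts, tuple(labels))


def _process_subject(rec: SubjectRecord, cfg: RunConfig) -> SubjectResult:
    ts = rec.timeseries
    if cfg.target_fs is not None:
        ts = R.downsample(ts, cfg.target_fs)
    z = R.zscore_timeseries(ts)
    raster1 = R.binarize(z, cfg.threshold)
    binned = R.bin_raster(raster1, cfg.bin_width)
    avalanches = R.segment_avalanches(binned, event_mode=cfg.event_mode)
    n_boundary = _count_boundary_runs(binned)
    if cfg.min_avalanche_size is not None:
        avalanches = [a for a in avalanches if a.n_bins > cfg.min_avalanche_size]
    if not avalanches:
        raise ValueError("no avalanches after segmentation/filtering")
    n_single = sum(1 for a in avalanches if a.n_bins == 1)
    try:
        sigma = R.cohort_branching(avalanches).sigma
    except ValueError:
        sigma = None
    if cfg.delay_resolution == "sample":
        dmat = _sample_resolution_matrix(
            raster1, avalanches, cfg.bin_width, binned.region_labels
        )
    else:
        dmat = D.subject_delay_matrix(
            avalanches, binned.region_labels, cfg.bin_width, binned.fs
        )
    vmat = None
    if rec.lengths is not None:
        vmat = D.velocity_matrix(dmat, rec.lengths, directed=cfg.directed)
    return SubjectResult(
        rec.subject_id,
        rec.group,
        len(avalanches),
        n_boundary,
        n_single,
        sigma,
        dmat,
        vmat,
        binned.fs,
        avalanches,
    )


def _group_mean_lengths(
    records: Sequence[SubjectRecord],
) -> D.TractLengthMatrix | None:
    mats = [r.lengths.lengths for r in records if r.lengths is not None]
    if not mats:
        return None
    labels = next(r.lengths.labels for r in records if r.lengths is not None)
    stack = np.stack(mats)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return D.TractLengthMatrix(mean, labels)


def run_pipeline(
    cfg: RunConfig, manifest: Sequence[SubjectRecord]
) -> PipelineResults:
    """Run every stage of the topochronic workflow on a cohort."""
    subjects: list[SubjectResult] = []
    failed: dict[str, str] = {}
    for rec in manifest:
        try:
            sr = _process_subject(rec, cfg)
        except Exception as e:  # isolate subject failures
            logger.warning("subject %s failed: %s", rec.subject_id, e)
            failed[rec.subject_id] = str(e)
            continue
        logger.info(
            "subject %s: %d avalanches (%d boundary runs discarded, "
            "%d single-bin), sigma=%s",
            sr.subject_id, sr.n_avalanches, sr.n_boundary_discarded,
            sr.n_single_bin, sr.sigma,
        )
        subjects.append(sr)
    controls = [s for s in subjects if s.group == "control"]
    patients = [s for s in subjects if s.group == "patient"]
    if not controls:
        raise ValueError("no control subject survived the per-subject stages")

    group_delays = {"control": D.group_delay_matrix([s.delay_matrix for s in controls])}
    if patients:
        group_delays["patient"] = D.group_delay_matrix(
            [s.delay_matrix for s in patients]
        )
    coverage = D.complete_coverage_edges(
        [s.delay_matrix for s in controls], directed=cfg.directed
    )
    lengths = _group_mean_lengths(manifest)

    correlation = None
    surrogate_tests: list[dict] = []
    delay_profile = velocity_profile = None
    if lengths is not None:
        gd = group_delays["control"]
        r_s, p_s = N.length_delay_correlation(gd, lengths, "spearman")
        r_p, p_p = N.length_delay_correlation(gd, lengths, "pearson")
        correlation = {
            "spearman_r": r_s, "spearman_p": p_s,
            "pearson_r": r_p, "pearson_p": p_p,
        }
        for s in controls:
            r_obs, _ = N.length_delay_correlation(s.delay_matrix, lengths)
            ens = N.surrogate_delay_ensemble(
                s.avalanches, gd.labels, cfg.n_perm, cfg.seed,
                cfg.bin_width, s.fs,
            )
            p_emp, rs = N.correlation_null_test(r_obs, ens, lengths, side=cfg.side)
            surrogate_tests.append(
                {
                    "subject": s.subject_id,
                    "observed_r": r_obs,
                    "empirical_p": p_emp,
                    "surrogate_r_mean": float(np.nanmean(rs)),
                    "n_perm": cfg.n_perm,
                }
            )
        n_edges = int((group_delays["control"].present & lengths.present).sum() // 2)
        nbins = min(cfg.n_percentile_bins, max(n_edges, 1))
        if n_edges >= 1:
            delay_profile = D.percentile_profile(gd, lengths, nbins)
            velocity_profile = D.percentile_profile(
                D.velocity_matrix(gd, lengths, directed=cfg.directed),
                lengths,
                nbins,
            )

    ks = edgewise = lesion = None
    if patients and coverage:
        edges = np.asarray(coverage, dtype=np.intp)
        cvals = D.symmetrize_delays(group_delays["control"]).mean_delay[
            edges[:, 0], edges[:, 1]
        ]
        pvals = D.symmetrize_delays(group_delays["patient"]).mean_delay[
            edges[:, 0], edges[:, 1]
        ]
        ks = N.ks_compare_groups(cvals, pvals[~np.isnan(pvals)])
        masks = {
            r.subject_id: r.lesion_mask
            for r in manifest
            if r.group == "patient" and r.lesion_mask is not None
        }
        with_mask = [s for s in patients if s.subject_id in masks]
        if with_mask:
            edgewise = N.edgewise_differences(
                [s.delay_matrix for s in with_mask],
                group_delays["control"],
                coverage,
                [masks[s.subject_id] for s in with_mask],
                [s.subject_id for s in with_mask],
            )
            if edgewise["lesioned"].any() and (~edgewise["lesioned"]).any():
                lesion = N.lesion_permutation_test(
                    edgewise, cfg.n_perm, cfg.seed, cfg.null_pool, cfg.side
                )

    convergence = None
    if len(controls) >= 2:
        convergence = N.convergence_curve(
            [s.delay_matrix for s in controls], seed=cfg.seed
        )

    return PipelineResults(
        config=cfg,
        subjects=subjects,
        failed_subjects=failed,
        group_delays=group_delays,
        group_lengths=lengths,
        coverage_edges=coverage,
        correlation=correlation,
        surrogate_tests=surrogate_tests,
        delay_profile=delay_profile,
        velocity_profile=velocity_profile,
        ks=ks,
        edgewise=edgewise,
        lesion_test=lesion,
        convergence=convergence,
    )


def _quantiles(x: np.ndarray) -> dict[str, float]:
    q = np.nanquantile(x, [0.05, 0.25, 0.5, 0.75, 0.95])
    return dict(zip(["q05", "q25", "q50", "q75", "q95"], map(float, q)))


def report(results: PipelineResults) -> dict:
    """Machine-readable summary of a completed run (JSON-serializable)."""
    cfg = dataclasses.asdict(results.config)
    out: dict = {
        "settings": cfg,
        "subjects": [
            {
                "subject": s.subject_id,
                "group": s.group,
                "n_avalanches": s.n_avalanches,
                "n_boundary_discarded": s.n_boundary_discarded,
                "n_single_bin": s.n_single_bin,
                "sigma": s.sigma,
                "n_delay_edges": int(s.delay_matrix.present.sum() // 2),
            }
            for s in results.subjects
        ],
        "failed_subjects": results.failed_subjects,
        "n_coverage_edges": len(results.coverage_edges),
    }
    gd = results.group_delays["control"]
    out["control_delay_quantiles_s"] = _quantiles(gd.mean_delay[gd.present])
    if results.group_lengths is not None:
        vm = D.velocity_matrix(gd, results.group_lengths)
        if vm.present.any():
            out["control_velocity_quantiles_m_s"] = _quantiles(
                vm.velocity[vm.present]
            )
    if results.correlation is not None:
        out["length_delay_correlation"] = results.correlation
    if results.surrogate_tests:
        out["surrogate_tests"] = results.surrogate_tests
    if results.ks is not None:
        out["ks_patients_vs_controls"] = {
            "statistic": results.ks.statistic,
            "p": results.ks.pvalue,
        }
    else:
        out["ks_patients_vs_controls"] = "skipped"
    if results.lesion_test is not None:
        lt = results.lesion_test
        out["lesion_permutation_test"] = {
            "observed_mean_s": lt.observed_mean,
            "p": lt.pvalue,
            "n_perm": lt.n_perm,
            "n_lesioned_records": lt.n_lesioned,
            "seed": lt.seed,
            "side": lt.side,
            "null_pool": lt.null_pool,
        }
    else:
        out["lesion_permutation_test"] = "skipped"
    if results.convergence is not None:
        out["convergence"] = {
            "sample_sizes": results.convergence.sample_sizes.tolist(),
            "mean_curve_s": results.convergence.mean_curve.tolist(),
            "median_curve_s": results.convergence.median_curve.tolist(),
        }
    return out


def write_report(results: PipelineResults, out_dir: str | Path) -> Path:
    """Write the JSON report plus figure-ready CSVs; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report(results), indent=2))
    gd = results.group_delays["control"]
    write_matrix(gd.mean_delay, gd.labels, out_dir / "group_delays_control.csv")
    write_matrix(gd.counts, gd.labels, out_dir / "group_delay_counts_control.csv")
    if "patient" in results.group_delays:
        gp = results.group_delays["patient"]
        write_matrix(gp.mean_delay, gp.labels, out_dir / "group_delays_patient.csv")
    if results.group_lengths is not None:
        vm = D.velocity_matrix(gd, results.group_lengths)
        write_matrix(vm.velocity, vm.labels, out_dir / "group_velocities_control.csv")
        fast = D.fast_edge_subgraph(
            vm, results.config.velocity_threshold,
            hemisphere_map={l: l[0] for l in vm.labels}
            if all(l[:1] in ("L", "R") for l in vm.labels) else None,
        )
        fast.to_csv(out_dir / "fast_edges.csv", index=False)
    for name, prof in (
        ("delay_profile", results.delay_profile),
        ("velocity_profile", results.velocity_profile),
    ):
        if prof is not None:
            pd.DataFrame(
                {
                    "percentile_bin": np.arange(1, prof.n_bins + 1),
                    "mean_value": prof.mean_value_per_bin,
                }
            ).to_csv(out_dir / f"{name}.csv", index=False)
    if results.ks is not None:
        results.ks.cdf_control.to_csv(out_dir / "cdf_controls.csv", index=False)
        results.ks.cdf_patient.to_csv(out_dir / "cdf_patients.csv", index=False)
    if results.lesion_test is not None:
        pd.DataFrame({"null_mean": results.lesion_test.null_distribution}).to_csv(
            out_dir / "lesion_null.csv", index=False
        )
    if results.edgewise is not None:
        results.edgewise.to_csv(out_dir / "edgewise_differences.csv", index=False)
    if results.convergence is not None:
        pd.DataFrame(
            results.convergence.curves,
            columns=[f"x={x}" for x in results.convergence.sample_sizes],
        ).to_csv(out_dir / "convergence_curves.csv", index=False)
    return path
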