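# topochron

Estimation of whole-brain **functional transmission delays and conduction
velocities** from neuronal avalanches — a "topochronic map" combining the
temporal structure of large-scale brain dynamics with the structural
connectome.

## Who this is for

Researchers with (a) source-reconstructed M/EEG regional time series and
(b) tractography-derived tract-length matrices, who want subject-specific,
edge-specific estimates of how fast activity propagates between brain
regions — for example to compare patients with demyelinating disease
(multiple sclerosis) against controls, or to supply subject-specific delays
to personalized whole-brain models.

## The method

1. **Avalanches.** Each regional signal is z-scored and thresholded at
   |z| > 3 (2.5 and 3.5 as variants); both polarities count. After binning
   (width chosen so the branching parameter σ ≈ 1, the critical regime), a
   *neuronal avalanche* is a maximal run of non-empty bins. The branching
   parameter is

   σᵢ = ∏ⱼ ( n(j+1) / n(j) )^(1/(N−1)),  σ = ( ∏ᵢ σᵢ )^(1/N_aval),

   the geometric-mean ratio of event counts in consecutive bins.
2. **Delays.** Within an avalanche, the delay from region *i* to region *j*
   is the time between their first activations. Averaging entrywise over
   avalanches (absences discarded, never zero-filled) gives a subject delay
   matrix **D** (seconds); averaging subjects gives a group matrix.
3. **Velocities.** With the tract-length matrix **L** (mm),
   **v** = (L/1000) / D (m/s), computed only on structurally connected
   pairs.
4. **Statistics.** Time-shuffled surrogates (frame order permuted within
   each avalanche, frame contents fixed) give the null for the
   length–delay correlation; a two-sample KS test compares patient and
   control delay distributions; a subset-resampling permutation test asks
   whether structurally lesioned edges slowed more than chance; a
   convergence curve tracks the stability of the group matrix in the
   number of subjects.

A fully synthetic cohort generator (`topochron.synth`) states a
ground-truthed world — log-normal tract lengths, a velocity law
v = a·L^b, cascades spreading along structural edges with first-arrival
recruitment, lesion-slowed patients — so every stage is testable without
clinical data.

## Worked example

```python
import topochron as tc
from topochron.pipeline import SubjectRecord, run_pipeline, report

params = tc.CascadeParams(n_avalanches=300, seed=1)   # 60-region world
bundle = tc.make_cohort(params, n_controls=3, n_patients=6,
                        lesion_fraction=0.2, lesion_slowdown=1.5)
records = [SubjectRecord(s.subject_id, s.group, s.timeseries,
                         lengths=bundle.ground_truth.lengths,
                         lesion_mask=s.ground_truth.lesion_mask)
           for s in bundle.subjects]
cfg = tc.RunConfig(fs=512.0, bin_width=2, n_perm=200, seed=1)
rep = report(run_pipeline(cfg, records))
```

Output (abridged) and what it means:

```
subjects[0]: {'subject': 'C00', 'sigma': 1.031, 'n_avalanches': 300}
length_delay_correlation: {'spearman_r': 0.395, 'spearman_p': 1.6e-09}
surrogate_tests[0]: {'observed_r': 0.439, 'surrogate_r_mean': 0.080,
                     'empirical_p': 0.0050}
control_velocity_quantiles_m_s: {'q05': 3.1, 'q50': 7.1, 'q95': 14.6}
ks_patients_vs_controls: {'statistic': 0.335, 'p': 0.00053}
lesion_permutation_test: {'observed_mean_s': 0.0040, 'p': 0.0050,
                          'n_lesioned_records': 55}
n_coverage_edges: 71
```

- σ ≈ 1.03: the cascades sit near the critical branching regime.
- Delays grow with tract length (Spearman r = 0.395) and the per-subject
  correlation (0.439) exceeds all 200 time-shuffle surrogates
  (mean surrogate r = 0.08, empirical p = 0.005): the temporal order of
  recruitment, not just its spatial pattern, carries the length–delay
  relation.
- Velocities span ~3–15 m/s and rise with tract length — long tracts are
  fast, so delays are far more homogeneous than constant-velocity
  propagation would predict.
- Patients' delays are stochastically larger than controls'
  (KS p = 0.0005), and the 55 lesioned-edge records slowed more than
  random edge subsets (+4.0 ms on average, permutation p = 0.005).

The same workflow is exposed as a CLI:

```bash
topochron simulate --seed 1 --out-dir cohort --n-controls 3 --n-patients 6
topochron run --manifest cohort/manifest.csv --out-dir results
topochron lesion-test --manifest cohort/manifest.csv --out lesion.json
```

## Reproducible end-to-end run

`scripts/acceptance.py` regenerates the synthetic cohort above from a seed,
runs every pipeline stage from raw time series to the final statistics, and
writes a machine-readable JSON report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# full report in results/pipeline_report.json
```

## Layout

- `topochron.raster` — z-scoring, thresholding, binning, avalanche
  segmentation, branching parameter, bin-width selection
- `topochron.delays` — delay/velocity matrices, percentile profiles,
  constant-velocity expectation, fast-edge subgraph
- `topochron.nulls` — time-shuffled surrogates, correlation nulls, KS,
  lesioned-edge permutation test, convergence
- `topochron.synth` — ground-truthed synthetic cohorts
- `topochron.io`, `topochron.pipeline`, `topochron.cli` — formats, run
  configuration, orchestration, command line

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
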