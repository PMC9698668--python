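# Methods

## Model and estimation chain

The package estimates per-edge functional transmission delays from the
temporal order in which brain regions are recruited during neuronal
avalanches, and converts them to conduction velocities using structural
tract lengths.

**Discretization.** Each regional time series is z-scored over the full
segment with the population (n) denominator — the simplest reproducible
choice when no normalization window is prescribed. Activations are strict
excursions |z| > threshold (default 3.0; 2.5/3.5 as configured variants);
positive and negative excursions both count. An *event* is an excursion
onset (the first suprathreshold sample/bin of a contiguous run), so a
sustained excursion contributes one event; `event_mode="occupancy"` counts
every suprathreshold bin instead. Down-sampling is integer decimation and
assumes anti-alias filtering upstream.

**Binning and avalanches.** Sample rasters are OR-reduced into bins
(default width 3 samples at 512 Hz; candidates 1–5 scored by the branching
parameter, ties toward the smaller width). An avalanche is a maximal run of
non-empty bins. Runs touching either recording boundary are discarded:
their onset or termination is unobservable, so their delays and branching
ratios would be biased. The branching parameter σᵢ is the geometric mean of
consecutive-bin event-count ratios; it is undefined (and the avalanche is
excluded from σ, with the exclusion counted) for single-bin avalanches and
whenever an intermediate bin carries zero events — the latter can occur in
onset event mode when an excursion spans several bins.

**Delays.** Each region's recruitment time is its first event bin in the
avalanche; later re-activations are ignored. Delays are recorded for *all*
ordered co-recruited pairs (not only structural neighbours); simultaneous
recruitments contribute nothing. Subject matrices are entrywise means over
the avalanches in which a pair was observed; group matrices repeat this
over subjects. Absence is explicit (NaN + zero count), never zero. The
default time base is the bin (`delay_resolution="bin"`); a raw-sample
readout within avalanche spans is available (`"sample"`).

**Velocities.** Before dividing, directed delays are symmetrized by the
count-weighted mean of the two directions (tract lengths are symmetric and
the directedness of published delay matrices is unspecified); `--directed`
disables this. Velocities exist only where a structural tract *and* a delay
estimate coexist. Units are fixed package-wide: lengths mm, delays s,
velocities m/s.

## Statistics

- **Time-shuffled surrogates** permute the frame order independently within
  each avalanche, preserving every frame's recruited-region set, avalanche
  size and duration — destroying temporal order only. Per-permutation RNG
  streams are spawned from a single root seed, so ensembles are
  bit-reproducible from `(seed, n_perm)`.
- **Empirical p-values** use the add-one estimator
  p = (1 + #extreme) / (1 + n_perm), so p ∈ (0, 1]. Default n_perm = 1000.
- **Lesion permutation test.** Observed statistic: mean patient-minus-control
  delay difference over lesioned records (restricted to complete-coverage
  edges, i.e. edges estimated in every control). Null: means of random
  same-size subsets drawn without replacement from all records
  (`null_pool="all"`; `"nonlesioned"` is the stricter variant). One-sided
  ("lesioned edges slowed more") by default.
- **KS comparison** operates by default on per-edge group-mean delays over
  complete-coverage edges; a per-percentile mode mirrors profile-style
  aggregation.
- **Convergence.** For each random subject ordering, mean |Δ| between
  cumulative group means over the first x and x−1 subjects, over the edges
  already present at x−1 (edges contributed only by the newest subject enter
  later; an edge updated by no new observation contributes exactly 0).

## The synthetic world

`CascadeParams` defaults state one world, chosen once:

| parameter | default | why |
|---|---|---|
| n_regions | 60 | desk-scale parcellation (cerebellum-free atlases have 84–90) |
| edge_density | 0.12 | mean degree ≈ 7, deterministic-tractography-like sparsity |
| tract lengths | log-normal, median 60 mm, σ=0.55 | fat-tailed, strictly positive, ~15–250 mm |
| velocity law | v = 0.3·L^0.8 m/s | velocities ~2–30 m/s rising with length; b=0 is the constant-velocity null, b=1 the homogeneous-delay regime |
| transmission_p | 0.057 | branching ratio R0 = p·(mean degree) ≈ 0.4 — see below |
| fs / bin_width | 512 Hz / 1 sample | ground-truth delays are 3–12 ms; a width-3 bin (5.9 ms) would be coarser than most of them |
| noise | clipped Gaussian, ±2.5 SD | after z-scoring no noise sample can cross |z|>3, so detection is exact |
| pulse | amplitude 12, sustained to the next recruitment | see duty-cycle note |

Cascades use first-arrival semantics: a uniformly random seed region
activates; each activation tries each structural neighbour once with
probability `transmission_p`, arriving after the edge's rounded delay in
bins; the earliest arrival recruits a region, at most once. Recruitment
times are therefore shortest-arrival times through the delayed network —
the same network effect the estimator inherits. Lesions multiply the
*delay* (not the length) of a random fraction of edges, matching an
analysis that deliberately avoids patient length estimates.

**Why sub-critical cascades (R0 ≈ 0.4).** The delay estimator attributes
co-activation lags to region pairs. In large (near-critical or
supercritical) cascades, a structurally connected pair is usually
co-recruited through common sources or multi-hop paths, whose lags are
nearly independent of that edge's own conduction delay; empirically the
estimated delay is then ~2–2.5× the direct delay and almost flat in tract
length, driving the recovered velocity exponent toward 1 regardless of the
generative b. Only when most multi-region events are single direct hops
(small cascades) does the per-edge mean read out the direct conduction
delay. The default R0 ≈ 0.4 was fixed by this mechanism and verified on
held-out master seeds (recovered b = 0.82 ± 0.02 for true b = 0.8). This is
a genuine limitation of the estimator, not of the generator: with dense,
critical dynamics the "delays" it returns are network transit times, and
their near-homogeneity across edge lengths is partly an estimator property.

**Duty-cycle constraint.** The pipeline z-scores per region, so a region
suprathreshold in a fraction f of samples has its SD inflated by its own
pulses; above f ≈ 10% *no* pulse amplitude can reach z > 3. The generator
therefore sustains each excursion only until the cascade's next recruitment
bin (keeping the avalanche's bin span gap-free, which sample-width pulses
would not) and pads the recording with quiet bins so every region stays
below a 4% duty cycle.

**What the generator does not emulate** — and hence what a green test does
not establish: volume conduction and source leakage, oscillatory/1-f
background structure, amplitude heterogeneity across regions, measurement
noise in tract lengths, refractoriness or repeated recruitment within an
avalanche, and directed (asymmetric) conduction. Detection is exact by
construction (bounded noise), so recovery results isolate estimator
behaviour from detection errors.

## Numerical choices

- Strict inequality |z| > threshold (the only printed form).
- Delay rounding in the simulator: `round(delay·fs/bin_width)`; an edge
  rounding to 0 bins raises (prevents instantaneous loops) — use finer
  bins or longer delays.
- Geometric means are computed in the log domain.
- Bin-width selection breaks |σ−1| ties toward the smaller width.
- Surrogate correlations that are undefined (e.g. constant surrogate
  delays) count as extreme — conservative.
- Matrix CSVs round-trip bit-identically (`float_precision="round_trip"`).
- Seeds: every stochastic operation takes an explicit seed; per-subject and
  per-permutation streams are spawned from it deterministically.

## Known limitations

- Delays are bin-quantized per avalanche; sub-bin resolution arises only
  from averaging across avalanches.
- The estimator conflates direct and indirect propagation (see above); in
  dense or strongly coupled regimes, "edge delay" should be read as a
  network transit time.
- Complete-coverage edge sets shrink geometrically with the number of
  controls when per-subject coverage is incomplete; group comparisons on
  few-control cohorts therefore run on few edges.
- The branching parameter at sample resolution is often undefined for
  sparse sub-critical cascades (inter-recruitment gaps exceed one bin);
  compute σ at bin widths ≥ 2 in such worlds.
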