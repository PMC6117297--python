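# Methods

`labelkin` models pulse-chase division-marker dilution in a structured
progenitor compartment and the statistics used to read it out.  This note
records the models, their assumptions, the defaults and why they were
chosen, and what the synthetic cohorts do and do not establish about real
data.

## The label-dilution model

During a labeling pulse (default 1008 h, i.e. six weeks of doxycycline), a
histone-GFP fusion is expressed in dividing cells.  We model labeling as
binary and saturating: every cell that divides at least once during the
pulse carries the full label `L0` at chase start, while a configurable
`unlabeled_fraction` of cells that never divided stays at zero label.  This
reproduces the observed tri-modal structure (never-labeled / diluted /
retaining) without modeling histone synthesis kinetics; the cost is that
cells dividing only in the pulse tail are not given intermediate label, so
the simulated week-0 labeled peak is tighter than a real one.

During the chase, cells follow a Bellman–Harris branching process:

* **Cycle lengths** are gamma-distributed with mean `T` (hours) and
  coefficient of variation `cv` per subpopulation; `cv = 0` gives
  deterministic cycles, `cv = 1` exponential ones.  Founders receive a
  uniform random phase within their first cycle, so populations are
  asynchronous from the start.
* **Division** splits the parent's label between two daughters with a
  symmetric Beta split (mean 1/2, CV `partition_cv`), so total label is
  conserved exactly under division — the bookkeeping oracle
  `total_label_conservation` checks this to 1e-9 relative.
* **Exit** (death or differentiation out of the compartment) is a
  per-subpopulation exponential rate.  The default, `"balanced"`, sets the
  rate to `ln 2 / T`, which holds each subpopulation near steady state.
  This is a deliberate departure from a single global exit knob: a common
  rate cannot keep both a ~20 h-cycling and a ~1200 h-cycling
  subpopulation at observable frequencies across an eight-week chase — the
  fast compartment either explodes (no exit) or starves the slow one out
  of the sampled fraction (globally balanced exit).  Per-compartment flux
  balance is also the biologically sensible reading of a transit
  population of fixed size.
* **Population cap.** When a mouse's population exceeds `max_population`
  it is thinned uniformly.  Because cell fates are independent, uniform
  thinning leaves the per-cell label distribution and division-count
  distribution unbiased; only absolute totals lose meaning, so the
  conservation tests run uncapped.

Default cohort structure mirrors the study design: groups `control`
(98 % proliferative, mean cycle 18.2 h) and `lmo2` (87 % proliferative at
50.1 h plus 5 % cycle-restricted at 1200 h), never-labeled fractions of
2 % and 8 %, chase samples at weeks {0, 1, 2, 4, 8}, cross-sectional mice
(each mouse sampled once).  The two proliferative cycle times are the two
cycling-time point estimates the assay is built to recover; the restricted
compartment's 1200 h cycle makes it lose roughly one label-halving over
eight weeks — slow loss rather than true dormancy.

**Measurement.** Measured GFP is `(true label + autofluorescence)` times a
log-normal factor with unit median and CV `measurement_cv` (so geometric
means are unbiased).  Ki67/DNA channels are phenomenological: a cell
dwelling longer than `g0_dwell_h` (default 30 h) since its last division
reads Ki67-negative with 2N DNA (G0); cycling cells read Ki67-positive,
with DNA ramping 2N→4N through the post-G1 half of the cycle.  With a
~50 h cycle this dwell rule puts roughly 40 % of proliferative cells in
G0-by-snapshot, matching the scale of Ki67 measurements in slow transit
compartments.

## Gating

Events are classed on the log10 fluorescence scale: `neg` below the neg
threshold, `hi` at or above the hi threshold, `lo` between, with boundary
ties assigned upward (a deterministic stand-in for gates drawn by eye).
Auto-derived gates place `hi` one decade below the labeled-population mode
of a week-0 cohort and `neg` at the autofluorescence mode plus three
robust SDs.  Count summaries exclude `neg` events from the denominator
(`dn3 = hi + lo`), the analogue of excluding never-divided cells.

One caveat the demo makes explicit: after enough divisions a diluted cell
is physically indistinguishable from a never-labeled one, so a strict neg
gate erodes the denominator at late chase times.  Where the ratio should
track the *total* compartment (as when absolute cell counts feed the
model), the right configuration is a permissive neg gate; the demo
pipeline does this.

## The label-loss model

Per mouse, `Y = log10((hi_count + c) / total_count)` with offset `c`
(default 100) keeping the log finite at zero hi counts; `c` must stay
below the smallest nonzero hi count, and the transform warns otherwise.
The demo uses `c = 5` because its counts are per-mouse event samples
(~10^3) rather than absolute organ counts (~10^4–10^5); the rule, not the
number, is the convention.

Label loss follows `Y = A + B·R^X` with chase time `X` in weeks,
`0 < R < 1` the weekly retention factor, `Y(0) = A + B`, asymptote `A`.
Fitting is least squares by variable projection: for fixed `R` the model
is linear in the `A`s and `B`s, so the profiled SSE is minimized over `R`
alone (241-point grid scan, then bounded Brent refinement to
`xatol = 1e-12`).  This is exact on noiseless data (recovery to better
than 1e-6 across the tested grid) and fast enough for tens of thousands of
bootstrap refits.  A fit with `R` within 1e-6 of either bound, or with
`|B|` indistinguishable from zero (a flat series), is returned flagged
non-identifiable rather than rejected.  Adjusted R² uses the standard
`1 − (SSE/(n−p)) / (SST/(n−1))` with the nonlinear SSE and the pooled
total sum of squares.

**Group structure** is chosen over the nested sequence shared(A,B,R) →
separate A → separate A,B → separate A,B,R, scored by extra-sum-of-squares
F-tests between successive least-squares fits.  The F-test is a declared
convention — the classical test for nested fixed-regressor models; exact
only asymptotically for nonlinear fits, and its simulated type-I error is
verified nominal in the acceptance suite.  The final reported model keeps
all three parameters group-specific regardless of the last test's
outcome, so per-group reduction times are always defined.

**Reduction times.**  `t_k = log((B−k)/B) / log(R)` solves
`Y(t) = Y(0) − k`; when `B ≤ k` the curve never falls `k` logs below its
start and the group is flagged asymptote-limited with `t_k = +inf` — for a
label-retaining population this is a finding, not an error.

**Bootstrap of residuals.**  Residuals are resampled with replacement
within group (preserving group-specific variance; pooled resampling is a
switch), added to fitted values, the model refit with the same structure,
and `t_k` recomputed; the contrast is `Δt_k = t_k(group 2) − t_k(group 1)`.
The two-sided p-value is `2·min(P(Δ*≤0), P(Δ*≥0))` floored at
`1/(n_boot+1)`; replicates where one group is asymptote-limited enter as
`±inf` on the appropriate tail, and replicates where both are count
against rejection on both sides (scored 0) — dropping them would bias the
null.  Confidence intervals are nearest-rank percentiles, well-defined
with infinite draws.  Calibration is checked by simulation: with
identical groups the rejection rate at α = 0.05 sits inside the exact
binomial band; at the generator's default separation (a fast-decaying
`R = 0.10` group against a retaining `R = 0.80` group, residual SD 0.3,
four mice per group per week) power exceeds 0.9.  Those defaults encode
the qualitative design the assay targets — one group losing all
label-retaining cells within ~2 weeks, the other retaining them through
week 8 — with residual scatter chosen so the final-model adjusted R² lands
in the mid-80 % range typical of such fits.

**Division times.**  Assuming mean fluorescence halves per division, the
divisions between chase times are `d = log2(MFI(t0)/MFI(t1))` and
`T = (t1−t0)/d`.  Because the design is cross-sectional, the reference
`MFI(t0)` is the pooled week-`t0` group mean and each later-week mouse
contributes its own `MFI(t1)`; per-mouse estimates are summarized as
mean ± SD across mice.  Arithmetic means are used (the flow convention);
the known autofluorescence floor is subtracted in the pipeline.  Mice
without a decline are flagged and excluded.  Under deterministic cycles
the estimator recovers 18.2 h and 50.1 h scenarios within a few percent
(asynchronous phases remove most discretization bias).  Under dispersed
cycle lengths it is biased *downward*: with exponential cycles the
population grows as `e^{t/T}` (Euler–Lotka), so the population-mean
fluorescence decays as `e^{−t/T}` rather than `2^{−t/T}` and the halving
estimator converges to `T·ln 2 ≈ 0.69·T` — fast lineages contribute more
descendants and drag the mean label down.  This ~30 % underestimate is
measured and documented by the acceptance suite, not corrected.

## Chromosome-level expression shifts

For a genes × samples log2 matrix, `logFC(g, s) = expr(g, s) −
median_s'(expr(g, s'))` (even sample counts average the central pair);
optional per-sample median centering first is a config switch, since the
normalization order is a genuinely open choice.  Genes are aggregated by
chromosome (mouse naming chr1–chr19, chrX, chrY; annotation joined on
gene id, unmatched genes dropped and counted), and each (chromosome,
sample) pair gets a median, an IQR, and a permutation p-value comparing
the observed median with medians of size-matched random gene sets from the
same sample.  Gene-set permutation (rather than sample-label shuffling)
preserves the sample's gene-level logFC distribution exactly, which is
what the positional statistic is measured against.  One gene permutation
per replicate is shared across chromosomes — the nested null sets leave
each per-chromosome p-value marginally valid while cutting the cost an
order of magnitude.

Calls: gain requires median ≥ `+0.3` log2 and BH-adjusted p ≤ α (default
0.01) across chromosomes within a sample; loss is symmetric; chromosomes
under 50 genes are always neutral.  The 0.3 threshold sits below the full
trisomy dosage `log2(3/2) ≈ 0.585` to tolerate partial dosage
compensation.  Note two consequences of the design: with ~20 testable
chromosomes, a call at α = 0.01 needs the permutation floor `2/(n_perm+1)`
below `α/20`, hence ≥ 3999 permutations (the demo uses 4999); and when a
minority of samples carries the spike, the cross-sample median shifts
slightly toward it, so the observed spiked-sample median is ~0.46 rather
than 0.585 with one spiked sample of six.  Spike-in recovery at noise
SD 0.5 on a 100-gene chromosome runs at ≥ 95 % sensitivity with ≤ 5 %
per-matrix false calls.

## What the synthetic cohorts do not show

The generator draws i.i.d. noise; real flow data have instrument drift,
spillover, doublets and gating subjectivity, none of which are modeled
(and compensation/doublet handling is explicitly out of scope).  The
expression generator has no gene–gene correlation, batch structure or
mean–variance trend, so the spike-in operating characteristics are an
upper bound on real-data performance.  Passing tests establish the
correctness and calibration of the *computations*, not the biology of any
particular dataset.

## Numerical and reproducibility choices

Chase time is in weeks, division and dwell times in hours; the single
conversion constant (168 h/week) lives in `labelkin._units`.  All
randomness flows from one root seed through `numpy.random.SeedSequence`
spawning (per-mouse child streams, separate streams for measurement,
bootstrap, and permutations), so identical configurations are
bit-reproducible, including across partial re-runs of the pipeline.  The
problem sizes in the test and acceptance runs (10^3–10^4 cells per mouse,
100–200 simulation replicates, 200–5000 bootstrap draws, 4999
permutations) were chosen as the smallest sizes at which the binomial
tolerances of the checks are meaningful.
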