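# labelkin

Cell-cycle kinetics of rare stem/progenitor populations from pulse-chase
division-marker dilution, plus chromosome-level expression-shift
(aneuploidy) calling from bulk transcriptomes.

## The problem

In a histone-GFP pulse-chase experiment, dividing cells load a fluorescent
label during a doxycycline pulse; after withdrawal the label dilutes
roughly twofold per division, so retained fluorescence reports division
history.  Applied to a thymocyte compartment harboring pre-leukemic stem
cells, the assay separates a fast-cycling majority (label lost within
weeks) from a rare cycle-restricted subpopulation that retains label
through an eight-week chase.  `labelkin` turns that design into a tested
pipeline for anyone analyzing label-retention data:

* **simcore** — a branching-process simulator of label dilution with known
  ground truth: subpopulations with gamma cycle times, conservative
  beta-split label partitioning, steady-state exit, log-normal measurement
  noise, Ki67/DNA channels.  Also generates synthetic log-ratio datasets
  and expression matrices with chromosome dosage spike-ins.
* **gating** — neg/lo/hi GFP classification on the log10 scale, per-mouse
  count series (never-labeled cells excluded from the denominator), and
  Ki67/DAPI-style cell-cycle fractions (G0 = Ki67⁻ 2N).
* **kinetics** — the core model.  Per-mouse log ratios
  `Y = log10((GFPhi + c)/total)` are fit to exponential label loss

      Y = A + B·R^X,  0 < R < 1,

  with `X` chase weeks, `Y(0) = A + B`, asymptote `A`, and weekly
  retention factor `R`.  Group structure (which of A, B, R differ between
  cohorts) is selected over a nested sequence with extra-sum-of-squares
  F-tests; times to 1-log and 2-log reduction get percentile CIs and
  p-values by bootstrap of residuals; and mean division times are
  estimated from fluorescence halving between chase timepoints.
* **aneuploidy** — per-gene log fold change versus the cross-sample
  median, aggregated by chromosome; gain/loss calls require a median
  shift beyond a dosage threshold (trisomy dosage is log2(3/2) ≈ 0.585)
  and a size-matched gene-set permutation p-value surviving
  Benjamini–Hochberg correction.
* **cli_io / pipeline** — CSV/JSON I/O contracts, a `labelkin` CLI, and a
  reproducible end-to-end runner with a checksummed manifest.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

The bundled demo simulates a two-group cohort (a `control` group cycling
at ~18 h and an `lmo2` group cycling at ~50 h with a 5 % cycle-restricted
subpopulation at ~1200 h), gates it, fits the label-loss model, bootstraps
the reduction-time contrast, estimates division times, and calls a
simulated trisomy-15 spike-in:

```bash
labelkin run --seed 7 --out demo_run
```

Selected output from `demo_run/` (seed 7):

```text
fit.json          control: A=-2.30  B=2.29  R=0.00   lmo2: A=-1.39  B=1.41  R=0.52
                  adjusted R^2 = 0.976
reduction_times   k=1: t[control]=0.06 wk   t[lmo2]=1.89 wk
                  k=2: t[control]=0.22 wk   t[lmo2]=inf (asymptote-limited)
bootstrap.json    delta t1 = 1.83 wk, p = 0.002 (500 resamples)
division_time     control: 17.9 ± 0.1 h    lmo2: 58.9 ± 0.7 h
aneuploidy_calls  chr15 gain in sample s6 (median logFC +0.59)
```

Reading it: the control group's label-retaining fraction collapses within
the first week (`R ≈ 0`, 1-log reduction in 0.06 weeks), while the `lmo2`
group needs 1.9 weeks for one log and never reaches two — its fitted
amplitude `B` is smaller than 2 logs because the cycle-restricted cells
hold the curve above the asymptote.  The bootstrap puts the
reduction-time gap at 1.8 weeks with p ≈ 0.002.  Fluorescence halving
over the first chase week recovers the two groups' mean cycling times,
and the expression module flags the one sample carrying the simulated
extra chromosome 15.  Identical seeds reproduce every output file
bit-for-bit (compare `manifest.json` checksums).

Each stage is also exposed separately: `labelkin simulate`, `gate`,
`fit`, `boot`, `divtime`, `aneuploidy` — see `--help` on each.

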