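# Methods

## Model and assumptions

The copy-number signal is a fold change of *fractional* depth of coverage
against the per-interval median of a co-captured batch. This rests on three
assumptions:

1. **Shared capture efficiency.** All samples in a batch are captured in one
   multiplexed pool, so per-bait efficiency is common to the batch and
   cancels in the ratio. Cross-batch references would break this and are not
   supported: the reference set *is* the batch.
2. **Majority copy-neutrality.** The per-interval batch median is a diploid
   reference only if most samples carry 2 copies at that interval. Common
   polymorphic CNVs violate this locally; they surface as recurrent calls
   (often with inverted sign in non-carriers) and are handled by annotation,
   not by the normalization.
3. **Stable within-sample composition.** Dividing by the sample's total
   coverage removes sequencing-depth differences but couples intervals: a
   very large event shifts the denominator. For a 5-exon event on a
   1,016-interval panel the shift is ≈ 0.004 log2 units — negligible, but it
   is why noiseless injected single-copy losses measure −0.996 rather than
   −1 exactly, and why the batch's sex mix perturbs autosomal ratios by up
   to ~0.02 on a panel with 5% X content.

On the log2 scale the diploid state is 0, a single-copy gain log2(3/2) ≈
0.58, a single-copy loss −1. These two constants anchor both the QC rule and
the copy-number estimate `2·2^median_log2`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `gain_log2` | 0.40 | log2 | fixed gain calling threshold |
| `loss_log2` | −0.55 | log2 | fixed loss calling threshold |
| `iqr_multiplier` | 3 | — | boxplot whisker multiplier (must be ≥ 1) |
| `qc_gain_bound` / `qc_loss_bound` | 0.58 / −1 | log2 | whisker limits for sample QC |
| `min_pass_samples` | 3 | samples | minimum batch size for a usable median |
| `min_probes_gain` / `min_probes_loss` | 1 / 1 | intervals | minimum run length per call type |
| `cohort_recurrence_fraction` | 0.01 | fraction | unique-call frequency above which a call is flagged recurrent |
| `gc_low` / `gc_high` | 0.35 / 0.65 | fraction | extreme-GC annotation bounds |
| `min_medoid_separation` | 0.3 | log2 | below this the sex clustering is declared degenerate |
| `x_trim_fraction` | 0.1 | fraction | outlier-probe trim per tail before the X summary |

The calling thresholds 0.40/−0.55, the IQR multiplier 3, the single-copy
bounds, the ≥3-sample floor, the 1% recurrence fraction and the 35/65% GC
bounds are the validated clinical operating point of the underlying method
and are the defaults; everything is configurable per run and echoed verbatim
into the run manifest.

`min_probes_loss` defaults to 1 even though losses are conceptually
multi-probe events: single-exon deletions are clinically real (and were the
reason for exon-level resolution in the first place), so length-1 calls are
allowed by default and the stringency is left to configuration.

## X correction and sex prediction

Per sample, the X summary is the median of its X-interval ratios after
trimming the top and bottom 10% (outlier probes — a handful of flaky X baits
must not move a sample between clusters). The two-cluster split is an exact
2-medoid optimization: every pair of samples is tried as medoids and the
pair minimizing total absolute deviation wins. With ≤10 samples this is at
most 45 evaluations, and exactness makes the step testable against
brute-force bipartition search. Each sample's X ratios are then shifted by
the negative of its cluster's median summary.

When the two medoids are closer than `min_medoid_separation` (0.3 log2 —
halfway between a single-sex batch's 0 and a mixed batch's ≈1), the batch is
treated as single-sex: one cluster, a global-median shift (≈0), and
predicted sex *indeterminate* for everyone, since coverage dosage alone
cannot tell an all-female batch from an all-male one. Otherwise the
lower-medoid cluster (one X dose against the batch reference) is predicted
male, the other female.

## QC loop

QC is evaluated on the post-X-correction matrix of each iteration, so an
unlucky sex mix cannot fail a sample whose autosomes are clean. Whisker
comparisons are strict (a whisker exactly at 0.58 or −1 passes: it must
*extend beyond* the bound to fail). Failed samples are removed and the
survivors renormalized — removal changes the batch median, so all ratios are
recomputed, and iteration folders (`iteration_1/`, `iteration_2/`, …) keep
each round's matrix, QC table and boxplots for review. The loop strictly
shrinks the batch whenever it fails anyone, so it terminates in at most *n*
iterations.

Quartiles are Tukey hinges (median of each half, halves including the median
element when *n* is odd) and whiskers are actual data values within
hinge ± multiplier × IQR, matching R's `boxplot.stats`, which the test suite
uses as an independent oracle. Multipliers below 1 are rejected: they can
place a fence inside the box, leaving no data value between hinge and fence.
Masked intervals (zero batch median) and floor cells (zero coverage at a
live interval, recorded as −10) are excluded from the summaries so a single
dead bait cannot fail a sample — but floor cells remain loss-eligible in
segmentation, because a genuine homozygous dropout should be callable.

## Calling

Eligibility is strict and dual: `ratio > max(gain_log2, upper_whisker)` for
gains, `ratio < min(loss_log2, lower_whisker)` for losses. The whisker arm
adapts to each sample's dispersion; it also means a large CNV slightly
raises its own sample's whisker, which costs a little sensitivity near the
threshold — visible in the simulation recovery rates below. Chromosome
boundaries and masked intervals break runs. Ids are per-sample, 1-based, in
genome order, and are the *same* identifiers drawn on the plots.

Recurrence groups calls by (chromosome, first rank, last rank, type) and
counts distinct cases. Within a single run the denominator is that run's
samples, where the 1% threshold is trivially exceeded by any call — the flag
becomes meaningful when `cohort-merge` recomputes it across many runs'
tables. Recurrent and extreme-GC calls are flagged, never silently removed
(`--drop-recurrent` opts into removal); GC content is user-supplied per
interval, since the tool deliberately does not read genome sequence.

The ddPCR calculator normalizes a raw copy-number value by the
reference-correction constant RCC = 2 × (AP3B1:RPP30) and rescales by 2 so a
perfectly calibrated assay (ratio 1) is unchanged; read literally, dividing
by 2× the ratio alone would halve a calibrated value, so the identity-
preserving scale is exposed as `rcc_scale`. The 0.9–1.2 QC window is applied
to the supplied reference ratio; since the window brackets 1, applying it to
the ratio or its reciprocal flags nearly the same assays.

## Synthetic batches

The generator emulates one multiplexed capture batch:
`coverage(s,i) = depth_mean · e_i · (cn(s,i)/2) · dosage(s,i) · 2^N(0, sd)`
rounded to integer read-bases, with per-interval efficiency
`e_i ~ lognormal(0, 0.5)` drawn once per batch (shared by all samples, as in
a real pool), `dosage` halving X intervals for males, and `noise_sd` the SD
of log2-scale multiplicative noise (default 0.1). Defaults are routine
conditions: 8 samples, 1,016 intervals (a realistic cardiomyopathy-panel
size), 5% of targets on chrX, ~100,000 read-bases per interval (≈700× over a
150 bp exon). QC-failing samples get noise inflated 6-fold; "bad baits" (1%
of intervals by default) get 4-fold inflation, producing the small recurrent
artifacts the annotation machinery exists for. An optional Poisson layer on
counts exists behind `poisson_counts`; at these depths count noise is
dominated by capture variation, so multiplicative noise is the primary
model.

What the generator does **not** emulate: GC-dependent coverage waves,
mappability structure, batch-to-batch efficiency drift, pseudo-autosomal
regions, or mosaicism. Passing tests therefore demonstrate the algorithmic
contracts (normalization identities, QC behavior, segmentation correctness,
recovery under well-behaved noise), not clinical sensitivity on real
capture data, which depends on bait-level artifacts the simulation leaves
out.

With `noise_sd = 0` a single-sex batch yields ratios that are exactly zero
(every sample is bit-identical before injection), making the generator an
end-to-end oracle: injected events are recovered with exactly their injected
spans and types.

## Validation experiment sizes

`scripts/acceptance.py` and the acceptance tests use: noiseless 8 × 1,016
batches for the two theoretical constants; 1,000 random 50-interval vectors
against the brute-force segmenter oracle; 300 random batches of 2–8 samples
against exhaustive bipartition search; 50 noisy batches (noise SD 0.1,
uniform — the bad-bait feature is off so every cell has the stated SD) each
carrying one 4-exon deletion and one 4-exon duplication for interval-level
recovery (typically 94–97%, the shortfall concentrated in gains near the
0.40/whisker boundary); and 5 noiseless batches for the zero-false-call
check. The whole script runs in a few seconds on one core.

## Known limitations

* The batch is the reference: a CNV shared by ≥half the batch at an interval
  shifts the median and is partially or wholly normalized away.
* Sex prediction is coverage-dosage only; sex-chromosome aneuploidies appear
  as ordinary X gains/losses relative to the corrected baseline rather than
  as karyotype calls.
* Copy-number estimates on X are relative to the sample's own corrected
  dosage, so an X loss in a male (0 copies) and in a female (1 copy) both
  report `inferred_cn ≈ 1`; interpret together with the predicted sex.
* Breakpoints are at target-interval resolution; no sub-exon localization,
  no statistical significance per call (fixed empirical thresholds only).
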