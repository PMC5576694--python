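# Methods

## The filter cascade

The pipeline assumes variant calling has already been done per sample and
consumes count tables: for each variant key `(chrom, pos, ref, alt)` and
each sample role (N = paired normal, P = pre-treatment tumor, R =
post-treatment resistant tumor), a total read count, a mutant read count,
a mapping quality and a variant quality score. The mutant read frequency
MRF = mutant / total is the only derived quantity; it is undefined (never 0)
when total = 0.

Steps, with the exact inequality conventions used:

| step | rule | convention |
|---|---|---|
| 1 | normal depth | removed iff total_N < 10 (10 survives) |
| 2+3 | germline call | germline iff (mutant_N ≥ 2 and 10 ≤ total_N ≤ 49) or (mutant_N ≥ 3 and total_N ≥ 50); band edges inclusive |
| 4 | tumor depth | removed iff total < 10 in any required tumor role (P and R for strategy B, R for strategy A) |
| 5 | selection | strategy A: MRF_R > 0; strategy B: MRF_R > 2·MRF_P, both strict |
| quality | final gate | kept iff MQ > 20 and QUAL > 20, both strict; missing quality fails |

The quality gate is applied last, only to variants that would otherwise be
selected; earlier removals keep their step-specific outcome so the audit
trace explains every variant exactly once. The variant universe per patient
is every key observed in a tumor role; a variant with no normal observation
is treated as normal depth 0 (step 1 removal, logged). Under strategy B a
variant with no P observation at all is removed at step 4: without a
recorded P depth its pre-treatment coverage cannot be verified, and a
missing observation is not evidence of MRF_P = 0. The "quality score" is the
variant-level QUAL column; genotype-level qualities are ignored — a
documented choice, since count tables rarely carry both.

Monotonicity caveat: raising the depth/MRF/quality thresholds can only
shrink the selected set, but raising the germline-band mutant-read minima
*relaxes* the germline exclusion and can grow it; the two families of
thresholds point in opposite directions by design.

## Prioritization

CADD classes use strict lower bounds: probable effect iff CADD > 20,
possible iff 10 < CADD ≤ 20, below otherwise. Missing scores (e.g.
frameshift rows without a CADD value) are carried as "unclassified" and are
never dropped from mutation counts, and never promoted. Recurrence counts
distinct patients (not biopsies or mutations) with at least one selected
mutation in the gene; the reporting threshold k is a parameter (k = 2 in the
packaged worked example). Gene symbols are compared case-sensitively after
whitespace trimming; alias resolution is out of scope. Database tiers:
absent-from-ExAC + present-in-COSMIC ranks first (likely somatic and
cancer-associated), absent from both second, present in ExAC last (likely a
residual personal variant); missing flags leave a variant untiered, listed
last.

## Pseudo-probe copy number

Input is a sorted, non-overlapping per-window count table (BED-convention
coordinates) whose counts are assumed to come from alignments with mapping
quality > 40. Windows are merged into pseudo probes of a target size
(default 2 kb, valid range 2–5 kb); mean per-base coverage is
`count × read_length / probe_size` with read_length a parameter (default
100 bp), and probes below 1× normal coverage are discarded and counted.

The log2 ratio is log2(tumor/normal) per probe, with a 0.5 pseudo-count
added to both counts only when the tumor count is 0 (flagged), and probes
with normal count 0 flagged unratioable and excluded from medians. GC
correction is median-binned: probes are binned by GC fraction (width 0.01),
the per-bin median log2 ratio defines a piecewise-linear median-vs-GC curve
over bins with at least 10 probes, and each probe subtracts the curve value
interpolated at its own GC (tail bins borrow the nearest well-populated
bin). This removes a multiplicative GC bias of any smooth shape without
tuning; a LOESS fit would be the natural refinement but is not needed at
the bin widths used. Finally the autosomal median is recentred to 0, which
also absorbs any global scaling of either sample. Counts are used as-is
rather than length-normalized because probes are near-uniform in size.

Region calls replace visual inspection with explicit thresholds: gain iff
median log2 ≥ +0.3, loss iff ≤ −0.3 (configurable); a region is discordant
when pre- and post-treatment calls differ. Both profiles must be tiled on
the identical grid. No segmentation algorithm (CBS/HMM) is applied — calls
are per supplied region, defaulting to one region per chromosome.

A side effect of median-based GC correction is a small shrinkage of the
signal inside large aberrant segments (they pull their GC-bin medians
toward themselves); with segments below ~10 % of the genome the bias is
≲ 0.03 log2 units, well inside the calling thresholds.

## Cohort statistics

RECIST 1.1 classes partition the percent-change axis with strict
inequalities: PR iff change < −30, PD iff change > +20, SD on the closed
interval between (so −30 and +20 are SD). ORR counts CR+PR (CR is accepted
in input though the packaged cohort has none); DCR adds SD. Kaplan–Meier
curves and medians come from lifelines; the median is the earliest time
with S(t) ≤ 0.5 and is reported undefined when the curve never reaches 0.5.
Median confidence limits use the Brookmeyer–Crowley log-log interval.
Log-rank is the standard observed-minus-expected chi-square with 1 df;
zero total events is reported as undefined rather than 0. The 2×2 test is
Pearson chi-square without continuity correction, with Fisher's exact test
offered because one expected cell of the packaged TKI table is below 5 —
both give p < 0.001 there. Percentages are reported to the nearest integer,
matching the source tables' formatting.

The packaged fixtures (tables 1–3 of the emulated cohort) are count tables;
`datasets.records_from_table1/2` expand them into per-patient records so the
same `summarize_cohort` path serves fixtures and simulated cohorts. In
table 1, T790M percentages are computed among EGFR-mutation-positive
patients only; wild-type and untested rows carry an undefined T790M flag and
drop out of the denominator.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

**Variants** (`VariantSimSpec`): per patient, `n_germline` heterozygous
germline variants (true allele fraction `germline_vaf`, default 0.5, in all
three samples), `n_shared_somatic` somatic variants with equal pre/post MRF
(`somatic_mrf_pre`, default 0.10), and `n_resistant_specific`
resistant-enriched variants whose post-treatment MRF is `mrf_fold_change`
(default 4) times the pre-treatment MRF — above the doubling threshold by
construction. `n_recurrent_genes` additionally plants one resistant-enriched
variant of a shared gene in two patients each. Total depth is Poisson around
`depth_mean` (default 100×) and mutant reads are binomial given the true
MRF, so mutant ≤ total always; `noise=False` replaces both draws by their
rounded expectations, which is what the exact ground-truth-recovery
contracts use. The study being emulated does not publish depth or tumor
purity; these defaults are this package's choice of a realistic
FFPE-exome scenario, not reported values. All variants carry passing
qualities (MQ 60, QUAL 99); quality-gate behavior is exercised by
explicitly constructed observations in the tests instead.

**Coverage** (`CnvSimSpec`): one synthetic chromosome tiled into windows,
diploid outside `planted_segments`; expected window counts scale with
copies/2 and with a linear multiplicative GC bias
`1 + gc_bias_strength · (GC − 0.5)`, applied to both samples (`shared`,
cancels in the ratio, as real library-prep bias largely does) or to the
tumor only (`tumor_only`, the adversarial case the normalization must fix).
Counts are Poisson; the default GC profile is a slow sinusoid plus jitter
clipped to [0.2, 0.8].

**Cohorts** (`CohortSimSpec`): exponential event times per group (median m ⇒
rate ln 2 / m), independent exponential censoring with rate chosen so the
expected censored fraction equals `censor_fraction` (the independence is
what makes Kaplan–Meier consistent here), and categorical RECIST responses
with a percent-change drawn uniformly inside the matching class interval.
Defaults emulate a second-line TKI cohort: PFS medians 2.8/2.7 months and
OS medians 8.8/3.6 months for T790M-positive/negative groups, response
probabilities PR 0.18 / SD 0.61 / PD 0.21.

What the generators deliberately do not model: tumor purity and subclonal
structure, strand bias and FFPE artifacts, mapping-quality variation,
correlated (non-Poisson) coverage noise, non-proportional hazards and
informative censoring. Passing tests therefore demonstrate the correctness
of the decision rules and estimators under their stated assumptions, not
robustness to those real-data complications.

## Validation problem sizes

Chosen once as the package's own test conditions: exact-recovery runs use
3 patients × 45 planted variants at 100× noise-free depth; oracle
equivalence uses 500-variant random tables concentrated on the rule
boundaries; copy-number recovery uses 100-probe segments at 30× coverage
(600 reads per 2 kb window of 100 bp reads); survival calibration uses
n = 2000 for median recovery (tolerance 0.2 months) and 1000 null
replicates at 50 patients per arm for the log-rank type-I rate
(5 % ± 1.5 %). The one deviation from those example sizes is the
generator-level sample-median check, run at n = 10 000 because its ±0.15
tolerance is only a 1.7 σ band at n = 2000 (≈ 9 % false-alarm rate by
sampling noise alone) and 3.7 σ at the larger n.

## Known limitations

Multi-allelic VCF records are split per alternate allele with the total
depth taken as the sum over all alleles. No tumor-purity correction is
applied to MRFs, so the doubling rule compares raw frequencies; purity
differences between biopsies can mimic or mask enrichment. The CNV module
calls per-region medians only — focal events smaller than a few probes are
invisible. No Cox regression or multiple-testing control is provided (the
analyses reproduced here use none).
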