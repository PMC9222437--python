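# Methods notes

This note records the models, parameter choices, numerical conventions and
known limitations behind `opsinhap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Haplotype model

The canonical panel is eight biallelic SNPs in opsin exon 3, shipped as a
packaged TSV (`data/snp_panel.tsv`) so the same machinery serves *OPN1LW*
and *OPN1MW*. Position order is rs94930, rs713, rs731614, rs5986963,
rs5986964, rs149897670, rs145009674, rs155715655. rs94930 carries the alias
rs949930, which appears in the literature for the same SNP. Five positions
are coding: rs713 (A→M/C→L at 153), rs5986963 (A→I/G→V at 171), rs149897670
(C→A/T→V at 174), rs145009674 (A→I/G→V at 178), rs155715655 (G→A/T→S at
180); rs94930, rs731614 and rs5986964 are synonymous (the codon of rs731614
is not specified in its source and is left unassigned).

The bundled cohort summary table (`data/table1_fixture.tsv`) stores one row
whose published spelling, `GCGGGGAT`, carries G at position 6 where the SNP's
defined alleles are C/T; its published amino-acid string LVVIS requires T at
that position. We treat the allele definitions as authoritative, store the
corrected `GCGGGTAT`, and preserve the published spelling in a
`printed_haplotype` provenance column. Strict parsing rejects the printed
spelling with an error naming the position and SNP; lenient parsing retains
and flags it.

Enumeration of the minigene design space constrains (rs5986963, rs5986964)
to the joint states (A,T)/(G,G) — they co-vary in *OPN1LW* genes — giving
2⁶ × 2 = 128 haplotypes, returned lexicographically sorted.

## SER estimation

`SER = −(AL·a + b·CC) + c` with published calibration (a, b, c) =
(2.03, 0.94, 88.58); CC must be the diopter-valued keratometry mean (the
0.94 coefficient with ~43 D inputs is only dimensionally sensible for
diopters; two keratometry read-outs may be supplied and are averaged, as may
replicate AL reads). Plausibility ranges AL ∈ (15, 35) mm, CC ∈ (35, 52) D
warn by default and can be promoted to errors. `fit_ser_formula` is plain
OLS per record (records, not subjects, are the unit — if both eyes are
supplied both enter the fit); slopes below 1e-10 of the data scale are
snapped to zero so constant-response inputs yield an exactly degenerate fit.
The default analysis eye is the left (OS), matching the source table.

## Splicing assay

Percent skipped is a ratio of peak areas, invariant to common rescaling;
both-areas-zero is an undefined measurement, not 0/0 = 0. Haplotype summaries
are arithmetic means over biological replicates. For per-SNP effects the
summary table is partitioned into matched pairs differing only at the tested
SNP (64 pairs in the full design); the two allele groups are compared with a
two-sided Mann–Whitney U — exact enumeration when min(n) ≤ 12 and both ≤ 20
and there are no ties, otherwise the normal approximation with continuity
and tie corrections. The constrained pair is tested as one unit (its two
joint states), so the full panel yields 7 tests and the Bonferroni divisor
defaults to 7. The effect "fold" is the ratio of allele-group means
(robust to zero-valued members); a mean-of-per-pair-ratios option exists.
The Mann–Whitney treats the 64-vs-64 groups as independent samples, matching
the named test, although the design is paired; identical groups short-circuit
to p = 1. A linear standard-curve check (`standard_curve`) reports
slope/intercept/R² of measured percentages against known template mixes.

## Cohort association

Inclusion filters run in two stages: subject flags (European ancestry,
normal color vision, no prior surgery/injury, single *OPN1LW* sequence)
first, then one pass of the haplotype group-size floor (≥ 4) on the
flag-passing set; the group-size pass is not iterated, which reproduces a
stable 11-group cohort on the bundled table, and the filter is idempotent.
Kruskal–Wallis (tie-corrected, χ² p with k−1 df) is used across haplotype
groups; the all-tied case, where the tie correction is 0/0, is defined as
H = 0, p = 1. The allele dichotomy reports medians, means, the
non-carrier-minus-carrier mean difference, and a Mann–Whitney p (exact for
the small carrier group). Cone-ratio classification rounds %L half-up to an
integer before applying skewed (≥67 or ≤33) vs balanced (34–66), closing the
open intervals the printed thresholds leave; the group comparison defaults
to a Welch t-test (the source does not name its test) with a Mann–Whitney
option.

## Split-halves ranking

Each iteration splits the cohort into two halves, stratified within
haplotype group by default: a group of n contributes ⌊n/2⌋ and ⌈n/2⌉, the
odd member's side decided by a random draw, so every haplotype is present in
both halves. Within each half, haplotypes are ranked by mean SER ascending
(most myopic = rank 1) with fractional mid-ranks on ties; the final rank is
the mean over both halves of all iterations (2000 half-rankings at the
default 1000 iterations — averaging both halves is chosen for symmetry and
lower variance). Consequently each half-ranking, and the final average, sums
to k(k+1)/2. A non-stratified mode splits the pooled cohort; haplotypes
absent from a half contribute no rank for that half.

Randomness is attached to subjects, never to group labels: each iteration
draws per-subject uniforms (from a seed-sequence child, so iterations are
order-independent), and groups are split by sorting their members' draws.
This makes final ranks exactly permutation-equivariant under haplotype
relabelling, which the test suite checks to machine precision.

Read-outs: `rank_mean_correlation` (Pearson r of group mean SER vs final
rank, t-distribution p with k−2 df), and `variance_explained` (per-subject
Pearson r² between SER and the subject's haplotype rank; optionally a
two-predictor OLS adding a 0/1 indicator for *OPN1MW* genes encoding only
MVVVA, reporting the model R² — the source does not define its combination
rule, and a nested OLS is the natural one; it can only increase R²).

The scrambled-label null permutes subject→haplotype assignments (group sizes
preserved), re-runs the ranking, and correlates the scrambled-label final
ranks against the *observed* group mean SERs. Correlating scrambled ranks
against the scrambled cohort's own means would be a self-correlation —
ranks are derived from those means, so it is strong for real and scrambled
data alike (r² ≈ 0.9 in our measurements) and cannot serve as a null; the
validation's purpose is precisely that exchangeable labels carry no
information about the real group structure. Under one fixed scramble the
final ranks converge to that scramble's own mean ordering, not to the flat
(k+1)/2 vector; flatness holds in expectation over scrambles, and is tested
that way.

Two readouts of the direct computation worth recording: Pearson r over the
bundled table's printed mean-SER/rank columns is 0.9332 (r² = 0.871), frozen
into the tests; a published appendix-based value of 0.98 is not recoverable
from the printed columns alone. The per-subject r² depends strongly on the
(unpublished) within-group spread and is checked only as a qualitative band
on synthetic data.

## Population genetics

X-linked Hardy–Weinberg proportions: male carriers q, female one-copy
2q(1−q), two-copy q². Attribution among myopes multiplies carriers/100 by a
penetrance supplied by the caller (never hard-coded) and divides by
myopes/100. Display rounding is two significant figures; full precision is
retained internally. Published sources quote 2.5%, 2.07% and 2.1% for the
same allele frequency in different populations/contexts; frequency is always
an input here.

## Lens trial

Trajectories are normalized to µm of change from the first visit; growth
rates are OLS slopes of µm vs day (≥ 3 points). The arm comparison is a
paired two-sided t-test on within-subject-period experimental−control slope
differences pooled across crossover periods (per-period results are also
emitted; a Wilcoxon signed-rank option exists). Period-2 eyes are new paired
observations with arms swapped, not averaged with period 1. All-zero
differences define p = 1.

## Synthetic generators

* Cohort: group sizes and mean SERs default to the bundled 11-group table
  (413 subjects). Within-group SER SD is not published; 2.0 D is used as a
  typical adult refraction spread and is exposed in ``CohortSpec`` because
  the per-subject variance-explained read-out depends on it directly. %L cones
  are truncated-normal(67, 12) in [0,100], emulating the ~2L:1M European
  average (the study's actual %L distribution is unpublished). The
  cone-ratio effect (0.61 D, balanced group more myopic) and
  *OPN1MW*-MVVVA effect (0.39 D, carrier frequency 64/413) are applied as
  offsets centred within each haplotype group at the realised class
  fractions, so configured group means are preserved exactly while the
  between-class contrast equals the configured effect. CC is drawn
  Normal(43.5, 1.4) D and AL is solved from the SER formula, so
  `estimate_ser` inverts the generator to machine precision.
* Assay: true skip% = 1.0% baseline × per-SNP factors on allele-2 carriers
  (12.7× at rs145009674; 3× and 2× at rs155715655 and rs5986963 encode the
  lesser effects — configuration defaults, not claims); replicates are
  Normal(truth, 1.5) clipped to [0,100], emitted as AUC pairs under a random
  common gain, which the percent formula removes. Clipping at 0 biases the
  low-skipping group's mean slightly upward, so recovered folds sit a little
  below the configured 12.7 (the tests allow for this).
* Trial: per-eye true slopes Normal(arm rate, 1.2 µm/day) with 10 µm
  per-point noise at biweekly visits over 84 days; those two noise values
  were back-solved once so simulated arm standard errors approximate the
  published ±0.33/±0.24 µm/day at 20 eyes per arm. 13 subjects in period 1;
  the first 7 re-enroll with lenses swapped.

Seeds flow through `numpy.random.SeedSequence` everywhere; equal seeds give
identical outputs.

## What passing tests do and do not show

The generators draw Gaussian (or truncated-Gaussian) noise around configured
group structures. Real cohorts have non-Gaussian, heteroscedastic SER
distributions (the reason the primary test is rank-based), measurement error
in AL/CC rather than phenotype-consistent biometry, and %L estimates with
their own uncertainty; real assay noise is not symmetric near 0% skipping;
real eyes do not grow exactly linearly. Parameter-recovery tests therefore
validate the estimators and the pipeline plumbing under the stated
conditions — they do not re-establish the empirical findings, and
subject-level statistics (the dichotomy medians, the per-subject r², exact
p-values) that depend on the unreleased raw data are checked only as
qualitative bands.

## Problem sizes used in checks

Acceptance recomputations use ~500 synthetic control-arm eyes for the
growth-rate recovery and 200 replicate cohorts for the cone-ratio recovery;
the Kruskal–Wallis type-I-error check uses 1000 null replicates; split-halves
convergence is checked at 5000 iterations across two seeds (agreement within
0.1 rank units). These sizes give Monte-Carlo standard errors comfortably
below the tolerances tested and run in seconds.
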