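# opsinhap

Analysis toolkit for studying how exon-3 haplotypes of the X-linked cone
opsin genes (*OPN1LW*, *OPN1MW*) relate to common myopia, and for evaluating
contrast-reducing spectacle lenses that slow axial eye growth.

## Who this is for

Vision-science and ophthalmic-genetics groups who genotype the Xq28 opsin
array, measure ocular biometry (IOL-Master axial length and keratometry), run
minigene splicing assays, or run paired-eye lens trials — and want the whole
analysis chain as tested, scriptable functions rather than one-off
spreadsheets.

## What it computes

**Haplotypes.** An exon-3 haplotype is the joint allele configuration at
eight SNPs (rs94930, rs713, rs731614, rs5986963, rs5986964, rs149897670,
rs145009674, rs155715655), written as an 8-nucleotide string. Five positions
are non-synonymous and determine opsin residues 153/171/174/178/180 (e.g.
`AACGGTGG` → MVVVA). Because rs5986963/rs5986964 occur only as (A,T) or
(G,G), the full minigene design space is 2⁶ × 2 = 128 haplotypes.

**Refraction from biometry.** Spherical equivalent refraction in diopters is
estimated as

    SER = −(AL · 2.03 + 0.94 · CC) + 88.58

with AL the axial length (mm) and CC the keratometric corneal power (D);
`fit_ser_formula` re-derives such a formula from any calibration table by
OLS.

**Exon-3 skipping.** From allele-specific primer-extension peak areas,
`% skipped = 100 · AUC_A / (AUC_A + AUC_T)`; per-SNP allele effects over the
128-minigene design are tested on 64 matched pairs with a two-sided
Mann–Whitney U, Bonferroni-corrected over 7 SNPs.

**Split-halves risk ranking.** The cohort is repeatedly halved at random;
haplotypes are ranked by mean SER within each half (rank 1 = most myopic);
final rank = the average over all half-rankings of 1000 iterations. Read-outs:
Pearson correlation of final ranks vs group mean SER, the per-subject rank-SER
r² (variance in refraction attributable to the haplotype), and a
scrambled-label null that re-runs the procedure on permuted subject→haplotype
assignments.

**X-linked carrier arithmetic.** For allele frequency q: males carry it with
probability q; females 2q(1−q) (one copy) and q² (two); attribution among
myopes = carriers × penetrance / prevalence.

**Lens trial.** Per-eye axial-length trajectories are normalized to µm from
baseline, growth rates fitted by OLS (µm/day), and experimental vs control
arms compared with a paired t-test on within-subject-period slope
differences pooled across crossover periods.

**Synthetic data.** Generators reproduce the study conditions for all three
domains (11 haplotype groups totalling 413 subjects; 128 minigenes × 2
replicates at 1.5-point assay noise; 13 + 7 crossover subjects) so every
analysis is testable without any restricted data.

## Worked example

```python
import opsinhap as oh

oh.translate_haplotype("AACGGTGG")        # 'MVVVA'
oh.estimate_ser(al_mm=25.1, cc_d=44.0)    # -3.733 D

subs  = oh.generate_cohort(oh.CohortSpec(seed=17))        # 413 subjects
ranks = oh.split_halves_rank(subs, oh.SplitHalvesConfig(1000, seed=17))
corr  = oh.rank_mean_correlation(oh.summarize_groups(subs), ranks)
corr.r, corr.r_squared                    # (0.9812, 0.9627)
oh.variance_explained(subs, ranks).r_squared   # 0.1026

d = oh.allele_dichotomy(subs, "rs145009674", "G")
d.group_sizes                             # {'G': 12, 'not_G': 401}
round(d.effect, 2), round(d.p_value, 4)   # (1.82, 0.0028)
```

The final ranks place `AACGGTGG` (MVVVA, the strongest exon-skipping
haplotype) most myopic at rank 1.1 and `GCCGGCAG` least at 10.59; group mean
SER correlates with rank at r = 0.98 on this draw, and the haplotype rank
explains ~10% of per-subject SER variance (a quantity sensitive to the
assumed within-group spread). The 12 carriers of G at rs145009674 are, on
average, 1.8 D more myopic than non-carriers here. Re-running the ranking on
scrambled labels (100 scrambles, 200 iterations each) gives a median null
r² of 0.066 with 91% of scrambles non-significant — the procedure invents no
association.

A command-line interface mirrors the library:

```
opsinhap simulate cohort --seed 17 --out cohort.tsv
opsinhap rank run --input cohort.tsv --iterations 1000 --seed 17 --out rank.json
opsinhap popgen carriers --q 0.021
opsinhap trial analyze --input trial.tsv --test paired-t
```

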