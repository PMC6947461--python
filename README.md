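# chimseq

Simultaneous monitoring of **donor chimerism** and **minimal residual
disease (MRD)** after allogeneic hematopoietic stem cell transplantation
(allo-HSCT), computed from the per-position A/C/G/T read counts of a
clinical NGS myeloid gene panel. The package is aimed at laboratory
bioinformaticians running myeloid panels (e.g. for MDS/AML follow-up)
who want engraftment and residual-disease answers from the same
sequencing run, without a dedicated chimerism assay.

## What it computes

**Donor chimerism.** At a biallelic panel SNP where the donor is
homozygous and the recipient's pre-transplant genotype differs, the
donor cell fraction is identifiable from the post-transplant allele
counts. Writing A for the donor's homozygous allele and a for the other
panel allele, the per-SNP donor allele burden is

| donor | recipient | burden |
|-------|-----------|--------|
| AA    | aa        | A/(A+a) |
| aa    | AA        | a/(A+a) |
| AA    | Aa        | 1 − 2·a/(A+a) |
| aa    | Aa        | 1 − 2·A/(A+a) |

and donor chimerism is 100× the unweighted mean of the per-SNP burdens
(clamped to [0, 1]). Genotypes are called from the ref/alt count
fractions: homozygous at 0.90–1.00, heterozygous when both alleles fall
in 0.45–0.60. Panel SNPs are pre-selected per cohort by heterozygosity
window (0.2–0.8), mean depth > 500×, background error ≤ 0.2 %, and
heterozygous measurement error < 10 %.

**MRD.** The mutant allele burden (MAB) of a patient-specific mutation
is 100× mutant-base reads / total depth. A marker-specific limit of
blank, LoB = mean %BE + 3 SD over mutation-negative samples, separates
signal from sequencing background; MAB strictly above the LoB is
MRD-positive.

**Method comparison.** Against a reference method (STR fragment
analysis) the package computes least-squares r², a Bland–Altman
analysis with a ±3 SD agreement band, and sensitivity / specificity /
PPV / NPV / overall agreement for the "complete donor chimerism" call
at configurable cutoffs (99 / 95 / 90 %).

A seeded simulator (Hardy–Weinberg genotypes, two-component cell
mixture, multinomial read sampling with uniform substitution error,
mutation spike-ins) makes the whole pipeline testable end to end, and a
packaged clinical validation series (14 MDS transplant cases, 25
post-transplant samples with paired STR/NGS chimerism and tracked
mutation burdens) backs the statistics.

## Worked example

Simulate a transplant with a true donor fraction of 0.80 at 1000×
depth, then estimate it back:

```bash
chimseq simulate --n-snps 60 --donor-fraction 0.8 --depth 1000 --seed 7 --out-dir simdemo
chimseq chimerism --panel simdemo/panel.tsv \
    --donor simdemo/donor_counts.tsv \
    --recipient simdemo/recipient_counts.tsv \
    --post simdemo/post_counts.tsv \
    --out simdemo/chimerism.json
```

prints

```
donor chimerism 80.58% (11 informative SNPs)
```

Of the 60 simulated SNPs, 11 fell in one of the four informative
donor/recipient configurations for this genotype draw; averaging their
burdens recovers the true 80 % donor fraction to within sampling noise
(SD across SNPs 1.0 percentage point). The concordance statistics on
the packaged clinical series:

```bash
chimseq concordance --out concordance.json
```

```
n=24 pairs, r^2=0.9861 -> concordance.json
```

The JSON report contains, per cutoff, the 2×2 table and derived rates —
at the 99 % cutoff: sensitivity 100 %, specificity 91.7 %, PPV 92.3 %,
NPV 100 % — plus the Bland–Altman summary (mean difference 0.71
percentage points, no pair outside the ±3 SD band).

Other subcommands: `qc-panel` (cohort marker selection), `mrd` (MAB vs
LoB calls), `filter-variants` (population-frequency and evidence
filtering of annotated variants to MRD markers).

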