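# Methods

## Model

A post-transplant blood or marrow sample is modelled as a two-component
mixture of donor- and recipient-derived diploid cells with donor
fraction f ∈ [0, 1]. At a biallelic SNP the expected fraction of the
alt allele among reads covering the two panel alleles is

    E[alt fraction] = f · d_D / 2 + (1 − f) · d_R / 2

where d_D, d_R ∈ {0, 1, 2} are the alt-allele dosages of donor and
recipient. When the donor is homozygous and the genotypes differ, f is
recovered from the post-transplant counts of the donor allele A and the
other panel allele a by one of four configuration-specific estimators
(A/(A+a), a/(A+a), 1 − 2·a/(A+a), 1 − 2·A/(A+a)); each is exact on
error-free expected counts, which the test suite checks to machine
precision. Donor-heterozygous pairs admit no single-formula estimator
of this form and are treated as non-informative. Donor chimerism is
100× the unweighted mean of the per-SNP estimates.

Assumptions: autosomal diploid loci (sex-chromosome SNPs are excluded
from the panel by default, configurable), a single donor, no
copy-number change at the SNPs, and sequencing error small relative to
the genotype-calling bands.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| hom band | major-allele fraction 0.90–1.00 | homozygous genotype call |
| het band | both fractions 0.45–0.60 | heterozygous genotype call |
| het-frequency window | 0.2–0.8 | candidate panel SNPs by population heterozygosity |
| depth criterion | mean > 500× | marker QC over the cohort |
| %BE criterion | ≤ 0.2 % | reads on neither panel allele |
| %ME criterion | < 10 % | het allele-count imbalance |
| LoB multiplier | 3 | LoB = blank mean + 3·SD |
| MRD call | MAB > LoB, strict | positive strictly above threshold |
| concordance cutoffs | 99 / 95 / 90 % | complete-chimerism call, inclusive (≥) |

Genotype fractions and burden denominators use the two panel alleles
only; the other two bases are background. MAB uses the full four-base
depth as denominator, the conventional allele-burden definition, at
hemizygous loci as well. Comparison operators follow the validated
assay settings exactly (depth strictly >, BE ≤, ME strictly <, MRD
strictly >, chimerism cutoff ≥).

## Design choices where the design was open

- **Out-of-range burdens are clamped to [0, 1] before averaging**, not
  excluded: sampling noise pushes estimates slightly past the
  boundaries at f near 0 or 1, and exclusion would bias the mean by
  censoring one tail. Clamped markers remain visible in the per-SNP
  report.
- **Unweighted means everywhere** (across SNPs for chimerism, across
  samples for QC aggregation): depth weighting would let a few
  high-depth amplicons dominate and complicates interpretation for
  marginal gains at panel depths.
- **%BE for marker QC is per-sample-then-averaged**, not pooled across
  reads, so each sample contributes equally regardless of its depth.
- **Markers never observed heterozygous in the QC cohort pass the ME
  criterion vacuously** but are flagged (`me_evaluable`), since the
  criterion is a condition on het calls and absence of evidence should
  not discard an otherwise clean marker.
- **Genotype fractions in the gap (0.60, 0.90) give no call** and the
  marker is dropped for that donor–recipient pair; an ambiguous
  genotype must not seed a burden formula.
- **LoB uses the sample SD (n−1)**, standard limit-of-blank practice.
- **Bland–Altman uses raw differences in percentage points** with the
  band at mean ± 3 SD; both axes are already percentages, so relative
  differences would only distort the low-chimerism end.
- **Tier assignment is a small configurable evidence map** (catalogue
  recurrence ≥ 10 → tier 1; retained on recurrence > 3 or
  LoF-in-LoF-gene → tier 2; rare but evidence-light → tier 3; common →
  tier 4). Clinical tiering guidelines are a framework, not an
  algorithm; the map is an explicit approximation and all database
  evidence arrives as input columns, never live queries.

## Simulator

The generator emulates the assay's study conditions: panel SNPs with
population heterozygosity drawn in 0.2–0.5 (Hardy–Weinberg caps
heterozygosity at 0.5; the minor-allele branch p = (1 − √(1 − 2h))/2
inverts it), unrelated donor/recipient genotypes (a full-sibling mode
shares parental haplotypes, which reduces informative-SNP counts as
with related donors), fixed per-locus depth of 1400× by default
(matching the assay's mean on-target depth), multinomial read sampling,
and a uniform per-base substitution error of 0.1 % — the magnitude of
panel-wide background error in a well-behaved hybrid-capture run. An
analytic mode replaces sampling with largest-remainder-rounded expected
counts for closed-form checks. Mutation spike-ins redraw the mutant
base Binomial(depth, MAB) and redistribute the remainder
proportionally, preserving depth.

Not emulated: read-level artefacts (PCR duplicates, strand bias,
context-specific error spectra, alignment error), indels, copy-number
change, and contamination. Passing tests therefore demonstrate the
correctness of the count-to-result algorithm under the stated sampling
model, not robustness to upstream artefacts in real libraries — the
marker QC criteria exist precisely to exclude loci where real data
deviate from this model.

## Numerical notes

- Fractions are exact ratios of integer counts; no smoothing or priors.
- Zero denominators (no reads on the panel alleles, zero depth) raise
  or skip with a logged reason — they are never imputed as 0.
- Chimerism with zero informative markers is a hard error, not 0 %.
- Reported chimerism is rounded to 2 decimals in outputs; internal
  values keep full precision. Reproducibility is bit-exact under a
  fixed seed.
- Problem sizes in the test suite and acceptance script — 30
  informative SNPs at 1000× with 100 replicates per donor fraction,
  1000 simulated blanks at 10⁴× for the LoB convergence check — were
  chosen so that binomial standard errors sit an order of magnitude
  below the asserted tolerances.

## Known limitations

- Single-donor transplants only; no lineage-sorted (CD34+) chimerism.
- Donor-het configurations are discarded rather than combined into a
  two-SNP estimator; with typical panels the informative-SNP count is
  ample, so the simplicity is worth the lost markers.
- The clamped mean is slightly biased toward the interior near f = 0
  and f = 1 (≈ 0.5 percentage points at 1000× with 30 markers, per the
  recovery measurements); reporting raw per-SNP values alongside makes
  this auditable.
- Recomputing r² from rounded percentages in the packaged series gives
  0.986; the value is sensitive in its third decimal to the rounding of
  the inputs, so tests bound it (> 0.98) rather than pin it.
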