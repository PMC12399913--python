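# Methods

## Scope and data model

`recurvar` operates downstream of variant calling and annotation. Its unit of
analysis is the *observation*: one decomposed alt allele in one patient,
carrying the genotype metrics needed for QC (GT, DP, GQ, allele depths, the
record's FILTER status) and an annotation bundle (gene symbol, consequence
class, HGVS protein change, four population allele frequencies, five
pathogenicity predictor outputs). Multi-allelic records are decomposed to one
observation per alt; decomposed allele pairs are normalized by trimming the
shared suffix, then the shared prefix (keeping at least one base), which
left-aligns simple indels. Coordinates are 1-based, as in VCF. Hemizygous
genotypes on sex chromosomes are treated as homozygous-alt: the only
genotype-level rule that distinguishes zygosity is the allele-balance check,
which by definition applies to heterozygotes only.

## Prioritization cascade

Stages run in a fixed order, and each observation is excluded at the first
stage it fails, with the reason tallied:

1. **FILTER pass.** Records not marked `PASS` are dropped first; the reader
   deliberately keeps them (with status preserved) so the exclusion is
   visible in the ledger rather than silent at parse time.
2. **Genotype QC.** GQ ≥ 20; DP ≥ 10 (≥ 5 on chrX/chrY); for heterozygotes,
   allele balance AD_alt/(AD_ref+AD_alt) within [0.2, 0.8], bounds
   inclusive. A heterozygote without allele depths is a hard error — allele
   balance cannot be evaluated, and guessing would corrupt the ledger.
3. **Rarity.** The maximum allele frequency across the four population
   sources must be strictly below 0.01; a missing frequency contributes 0
   (absence from a population database is treated as "not observed", the
   convention for rare-variant filters). A variant at exactly 0.01 is
   excluded. The max-across-sources rule means one database suffices to
   disqualify a variant.
4. **Consequence.** Only missense, nonsense, stop-loss, splicing-region and
   frameshift-indel classes continue; synonymous, intronic, intergenic and
   other classes are excluded. Splicing variants are kept within the
   "protein-altering" set even though they carry no protein coordinate.
5. **Consensus-benign vote.** Each predictor casts benign/deleterious/abstain:
   SIFT deleterious below 0.05 (tool-native direction), PolyPhen2-HumDiv
   deleterious at ≥ 0.435, PolyPhen2-HumVar at ≥ 0.445, CADD at ≥ 5 on the
   Phred-like scale, MutationTaster deleterious for D/A and benign for N/P.
   Ties at a cutoff go to deleterious for the ≥-style cutoffs, mirroring the
   inclusive style of the rarity threshold. A **missing score abstains**: a
   variant is consensus benign only on ≥ 3 *actual* benign calls. This is the
   conservative reading — an unscored variant is never excluded for
   benignity — and it is asymmetric on purpose: missing frequencies default
   toward retention too.

The survivor ledger enforces three invariants: stage counts are
non-increasing; retained = Σ of the five per-class counts; and
input = retained + Σ exclusion reasons. PolyPhen2 contributes two voters
(HumDiv and HumVar), which is why the panel has five voters over four tools.

## Recurrence

A gene is recurrently mutated when `carrier_count ≥ ⌈f·n⌉` with f = 0.30 by
default — **distinct patients**, not variant tallies, because a cohort
fraction is a statement about patients; a raw variant-level tally is exposed
alongside for comparison. The ceiling is computed with a 1e-9 slack so that
binary float noise (0.30 × 50 is not exactly 15 in floats) cannot shift the
threshold. The mutational-print matrix shows one class per gene × patient
cell with precedence frameshift > nonsense > stop loss > splicing >
missense — more disruptive classes win, a display rule only. Chromosome
density is (retained observations in r.m. genes per chromosome) divided by
that chromosome's protein-coding gene count, with the across-chromosome
median exposed as the reference line. Per-patient burden outliers use the
Tukey upper fence (Q3 + 1.5·IQR); the fence is a flag, not an exclusion.

## Exact association

Carrier status per gene (≥ 1 retained variant) is cross-classified against a
binary covariate. Built-in covariates: very-early onset (onset age ≤ 20 vs
> 20 years), female sex, cardiomyopathy. The test enumerates the
hypergeometric distribution of cell *a* over its support given fixed
margins; the two-sided p sums probabilities ≤ the observed one, with a
relative tie tolerance of 1e-7 so floating-point noise cannot exclude
genuinely tied tables (the same convention R's `fisher.test` uses).
Degenerate margins give p = 1 with a flag.

Two OR flavors are reported because they answer differently at zero cells:
the sample OR ad/bc (0 or ∞ at single zero cells, undefined for a zero
diagonal), and the conditional MLE, the default "OR" column. The CMLE solves
the score equation E_ψ[a] = a_obs on the log-odds scale by bracketed Brent
root-finding on log-sum-exp–stabilized weights; when a sits at the support
boundary the estimate is 0 or ∞. The exact CI inverts the one-sided tail
tests: the lower limit solves P_ψ(A ≥ a) = α/2, the upper solves
P_ψ(A ≤ a) = α/2, with one-sided intervals at boundary tables. Root-finding
runs at xtol 1e-12, so the package's endpoints satisfy the defining tail
equations to ~1e-13 (tighter than R's uniroot default, which is why
cross-checks against R agree to ~1e-2 on CI endpoints but the tail equations
agree exactly).

BH adjustment is the standard step-up with enforced monotonicity and stable
tie handling; the family is all genes tested within one covariate analysis.
For plot exports only, ORs are clamped into [0.01, 100]; finite values
beyond the caps are clamped too, keeping the log2 plot column bounded, while
raw columns are never modified.

## Hotspots

The HGVS `p.` parser accepts one- and three-letter codes (three-letter
normalized via Biopython's IUPAC table), an optional `p.` prefix, stop as
`*`/`Ter`, frameshifts with truncated `fs*N` suffixes, and spans
(`p.X12_Y14del`) mapped to the first affected residue. Unparseable or absent
strings make the observation *unmapped* (counted, never fatal), so
mapped + unmapped equals the observations passed in. Positions beyond the
registry protein length — transcript-isoform mismatches — are quarantined
with a warning rather than clipped or dropped silently. Per-position counts
are (patient, variant) observations by default, so distinct substitutions at
one residue sum; a distinct-patient toggle is provided.

## Crosswalk

Single-cell inputs are consumed strictly as summary tables (any upstream
toolchain may produce them). DE overlays rank by log2FC descending
(configurable) with alphabetical tie-break. Over-representation is the
hypergeometric upper tail P(X ≥ overlap), sharing scipy's hypergeometric
engine with the exact-test module. Composition differences are percentage
points per cell type; per-condition percentages sum to 100 and differences
sum to 0 by construction.

## Synthetic cohort generator

The generator's defaults describe a 50-patient early-onset arrhythmia-style
cohort: female probability 0.42; onset age from a truncated normal
(mean 22.16, SD 9.21, bounds 9–49 years) rounded to whole years; category
probabilities atrial 0.76 / ventricular 0.20 / general 0.04; cardiomyopathy
conditional on category (0.50 ventricular, 0.053 atrial, 1.0 general, which
reconstructs an expected 9/50 positives); 132 planted r.m. genes with
carrier counts uniform on [15, 40] sampled **without replacement**, so
recurrence recovery is exact rather than probabilistic; a target median
retained burden of 452 with one patient's background scaled ×3.6 as a burden
outlier; and two planted associations (OR 9.71 against very-early onset at
baseline carrier probability 0.20, OR 3.41 against female sex at baseline
0.30).

Design choices worth stating:

- **Association genes are r.m. genes.** Associations are tested among
  recurrently mutated genes, so the planted association genes count inside
  `n_rm_genes`. Their carriers are drawn per covariate group at the
  probabilities (baseline, OR) imply — p1 = OR·odds0/(1 + OR·odds0) — and
  the draw is repeated if the total falls below the recurrence threshold.
  With defaults the expected carrier counts are ~21–23 against a threshold
  of 15, so redraws are rare and the conditioning negligible; the manifest
  records the *realized* 2×2 table, which downstream recovery is checked
  against.
- **Background genes are capped at threshold − 1 carriers** during
  assignment, so the r.m. caller can produce no false positives by
  construction and planted-set recovery is an exact equality.
- **Burden calibration** is analytic: the background Poisson mean is the
  target median minus the expected planted contribution (planted gene
  carrier mass per patient plus the covariate-weighted association carrier
  probabilities). Poisson medians track their means closely at these rates,
  and the planted contribution concentrates (SD ≈ 6 at defaults), so the
  realized cohort median lands within a few percent of the target. A
  negative-binomial option (`burden_dispersion`) exists because real
  per-patient burden is likely overdispersed.
- **Fates are constructive.** Decoys are built to violate exactly the rule
  their fate names: QC decoys break one genotype rule (non-PASS FILTER, GQ,
  DP with the sex-chromosome threshold, or allele balance); common decoys
  get one frequency ≥ 0.01; benign decoys get ≥ 3 actual benign-side scores;
  non-exonic decoys get excluded consequence classes; retained variants get
  rare frequencies, retained-class consequences, and at most 2 benign votes,
  with missing scores (NA masking) only where they cannot change the fate.
  Decoy volumes default to 0.05/0.15/0.45/0.20 of the target burden per
  patient for QC/common/benign/non-exonic respectively — the benign fraction
  mirrors a callset in which roughly 40% of exonic rare variants fail the
  consensus vote.
- Variant sites are reused across patients with probability 0.5 within a
  (gene, fate) pool, giving shared-site recurrence for hotspot tracks while
  keeping (patient, site) pairs unique.

**What the generator does not emulate:** linkage and haplotype structure,
mutational signatures, per-gene length-dependent mutability, annotation
errors (wrong gene or consequence), relatedness, population stratification,
or realistic chromosome assignment (genes are distributed round-robin).
Passing recovery tests on this generator therefore demonstrates the
*pipeline's* correctness — that every rule triggers exactly when it should
and the planted structure is recovered — not robustness to the biological
messiness of real exomes.

## Problem sizes in the shipped checks

The test suite exercises a scaled-down cohort (20 patients, 12 planted
genes, target burden 60) for pipeline-level properties and the full default
cohort (50 patients, 132 genes, target 452, ~40k observations) in the
acceptance path; CI coverage is simulated at 200 patients/arm over 500
replicates, and association recovery at 5,000 per arm averaged over 10
seeds. These sizes make the whole suite run in well under a minute while
keeping every check at the scale its claim concerns.

## Known limitations

- The association module tests marginal 2×2 associations only — no
  covariate adjustment, regression, or permutation testing; with ~50
  patients, exact tests are the honest tool, and the FDR family is one
  covariate's gene list.
- Carrier status collapses allele counts: a patient with two retained
  variants in a gene counts once, and zygosity is ignored (no dominant /
  recessive modeling).
- One gene symbol per variant; overlapping transcripts must be resolved by
  the upstream annotator.
- The rarity filter trusts the annotation table's frequencies; there is no
  internal cohort-frequency filter.
- HGVS parsing covers substitutions, stops, frameshifts, duplications,
  deletions and extensions in the common dialects, not the full HGVS
  grammar; exotic descriptions land in the unmapped counter by design.
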