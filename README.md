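# recurvar

Rare-variant prioritization, gene-recurrence calling, and exact
genotype–phenotype association for small, deeply phenotyped disease cohorts —
built around the kind of whole-exome study design used for cardiac
arrhythmia cohorts (tens of patients, no matched control exomes), where the
signal of interest is *which genes are recurrently hit by rare deleterious
variants* and *whether carrying such a gene tracks a clinical covariate*.

## What it computes

**Prioritization cascade.** Per-patient variant observations (decomposed VCF
genotypes) pass through, in order: VCF `FILTER = PASS`; genotype QC
(genotype quality ≥ 20, depth ≥ 10 on autosomes / ≥ 5 on sex chromosomes,
allele balance within [0.2, 0.8] for heterozygotes); population rarity
(maximum allele frequency across 1000 Genomes / gnomAD / ExAC / in-house
sources **< 0.01**, missing frequencies treated as 0); protein-altering
consequence (missense, nonsense, stop loss, splicing, frameshift indel); and
a consensus-benign exclusion — a variant called benign by **≥ 3 of 5**
predictors (SIFT < 0.05, PolyPhen2-HumDiv ≥ 0.435, PolyPhen2-HumVar ≥ 0.445,
CADD ≥ 5 on the Phred scale, MutationTaster D/A deleterious vs N/P benign;
missing scores abstain) is dropped. Every exclusion is tallied, so
`input = retained + Σ excluded`.

**Recurrence.** A gene is *recurrently mutated* (r.m.) when at least
⌈f·n⌉ distinct patients (default f = 0.30) carry a retained variant in it.
Downstream summaries: the gene × patient mutational-print matrix,
per-chromosome variant density normalized by protein-coding gene count,
the deleteriousness-vote histogram, and per-patient burden with Tukey-fence
outlier flags.

**Association.** For each gene g and binary covariate x (very-early onset
≤ 20 y, female sex, cardiomyopathy), the 2×2 carrier table is tested with
Fisher's exact test. Writing ψ for the odds ratio, the two-sided p-value
sums hypergeometric probabilities of all tables with the observed margins
that are no more probable than the observed one; the reported OR is the
conditional MLE — the ψ maximizing the Fisher noncentral hypergeometric
likelihood, i.e. solving E_ψ[a] = a_obs — with the exact CI from inverting
one-sided tail tests at α/2 (the quantities R's `fisher.test` prints).
P-values are Benjamini–Hochberg adjusted across genes. For log-scale plot
exports, ORs of 0 / ∞ are capped to 0.01 / 100 (visualization only; raw
values are preserved).

**Hotspots.** HGVS `p.` strings (one- or three-letter) are parsed and
retained variants are mapped onto protein coordinates as per-residue
recurrence "lollipop" tracks.

**Crosswalk.** The r.m. gene set is projected onto external single-cell
summaries: DE tables (gene, log2FC, adjusted p, cell type) get rank overlays
and hypergeometric over-representation tests; composition tables yield
per-cell-type percentage differences between conditions.

**Synthetic cohorts.** A seedable generator produces clinical tables,
annotated variant tables and VCFs with planted r.m. genes (exact carrier
sets), planted covariate-associated genes (carrier probabilities implied by
a baseline probability and a true OR), background burden calibrated to a
target median, and fate-tagged decoys that each violate exactly one filter
rule — plus a ground-truth manifest, so pipeline recovery is testable
end-to-end.

## Worked example

```python
from recurvar import (GeneratorConfig, PlantedAssociation, generate_cohort,
                      prioritize_cohort, summarize_genes, burden_summary,
                      CovariateAssociation, rm_threshold)
from recurvar.io import retained_to_frame

config = GeneratorConfig(
    n_patients=20, n_rm_genes=10, rm_carrier_min=6, rm_carrier_max=15,
    target_median_burden=60, n_background_genes=500,
    planted_associations=[PlantedAssociation("ASSOC_ONSET", "very_early_onset",
                                             true_or=9.71, baseline_carrier_prob=0.20)],
    seed=5)
clinical, observations, annotations, registry, manifest = generate_cohort(config)

retained, ledger = prioritize_cohort(observations, annotations)
print(f"retained {ledger.retained_count} of {ledger.input_count} observations")

frame = retained_to_frame(retained)
print(f"median burden per patient: {burden_summary(frame, clinical).median}")

summaries = summarize_genes(frame, clinical)
rm_genes = [s.gene for s in summaries if s.is_rm]
print(f"{len(rm_genes)} recurrently mutated genes at threshold "
      f"{rm_threshold(len(clinical), 0.30)}")

results = CovariateAssociation(frame, clinical, "very_early_onset", genes=rm_genes).fit()
print(results.summary(max_rows=3))
```

prints

```
retained 1150 of 2125 observations
median burden per patient: 57.0
10 recurrently mutated genes at threshold 6
Exact gene-covariate association: covariate=very_early_onset, genes=10, CI level=95%
==============================================================================
       gene  a  b  c  d        p    q_bh or_cmle ci_low ci_high
ASSOC_ONSET  6  3  0 11 0.002167 0.02167     inf  2.376     inf
      RM005  5  6  1  8   0.1571  0.7856   6.072 0.4866   353.8
      RM007  5  7  1  7   0.3246       1   4.635  0.369   269.6
... (7 more genes)
```

The filter retained 1,150 of 2,125 observations (the rest excluded by QC,
rarity, consequence class or consensus-benign vote, per the ledger); the
median per-patient burden (57) sits at the calibration target (60) up to
sampling noise; all 10 planted r.m. genes are recovered; and the planted
onset-associated gene is the top association — all 6 of its early-onset
carriers versus none of the late-onset non-carrier group, an infinite sample
OR whose exact CI lower bound (2.38) excludes 1, surviving FDR adjustment.

The same pipeline is scriptable from the shell via the `recurvar` command
(`simulate`, `validate`, `filter`, `recur`, `assoc`, `hotspots`,
`crosswalk`); each subcommand reads/writes plain TSV + JSON.

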