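"""Recurrently-mutated (r.m.) gene calling and cohort-level summaries.

A gene is recurrently mutated when at least a set fraction of the cohort
(default 30%) carries one or more retained rare deleterious variants in it.
Recurrence counts *distinct carriers*, not raw variant tallies; a raw
variant-level tally is exposed alongside for comparison. Downstream
summaries: the gene x patient mutational-print matrix (one display class per
cell), variant counts per chromosome normalized by protein-coding gene
count, the deleteriousness-vote histogram, and the per-patient burden
summary with Tukey-fence outlier flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ClinicalRecord, GeneRegistry

#: display precedence in the mutational print: more disruptive classes win
DISPLAY_PRECEDENCE = ["frameshift_indel", "nonsense", "stoploss", "splicing", "missense"]

DEFAULT_RM_FRACTION = 0.30


@dataclass
class GeneRecurrenceSummary:
    gene: str
    carrier_count: int
    variant_count: int
    counts_by_type: dict
    is_rm: bool


@dataclass
class MutationalPrint:
    matrix: pd.DataFrame        # gene x patient, values in DISPLAY_PRECEDENCE or "none"
    gene_totals: pd.Series      # retained observations per gene
    patient_totals: pd.Series   # retained observations per patient


@dataclass
class ChromDensity:
    table: pd.DataFrame         # chrom, rm_variant_count, protein_coding_gene_count, density
    median_density: float


@dataclass
class BurdenSummary:
    per_patient: pd.Series      # retained variant count per patient (cohort-complete)
    median: float
    q1: float
    q3: float
    outlier_threshold: float
    outliers: list = field(default_factory=list)


def rm_threshold(cohort_size: int, fraction: float = DEFAULT_RM_FRACTION) -> int:
    """Smallest integer carrier count at or above ``fraction`` of the cohort."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if cohort_size < 1:
        raise ValueError(f"cohort_size must be >= 1, got {cohort_size}")
    # guard against float noise pushing an exact product over the next integer
    return int(math.ceil(fraction * cohort_size - 1e-9))


def summarize_genes(retained: pd.DataFrame, clinical: list[ClinicalRecord],
                    fraction: float = DEFAULT_RM_FRACTION) -> list[GeneRecurrenceSummary]:
    """Per-gene carrier and variant tallies with the r.m. call at the
    cohort-fraction threshold (inclusive)."""
    threshold = rm_threshold(len(clinical), fraction)
    summaries = []
    if retained.empty:
        return summaries
    for gene, grp in retained.groupby("gene", sort=True):
        carriers = grp["patient_id"].nunique()
        by_type = grp["consequence"].value_counts().to_dict()
        summaries.append(GeneRecurrenceSummary(
            gene=str(gene),
            carrier_count=int(carriers),
            variant_count=int(len(grp)),
            counts_by_type=by_type,
            is_rm=carriers >= threshold,
        ))
    return summaries


def gene_summary_frame(summaries: list[GeneRecurrenceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"gene": s.gene, "carrier_count": s.carrier_count,
               "variant_count": s.variant_count, "is_rm": s.is_rm}
        for cat in DISPLAY_PRECEDENCE:
            row[f"n_{cat}"] = s.counts_by_type.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["carrier_count", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def mutational_print(retained: pd.DataFrame, rm_genes: list[str],
                     clinical: list[ClinicalRecord]) -> MutationalPrint:
    """Gene x patient display matrix over the r.m. gene set.

    A cell shows the most disruptive variant class the patient carries in
    the gene (frameshift > nonsense > stop loss > splicing > missense);
    genes with no carriers among the given patients are dropped.
    """
    patients = [rec.patient_id for rec in clinical]
    patient_set = set(patients)
    unknown = set(retained["patient_id"]) - patient_set
    if unknown:
        raise ValueError(f"retained observations for patients absent from the cohort: {sorted(unknown)}")
    sub = retained[retained["gene"].isin(set(rm_genes))]
    rank = {cat: i for i, cat in enumerate(DISPLAY_PRECEDENCE)}
    matrix = pd.DataFrame("none", index=sorted(set(rm_genes) & set(sub["gene"])), columns=patients)
    for (gene, patient), grp in sub.groupby(["gene", "patient_id"]):
        best = min(grp["consequence"], key=lambda c: rank[c])
        matrix.loc[gene, patient] = best
    gene_totals = sub.groupby("gene")["patient_id"].count().reindex(matrix.index, fill_value=0)
    patient_totals = sub.groupby("patient_id")["gene"].count().reindex(patients, fill_value=0)
    return MutationalPrint(matrix=matrix, gene_totals=gene_totals, patient_totals=patient_totals)


def chromosome_density(retained_rm: pd.DataFrame, registry: GeneRegistry) -> ChromDensity:
    """Variant count per chromosome normalized by its protein-coding gene
    count, over retained observations restricted to r.m. genes, plus the
    median density across chromosomes (the reference line in density plots)."""
    counts = retained_rm.groupby("chrom")["pos"].count() if not retained_rm.empty else pd.Series(dtype=int)
    missing = set(counts.index) - set(registry.chromosome_gene_counts)
    if missing:
        raise ValueError(f"chromosomes missing from registry: {sorted(missing)}")
    rows = []
    for chrom, gene_count in sorted(registry.chromosome_gene_counts.items()):
        if gene_count == 0:
            raise ValueError(f"chromosome {chrom} has zero protein-coding genes; density undefined")
        n = int(counts.get(chrom, 0))
        rows.append({"chrom": chrom, "rm_variant_count": n,
                     "protein_coding_gene_count": int(gene_count),
                     "density": n / gene_count})
    table = pd.DataFrame(rows)
    return ChromDensity(table=table, median_density=float(table["density"].median()))


def vote_stratification(retained: pd.DataFrame) -> pd.Series:
    """Histogram of retained variants by number of predictors voting
    deleterious (0-5); the retained set can never contain 3+ benign votes."""
    counts = retained["deleterious_votes"].value_counts() if not retained.empty else pd.Series(dtype=int)
    return counts.reindex(range(6), fill_value=0).astype(int)


def burden_summary(retained: pd.DataFrame, clinical: list[ClinicalRecord]) -> BurdenSummary:
    """Per-patient retained-variant counts with the cohort median and Tukey
    1.5 x IQR upper-fence outlier flags."""
    patients = [rec.patient_id for rec in clinical]
    counts = (retained.groupby("patient_id")["pos"].count() if not retained.empty
              else pd.Series(dtype=int))
    counts = counts.reindex(patients, fill_value=0).astype(int)
    q1, q3 = np.percentile(counts, [25, 75]) if len(counts) else (0.0, 0.0)
    fence = q3 + 1.5 * (q3 - q1)
    outliers = sorted(counts.index[counts > fence])
    return BurdenSummary(per_patient=counts, median=float(counts.median()),
                         q1=float(q1), q3=float(q3),
                         outlier_threshold=float(fence), outliers=list(outliers))


def variant_level_tally(retained: pd.DataFrame) -> pd.Series:
    """Raw (patient, variant) observation count per gene — the variant-level
    alternative reading of recurrence, exposed for comparison with the
    carrier-based call."""
    if retained.empty:
        return pd.Series(dtype=int)
    return retained.groupby("gene")["pos"].count().sort_values(ascending=False)
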