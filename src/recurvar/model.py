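"""Shared domain types for the cohort rare-variant pipeline.

The pipeline operates on per-patient variant *observations*: one record per
(patient, decomposed alt allele) carrying the genotype metrics used for QC
and the annotation bundle (population frequencies + pathogenicity predictor
outputs) used for prioritization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Sex(str, Enum):
    female = "female"
    male = "male"


class ArrhythmiaCategory(str, Enum):
    atrial = "atrial"
    ventricular = "ventricular"
    general = "general"


class Zygosity(str, Enum):
    het = "het"
    hom_alt = "hom_alt"
    hom_ref = "hom_ref"
    missing = "missing"


class Consequence(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    stoploss = "stoploss"
    splicing = "splicing"
    frameshift_indel = "frameshift_indel"
    synonymous = "synonymous"
    intronic = "intronic"
    intergenic = "intergenic"
    other = "other"


#: consequence classes retained by the prioritization cascade
RETAINED_CONSEQUENCES = (
    Consequence.missense,
    Consequence.nonsense,
    Consequence.stoploss,
    Consequence.splicing,
    Consequence.frameshift_indel,
)

FREQUENCY_SOURCES = ("kg1000", "gnomad", "exac", "inhouse")
PREDICTOR_TOOLS = ("sift", "pp2_hdiv", "pp2_hvar", "mutation_taster", "cadd")

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


def is_sex_chromosome(chrom: str) -> bool:
    return chrom in SEX_CHROMOSOMES or chrom.lstrip("chr") in ("X", "Y")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical covariates."""

    patient_id: str
    sex: Sex
    onset_age: int
    category: ArrhythmiaCategory
    cardiomyopathy: bool

    def __post_init__(self):
        if self.onset_age < 0 or not math.isfinite(self.onset_age):
            raise ValueError(f"onset_age must be a finite non-negative integer, got {self.onset_age!r}")


@dataclass(frozen=True)
class GenotypeCall:
    """Genotype metrics for one observation, as parsed from a VCF record."""

    patient_id: str
    gt: Zygosity
    dp: Optional[int]
    gq: Optional[int]
    ad: Optional[tuple[int, int]]  # (ref reads, alt reads) for the decomposed alt
    filter_status: str = "PASS"

    def allele_balance(self) -> Optional[float]:
        """Alt-read fraction AD_alt / (AD_ref + AD_alt); None if not computable."""
        if self.ad is None:
            return None
        ref, alt = self.ad
        if ref < 0 or alt < 0:
            raise ValueError(f"negative allele depth {self.ad!r}")
        denom = ref + alt
        if denom == 0:
            return None
        return alt / denom


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotation: gene, consequence, protein change, population
    frequencies (four sources) and five pathogenicity predictor outputs.

    Missing values are represented as ``None`` (never zero) -- zeroing of
    missing frequencies is a *filtering* rule, not an I/O one.
    """

    gene: str
    consequence: Consequence
    hgvs_p: Optional[str] = None
    freqs: dict = field(default_factory=dict)       # source -> float or None
    predictors: dict = field(default_factory=dict)  # tool -> float/str or None

    def __post_init__(self):
        for src, v in self.freqs.items():
            if src not in FREQUENCY_SOURCES:
                raise ValueError(f"unknown frequency source {src!r}")
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"frequency {src}={v!r} outside [0, 1]")
        for tool, v in self.predictors.items():
            if tool not in PREDICTOR_TOOLS:
                raise ValueError(f"unknown predictor tool {tool!r}")


@dataclass(frozen=True)
class VariantObservation:
    """One decomposed variant call in one patient."""

    chrom: str
    pos: int
    ref: str
    alt: str
    patient_id: str
    call: GenotypeCall
    ann: Optional[AnnotationBundle] = None

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_annotation(self, ann: AnnotationBundle) -> "VariantObservation":
        return VariantObservation(self.chrom, self.pos, self.ref, self.alt,
                                  self.patient_id, self.call, ann)


@dataclass
class GeneRegistry:
    """Gene -> (chromosome, protein length) plus per-chromosome counts of
    protein-coding genes, used to normalize variant density."""

    genes: dict                 # gene -> (chrom, protein_length)
    chromosome_gene_counts: dict  # chrom -> protein-coding gene count

    def __post_init__(self):
        for gene, (chrom, plen) in self.genes.items():
            if plen < 1:
                raise ValueError(f"protein_length for {gene} must be >= 1, got {plen}")
            if chrom not in self.chromosome_gene_counts:
                raise ValueError(f"gene {gene} on chromosome {chrom} absent from chromosome table")

    def chrom_of(self, gene: str) -> str:
        return self.genes[gene][0]

    def protein_length(self, gene: str) -> int:
        return self.genes[gene][1]

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes
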