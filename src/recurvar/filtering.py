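"""Rare-deleterious-variant prioritization cascade.

Stages, in order: VCF FILTER pass -> genotype QC (GQ, DP, allele balance) ->
population-frequency rarity -> consequence-class restriction -> consensus-
benign exclusion by predictor vote. Every excluded observation is tallied by
reason so the survivor ledger is conservative: input = retained + excluded.

Genotype QC thresholds: genotype quality >= 20, depth >= 10 (>= 5 on sex
chromosomes), allele balance within [0.2, 0.8] for heterozygous calls
(bounds inclusive). Rarity: a variant is rare when its maximum allele
frequency across the four population sources (missing treated as zero) is
strictly below 0.01. Consensus benign: called benign by at least three of
the five predictors (SIFT, PolyPhen2-HumDiv, PolyPhen2-HumVar,
MutationTaster, CADD); a missing score abstains rather than voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    AnnotationBundle,
    Consequence,
    GenotypeCall,
    RETAINED_CONSEQUENCES,
    VariantObservation,
    Zygosity,
    is_sex_chromosome,
)

# QC thresholds
MIN_GQ = 20
MIN_DP_AUTOSOME = 10
MIN_DP_SEX = 5
AB_LOW = 0.2
AB_HIGH = 0.8

# rarity threshold: variants with max population AF >= this are excluded
MAX_AF = 0.01

# predictor pathogenicity cutoffs (tool-native directions: SIFT deleterious
# below its cutoff, the others at or above theirs)
SIFT_CUTOFF = 0.05
PP2_HDIV_CUTOFF = 0.435
PP2_HVAR_CUTOFF = 0.445
CADD_CUTOFF = 5.0
MT_DELETERIOUS = frozenset({"D", "A"})   # disease causing (automatic)
MT_BENIGN = frozenset({"N", "P"})        # polymorphism (automatic)

BENIGN_VOTES_REQUIRED = 3


@dataclass(frozen=True)
class QCThresholds:
    min_gq: int = MIN_GQ
    min_dp: int = MIN_DP_AUTOSOME
    min_dp_sex: int = MIN_DP_SEX
    ab_low: float = AB_LOW
    ab_high: float = AB_HIGH


@dataclass(frozen=True)
class PredictorVerdict:
    benign_votes: int
    deleterious_votes: int
    missing_votes: int

    @property
    def is_consensus_benign(self) -> bool:
        return self.benign_votes >= BENIGN_VOTES_REQUIRED

    def __post_init__(self):
        if self.benign_votes + self.deleterious_votes + self.missing_votes != 5:
            raise ValueError("predictor votes must sum to 5")


@dataclass
class FilterSummary:
    """Stage-by-stage survivor ledger for one cascade run."""

    input_count: int = 0
    pass_filter_count: int = 0
    genotype_qc_count: int = 0
    rare_count: int = 0
    exonic_count: int = 0
    retained_count: int = 0
    excluded_consensus_benign_count: int = 0
    retained_by_category: dict = field(default_factory=dict)
    exclusion_reasons: dict = field(default_factory=dict)

    def validate(self) -> None:
        stages = [self.input_count, self.pass_filter_count, self.genotype_qc_count,
                  self.rare_count, self.exonic_count, self.retained_count]
        for earlier, later in zip(stages, stages[1:]):
            if later > earlier:
                raise ValueError(f"cascade counts must be non-increasing, got {stages}")
        if self.retained_count != sum(self.retained_by_category.values()):
            raise ValueError("retained_count != sum of per-category counts")
        if self.exonic_count != self.retained_count + self.excluded_consensus_benign_count:
            raise ValueError("exonic_count != retained + consensus-benign")
        if self.input_count != self.retained_count + sum(self.exclusion_reasons.values()):
            raise ValueError("ledger not conservative: input != retained + excluded")


def genotype_qc(call: GenotypeCall, chrom: str,
                thresholds: QCThresholds = QCThresholds(),
                check_filter: bool = True) -> Optional[str]:
    """Return None when the call passes genotype QC, else the failure reason
    (one of ``not_pass_filter``, ``low_gq``, ``low_dp``, ``allele_balance``)."""
    if check_filter and call.filter_status != "PASS":
        return "not_pass_filter"
    if call.gq is None or call.gq < thresholds.min_gq:
        return "low_gq"
    min_dp = thresholds.min_dp_sex if is_sex_chromosome(chrom) else thresholds.min_dp
    if call.dp is None or call.dp < min_dp:
        return "low_dp"
    if call.gt == Zygosity.het:
        ab = call.allele_balance()
        if ab is None:
            raise ValueError(
                f"heterozygous call for {call.patient_id} lacks allele depths; allele balance not computable"
            )
        if not (thresholds.ab_low <= ab <= thresholds.ab_high):
            return "allele_balance"
    return None


def max_population_frequency(ann: AnnotationBundle) -> float:
    """Maximum allele frequency across the population sources, with missing
    entries assigned zero."""
    return max((v if v is not None else 0.0) for v in ann.freqs.values()) if ann.freqs else 0.0


def is_rare(freq: float, max_af: float = MAX_AF) -> bool:
    """Strict threshold: frequency exactly at the cutoff counts as common."""
    return freq < max_af


def classify_consequence(ann: AnnotationBundle) -> str:
    """One of the five retained consequence classes, or ``excluded`` for
    non-exonic / synonymous / other classes."""
    if not isinstance(ann.consequence, Consequence):
        raise ValueError(f"unknown consequence token {ann.consequence!r}")
    if ann.consequence in RETAINED_CONSEQUENCES:
        return ann.consequence.value
    return "excluded"


def _tool_vote(tool: str, value) -> str:
    if value is None:
        return "missing"
    if tool == "sift":
        return "deleterious" if value < SIFT_CUTOFF else "benign"
    if tool == "pp2_hdiv":
        return "deleterious" if value >= PP2_HDIV_CUTOFF else "benign"
    if tool == "pp2_hvar":
        return "deleterious" if value >= PP2_HVAR_CUTOFF else "benign"
    if tool == "cadd":
        return "deleterious" if value >= CADD_CUTOFF else "benign"
    if tool == "mutation_taster":
        if value in MT_DELETERIOUS:
            return "deleterious"
        if value in MT_BENIGN:
            return "benign"
        raise ValueError(f"MutationTaster call {value!r} not in {{D, A, N, P}} or NA")
    raise ValueError(f"unknown predictor tool {tool!r}")


def predictor_verdict(predictors: dict) -> PredictorVerdict:
    """Tally benign/deleterious/abstain votes over the five predictors."""
    votes = {"benign": 0, "deleterious": 0, "missing": 0}
    for tool in ("sift", "pp2_hdiv", "pp2_hvar", "mutation_taster", "cadd"):
        votes[_tool_vote(tool, predictors.get(tool))] += 1
    return PredictorVerdict(votes["benign"], votes["deleterious"], votes["missing"])


def prioritize_cohort(observations: list[VariantObservation],
                      annotations: dict,
                      thresholds: QCThresholds = QCThresholds(),
                      max_af: float = MAX_AF) -> tuple[list[VariantObservation], FilterSummary]:
    """Run the full cascade over per-patient observations.

    ``annotations`` maps (chrom, pos, ref, alt) to AnnotationBundle;
    observations without an annotation are excluded with reason
    ``no_annotation``. Returns retained observations (annotation attached)
    and the survivor ledger.
    """
    summary = FilterSummary()
    summary.input_count = len(observations)
    summary.retained_by_category = {c.value: 0 for c in RETAINED_CONSEQUENCES}
    reasons = summary.exclusion_reasons
    retained: list[VariantObservation] = []

    def exclude(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    for obs in observations:
        if obs.call.filter_status != "PASS":
            exclude("not_pass_filter")
            continue
        summary.pass_filter_count += 1
        qc_reason = genotype_qc(obs.call, obs.chrom, thresholds, check_filter=False)
        if qc_reason is not None:
            exclude(qc_reason)
            continue
        summary.genotype_qc_count += 1
        ann = obs.ann if obs.ann is not None else annotations.get(obs.key)
        if ann is None:
            exclude("no_annotation")
            continue
        if not is_rare(max_population_frequency(ann), max_af):
            exclude("common")
            continue
        summary.rare_count += 1
        category = classify_consequence(ann)
        if category == "excluded":
            exclude("non_exonic")
            continue
        summary.exonic_count += 1
        if predictor_verdict(ann.predictors).is_consensus_benign:
            summary.excluded_consensus_benign_count += 1
            exclude("consensus_benign")
            continue
        summary.retained_count += 1
        summary.retained_by_category[category] += 1
        retained.append(obs if obs.ann is not None else obs.with_annotation(ann))

    summary.validate()
    return retained, summary
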