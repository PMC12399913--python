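"""Seedable synthetic arrhythmia-cohort generator with a ground-truth manifest.

The generator emulates the statistical structure the pipeline assumes: a
~50-patient cohort with realistic clinical marginals, a set of planted
recurrently mutated (r.m.) genes whose carrier sets are sampled *without
replacement* at sizes at or above the 30% recurrence threshold (so recurrence
recovery is exact, not probabilistic), planted covariate-associated genes
whose per-group carrier probabilities follow from a baseline probability and
a true odds ratio, a large pool of background genes calibrated so the median
per-patient retained burden hits a target, and fate-tagged decoys (QC
failures, common-frequency contaminants, consensus-benign variants,
non-exonic variants) that each violate exactly the filter rule their fate
names. Every variant's intended fate is recorded in the manifest, and the
annotation values are constructed *from* the fates, so running the real
pipeline on generated data must reproduce the manifest exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from . import io as cohort_io
from .association import get_covariate
from .model import (
    AnnotationBundle,
    ArrhythmiaCategory,
    ClinicalRecord,
    Consequence,
    FREQUENCY_SOURCES,
    GeneRegistry,
    GenotypeCall,
    Sex,
    VariantObservation,
    Zygosity,
)
from .recurrence import rm_threshold

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

#: retained-class consequence mix (missense, nonsense, stop loss, splicing,
#: frameshift), matching the composition of a rare-deleterious exome callset
RETAINED_CONSEQUENCE_MIX = {
    Consequence.missense: 0.8624,
    Consequence.nonsense: 0.0595,
    Consequence.stoploss: 0.0013,
    Consequence.splicing: 0.0002,
    Consequence.frameshift_indel: 0.0766,
}

NONEXONIC_CLASSES = (Consequence.synonymous, Consequence.intronic, Consequence.intergenic)

QC_RULES = ("not_pass_filter", "low_gq", "low_dp", "allele_balance")

CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


@dataclass(frozen=True)
class PlantedAssociation:
    """A gene whose carrier status depends on a clinical covariate."""

    gene: str
    covariate: str
    true_or: float
    baseline_carrier_prob: float

    def carrier_prob_level1(self) -> float:
        """Carrier probability in the covariate=1 group implied by the odds
        ratio: p1 = OR*odds0 / (1 + OR*odds0)."""
        odds0 = self.baseline_carrier_prob / (1.0 - self.baseline_carrier_prob)
        odds1 = self.true_or * odds0
        return odds1 / (1.0 + odds1)


@dataclass
class GeneratorConfig:
    n_patients: int = 50
    sex_female_prob: float = 0.42
    onset_age_mean: float = 22.16
    onset_age_sd: float = 9.21
    onset_age_min: int = 9
    onset_age_max: int = 49
    category_probs: dict = field(default_factory=lambda: {
        "atrial": 0.76, "ventricular": 0.20, "general": 0.04})
    cardiomyopathy_probs: dict = field(default_factory=lambda: {
        "ventricular": 0.50, "atrial": 0.053, "general": 1.0})
    n_rm_genes: int = 132
    rm_fraction: float = 0.30
    rm_carrier_min: int = 15
    rm_carrier_max: int = 40
    n_background_genes: int = 4000
    target_median_burden: int = 452
    # decoy rates: expected decoys per patient as a fraction of the target burden
    qc_fail_rate: float = 0.05
    common_contaminant_rate: float = 0.15
    benign_decoy_rate: float = 0.45
    nonexonic_rate: float = 0.20
    na_frequency_rate: float = 0.30
    na_score_rate: float = 0.10
    benign_vote_prob_retained: float = 0.20
    site_reuse_prob: float = 0.5
    planted_associations: list = field(default_factory=lambda: [
        PlantedAssociation("ASSOC_ONSET", "very_early_onset", 9.71, 0.20),
        PlantedAssociation("ASSOC_FEMALE", "female", 3.41, 0.30),
    ])
    outlier_patient_index: Optional[int] = 20   # burden outlier, like a real cohort's extreme sample
    outlier_multiplier: float = 3.6
    burden_dispersion: Optional[float] = None   # None = Poisson; else negative binomial shape
    seed: int = 0

    def __post_init__(self):
        for name in ("sex_female_prob", "qc_fail_rate", "common_contaminant_rate",
                     "benign_decoy_rate", "nonexonic_rate", "na_frequency_rate",
                     "na_score_rate", "benign_vote_prob_retained", "site_reuse_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.category_probs.values()) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        threshold = rm_threshold(self.n_patients, self.rm_fraction)
        if self.rm_carrier_min < threshold:
            raise ValueError(
                f"rm_carrier_min {self.rm_carrier_min} below recurrence threshold {threshold}")
        if self.rm_carrier_max > self.n_patients:
            raise ValueError("rm_carrier_max exceeds n_patients")
        if len(self.planted_associations) > self.n_rm_genes:
            raise ValueError("more planted associations than r.m. genes")
        self.planted_associations = [
            a if isinstance(a, PlantedAssociation) else PlantedAssociation(**a)
            for a in self.planted_associations
        ]

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class GroundTruthManifest:
    rm_genes: dict                  # gene -> sorted carrier patient ids
    associations: list              # per planted association: realized 2x2 + probs
    fates: dict                     # (chrom, pos, ref, alt, patient_id) -> fate
    background_poisson_mean: float = 0.0

    def fate_counts(self) -> dict:
        counts: dict = {}
        for fate in self.fates.values():
            counts[fate] = counts.get(fate, 0) + 1
        return counts

    def to_json_dict(self) -> dict:
        return {
            "rm_genes": self.rm_genes,
            "associations": self.associations,
            "background_poisson_mean": self.background_poisson_mean,
            "fate_counts": self.fate_counts(),
            "fates": {":".join(map(str, k)): v for k, v in sorted(self.fates.items())},
        }


def generate_clinical(config: GeneratorConfig, seed: Optional[int] = None) -> list[ClinicalRecord]:
    """Clinical table with the configured marginals: Bernoulli sex, truncated
    normal onset age rounded to whole years, categorical arrhythmia type, and
    cardiomyopathy drawn conditionally on the type."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    a = (config.onset_age_min - config.onset_age_mean) / config.onset_age_sd
    b = (config.onset_age_max - config.onset_age_mean) / config.onset_age_sd
    ages = truncnorm.rvs(a, b, loc=config.onset_age_mean, scale=config.onset_age_sd,
                         size=config.n_patients, random_state=rng)
    cats = list(config.category_probs)
    cat_p = np.array([config.category_probs[c] for c in cats])
    records = []
    for i in range(config.n_patients):
        category = rng.choice(cats, p=cat_p)
        records.append(ClinicalRecord(
            patient_id=f"CS{i + 1:03d}",
            sex=Sex.female if rng.random() < config.sex_female_prob else Sex.male,
            onset_age=int(round(ages[i])),
            category=ArrhythmiaCategory(category),
            cardiomyopathy=bool(rng.random() < config.cardiomyopathy_probs[category]),
        ))
    return records


def _covariate_prevalence(config: GeneratorConfig, covariate: str) -> float:
    """Analytic prevalence of a built-in covariate under the config marginals."""
    if covariate == "female":
        return config.sex_female_prob
    if covariate == "cardiomyopathy_positive":
        return sum(config.category_probs[c] * config.cardiomyopathy_probs[c]
                   for c in config.category_probs)
    if covariate == "very_early_onset":
        a = (config.onset_age_min - config.onset_age_mean) / config.onset_age_sd
        b = (config.onset_age_max - config.onset_age_mean) / config.onset_age_sd
        # age is rounded to integer years, so <= 20 means the draw was < 20.5
        return float(truncnorm.cdf(20.5, a, b, loc=config.onset_age_mean,
                                   scale=config.onset_age_sd))
    raise ValueError(f"no analytic prevalence for covariate {covariate!r}")


def expected_planted_burden(config: GeneratorConfig) -> float:
    """Expected retained variants per patient contributed by planted genes."""
    n_plain = config.n_rm_genes - len(config.planted_associations)
    mean_carriers = (config.rm_carrier_min + config.rm_carrier_max) / 2.0
    contrib = n_plain * mean_carriers / config.n_patients
    for assoc in config.planted_associations:
        prev = _covariate_prevalence(config, assoc.covariate)
        p1 = assoc.carrier_prob_level1()
        contrib += prev * p1 + (1.0 - prev) * assoc.baseline_carrier_prob
    return contrib


def calibrate_burden(config: GeneratorConfig) -> float:
    """Background per-patient Poisson mean such that the post-filter median
    burden (planted + background) matches the configured target.

    The per-patient retained count is (planted carriers) + Poisson(lambda);
    both distributions are centered near their means, so the calibration
    solves mean(planted) + lambda = target.
    """
    lam = config.target_median_burden - expected_planted_burden(config)
    if lam <= 0:
        raise ValueError(
            f"target median burden {config.target_median_burden} unattainable: planted "
            f"genes alone contribute {expected_planted_burden(config):.1f} variants/patient")
    return lam


class _SiteFactory:
    """Allocates unique variant sites per gene and builds fate-consistent
    annotation bundles."""

    def __init__(self, config: GeneratorConfig, registry: GeneRegistry, rng: np.random.Generator):
        self.config = config
        self.registry = registry
        self.rng = rng
        self._counters: dict = {}       # gene -> next position offset
        self._blocks: dict = {}         # gene -> (chrom, block start)
        self._pools: dict = {}          # (gene, fate_key) -> list of site keys
        self.annotations: dict = {}     # site key -> AnnotationBundle
        self._gene_slot: dict = {}      # chrom -> next block slot
        self._consequences = list(RETAINED_CONSEQUENCE_MIX)
        self._consequence_p = np.array(list(RETAINED_CONSEQUENCE_MIX.values()))
        self._consequence_p = self._consequence_p / self._consequence_p.sum()

    def _block(self, gene: str) -> tuple[str, int]:
        if gene not in self._blocks:
            chrom = self.registry.chrom_of(gene)
            slot = self._gene_slot.get(chrom, 0)
            self._gene_slot[chrom] = slot + 1
            self._blocks[gene] = (chrom, 100_000 + slot * 50_000)
        return self._blocks[gene]

    def _rare_freqs(self) -> dict:
        freqs = {}
        for src in FREQUENCY_SOURCES:
            if self.rng.random() < self.config.na_frequency_rate:
                freqs[src] = None
            else:
                freqs[src] = float(self.rng.uniform(0.0, 0.009))
        return freqs

    def _deleterious_scores(self) -> dict:
        """All five predictors on the deleterious side of their cutoffs."""
        return {
            "sift": float(self.rng.uniform(0.0, 0.049)),
            "pp2_hdiv": float(self.rng.uniform(0.5, 1.0)),
            "pp2_hvar": float(self.rng.uniform(0.5, 1.0)),
            "mutation_taster": str(self.rng.choice(["D", "A"])),
            "cadd": float(self.rng.uniform(10.0, 40.0)),
        }

    def _benign_scores(self) -> dict:
        return {
            "sift": float(self.rng.uniform(0.1, 1.0)),
            "pp2_hdiv": float(self.rng.uniform(0.0, 0.4)),
            "pp2_hvar": float(self.rng.uniform(0.0, 0.4)),
            "mutation_taster": str(self.rng.choice(["N", "P"])),
            "cadd": float(self.rng.uniform(0.0, 4.9)),
        }

    def _retained_predictors(self) -> dict:
        """At most two benign votes (never consensus benign); missing scores
        abstain and cannot tip the vote either way."""
        benign_pool = self._benign_scores()
        deleterious_pool = self._deleterious_scores()
        tools = list(deleterious_pool)
        predictors = {}
        n_benign = 0
        for tool in tools:
            if self.rng.random() < self.config.na_score_rate:
                predictors[tool] = None
            elif n_benign < 2 and self.rng.random() < self.config.benign_vote_prob_retained:
                predictors[tool] = benign_pool[tool]
                n_benign += 1
            else:
                predictors[tool] = deleterious_pool[tool]
        return predictors

    def _benign_decoy_predictors(self) -> dict:
        """At least three actual benign votes."""
        benign_pool = self._benign_scores()
        deleterious_pool = self._deleterious_scores()
        tools = list(deleterious_pool)
        n_benign = int(self.rng.integers(3, 6))
        benign_tools = set(self.rng.choice(tools, size=n_benign, replace=False))
        predictors = {}
        for tool in tools:
            if tool in benign_tools:
                predictors[tool] = benign_pool[tool]
            elif self.rng.random() < self.config.na_score_rate:
                predictors[tool] = None
            else:
                predictors[tool] = deleterious_pool[tool]
        return predictors

    def _hgvs_for(self, gene: str, consequence: Consequence) -> Optional[str]:
        plen = self.registry.protein_length(gene)
        pos = int(self.rng.integers(1, plen + 1))
        aa = lambda: self.rng.choice(list(AMINO_ACIDS))  # noqa: E731
        if consequence == Consequence.missense:
            ref = aa()
            alt = aa()
            while alt == ref:
                alt = aa()
            return f"p.{ref}{pos}{alt}"
        if consequence == Consequence.nonsense:
            return f"p.{aa()}{pos}*"
        if consequence == Consequence.stoploss:
            return f"p.*{plen}{aa()}"
        if consequence == Consequence.frameshift_indel:
            return f"p.{aa()}{pos}fs"
        return None  # splicing / non-exonic: no protein change

    def _new_site(self, gene: str, fate_key: str) -> tuple:
        chrom, start = self._block(gene)
        offset = self._counters.get(gene, 0)
        self._counters[gene] = offset + 1
        pos = start + offset
        consequence_fate = fate_key.split("|")[0]
        if consequence_fate == "non_exonic":
            consequence = Consequence(str(self.rng.choice([c.value for c in NONEXONIC_CLASSES])))
        else:
            consequence = Consequence(str(self.rng.choice(
                [c.value for c in self._consequences], p=self._consequence_p)))
        if consequence == Consequence.frameshift_indel:
            ref = str(self.rng.choice(list(BASES)))
            alt = ref + str(self.rng.choice(list(BASES)))
        else:
            ref = str(self.rng.choice(list(BASES)))
            alt = str(self.rng.choice([b for b in BASES if b != ref]))
        freqs = self._rare_freqs()
        if consequence_fate == "common":
            src = str(self.rng.choice(FREQUENCY_SOURCES))
            freqs[src] = float(self.rng.uniform(0.01, 0.20))
        if consequence_fate == "retained" or consequence_fate == "qc_fail":
            predictors = self._retained_predictors()
        elif consequence_fate == "benign_consensus":
            predictors = self._benign_decoy_predictors()
        else:  # common / non_exonic: excluded upstream of the vote; any scores do
            predictors = self._retained_predictors()
        key = (chrom, pos, ref, alt)
        self.annotations[key] = AnnotationBundle(
            gene=gene, consequence=consequence,
            hgvs_p=self._hgvs_for(gene, consequence),
            freqs=freqs, predictors=predictors,
        )
        return key

    def site(self, gene: str, fate_key: str, used: set) -> tuple:
        """A site for (gene, fate), reusing an existing one with the
        configured probability; never returns a site already in ``used``."""
        pool = self._pools.setdefault((gene, fate_key), [])
        if pool and self.rng.random() < self.config.site_reuse_prob:
            candidates = [k for k in pool if k not in used]
            if candidates:
                return candidates[int(self.rng.integers(len(candidates)))]
        key = self._new_site(gene, fate_key)
        pool.append(key)
        return key


def _passing_call(patient_id: str, rng: np.random.Generator) -> GenotypeCall:
    if rng.random() < 0.1:
        total = int(rng.integers(15, 60))
        return GenotypeCall(patient_id, Zygosity.hom_alt, dp=total,
                            gq=int(rng.integers(30, 100)), ad=(0, total))
    total = int(rng.integers(20, 60))
    lo = math.ceil(0.25 * total)
    hi = math.floor(0.75 * total)
    alt = int(rng.integers(lo, hi + 1))
    return GenotypeCall(patient_id, Zygosity.het, dp=total,
                        gq=int(rng.integers(30, 100)), ad=(total - alt, alt))


def _failing_call(patient_id: str, rule: str, sex_chrom: bool,
                  rng: np.random.Generator) -> GenotypeCall:
    """A genotype violating exactly the named QC rule."""
    good = _passing_call(patient_id, rng)
    if rule == "not_pass_filter":
        return GenotypeCall(patient_id, good.gt, good.dp, good.gq, good.ad,
                            filter_status="VQSRTrancheSNP99.90to100.00")
    if rule == "low_gq":
        return GenotypeCall(patient_id, good.gt, good.dp, int(rng.integers(0, 20)), good.ad)
    if rule == "low_dp":
        dp = int(rng.integers(0, 5 if sex_chrom else 10))
        ref = dp // 2
        return GenotypeCall(patient_id, Zygosity.het if dp - ref > 0 and ref > 0 else Zygosity.hom_alt,
                            dp, good.gq, (ref, dp - ref))
    if rule == "allele_balance":
        total = int(rng.integers(20, 60))
        frac = rng.uniform(0.02, 0.15) if rng.random() < 0.5 else rng.uniform(0.85, 0.98)
        alt = min(max(int(round(frac * total)), 0), total)
        # keep strictly outside [0.2, 0.8]
        if 0.2 <= alt / total <= 0.8:
            alt = max(1, int(0.1 * total))
        return GenotypeCall(patient_id, Zygosity.het, total, good.gq, (total - alt, alt))
    raise ValueError(f"unknown QC rule {rule!r}")


def _build_registry(config: GeneratorConfig, rng: np.random.Generator) -> tuple[GeneRegistry, list, list]:
    n_plain = config.n_rm_genes - len(config.planted_associations)
    rm_genes = [f"RM{i + 1:03d}" for i in range(n_plain)]
    assoc_genes = [a.gene for a in config.planted_associations]
    background = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    genes = {}
    for i, gene in enumerate(rm_genes + assoc_genes + background):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        genes[gene] = (chrom, int(rng.integers(200, 2000)))
    counts: dict = {}
    for chrom, _ in genes.values():
        counts[chrom] = counts.get(chrom, 0) + 1
    return GeneRegistry(genes=genes, chromosome_gene_counts=counts), rm_genes, background


def generate_variants(config: GeneratorConfig, clinical: list[ClinicalRecord],
                      seed: Optional[int] = None):
    """Generate per-patient variant observations, the annotation map, the
    synthetic gene registry, and the ground-truth manifest.

    Returns (observations, annotations, registry, manifest).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    registry, rm_plain, background = _build_registry(config, rng)
    factory = _SiteFactory(config, registry, rng)
    patients = [r.patient_id for r in clinical]
    threshold = rm_threshold(config.n_patients, config.rm_fraction)
    cap = threshold - 1

    observations: list[VariantObservation] = []
    fates: dict = {}
    used_sites: dict = {p: set() for p in patients}

    def add_observation(patient_id: str, gene: str, fate: str, fate_key: str,
                        call_rule: Optional[str] = None) -> None:
        key = factory.site(gene, fate_key, used_sites[patient_id])
        used_sites[patient_id].add(key)
        chrom = key[0]
        if call_rule is None:
            call = _passing_call(patient_id, rng)
        else:
            call = _failing_call(patient_id, call_rule, chrom in ("chrX", "chrY"), rng)
        observations.append(VariantObservation(key[0], key[1], key[2], key[3], patient_id, call))
        fates[key + (patient_id,)] = fate

    # planted r.m. genes: exact carrier sets, one retained variant per carrier
    manifest_rm: dict = {}
    for gene in rm_plain:
        size = int(rng.integers(config.rm_carrier_min, config.rm_carrier_max + 1))
        carriers = sorted(rng.choice(patients, size=size, replace=False).tolist())
        manifest_rm[gene] = carriers
        for pid in carriers:
            add_observation(pid, gene, "retained", "retained")

    # planted association genes: covariate-dependent carriers, redrawn until
    # the gene clears the recurrence threshold (expected counts sit well above
    # it, so redraws are rare)
    manifest_assoc = []
    for assoc in config.planted_associations:
        spec = get_covariate(assoc.covariate)
        p1 = assoc.carrier_prob_level1()
        for _ in range(1000):
            carriers = [r.patient_id for r in clinical
                        if rng.random() < (p1 if spec.rule(r) == 1 else assoc.baseline_carrier_prob)]
            if len(carriers) >= threshold:
                break
        else:
            raise RuntimeError(f"could not reach recurrence threshold for {assoc.gene}")
        carriers = sorted(carriers)
        manifest_rm[assoc.gene] = carriers
        carrier_set = set(carriers)
        a = sum(1 for r in clinical if r.patient_id in carrier_set and spec.rule(r) == 1)
        b = len(carriers) - a
        n1 = sum(1 for r in clinical if spec.rule(r) == 1)
        manifest_assoc.append({
            "gene": assoc.gene, "covariate": assoc.covariate,
            "true_or": assoc.true_or,
            "baseline_carrier_prob": assoc.baseline_carrier_prob,
            "carrier_prob_level1": p1,
            "table": {"a": a, "b": b, "c": n1 - a,
                      "d": (len(clinical) - n1) - b},
            "carriers": carriers,
        })
        for pid in carriers:
            add_observation(pid, assoc.gene, "retained", "retained")

    # background retained burden, calibrated to the target median
    lam = calibrate_burden(config)
    bg_carriers: dict = {g: set() for g in background}
    n_bg = len(background)
    for idx, rec in enumerate(clinical):
        mean = lam * (config.outlier_multiplier if idx == config.outlier_patient_index else 1.0)
        if config.burden_dispersion is None:
            k = int(rng.poisson(mean))
        else:
            shape = config.burden_dispersion
            k = int(rng.negative_binomial(shape, shape / (shape + mean)))
        for _ in range(k):
            for _ in range(100):
                gene = background[int(rng.integers(n_bg))]
                if rec.patient_id in bg_carriers[gene] or len(bg_carriers[gene]) <= cap - 1:
                    break
            bg_carriers[gene].add(rec.patient_id)
            add_observation(rec.patient_id, gene, "retained", "retained")

    # fate-tagged decoys, assigned to background genes
    decoy_plan = (
        ("qc_fail", config.qc_fail_rate),
        ("common", config.common_contaminant_rate),
        ("benign_consensus", config.benign_decoy_rate),
        ("non_exonic", config.nonexonic_rate),
    )
    for rec in clinical:
        for fate, rate in decoy_plan:
            k = int(rng.poisson(rate * config.target_median_burden))
            for _ in range(k):
                gene = background[int(rng.integers(n_bg))]
                if fate == "qc_fail":
                    rule = QC_RULES[int(rng.integers(len(QC_RULES)))]
                    add_observation(rec.patient_id, gene, "qc_fail", f"qc_fail|{rule}", call_rule=rule)
                else:
                    add_observation(rec.patient_id, gene, fate, fate)

    manifest = GroundTruthManifest(
        rm_genes={g: manifest_rm[g] for g in sorted(manifest_rm)},
        associations=manifest_assoc,
        fates=fates,
        background_poisson_mean=lam,
    )
    return observations, factory.annotations, registry, manifest


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None):
    """Convenience wrapper: (clinical, observations, annotations, registry, manifest)."""
    clinical = generate_clinical(config, seed=seed)
    observations, annotations, registry, manifest = generate_variants(config, clinical, seed=seed)
    return clinical, observations, annotations, registry, manifest


# ---------------------------------------------------------------------------
# VCF + file emission

def _vcf_lines(observations: list[VariantObservation], annotations: dict,
               patients: list[str]) -> list[str]:
    from .association import _chrom_sort_key

    by_site: dict = {}
    site_filter: dict = {}
    for obs in observations:
        by_site.setdefault(obs.key, {})[obs.patient_id] = obs.call
        if obs.call.filter_status != "PASS":
            site_filter[obs.key] = obs.call.filter_status
    contigs = sorted({k[0] for k in by_site}, key=_chrom_sort_key)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="Low VQSR tranche">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(patients),
    ]
    for key in sorted(by_site, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
        chrom, pos, ref, alt = key
        filt = site_filter.get(key, "PASS")
        cols = [chrom, str(pos), ".", ref, alt, "100", filt, ".", "GT:DP:GQ:AD"]
        calls = by_site[key]
        for pid in patients:
            call = calls.get(pid)
            if call is None:
                cols.append("0/0:30:99:30,0")
            else:
                gt = "1/1" if call.gt == Zygosity.hom_alt else "0/1"
                ad = f"{call.ad[0]},{call.ad[1]}" if call.ad else ".,."
                cols.append(f"{gt}:{call.dp}:{call.gq}:{ad}")
        lines.append("\t".join(cols))
    return lines


def emit(config: GeneratorConfig, out_dir, seed: Optional[int] = None) -> dict:
    """Write the synthetic cohort to ``out_dir``: VCF, clinical TSV,
    annotation TSV, gene registry, ground-truth manifest, and the resolved
    config. Byte-identical for identical (config, seed). Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clinical, observations, annotations, registry, manifest = generate_cohort(config, seed=seed)
    paths = {
        "vcf": out / "cohort.vcf",
        "clinical": out / "clinical.tsv",
        "annotations": out / "annotations.tsv",
        "registry_genes": out / "registry_genes.tsv",
        "registry_chromosomes": out / "registry_chromosomes.tsv",
        "manifest": out / "manifest.json",
        "config": out / "config.json",
    }
    patients = [r.patient_id for r in clinical]
    paths["vcf"].write_text("\n".join(_vcf_lines(observations, annotations, patients)) + "\n")
    cohort_io.write_clinical(clinical, paths["clinical"])
    cohort_io.write_annotation_table(annotations, paths["annotations"])
    cohort_io.write_registry(registry, paths["registry_genes"], paths["registry_chromosomes"])
    paths["manifest"].write_text(json.dumps(manifest.to_json_dict(), indent=2, sort_keys=True) + "\n")
    config.to_json(paths["config"])
    return {k: str(v) for k, v in paths.items()}


def output_digest(out_dir) -> dict:
    """SHA-256 of every file in an emitted directory (determinism checks)."""
    out = Path(out_dir)
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir()) if p.is_file()}
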