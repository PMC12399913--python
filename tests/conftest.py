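import pytest

from recurvar.model import (
    AnnotationBundle,
    Consequence,
    GenotypeCall,
    VariantObservation,
    Zygosity,
)
from recurvar.synthetic import GeneratorConfig, PlantedAssociation, generate_cohort

SMALL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ:AD\t0/1:30:99:15,15\t0/0:28:99:28,0\t1/1:25:90:0,25
chr1\t200\t.\tC\tT\t50\tPASS\t.\tGT:DP:GQ:AD\t0/0:30:99:30,0\t0/0:22:88:22,0\t0/1:40:99:20,20
chr2\t300\t.\tG\tA,T\t50\tPASS\t.\tGT:DP:GQ:AD\t1/2:30:99:0,14,16\t0/0:30:99:30,0,0\t./.:.:.:.
"""


@pytest.fixture
def small_vcf(tmp_path):
    """Three records x three samples; hand enumeration gives 5 observations
    (two alt observations for the decomposed 1/2 multi-allelic genotype)."""
    path = tmp_path / "small.vcf"
    path.write_text(SMALL_VCF)
    return path


def passing_call(pid="P1", gt=Zygosity.het, dp=20, gq=30, ad=(10, 10), filt="PASS"):
    return GenotypeCall(pid, gt, dp, gq, ad, filt)


def ann(gene="G1", consequence=Consequence.missense, hgvs_p=None,
        freqs=None, predictors=None):
    deleterious = {"sift": 0.01, "pp2_hdiv": 0.9, "pp2_hvar": 0.7,
                   "mutation_taster": "D", "cadd": 25.0}
    return AnnotationBundle(
        gene=gene, consequence=consequence, hgvs_p=hgvs_p,
        freqs=freqs if freqs is not None else {s: 0.0 for s in ("kg1000", "gnomad", "exac", "inhouse")},
        predictors=predictors if predictors is not None else deleterious,
    )


def obs(chrom="chr1", pos=100, ref="A", alt="G", pid="P1", call=None, annotation=None):
    return VariantObservation(chrom, pos, ref, alt, pid,
                              call if call is not None else passing_call(pid),
                              annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down synthetic cohort for pipeline-level tests: 20 patients,
    12 planted r.m. genes (one covariate-associated), target burden 60."""
    cfg = GeneratorConfig(
        n_patients=20, n_rm_genes=12, rm_carrier_min=6, rm_carrier_max=15,
        target_median_burden=60, n_background_genes=600,
        planted_associations=[PlantedAssociation("ASSOC_ONSET", "very_early_onset", 9.71, 0.20)],
        outlier_patient_index=None, seed=11,
    )
    clinical, observations, annotations, registry, manifest = generate_cohort(cfg)
    return {
        "config": cfg, "clinical": clinical, "observations": observations,
        "annotations": annotations, "registry": registry, "manifest": manifest,
    }
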