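"""Prioritization cascade: QC rules, rarity, consequence classes, consensus vote."""

import random

import pytest

from recurvar.filtering import (
    FilterSummary,
    genotype_qc,
    is_rare,
    max_population_frequency,
    predictor_verdict,
    prioritize_cohort,
)
from recurvar.model import Consequence, GenotypeCall, Zygosity

from conftest import ann, obs, passing_call


class TestGenotypeQC:
    @pytest.mark.parametrize("call,chrom,expected", [
        (passing_call(ad=(10, 10), gq=30, dp=20), "chr1", None),
        (passing_call(ad=(17, 3), gq=30, dp=20), "chr1", "allele_balance"),   # AB = 0.15
        (passing_call(ad=(16, 4), gq=30, dp=20), "chr1", None),               # AB = 0.20 inclusive
        (passing_call(ad=(4, 16), gq=30, dp=20), "chr1", None),               # AB = 0.80 inclusive
        (passing_call(ad=(3, 17), gq=30, dp=20), "chr1", "allele_balance"),   # AB = 0.85
        (passing_call(gq=19), "chr1", "low_gq"),
        (passing_call(gq=20), "chr1", None),
        (passing_call(dp=9, ad=(5, 4)), "chr1", "low_dp"),
        (passing_call(dp=7, ad=(4, 3)), "chrX", None),                        # sex-chromosome DP >= 5
        (passing_call(dp=7, ad=(4, 3)), "chr2", "low_dp"),
        (passing_call(dp=4, ad=(2, 2)), "chrX", "low_dp"),
        (passing_call(filt="VQSRTranche"), "chr1", "not_pass_filter"),
    ])
    def test_rules_and_boundaries(self, call, chrom, expected):
        assert genotype_qc(call, chrom) == expected

    def test_het_without_ad_is_an_error(self):
        call = GenotypeCall("P1", Zygosity.het, 30, 50, None)
        with pytest.raises(ValueError, match="allele balance"):
            genotype_qc(call, "chr1")

    def test_hom_alt_skips_allele_balance(self):
        call = GenotypeCall("P1", Zygosity.hom_alt, 30, 50, (0, 30))
        assert genotype_qc(call, "chr1") is None


class TestRarity:
    def test_all_missing_frequencies_are_zero(self):
        a = ann(freqs={"kg1000": None, "gnomad": None, "exac": None, "inhouse": None})
        assert max_population_frequency(a) == 0.0

    @pytest.mark.parametrize("freqs,expected", [
        ({"kg1000": 0.005, "gnomad": None, "exac": 0.009, "inhouse": 0.0}, 0.009),
        ({"kg1000": 0.02, "gnomad": 0.001, "exac": None, "inhouse": None}, 0.02),
    ])
    def test_max_over_sources_with_na_as_zero(self, freqs, expected):
        assert max_population_frequency(ann(freqs=freqs)) == expected

    @pytest.mark.parametrize("freq,rare", [(0.0099, True), (0.01, False), (0.0, True)])
    def test_strict_threshold(self, freq, rare):
        assert is_rare(freq) is rare


class TestPredictorVerdict:
    def test_all_benign_sides_make_consensus_benign(self):
        v = predictor_verdict({"sift": 0.30, "pp2_hdiv": 0.10, "pp2_hvar": 0.20,
                               "mutation_taster": "N", "cadd": 3.0})
        assert (v.benign_votes, v.is_consensus_benign) == (5, True)

    def test_all_deleterious_sides(self):
        v = predictor_verdict({"sift": 0.01, "pp2_hdiv": 0.90, "pp2_hvar": 0.70,
                               "mutation_taster": "D", "cadd": 25.0})
        assert (v.benign_votes, v.deleterious_votes) == (0, 5)

    def test_missing_scores_abstain(self):
        v = predictor_verdict({"sift": None, "pp2_hdiv": None, "pp2_hvar": 0.20,
                               "mutation_taster": None, "cadd": None})
        assert (v.benign_votes, v.missing_votes, v.is_consensus_benign) == (1, 4, False)

    @pytest.mark.parametrize("predictors,tool,vote", [
        ({"sift": 0.05}, "sift", "benign"),           # SIFT deleterious strictly below 0.05
        ({"sift": 0.049}, "sift", "deleterious"),
        ({"cadd": 5.0}, "cadd", "deleterious"),       # CADD deleterious at or above 5
        ({"cadd": 4.99}, "cadd", "benign"),
        ({"pp2_hdiv": 0.435}, "pp2_hdiv", "deleterious"),
        ({"pp2_hvar": 0.445}, "pp2_hvar", "deleterious"),
        ({"pp2_hvar": 0.444}, "pp2_hvar", "benign"),
    ])
    def test_cutoff_boundaries(self, predictors, tool, vote):
        base = {"sift": None, "pp2_hdiv": None, "pp2_hvar": None,
                "mutation_taster": None, "cadd": None}
        base.update(predictors)
        v = predictor_verdict(base)
        assert getattr(v, f"{vote}_votes") == 1

    def test_bad_mutation_taster_token(self):
        with pytest.raises(ValueError, match="MutationTaster"):
            predictor_verdict({"sift": None, "pp2_hdiv": None, "pp2_hvar": None,
                               "mutation_taster": "Q", "cadd": None})

    def test_vote_algebra_sums_to_five(self):
        rng = random.Random(7)
        for _ in range(50):
            preds = {
                "sift": rng.choice([None, rng.random()]),
                "pp2_hdiv": rng.choice([None, rng.random()]),
                "pp2_hvar": rng.choice([None, rng.random()]),
                "mutation_taster": rng.choice([None, "D", "A", "N", "P"]),
                "cadd": rng.choice([None, rng.uniform(0, 40)]),
            }
            v = predictor_verdict(preds)
            assert v.benign_votes + v.deleterious_votes + v.missing_votes == 5


def _ten_observation_fixture():
    """2 QC failures, 2 common, 2 synonymous, 1 consensus benign, 3 retained."""
    common = {"kg1000": 0.05, "gnomad": None, "exac": None, "inhouse": None}
    benign = {"sift": 0.5, "pp2_hdiv": 0.1, "pp2_hvar": 0.1,
              "mutation_taster": "D", "cadd": 30.0}  # 3 benign votes
    items = [
        (obs(pos=1, pid="P1", call=passing_call("P1", gq=10)), ann()),                       # low_gq
        (obs(pos=2, pid="P2", call=passing_call("P2", ad=(19, 1))), ann()),                  # allele balance
        (obs(pos=3, pid="P1"), ann(freqs=common)),                                           # common
        (obs(pos=4, pid="P2"), ann(freqs=common)),                                           # common
        (obs(pos=5, pid="P3"), ann(consequence=Consequence.synonymous)),                     # non-exonic
        (obs(pos=6, pid="P3"), ann(consequence=Consequence.intronic)),                       # non-exonic
        (obs(pos=7, pid="P1"), ann(predictors=benign)),                                      # consensus benign
        (obs(pos=8, pid="P1"), ann()),                                                       # retained
        (obs(pos=9, pid="P2"), ann(consequence=Consequence.frameshift_indel)),               # retained
        (obs(pos=10, pid="P3"), ann(consequence=Consequence.nonsense)),                      # retained
    ]
    observations = [o for o, _ in items]
    annotations = {o.key: a for o, a in items}
    return observations, annotations


class TestPrioritizeCohort:
    def test_hand_traced_fixture_ledger(self):
        observations, annotations = _ten_observation_fixture()
        retained, summary = prioritize_cohort(observations, annotations)
        assert summary.retained_count == 3
        assert summary.exclusion_reasons == {
            "low_gq": 1, "allele_balance": 1, "common": 2,
            "non_exonic": 2, "consensus_benign": 1,
        }
        assert summary.excluded_consensus_benign_count == 1
        assert summary.exonic_count == 4
        assert {o.pos for o in retained} == {8, 9, 10}
        assert summary.retained_by_category == {
            "missense": 1, "nonsense": 1, "stoploss": 0,
            "splicing": 0, "frameshift_indel": 1,
        }

    def test_empty_input_all_zero(self):
        retained, summary = prioritize_cohort([], {})
        assert retained == [] and summary.input_count == summary.retained_count == 0

    def test_order_insensitivity(self):
        observations, annotations = _ten_observation_fixture()
        base_retained, base_summary = prioritize_cohort(observations, annotations)
        rng = random.Random(3)
        for _ in range(5):
            shuffled = observations[:]
            rng.shuffle(shuffled)
            retained, summary = prioritize_cohort(shuffled, annotations)
            assert {(o.key, o.patient_id) for o in retained} == \
                   {(o.key, o.patient_id) for o in base_retained}
            assert summary.exclusion_reasons == base_summary.exclusion_reasons

    def test_unannotated_observation_counted(self):
        observations, annotations = _ten_observation_fixture()
        del annotations[("chr1", 8, "A", "G")]
        retained, summary = prioritize_cohort(observations, annotations)
        assert summary.exclusion_reasons["no_annotation"] == 1
        assert summary.retained_count == 2

    def test_ledger_conservation_on_synthetic_cohort(self, small_cohort):
        retained, summary = prioritize_cohort(
            small_cohort["observations"], small_cohort["annotations"])
        assert summary.input_count == summary.retained_count + sum(
            summary.exclusion_reasons.values())
        assert summary.retained_count == sum(summary.retained_by_category.values())
        summary.validate()


class TestFilterSummaryInvariants:
    def test_non_monotone_cascade_rejected(self):
        summary = FilterSummary(input_count=5, pass_filter_count=6)
        with pytest.raises(ValueError, match="non-increasing"):
            summary.validate()
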