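"""Filter predicate unit tests plus the exhaustive segregation oracle."""

import itertools

import pytest

from adfunnel.filters import (
    HIGH_IMPACT,
    OTHER,
    FilterConfig,
    classify_impact,
    passes_ad_segregation,
    passes_consequence_class,
    passes_frequency,
    passes_genotype_quality,
    passes_het_only,
    passes_pathogenicity,
    passes_site_quality,
)
from adfunnel.model import (
    SampleGenotype,
    TranscriptAnnotation,
    VariantRecord,
    VariantScores,
)
from adfunnel.pedigree import Individual, Pedigree


def ann(*terms):
    return TranscriptAnnotation("G", "T", tuple(terms))


def variant(qual=100.0, qd=20.0, mq=60.0, fs=1.0, genotypes=None, scores=None):
    return VariantRecord(
        "1", 100, "A", "G",
        site_qual=qual, qd=qd, mq=mq, fs=fs,
        genotypes=genotypes or {},
        annotations=[ann("missense_variant")],
        scores=scores or VariantScores(),
    )


def gt(sid, alleles, dp=30, gq=99):
    return SampleGenotype(sid, alleles, depth=dp, genotype_quality=gq)


class TestSiteQuality:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            ({"qual": 9.9}, False),
            ({"qual": 10.0}, True),
            ({"qd": 1.9}, False),
            ({"mq": 19.9}, False),
            ({"fs": 250.0}, False),
            ({"fs": 200.0}, True),
            ({"qual": 50.0, "qd": None, "mq": None, "fs": None}, True),
        ],
    )
    def test_thresholds(self, cfg, kwargs, expected):
        assert passes_site_quality(variant(**kwargs), cfg) is expected


class TestGenotypeQuality:
    def test_all_samples_passing(self, cfg):
        v = variant(genotypes={"a": gt("a", (0, 1), dp=15), "b": gt("b", (0, 0), dp=15)})
        assert passes_genotype_quality(v, ["a", "b"], cfg)

    @pytest.mark.parametrize(
        "bad",
        [gt("a", (0, 1), dp=10), gt("a", (0, 1), gq=98), SampleGenotype("a", None, 30, 99),
         SampleGenotype("a", (0, 1), depth=None, genotype_quality=99)],
        ids=["dp-at-boundary", "gq-below", "missing-call", "missing-dp"],
    )
    def test_any_failing_sample_fails_variant(self, cfg, bad):
        v = variant(genotypes={"a": bad, "b": gt("b", (0, 1))})
        assert not passes_genotype_quality(v, ["a", "b"], cfg)

    def test_unlisted_samples_ignored(self, cfg):
        v = variant(genotypes={"a": gt("a", (0, 1)), "z": gt("z", (0, 1), dp=1)})
        assert passes_genotype_quality(v, ["a"], cfg)

    def test_unknown_sample_is_an_error(self, cfg):
        with pytest.raises(KeyError):
            passes_genotype_quality(variant(genotypes={}), ["ghost"], cfg)


class TestHetOnly:
    @pytest.mark.parametrize(
        "alleles,expected", [((0, 1), True), ((1, 0), True), ((1, 1), False),
                             ((0, 0), False), (None, False)]
    )
    def test_heterozygous_retention(self, alleles, expected):
        v = variant(genotypes={"s": gt("s", alleles)})
        assert passes_het_only(v, "s") is expected


class TestSegregation:
    def test_published_carrier_pattern_cosegregates(self, family_ped):
        carriers = {"G1-Fa", "G2-Da1", "G2-Da2", "G3-Da"}
        v = variant(genotypes={
            s: gt(s, (0, 1) if s in carriers else (0, 0)) for s in family_ped.sample_ids
        })
        assert passes_ad_segregation(v, family_ped)

    def test_het_in_unaffected_spouse_breaks_segregation(self, family_ped):
        carriers = {"G1-Fa", "G2-Da1", "G2-Da2", "G3-Da", "G2-So"}
        v = variant(genotypes={
            s: gt(s, (0, 1) if s in carriers else (0, 0)) for s in family_ped.sample_ids
        })
        assert not passes_ad_segregation(v, family_ped)

    def test_hom_ref_in_affected_breaks_segregation(self, family_ped):
        carriers = {"G1-Fa", "G2-Da1", "G2-Da2"}  # G3-Da non-carrier
        v = variant(genotypes={
            s: gt(s, (0, 1) if s in carriers else (0, 0)) for s in family_ped.sample_ids
        })
        assert not passes_ad_segregation(v, family_ped)

    def test_missing_call_in_pedigree_member_fails(self, family_ped):
        genotypes = {s: gt(s, (0, 1) if s != "G1-Mo" else (0, 0))
                     for s in family_ped.sample_ids}
        genotypes["G2-So"] = SampleGenotype("G2-So", None, 30, 99)
        assert not passes_ad_segregation(variant(genotypes=genotypes), family_ped)

    def test_agrees_with_exhaustive_enumeration(self, family_ped):
        """Oracle: all 3^6 genotype vectors vs the explicit dominant rule."""
        states = [(0, 0), (0, 1), (1, 1)]
        affected = set(family_ped.affected_ids)
        unaffected = set(family_ped.unaffected_ids)
        ids = family_ped.sample_ids
        for combo in itertools.product(states, repeat=len(ids)):
            genotypes = {s: gt(s, a) for s, a in zip(ids, combo)}
            expected = all(genotypes[s].alleles in [(0, 1), (1, 0)] for s in affected) and all(
                genotypes[s].alleles == (0, 0) for s in unaffected
            )
            assert passes_ad_segregation(variant(genotypes=genotypes), family_ped) is expected


class TestImpactAndFrequency:
    @pytest.mark.parametrize(
        "terms,expected",
        [(("stop_gained",), HIGH_IMPACT), (("frameshift_variant",), HIGH_IMPACT),
         (("missense_variant",), OTHER), (("synonymous_variant",), OTHER),
         (("missense_variant", "splice_donor_variant"), HIGH_IMPACT)],
    )
    def test_classify_impact(self, cfg, terms, expected):
        assert classify_impact(ann(*terms), cfg) == expected

    @pytest.mark.parametrize(
        "consequence,af,expected",
        [
            ("stop_gained", 0.005, True),   # 1% tier
            ("stop_gained", 0.02, False),
            ("missense_variant", 0.0002, False),  # 0.01% tier
            ("missense_variant", 0.0001, True),
            ("missense_variant", None, True),  # absent from gnomAD -> novel
        ],
    )
    def test_impact_stratified_af_tiers(self, cfg, consequence, af, expected):
        v = variant(scores=VariantScores(population_af=af))
        assert passes_frequency(v, ann(consequence), cfg) is expected

    def test_tier_monotonicity_other_pass_implies_high_impact_pass(self, cfg):
        for af in (0.0, 1e-5, 1e-4, 5e-4, 0.01, 0.5):
            v = variant(scores=VariantScores(population_af=af))
            if passes_frequency(v, ann("missense_variant"), cfg):
                assert passes_frequency(v, ann("stop_gained"), cfg)


class TestPathogenicity:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            (VariantScores(cadd_phred=25, revel=0.646, alphamissense=0.91), True),
            (VariantScores(revel=0.49), False),
            (VariantScores(cadd_phred=35), True),  # LoF without REVEL/AM survives
            (VariantScores(cadd_phred=30, clinvar_significance="Likely_benign"), False),
            (VariantScores(cadd_phred=30, clinvar_significance="Benign"), False),
            (VariantScores(cadd_phred=19.9), False),
            (VariantScores(alphamissense=0.563), False),
            (VariantScores(), True),  # nothing present, nothing excludes
            (VariantScores(clinvar_significance="Conflicting_interpretations_of_pathogenicity"), True),
            (VariantScores(clinvar_significance="Benign/Likely_benign"), False),
            (VariantScores(clinvar_significance="Likely_pathogenic"), True),
        ],
    )
    def test_score_and_clinvar_gates(self, cfg, scores, expected):
        assert passes_pathogenicity(variant(scores=scores), cfg) is expected


class TestConsequenceClass:
    @pytest.mark.parametrize(
        "terms,expected",
        [(("splice_donor_variant",), True), (("inframe_insertion",), True),
         (("missense_variant",), True), (("intron_variant",), False),
         (("synonymous_variant",), False), (("intron_variant", "missense_variant"), True)],
    )
    def test_coding_and_splice_restriction(self, cfg, terms, expected):
        assert passes_consequence_class(ann(*terms), cfg) is expected


class TestConfig:
    def test_inverted_af_tiers_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(af_max_high_impact=1e-5, af_max_other=1e-2)

    def test_qualifying_must_contain_high_impact(self):
        with pytest.raises(ValueError):
            FilterConfig(qualifying_consequences=frozenset({"missense_variant"}))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("min_cadd: 15\nmin_gq: 90\n")
        cfg = FilterConfig.from_file(path)
        assert (cfg.min_cadd, cfg.min_gq) == (15, 90)
        assert cfg.af_max_other == 0.0001  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("max_cadd: 15\n")
        with pytest.raises(ValueError, match="unknown"):
            FilterConfig.from_file(path)


def test_predicate_conjunction_is_order_independent(family_ped, cfg, panels):
    """The retained set is identical under any permutation of predicates."""
    import itertools as it

    from adfunnel.model import representative_annotation
    from adfunnel.panels import assign_pathways
    from adfunnel.simulate import SimParams, simulate_family_vcf

    records, _ = simulate_family_vcf(family_ped, SimParams(n_background=60, n_causal=2, seed=5))
    preds = [
        lambda v: passes_site_quality(v, cfg) and passes_genotype_quality(v, family_ped.sample_ids, cfg),
        lambda v: passes_ad_segregation(v, family_ped),
        lambda v: passes_frequency(v, representative_annotation(v.annotations), cfg),
        lambda v: passes_pathogenicity(v, cfg),
        lambda v: passes_consequence_class(representative_annotation(v.annotations), cfg),
        lambda v: bool(assign_pathways(representative_annotation(v.annotations).gene_symbol, panels)),
    ]
    reference = None
    for perm in it.islice(it.permutations(preds), 0, 24, 5):
        kept = [v.variant_id for v in records if all(p(v) for p in perm)]
        if reference is None:
            reference = kept
        assert kept == reference
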