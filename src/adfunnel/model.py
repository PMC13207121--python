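"""Core data model for annotated, decomposed variant records.

Every record is biallelic: multi-allelic VCF sites are split into one
record per alternate allele before anything downstream sees them, so all
filter predicates and genotype logic can assume allele indices in {0, 1}.
Missing values (uncalled genotypes, absent scores, absent site statistics)
are represented as ``None`` and their treatment is deferred to the filter
layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SampleGenotype",
    "TranscriptAnnotation",
    "VariantScores",
    "VariantRecord",
    "SEVERITY_ORDER",
    "IMPACT_BY_CONSEQUENCE",
    "consequence_rank",
    "representative_annotation",
]

# Sequence Ontology consequence terms ranked most→least severe, following
# the ordering Ensembl VEP uses to pick a variant's "most severe consequence".
SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)

_SEVERITY_RANK = {term: i for i, term in enumerate(SEVERITY_ORDER)}

# VEP impact tier per consequence term; used when the annotation source
# does not carry an IMPACT sub-field.
IMPACT_BY_CONSEQUENCE: dict[str, str] = {
    **{t: "HIGH" for t in (
        "transcript_ablation", "splice_acceptor_variant", "splice_donor_variant",
        "stop_gained", "frameshift_variant", "stop_lost", "start_lost",
        "transcript_amplification", "feature_elongation", "feature_truncation",
    )},
    **{t: "MODERATE" for t in (
        "inframe_insertion", "inframe_deletion", "missense_variant",
        "protein_altering_variant",
    )},
    **{t: "LOW" for t in (
        "splice_donor_5th_base_variant", "splice_region_variant",
        "splice_donor_region_variant", "splice_polypyrimidine_tract_variant",
        "incomplete_terminal_codon_variant", "start_retained_variant",
        "stop_retained_variant", "synonymous_variant",
    )},
}


def consequence_rank(term: str) -> int:
    """Severity rank of a Sequence Ontology term (0 = most severe).

    Unknown terms rank after every known term so they never outcompete a
    recognized consequence.
    """
    return _SEVERITY_RANK.get(term, len(SEVERITY_ORDER))


@dataclass(frozen=True)
class SampleGenotype:
    """One sample's call at one biallelic site.

    ``alleles`` is an ordered pair of allele indices (0 = reference,
    1 = the record's single alternate) or ``None`` for an uncalled
    genotype. ``depth`` (DP) and ``genotype_quality`` (GQ) may be missing.
    """

    sample_id: str
    alleles: Optional[tuple[int, int]]
    depth: Optional[int] = None
    genotype_quality: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if len(self.alleles) != 2 or any(a not in (0, 1) for a in self.alleles):
                raise ValueError(
                    f"allele indices must be in {{0,1}} after decomposition, "
                    f"got {self.alleles!r} for sample {self.sample_id!r}"
                )
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth for sample {self.sample_id!r}")
        if self.genotype_quality is not None and self.genotype_quality < 0:
            raise ValueError(f"negative GQ for sample {self.sample_id!r}")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        """True for a 0/1 (or 1/0) call."""
        return self.alleles is not None and sorted(self.alleles) == [0, 1]

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles == (1, 1)

    @property
    def n_alt(self) -> int:
        """Alternate-allele dosage; 0 for a missing call."""
        return 0 if self.alleles is None else sum(self.alleles)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Per-transcript functional annotation (one VEP CSQ block)."""

    gene_symbol: str
    transcript_id: str
    consequence_terms: tuple[str, ...]
    impact_tier: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.consequence_terms:
            raise ValueError("consequence_terms must be non-empty")

    @property
    def most_severe_rank(self) -> int:
        return min(consequence_rank(t) for t in self.consequence_terms)

    @property
    def most_severe_consequence(self) -> str:
        return min(self.consequence_terms, key=consequence_rank)

    def impact(self) -> str:
        """Declared impact tier, or one derived from the severity table."""
        if self.impact_tier:
            return self.impact_tier
        return IMPACT_BY_CONSEQUENCE.get(self.most_severe_consequence, "MODIFIER")


@dataclass(frozen=True)
class VariantScores:
    """Variant-level population frequency and in-silico pathogenicity scores.

    All fields are optional; an absent score never excludes a variant on
    its own (that policy lives in :mod:`adfunnel.filters`).
    """

    population_af: Optional[float] = None
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    alphamissense: Optional[float] = None
    clinvar_significance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError(f"population_af outside [0,1]: {self.population_af}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"negative CADD: {self.cadd_phred}")
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError(f"REVEL outside [0,1]: {self.revel}")
        if self.alphamissense is not None and not (0.0 <= self.alphamissense <= 1.0):
            raise ValueError(f"AlphaMissense outside [0,1]: {self.alphamissense}")


@dataclass
class VariantRecord:
    """One biallelic variant with site statistics, genotypes, annotations.

    Positions are 1-based as in VCF. ``site_qual`` is the VCF QUAL column;
    ``qd``/``mq``/``fs`` are the GATK site annotations (QD, MQ, FS) and may
    be missing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_qual: Optional[float] = None
    qd: Optional[float] = None
    mq: Optional[float] = None
    fs: Optional[float] = None
    genotypes: dict[str, SampleGenotype] = field(default_factory=dict)
    annotations: list[TranscriptAnnotation] = field(default_factory=list)
    scores: VariantScores = field(default_factory=VariantScores)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError("VariantRecord holds exactly one alt allele")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def genotype(self, sample_id: str) -> SampleGenotype:
        try:
            return self.genotypes[sample_id]
        except KeyError:
            raise KeyError(
                f"sample {sample_id!r} has no genotype at {self.variant_id}"
            ) from None


def representative_annotation(
    annotations: list[TranscriptAnnotation],
    severity_order: tuple[str, ...] = SEVERITY_ORDER,
) -> TranscriptAnnotation:
    """Pick the single annotation that represents a variant.

    If exactly one annotation is flagged canonical it wins; otherwise the
    annotation whose most severe consequence ranks highest in
    ``severity_order`` wins, with ties broken by lexicographic transcript
    id. Deterministic and idempotent.
    """
    if not annotations:
        raise ValueError("representative_annotation requires >= 1 annotation")
    canonical = [a for a in annotations if a.canonical]
    if len(canonical) == 1:
        return canonical[0]
    rank = {term: i for i, term in enumerate(severity_order)}
    n = len(severity_order)

    def key(a: TranscriptAnnotation) -> tuple[int, str]:
        best = min(rank.get(t, n) for t in a.consequence_terms)
        return (best, a.transcript_id)

    return min(annotations, key=key)
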