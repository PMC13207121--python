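"""Per-variant exclusion predicates for dominant-variant prioritization.

Each predicate is pure and order-independent: the final retained set is
the conjunction of all predicates regardless of the order they are
applied in (only the per-stage funnel counts depend on order).

Default thresholds implement a GATK + VEP exome workflow: site-level
QUAL/QD/MQ/FS hard filters, per-sample DP/GQ retention, impact-stratified
gnomAD allele-frequency tiers (1% for putative loss-of-function, 0.01%
otherwise), CADD/REVEL/AlphaMissense in-silico gates, ClinVar
benign/likely-benign removal, and restriction to protein-altering or
splice-site consequences. Missing values never exclude: a variant absent
from gnomAD cannot exceed a frequency bound, and a loss-of-function
variant without a REVEL/AlphaMissense prediction is not penalized for it.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Sequence, Union

import yaml

from .model import TranscriptAnnotation, VariantRecord
from .pedigree import Pedigree

__all__ = [
    "FilterConfig",
    "HIGH_IMPACT",
    "OTHER",
    "passes_site_quality",
    "passes_genotype_quality",
    "passes_ad_segregation",
    "passes_het_only",
    "classify_impact",
    "passes_frequency",
    "passes_pathogenicity",
    "passes_consequence_class",
]

HIGH_IMPACT = "HIGH_IMPACT"
OTHER = "OTHER"

DEFAULT_HIGH_IMPACT_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "stop_lost",
        "start_lost",
        "transcript_ablation",
    }
)

DEFAULT_QUALIFYING_CONSEQUENCES = DEFAULT_HIGH_IMPACT_CONSEQUENCES | frozenset(
    {
        "missense_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
    }
)

DEFAULT_BENIGN_LABELS = frozenset({"benign", "likely_benign"})


@dataclass(frozen=True)
class FilterConfig:
    """All thresholds of the filtering cascade, in one place.

    Defaults: DP > 10 and GQ >= 99 per sample; site QUAL >= 10.0,
    QD >= 2.0, MQ >= 20.0, FS <= 200.0; allele-frequency caps 1% for
    high-impact and 0.01% for other consequences; CADD >= 20,
    REVEL >= 0.5, AlphaMissense >= 0.564 when the score is present.
    """

    min_depth_exclusive: int = 10
    min_gq: int = 99
    min_qual: float = 10.0
    min_qd: float = 2.0
    min_mq: float = 20.0
    max_fs: float = 200.0
    af_max_high_impact: float = 0.01
    af_max_other: float = 0.0001
    min_cadd: float = 20.0
    min_revel: float = 0.5
    min_am: float = 0.564
    high_impact_consequences: frozenset[str] = DEFAULT_HIGH_IMPACT_CONSEQUENCES
    qualifying_consequences: frozenset[str] = DEFAULT_QUALIFYING_CONSEQUENCES
    benign_clinvar_labels: frozenset[str] = DEFAULT_BENIGN_LABELS

    def __post_init__(self) -> None:
        if self.af_max_other > self.af_max_high_impact:
            raise ValueError(
                "af_max_other must not exceed af_max_high_impact "
                f"({self.af_max_other} > {self.af_max_high_impact})"
            )
        if not self.high_impact_consequences <= self.qualifying_consequences:
            raise ValueError(
                "qualifying_consequences must contain every high-impact consequence"
            )

    @classmethod
    def from_mapping(cls, data: dict) -> "FilterConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in (
            "high_impact_consequences",
            "qualifying_consequences",
            "benign_clinvar_labels",
        ):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FilterConfig":
        """Load thresholds from a YAML (or JSON) mapping; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


def passes_site_quality(v: VariantRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """Site-level hard filters: QUAL, QD, MQ, FS. Missing QD/MQ/FS never exclude."""
    if v.site_qual is not None and v.site_qual < cfg.min_qual:
        return False
    if v.qd is not None and v.qd < cfg.min_qd:
        return False
    if v.mq is not None and v.mq < cfg.min_mq:
        return False
    if v.fs is not None and v.fs > cfg.max_fs:
        return False
    return True


def passes_genotype_quality(
    v: VariantRecord,
    sample_ids: Sequence[str],
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Per-sample call quality: every listed sample called, DP > 10, GQ >= 99.

    A missing call, DP or GQ among the listed samples fails the variant.
    """
    for sid in sample_ids:
        g = v.genotype(sid)
        if g.is_missing:
            return False
        if g.depth is None or g.depth <= cfg.min_depth_exclusive:
            return False
        if g.genotype_quality is None or g.genotype_quality < cfg.min_gq:
            return False
    return True


def passes_ad_segregation(v: VariantRecord, ped: Pedigree) -> bool:
    """Autosomal-dominant co-segregation across the pedigree.

    True iff every affected member is heterozygous and every unaffected
    member is homozygous reference; any missing call among pedigree
    members fails. Members with unknown phenotype are not constrained.
    """
    for sid in ped.affected_ids:
        g = v.genotype(sid)
        if g.is_missing or not g.is_het:
            return False
    for sid in ped.unaffected_ids:
        g = v.genotype(sid)
        if g.is_missing or not g.is_hom_ref:
            return False
    return True


def passes_het_only(v: VariantRecord, sample_id: str) -> bool:
    """Singleton mode: retain only heterozygous calls in the given sample."""
    g = v.genotype(sample_id)
    return not g.is_missing and g.is_het


def classify_impact(
    a: TranscriptAnnotation, cfg: FilterConfig = FilterConfig()
) -> str:
    """HIGH_IMPACT if any consequence term is in the configured LoF set, else OTHER."""
    if any(t in cfg.high_impact_consequences for t in a.consequence_terms):
        return HIGH_IMPACT
    return OTHER


def passes_frequency(
    v: VariantRecord,
    a: TranscriptAnnotation,
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Impact-stratified population allele-frequency cap.

    High-impact variants tolerate AF up to 1%; all others up to 0.01%.
    A variant with no population AF is treated as novel and retained.
    """
    af = v.scores.population_af
    if af is None:
        return True
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"population AF outside [0,1]: {af}")
    cap = (
        cfg.af_max_high_impact
        if classify_impact(a, cfg) == HIGH_IMPACT
        else cfg.af_max_other
    )
    return af <= cap


def _is_benign_label(clin_sig: str, benign_labels: frozenset[str]) -> bool:
    # Conservative: a record that also carries pathogenic or conflicting
    # assertions is not treated as benign.
    norm = clin_sig.strip().lower().replace(" ", "_")
    if "pathogenic" in norm or "conflicting" in norm:
        return False
    return any(label in norm for label in benign_labels)


def passes_pathogenicity(v: VariantRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """In-silico pathogenicity gate plus ClinVar benign removal.

    Excludes when any *present* score is sub-threshold (CADD < 20,
    REVEL < 0.5, AlphaMissense < 0.564) or when the ClinVar significance
    matches a benign/likely-benign label (case-insensitive substring;
    entries that also assert pathogenic or conflicting are kept).
    Missing scores never exclude.
    """
    s = v.scores
    if s.cadd_phred is not None and s.cadd_phred < cfg.min_cadd:
        return False
    if s.revel is not None and s.revel < cfg.min_revel:
        return False
    if s.alphamissense is not None and s.alphamissense < cfg.min_am:
        return False
    if s.clinvar_significance is not None and _is_benign_label(
        s.clinvar_significance, cfg.benign_clinvar_labels
    ):
        return False
    return True


def passes_consequence_class(
    a: TranscriptAnnotation, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Retain only coding/splice-site consequences that can alter the protein."""
    return any(t in cfg.qualifying_consequences for t in a.consequence_terms)
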