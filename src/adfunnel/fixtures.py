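"""Packaged study fixtures and the family worked example.

Ships three small plain-text fixtures: the 22-participant clinical
cohort table, the per-patient candidate-gene table (with each gene's
family-pathway flag as published), and the six-member three-generation
pedigree. Also builds, in memory, the family worked-example VCF: the
three co-segregating causative variants (CD44 splice-donor, ITIH2
missense, ADAM21 stop-gain) with their published carrier pattern, plus
seven synthetic distractor variants that each violate exactly one
pipeline stage.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .model import SampleGenotype, TranscriptAnnotation, VariantRecord, VariantScores
from .panels import FAMILY_CAUSATIVE_GENES, SharedPathwaySummary
from .pedigree import Pedigree, read_pedigree

__all__ = [
    "load_cohort_table",
    "load_patient_candidates",
    "patient_shared_summary",
    "load_family_pedigree",
    "family_worked_example",
]

_FAMILY_SAMPLES = ("G1-Fa", "G1-Mo", "G2-So", "G2-Da1", "G2-Da2", "G3-Da")
_AFFECTED = ("G1-Fa", "G2-Da1", "G2-Da2", "G3-Da")


def _data_path(name: str):
    return resources.files("adfunnel.data").joinpath(name)


def load_cohort_table() -> pd.DataFrame:
    """The packaged clinical cohort table (22 participants).

    List-valued columns (complications, laxity_events) are pre-tokenized,
    semicolon-separated canonical terms and are returned as Python lists.
    """
    with resources.as_file(_data_path("cohort.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"participant": str})
    for col in ("complications", "laxity_events"):
        df[col] = df[col].fillna("").map(
            lambda s: [t for t in s.split(";") if t]
        )
    df["ankle_symptom"] = df["ankle_symptom"].fillna("").map(lambda s: s or None)
    df["dance_major"] = df["dance_major"].astype(bool)
    df["family_history"] = df["family_history"].astype(bool)
    return df


def load_patient_candidates() -> pd.DataFrame:
    """Per-patient candidate genes with published family-pathway flags.

    One row per (participant, pathway-related gene); ``n_target_variants``
    is the participant's total candidate-variant count and
    ``family_pathway`` records whether the gene belongs to one of the
    pathways harboring the family-derived causative genes.
    """
    with resources.as_file(_data_path("patient_candidates.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"participant": str})
    df["family_pathway"] = df["family_pathway"].astype(bool)
    df["patient_pathways"] = df["patient_pathways"].map(lambda s: s.split(";"))
    return df


def patient_shared_summary(df: Optional[pd.DataFrame] = None) -> SharedPathwaySummary:
    """Shared-gene/pathway flags per patient from the candidate table.

    A patient is flagged when any candidate gene either is one of the
    family causative genes or carries the recorded family-pathway flag.
    """
    if df is None:
        df = load_patient_candidates()
    per_patient: dict[str, dict] = {}
    flagged: list[str] = []
    unflagged: list[str] = []
    for patient, group in df.groupby("participant", sort=False):
        same_gene = bool(group["gene"].isin(FAMILY_CAUSATIVE_GENES).any())
        same_pathway = bool(group["family_pathway"].any())
        per_patient[patient] = {"same_gene": same_gene, "same_pathway": same_pathway}
        (flagged if (same_gene or same_pathway) else unflagged).append(patient)
    return SharedPathwaySummary(
        per_patient=per_patient,
        flagged_patients=flagged,
        unflagged_patients=unflagged,
    )


def load_family_pedigree() -> Pedigree:
    """The packaged three-generation, six-member pedigree (4 affected)."""
    with resources.as_file(_data_path("family.ped")) as path:
        return read_pedigree(path)


def _family_genotypes(
    carriers: tuple[str, ...] = _AFFECTED,
    dp: int = 45,
    gq: int = 99,
    overrides: Optional[dict[str, SampleGenotype]] = None,
) -> dict[str, SampleGenotype]:
    genotypes = {
        sid: SampleGenotype(
            sample_id=sid,
            alleles=(0, 1) if sid in carriers else (0, 0),
            depth=dp,
            genotype_quality=gq,
        )
        for sid in _FAMILY_SAMPLES
    }
    if overrides:
        genotypes.update(overrides)
    return genotypes


def _variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: str,
    consequence: str,
    hgvs_c: str = "",
    hgvs_p: str = "",
    scores: VariantScores = VariantScores(),
    genotypes: Optional[dict[str, SampleGenotype]] = None,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        site_qual=1200.0,
        qd=25.0,
        mq=60.0,
        fs=1.5,
        genotypes=genotypes if genotypes is not None else _family_genotypes(),
        annotations=[
            TranscriptAnnotation(
                gene_symbol=gene,
                transcript_id=f"ENST_{gene}",
                consequence_terms=(consequence,),
                hgvs_c=hgvs_c or None,
                hgvs_p=hgvs_p or None,
                canonical=True,
            )
        ],
        scores=scores,
    )


def family_worked_example() -> tuple[list[VariantRecord], Pedigree]:
    """The three published causative variants plus seven synthetic distractors.

    The causative records reproduce the published loci, consequences and
    carrier pattern (heterozygous in the four affected members, absent in
    the two unaffected spouses). Each distractor is fully compliant except
    for exactly one filter stage: low GQ, broken co-segregation, common
    allele frequency, low CADD, ClinVar benign, intronic consequence, and
    an off-panel gene.
    """
    ped = load_family_pedigree()
    causal = [
        _variant(
            "chr11", 35_208_207, "G", "A", "CD44", "splice_donor_variant",
            hgvs_c="c.1516+1G>A",
            scores=VariantScores(cadd_phred=34.0),
        ),
        _variant(
            "chr10", 7_721_693, "C", "G", "ITIH2", "missense_variant",
            hgvs_c="c.783C>G", hgvs_p="p.Cys261Trp",
            scores=VariantScores(cadd_phred=25.0, revel=0.646, alphamissense=0.91),
        ),
        _variant(
            "chr14", 70_457_896, "C", "T", "ADAM21", "stop_gained",
            hgvs_c="c.397C>T", hgvs_p="p.Arg133Ter",
            scores=VariantScores(cadd_phred=35.0),
        ),
    ]
    low_gq = SampleGenotype("G2-Da1", (0, 1), depth=45, genotype_quality=50)
    het_spouse = SampleGenotype("G2-So", (0, 1), depth=45, genotype_quality=99)
    distractors = [
        _variant(
            "chr2", 10_000, "A", "G", "TTN", "missense_variant",
            scores=VariantScores(cadd_phred=28.0, revel=0.8, alphamissense=0.7),
            genotypes=_family_genotypes(overrides={"G2-Da1": low_gq}),
        ),
        _variant(
            "chr5", 20_000, "C", "T", "HMMR", "missense_variant",
            scores=VariantScores(cadd_phred=27.0, revel=0.7, alphamissense=0.8),
            genotypes=_family_genotypes(carriers=_AFFECTED + ("G2-So",),
                                        overrides={"G2-So": het_spouse}),
        ),
        _variant(
            "chr1", 30_000, "G", "A", "MMP8", "missense_variant",
            scores=VariantScores(population_af=0.02, cadd_phred=26.0,
                                 revel=0.75, alphamissense=0.7),
        ),
        _variant(
            "chr17", 40_000, "T", "C", "SOX9", "missense_variant",
            scores=VariantScores(cadd_phred=5.0, revel=0.7, alphamissense=0.7),
        ),
        _variant(
            "chr14", 50_000, "G", "C", "SEC23A", "missense_variant",
            scores=VariantScores(cadd_phred=30.0, revel=0.7, alphamissense=0.7,
                                 clinvar_significance="Benign"),
        ),
        _variant(
            "chr11", 60_000, "A", "T", "CD44", "intron_variant",
            scores=VariantScores(cadd_phred=22.0),
        ),
        _variant(
            "chr7", 70_000, "C", "A", "ACTB", "missense_variant",
            scores=VariantScores(cadd_phred=29.0, revel=0.9, alphamissense=0.9),
        ),
    ]
    return causal + distractors, ped
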