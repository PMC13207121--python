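"""Funnel orchestration: fixed stage order, per-stage accounting, reports.

The cascade applies the filter predicates in the canonical order

    quality -> inheritance (co-segregation or het-only) -> frequency
    -> pathogenicity -> consequence -> pathway

recording (retained variants, distinct representative genes) after each
stage. The predicates are conjunctive, so the order only affects the
intermediate counts, never the final retained set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

import pandas as pd

from .filters import (
    FilterConfig,
    passes_ad_segregation,
    passes_consequence_class,
    passes_frequency,
    passes_genotype_quality,
    passes_het_only,
    passes_pathogenicity,
    passes_site_quality,
)
from .model import VariantRecord, representative_annotation
from .panels import CandidateVariant, GenePanel, assign_pathways, prioritize
from .pedigree import Pedigree
from .vcfio import read_vcf

__all__ = [
    "FunnelReport",
    "PipelineResult",
    "CohortResult",
    "run_family_pipeline",
    "run_cohort_pipeline",
    "cosegregation_table",
]

STAGE_QUALITY = "quality"
STAGE_SEGREGATION = "segregation"
STAGE_HET_ONLY = "heterozygous"
STAGE_FREQUENCY = "frequency"
STAGE_PATHOGENICITY = "pathogenicity"
STAGE_CONSEQUENCE = "consequence"
STAGE_PATHWAY = "pathway"


def _round1(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FunnelReport:
    """Ordered per-stage (variant count, distinct gene count) pairs."""

    mode: str  # "family" | "singleton"
    stages: list[dict]

    def __post_init__(self) -> None:
        prev_v = prev_g = None
        for st in self.stages:
            if st["gene_count"] > st["variant_count"]:
                raise ValueError(
                    f"stage {st['stage_name']}: gene count exceeds variant count"
                )
            if prev_v is not None and (
                st["variant_count"] > prev_v or st["gene_count"] > prev_g
            ):
                raise ValueError(
                    f"stage {st['stage_name']}: counts increased along the funnel"
                )
            prev_v, prev_g = st["variant_count"], st["gene_count"]

    def counts(self) -> list[tuple[int, int]]:
        return [(s["variant_count"], s["gene_count"]) for s in self.stages]

    def final_count(self) -> int:
        return self.stages[-1]["variant_count"]

    def to_json(self, destination: Union[str, Path, IO[str], None] = None) -> str:
        payload = json.dumps({"mode": self.mode, "stages": self.stages}, indent=2)
        if destination is not None:
            if hasattr(destination, "write"):
                destination.write(payload)
            else:
                Path(destination).write_text(payload + "\n")
        return payload


@dataclass
class PipelineResult:
    funnel: FunnelReport
    candidates: list[CandidateVariant]
    cosegregation: Optional[pd.DataFrame]
    audit: Optional[dict[str, str]] = None  # variant_id -> first failing stage


@dataclass
class CohortResult:
    funnels: dict[str, FunnelReport]
    candidates: dict[str, list[CandidateVariant]]
    summary: dict


def _gene_of(v: VariantRecord) -> str:
    return representative_annotation(v.annotations).gene_symbol.upper()


def _stage_counts(variants: Sequence[VariantRecord]) -> tuple[int, int]:
    genes = {_gene_of(v) for v in variants if v.annotations}
    genes.discard("")
    return len(variants), len(genes)


def _run_funnel(
    variants: list[VariantRecord],
    stages: list[tuple[str, callable]],
    mode: str,
    audit: bool,
) -> tuple[FunnelReport, list[VariantRecord], Optional[dict[str, str]]]:
    audit_log: Optional[dict[str, str]] = {} if audit else None
    counts = [
        {
            "stage_name": "initial",
            "variant_count": _stage_counts(variants)[0],
            "gene_count": _stage_counts(variants)[1],
        }
    ]
    retained = variants
    for name, predicate in stages:
        kept = []
        for v in retained:
            if predicate(v):
                kept.append(v)
            elif audit_log is not None and v.variant_id not in audit_log:
                audit_log[v.variant_id] = name
        retained = kept
        n_v, n_g = _stage_counts(retained)
        counts.append({"stage_name": name, "variant_count": n_v, "gene_count": n_g})
    return FunnelReport(mode=mode, stages=counts), retained, audit_log


def _build_stages(
    cfg: FilterConfig,
    panels: Sequence[GenePanel],
    quality_samples: Sequence[str],
    inheritance_name: str,
    inheritance_pred,
) -> list[tuple[str, callable]]:
    def quality(v: VariantRecord) -> bool:
        return passes_site_quality(v, cfg) and passes_genotype_quality(
            v, quality_samples, cfg
        )

    def frequency(v: VariantRecord) -> bool:
        return passes_frequency(v, representative_annotation(v.annotations), cfg)

    def consequence(v: VariantRecord) -> bool:
        return passes_consequence_class(representative_annotation(v.annotations), cfg)

    def pathway(v: VariantRecord) -> bool:
        return bool(assign_pathways(_gene_of(v), panels))

    return [
        (STAGE_QUALITY, quality),
        (inheritance_name, inheritance_pred),
        (STAGE_FREQUENCY, frequency),
        (STAGE_PATHOGENICITY, lambda v: passes_pathogenicity(v, cfg)),
        (STAGE_CONSEQUENCE, consequence),
        (STAGE_PATHWAY, pathway),
    ]


def _load(vcf: Union[str, Path, Sequence[VariantRecord]]) -> list[VariantRecord]:
    if isinstance(vcf, (str, Path)):
        return read_vcf(vcf)
    return list(vcf)


def run_family_pipeline(
    vcf: Union[str, Path, Sequence[VariantRecord]],
    ped: Pedigree,
    cfg: FilterConfig,
    panels: Sequence[GenePanel],
    audit: bool = False,
) -> PipelineResult:
    """Family mode: dominant co-segregation across the whole pedigree.

    Every pedigree member must have a genotype column in the VCF. Returns
    the funnel report, the prioritized candidates, and the co-segregation
    matrix of the candidates across the pedigree.
    """
    variants = _load(vcf)
    if variants:
        missing = set(ped.sample_ids) - set(variants[0].genotypes)
        if missing:
            raise ValueError(
                f"pedigree members absent from VCF samples: {sorted(missing)}"
            )
    stages = _build_stages(
        cfg,
        panels,
        quality_samples=ped.sample_ids,
        inheritance_name=STAGE_SEGREGATION,
        inheritance_pred=lambda v: passes_ad_segregation(v, ped),
    )
    funnel, retained, audit_log = _run_funnel(variants, stages, "family", audit)
    candidates = prioritize([("family", v) for v in retained], panels)
    matrix = cosegregation_table(candidates, ped)
    return PipelineResult(
        funnel=funnel, candidates=candidates, cosegregation=matrix, audit=audit_log
    )


def run_cohort_pipeline(
    vcf_per_patient: Mapping[str, Union[str, Path, Sequence[VariantRecord]]],
    cfg: FilterConfig,
    panels: Sequence[GenePanel],
    sample_map: Optional[Mapping[str, str]] = None,
    audit: bool = False,
) -> CohortResult:
    """Singleton mode: one funnel per patient with het-only inheritance.

    ``sample_map`` selects the sample column per patient when a VCF holds
    several samples; by default a single-sample VCF's sole sample is used
    (or a column named after the patient, if present).
    """
    funnels: dict[str, FunnelReport] = {}
    per_patient: dict[str, list[CandidateVariant]] = {}
    audits: dict[str, str] = {}
    for patient, source in vcf_per_patient.items():
        if patient in funnels:
            raise ValueError(f"patient id collision: {patient!r}")
        variants = _load(source)
        if sample_map and patient in sample_map:
            sample = sample_map[patient]
        elif variants and patient in variants[0].genotypes:
            sample = patient
        elif variants and len(variants[0].genotypes) == 1:
            sample = next(iter(variants[0].genotypes))
        else:
            sample = patient
        stages = _build_stages(
            cfg,
            panels,
            quality_samples=[sample],
            inheritance_name=STAGE_HET_ONLY,
            inheritance_pred=lambda v, s=sample: passes_het_only(v, s),
        )
        funnel, retained, audit_log = _run_funnel(variants, stages, "singleton", audit)
        funnels[patient] = funnel
        per_patient[patient] = prioritize([(patient, v) for v in retained], panels)
        if audit_log:
            audits.update({f"{patient}:{k}": v for k, v in audit_log.items()})

    all_candidates = [c for cands in per_patient.values() for c in cands]
    genes = sorted({c.gene_symbol for c in all_candidates})
    pathway_gene_counts: dict[str, int] = {}
    for gene in genes:
        for pw in assign_pathways(gene, panels):
            pathway_gene_counts[pw] = pathway_gene_counts.get(pw, 0) + 1
    n_patients = len(vcf_per_patient)
    summary = {
        "n_patients": n_patients,
        "total_candidate_variants": len(all_candidates),
        "distinct_candidate_genes": len(genes),
        "genes": genes,
        "per_pathway_gene_counts": dict(sorted(pathway_gene_counts.items())),
        "mean_variants_per_patient": _round1(len(all_candidates) / n_patients)
        if n_patients
        else 0.0,
        "mean_genes_per_patient": _round1(
            sum(len({c.gene_symbol for c in v}) for v in per_patient.values())
            / n_patients
        )
        if n_patients
        else 0.0,
    }
    return CohortResult(funnels=funnels, candidates=per_patient, summary=summary)


def cosegregation_table(
    candidates: Sequence[CandidateVariant],
    ped: Pedigree,
    variants: Optional[Sequence[VariantRecord]] = None,
) -> pd.DataFrame:
    """Carrier matrix: one row per pedigree member, one column per candidate.

    Cells are "+" (carries the alternate allele), "-" (does not), or "."
    (missing call). Row metadata gives id, sex, and affected status.
    """
    by_id = {c.variant.variant_id: c for c in candidates}
    if variants is not None:
        lookup = {v.variant_id: v for v in variants}
    else:
        lookup = {vid: c.variant for vid, c in by_id.items()}
    rows = []
    columns = [
        (c.gene_symbol, c.variant.variant_id) for c in candidates
    ]
    for ind in ped.individuals:
        row: dict[str, object] = {
            "id": ind.id,
            "sex": ind.sex,
            "affected": "A" if ind.affected else ("U" if ind.affected is False else "?"),
        }
        for gene, vid in columns:
            g = lookup[vid].genotype(ind.id)
            row[gene] = "." if g.is_missing else ("+" if g.n_alt > 0 else "-")
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", "sex", "affected"] + [g for g, _ in columns])
    return df.set_index("id")
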