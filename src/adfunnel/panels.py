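"""Pathway gene panels and pathway-level prioritization.

A panel is a named pathway with a set of gene symbols; symbols are
normalized to uppercase and matching is exact (alias resolution, if
needed, is supplied through the config, never inferred). The packaged
default panels cover the hEDS-related pathways used for candidate
prioritization; the pathways that harbor the family-derived causative
genes (hyaluronan-ECM axis, ECM remodeling, cell-matrix adhesion) carry a
``family_shared`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .model import VariantRecord, representative_annotation
from .vcfio import CandidateRow

__all__ = [
    "GenePanel",
    "CandidateVariant",
    "SharedPathwaySummary",
    "load_panels",
    "default_panels",
    "family_shared_pathways",
    "assign_pathways",
    "prioritize",
    "shared_pathway_summary",
]

FAMILY_CAUSATIVE_GENES = frozenset({"CD44", "ITIH2", "ADAM21"})


@dataclass(frozen=True)
class GenePanel:
    pathway_name: str
    gene_symbols: frozenset[str]
    family_shared: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"panel {self.pathway_name!r} has an empty gene list")

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.gene_symbols


@dataclass(frozen=True)
class CandidateVariant:
    """A post-filter variant assigned to at least one pathway panel."""

    patient_id: str
    variant: VariantRecord
    gene_symbol: str
    pathways: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("CandidateVariant requires >= 1 pathway")

    def to_row(self) -> CandidateRow:
        rep = representative_annotation(self.variant.annotations)
        return CandidateRow(
            patient_id=self.patient_id,
            gene=self.gene_symbol,
            chrom=self.variant.chrom,
            pos=self.variant.pos,
            ref=self.variant.ref,
            alt=self.variant.alt,
            hgvs_c=rep.hgvs_c or "",
            hgvs_p=rep.hgvs_p or "",
            consequence=rep.most_severe_consequence,
            pathways=self.pathways,
        )


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def load_panels(
    config: Union[Mapping, str, Path],
) -> list[GenePanel]:
    """Build panels from a mapping or a YAML/JSON panel file.

    Two layouts are accepted: ``{pathway: [genes...]}`` or the richer
    ``{"pathways": {pathway: {"genes": [...], "family_shared": bool}}}``.
    Duplicate pathway names and empty gene lists are errors.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not config:
        raise ValueError("panel config is empty")
    entries = config.get("pathways", config) if isinstance(config, Mapping) else config
    pairs = entries.items() if isinstance(entries, Mapping) else entries
    panels: list[GenePanel] = []
    seen: set[str] = set()
    for name, spec in pairs:
        if name in seen:
            raise ValueError(f"duplicate pathway name {name!r}")
        seen.add(name)
        if isinstance(spec, Mapping):
            genes = spec.get("genes", [])
            shared = bool(spec.get("family_shared", False))
        else:
            genes = spec
            shared = False
        panels.append(
            GenePanel(
                pathway_name=name,
                gene_symbols=frozenset(_normalize(g) for g in genes),
                family_shared=shared,
            )
        )
    return panels


def default_panels() -> list[GenePanel]:
    """The packaged default hEDS pathway panels."""
    ref = resources.files("adfunnel.data").joinpath("panels.yaml")
    with resources.as_file(ref) as path:
        return load_panels(path)


def family_shared_pathways(panels: Sequence[GenePanel]) -> frozenset[str]:
    """Names of the pathways flagged as containing the family causative genes."""
    return frozenset(p.pathway_name for p in panels if p.family_shared)


def assign_pathways(gene: str, panels: Sequence[GenePanel]) -> list[str]:
    """All pathway names whose panel contains the gene (case-insensitive)."""
    g = _normalize(gene)
    return [p.pathway_name for p in panels if g in p.gene_symbols]


def prioritize(
    variants: Iterable[tuple[str, VariantRecord]],
    panels: Sequence[GenePanel],
) -> list[CandidateVariant]:
    """Keep only variants whose representative gene sits in >= 1 panel.

    Input order is preserved; each retained variant is annotated with all
    of its matching pathways.
    """
    out: list[CandidateVariant] = []
    for patient_id, v in variants:
        gene = representative_annotation(v.annotations).gene_symbol
        pathways = assign_pathways(gene, panels)
        if pathways:
            out.append(
                CandidateVariant(
                    patient_id=patient_id,
                    variant=v,
                    gene_symbol=_normalize(gene),
                    pathways=tuple(pathways),
                )
            )
    return out


@dataclass
class SharedPathwaySummary:
    """Per-patient overlap with the family-derived causative genes/pathways."""

    per_patient: dict[str, dict]
    flagged_patients: list[str]
    unflagged_patients: list[str]

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_patients)

    @property
    def n_unflagged(self) -> int:
        return len(self.unflagged_patients)


def shared_pathway_summary(
    per_patient_candidates: Mapping[str, Sequence[CandidateVariant]],
    family_genes: frozenset[str] = FAMILY_CAUSATIVE_GENES,
    family_pathways: Optional[frozenset[str]] = None,
    panels: Optional[Sequence[GenePanel]] = None,
) -> SharedPathwaySummary:
    """Flag patients whose candidates overlap the family genes or pathways.

    ``same_gene`` marks a candidate gene among the family causative genes;
    ``same_pathway`` marks any candidate pathway among the family-shared
    pathways (default: the ``family_shared`` panels). A patient is flagged
    if either holds for at least one candidate.
    """
    if family_pathways is None:
        family_pathways = family_shared_pathways(panels if panels is not None else default_panels())
    family_genes = frozenset(_normalize(g) for g in family_genes)
    per_patient: dict[str, dict] = {}
    flagged: list[str] = []
    unflagged: list[str] = []
    for patient, candidates in per_patient_candidates.items():
        same_gene = any(_normalize(c.gene_symbol) in family_genes for c in candidates)
        same_pathway = any(
            set(c.pathways) & family_pathways for c in candidates
        )
        per_patient[patient] = {"same_gene": same_gene, "same_pathway": same_pathway}
        (flagged if (same_gene or same_pathway) else unflagged).append(patient)
    return SharedPathwaySummary(
        per_patient=per_patient,
        flagged_patients=flagged,
        unflagged_patients=unflagged,
    )
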