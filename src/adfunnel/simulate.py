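"""Synthetic annotated exome VCFs with Mendelian transmission and truth.

The generator emulates the annotation schema the pipeline consumes
(GATK-style site statistics, per-sample DP/GQ, a VEP CSQ field with
gnomAD AF, CADD, REVEL, AlphaMissense and ClinVar) on synthetic contigs,
so every pipeline stage is testable without any reference data. Causal
variants are constructed to satisfy every filter; each background variant
is constructed to violate exactly the stage(s) recorded in its truth
entry, with co-segregation violations arising from Mendelian transmission
out of a random founder rather than by fiat. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np

from .model import SampleGenotype, TranscriptAnnotation, VariantRecord, VariantScores
from .panels import GenePanel, default_panels
from .pedigree import Pedigree
from .pipeline import (
    STAGE_CONSEQUENCE,
    STAGE_FREQUENCY,
    STAGE_HET_ONLY,
    STAGE_PATHOGENICITY,
    STAGE_PATHWAY,
    STAGE_QUALITY,
    STAGE_SEGREGATION,
)

__all__ = [
    "SimParams",
    "TruthEntry",
    "TruthTable",
    "simulate_family_vcf",
    "simulate_cohort_vcfs",
]

FAMILY_VIOLATION_STAGES = (
    STAGE_QUALITY,
    STAGE_SEGREGATION,
    STAGE_FREQUENCY,
    STAGE_PATHOGENICITY,
    STAGE_CONSEQUENCE,
    STAGE_PATHWAY,
)
SINGLETON_VIOLATION_STAGES = (
    STAGE_QUALITY,
    STAGE_HET_ONLY,
    STAGE_FREQUENCY,
    STAGE_PATHOGENICITY,
    STAGE_CONSEQUENCE,
    STAGE_PATHWAY,
)

# Compliant consequence sampler: protein-altering terms with LoF minority.
_QUALIFYING_TERMS = (
    "missense_variant",
    "stop_gained",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
)
_QUALIFYING_PROBS = (0.5, 0.15, 0.15, 0.1, 0.1)
_NON_QUALIFYING_TERMS = (
    "intron_variant",
    "synonymous_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
    "upstream_gene_variant",
)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimParams:
    """Knobs of the simulator; defaults give smoke-testable funnels.

    ``panel_fraction`` is the chance a background variant's gene is drawn
    from the panels (off-panel genes are synthesized). ``common_af_range``
    is the allele-frequency band used for frequency violations;
    compliant variants draw missing AF 90% of the time and AF < 1e-4
    otherwise.
    """

    n_background: int = 100
    n_causal: int = 3
    seed: int = 0
    panel_fraction: float = 0.5
    p_af_missing: float = 0.9
    rare_af_max: float = 1e-4
    common_af_range: tuple[float, float] = (0.001, 0.1)
    dp_range: tuple[int, int] = (15, 80)
    causal_genes: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_causal < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.panel_fraction <= 1.0):
            raise ValueError("panel_fraction must be in [0,1]")


@dataclass(frozen=True)
class TruthEntry:
    variant_id: str
    is_causal: bool
    gene: str
    planted_violations: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.is_causal and self.planted_violations:
            raise ValueError("causal variants must have no planted violations")


@dataclass
class TruthTable:
    entries: list[TruthEntry]

    @property
    def by_id(self) -> dict[str, TruthEntry]:
        return {e.variant_id: e for e in self.entries}

    def causal_ids(self) -> set[str]:
        return {e.variant_id for e in self.entries if e.is_causal}

    def to_tsv(self, destination: Union[str, Path, IO[str]]) -> None:
        lines = ["variant_id\tis_causal\tgene\tplanted_violations"]
        for e in self.entries:
            lines.append(
                f"{e.variant_id}\t{int(e.is_causal)}\t{e.gene}\t"
                + ",".join(e.planted_violations)
            )
        text = "\n".join(lines) + "\n"
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)


def _panel_gene_pool(panels: Sequence[GenePanel]) -> list[str]:
    return sorted({g for p in panels for g in p.gene_symbols})


def _sample_scores(rng: np.random.Generator, consequence: str, p: SimParams) -> VariantScores:
    """Scores that satisfy every pathogenicity/frequency gate."""
    af = None if rng.random() < p.p_af_missing else float(rng.uniform(0, p.rare_af_max))
    if consequence == "missense_variant":
        return VariantScores(
            population_af=af,
            cadd_phred=float(rng.uniform(20, 40)),
            revel=float(rng.uniform(0.5, 1.0)),
            alphamissense=float(rng.uniform(0.564, 1.0)),
        )
    return VariantScores(population_af=af, cadd_phred=float(rng.uniform(20, 40)))


def _annotation(gene: str, consequence: str, idx: int) -> TranscriptAnnotation:
    return TranscriptAnnotation(
        gene_symbol=gene,
        transcript_id=f"ENST{idx:011d}",
        consequence_terms=(consequence,),
        impact_tier=None,
        hgvs_c=f"c.{idx + 1}A>G",
        hgvs_p=None,
        canonical=True,
    )


def _compliant_call(sid: str, het: bool, rng: np.random.Generator, p: SimParams) -> SampleGenotype:
    return SampleGenotype(
        sample_id=sid,
        alleles=(0, 1) if het else (0, 0),
        depth=int(rng.integers(p.dp_range[0], p.dp_range[1] + 1)),
        genotype_quality=99,
    )


def _segregating_genotypes(
    ped: Pedigree, rng: np.random.Generator, p: SimParams
) -> dict[str, SampleGenotype]:
    return {
        ind.id: _compliant_call(ind.id, het=bool(ind.affected), rng=rng, p=p)
        for ind in ped.individuals
    }


def _mendelian_transmission(
    ped: Pedigree, carrier_founder: str, rng: np.random.Generator
) -> dict[str, int]:
    """Alt-allele dosage per individual, one alt copy entering via a founder."""
    dosage: dict[str, tuple[int, int]] = {}

    def alleles_of(iid: str) -> tuple[int, int]:
        if iid in dosage:
            return dosage[iid]
        ind = ped.by_id[iid]
        if ind.is_founder:
            a = (0, 1) if iid == carrier_founder else (0, 0)
        else:
            pat = alleles_of(ind.father_id) if ind.father_id else (0, 0)
            mat = alleles_of(ind.mother_id) if ind.mother_id else (0, 0)
            a = (pat[int(rng.integers(2))], mat[int(rng.integers(2))])
        dosage[iid] = a
        return a

    return {ind.id: sum(alleles_of(ind.id)) for ind in ped.individuals}


def _violating_transmission(
    ped: Pedigree, rng: np.random.Generator, p: SimParams
) -> dict[str, SampleGenotype]:
    """Mendelian genotypes that do NOT co-segregate dominantly.

    Rejection-samples transmissions from a random founder until the
    pattern violates "all affected het and all unaffected hom-ref";
    a hom-ref affected member is forced if sampling never violates.
    """
    founders = ped.founder_ids
    for _ in range(64):
        carrier = founders[int(rng.integers(len(founders)))]
        dosage = _mendelian_transmission(ped, carrier, rng)
        ok = all(dosage[s] == 1 for s in ped.affected_ids) and all(
            dosage[s] == 0 for s in ped.unaffected_ids
        )
        if not ok:
            return {
                ind.id: SampleGenotype(
                    sample_id=ind.id,
                    alleles=(0, 1) if dosage[ind.id] == 1 else ((1, 1) if dosage[ind.id] == 2 else (0, 0)),
                    depth=int(rng.integers(p.dp_range[0], p.dp_range[1] + 1)),
                    genotype_quality=99,
                )
                for ind in ped.individuals
            }
    genotypes = _segregating_genotypes(ped, rng, p)
    victim = ped.affected_ids[0]
    return {**genotypes, victim: replace(genotypes[victim], alleles=(0, 0))}


def _base_pair(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _make_variant(
    idx: int,
    pos: int,
    gene: str,
    consequence: str,
    genotypes: dict[str, SampleGenotype],
    scores: VariantScores,
    rng: np.random.Generator,
) -> VariantRecord:
    ref, alt = _base_pair(rng)
    return VariantRecord(
        chrom="chrS1",
        pos=pos,
        ref=ref,
        alt=alt,
        site_qual=float(rng.uniform(100, 2000)),
        qd=float(rng.uniform(5, 35)),
        mq=60.0,
        fs=float(rng.uniform(0, 10)),
        genotypes=genotypes,
        annotations=[_annotation(gene, consequence, idx)],
        scores=scores,
    )


def _apply_quality_violation(
    v: VariantRecord, rng: np.random.Generator
) -> VariantRecord:
    kind = int(rng.integers(6))
    if kind == 0:
        v.site_qual = float(rng.uniform(0, 9.9))
    elif kind == 1:
        v.qd = float(rng.uniform(0, 1.9))
    elif kind == 2:
        v.mq = float(rng.uniform(0, 19.9))
    elif kind == 3:
        v.fs = float(rng.uniform(200.1, 500))
    else:
        sid = list(v.genotypes)[int(rng.integers(len(v.genotypes)))]
        g = v.genotypes[sid]
        if kind == 4:
            v.genotypes[sid] = replace(g, depth=int(rng.integers(0, 11)))
        else:
            v.genotypes[sid] = replace(g, genotype_quality=int(rng.integers(0, 99)))
    return v


def _violated_scores(
    rng: np.random.Generator, consequence: str, stage: str, p: SimParams
) -> tuple[str, VariantScores]:
    """Consequence and scores realizing a frequency/pathogenicity/consequence violation."""
    if stage == STAGE_FREQUENCY:
        # a common missense fails the 0.01% tier regardless of scores
        s = _sample_scores(rng, "missense_variant", p)
        af = float(rng.uniform(*p.common_af_range))
        return "missense_variant", replace(s, population_af=af)
    if stage == STAGE_PATHOGENICITY:
        s = _sample_scores(rng, "missense_variant", p)
        kind = int(rng.integers(4))
        if kind == 0:
            s = replace(s, cadd_phred=float(rng.uniform(0, 19.9)))
        elif kind == 1:
            s = replace(s, revel=float(rng.uniform(0, 0.49)))
        elif kind == 2:
            s = replace(s, alphamissense=float(rng.uniform(0, 0.563)))
        else:
            s = replace(
                s,
                clinvar_significance="Benign" if rng.random() < 0.5 else "Likely_benign",
            )
        return "missense_variant", s
    if stage == STAGE_CONSEQUENCE:
        term = _NON_QUALIFYING_TERMS[int(rng.integers(len(_NON_QUALIFYING_TERMS)))]
        af = None if rng.random() < p.p_af_missing else float(rng.uniform(0, p.rare_af_max))
        return term, VariantScores(population_af=af, cadd_phred=float(rng.uniform(20, 40)))
    raise ValueError(stage)


def _compliant_consequence(rng: np.random.Generator) -> str:
    return str(rng.choice(_QUALIFYING_TERMS, p=_QUALIFYING_PROBS))


def _background_gene(
    idx: int, rng: np.random.Generator, pool: list[str], p: SimParams, off_panel: bool
) -> str:
    if off_panel:
        return f"OFFPANEL{idx}"
    if rng.random() < p.panel_fraction:
        return pool[int(rng.integers(len(pool)))]
    return f"BGGENE{idx}"


def simulate_family_vcf(
    ped: Pedigree,
    params: SimParams,
    panels: Optional[Sequence[GenePanel]] = None,
) -> tuple[list[VariantRecord], TruthTable]:
    """Simulate a multi-sample family VCF with planted causal variants.

    Causal variants co-segregate dominantly and satisfy every filter
    threshold; each background variant violates exactly one pipeline
    stage, drawn uniformly. Returns records in position order plus the
    truth table.
    """
    if panels is None:
        panels = default_panels()
    pool = _panel_gene_pool(panels)
    if params.n_causal > len(pool) and params.causal_genes is None:
        raise ValueError(
            f"n_causal={params.n_causal} exceeds the {len(pool)} available panel genes"
        )
    rng = np.random.default_rng(params.seed)
    causal_pool = (
        list(params.causal_genes)
        if params.causal_genes is not None
        else [pool[i] for i in rng.choice(len(pool), size=params.n_causal, replace=False)]
    )
    roles = ["causal"] * params.n_causal + ["background"] * params.n_background
    rng.shuffle(roles)

    records: list[VariantRecord] = []
    entries: list[TruthEntry] = []
    pos = 0
    n_causal_done = 0
    for idx, role in enumerate(roles):
        pos += int(rng.integers(100, 1000))
        if role == "causal":
            gene = causal_pool[n_causal_done % len(causal_pool)]
            n_causal_done += 1
            consequence = _compliant_consequence(rng)
            v = _make_variant(
                idx,
                pos,
                gene,
                consequence,
                _segregating_genotypes(ped, rng, params),
                _sample_scores(rng, consequence, params),
                rng,
            )
            entries.append(TruthEntry(v.variant_id, True, gene, ()))
            records.append(v)
            continue
        stage = FAMILY_VIOLATION_STAGES[int(rng.integers(len(FAMILY_VIOLATION_STAGES)))]
        gene = _background_gene(idx, rng, pool, params, off_panel=stage == STAGE_PATHWAY)
        if stage in (STAGE_FREQUENCY, STAGE_PATHOGENICITY, STAGE_CONSEQUENCE):
            consequence, scores = _violated_scores(rng, "", stage, params)
        else:
            consequence = _compliant_consequence(rng)
            scores = _sample_scores(rng, consequence, params)
        if stage == STAGE_SEGREGATION:
            genotypes = _violating_transmission(ped, rng, params)
        else:
            genotypes = _segregating_genotypes(ped, rng, params)
        v = _make_variant(idx, pos, gene, consequence, genotypes, scores, rng)
        if stage == STAGE_QUALITY:
            v = _apply_quality_violation(v, rng)
        entries.append(TruthEntry(v.variant_id, False, gene, (stage,)))
        records.append(v)
    return records, TruthTable(entries)


def simulate_cohort_vcfs(
    n_patients: int,
    params: SimParams,
    panels: Optional[Sequence[GenePanel]] = None,
) -> tuple[dict[str, list[VariantRecord]], TruthTable]:
    """Simulate one single-sample VCF per patient plus a pooled truth table.

    Causal variants are heterozygous calls in panel genes satisfying all
    thresholds; background variants violate exactly one singleton-mode
    stage (het-only inheritance violations are hom-alt or hom-ref calls).
    Truth ids are prefixed ``patient:variant_id``.
    """
    if panels is None:
        panels = default_panels()
    pool = _panel_gene_pool(panels)
    rng = np.random.default_rng(params.seed)
    per_patient: dict[str, list[VariantRecord]] = {}
    entries: list[TruthEntry] = []
    for p_idx in range(n_patients):
        patient = f"P{p_idx + 1:02d}"
        causal_pool = (
            list(params.causal_genes)
            if params.causal_genes is not None
            else [pool[i] for i in rng.choice(len(pool), size=params.n_causal, replace=False)]
        )
        roles = ["causal"] * params.n_causal + ["background"] * params.n_background
        rng.shuffle(roles)
        records: list[VariantRecord] = []
        pos = 0
        n_causal_done = 0
        for idx, role in enumerate(roles):
            pos += int(rng.integers(100, 1000))
            uid = p_idx * (len(roles) + 1) + idx
            if role == "causal":
                gene = causal_pool[n_causal_done % len(causal_pool)]
                n_causal_done += 1
                consequence = _compliant_consequence(rng)
                v = _make_variant(
                    uid,
                    pos,
                    gene,
                    consequence,
                    {patient: _compliant_call(patient, het=True, rng=rng, p=params)},
                    _sample_scores(rng, consequence, params),
                    rng,
                )
                entries.append(TruthEntry(f"{patient}:{v.variant_id}", True, gene, ()))
                records.append(v)
                continue
            stage = SINGLETON_VIOLATION_STAGES[
                int(rng.integers(len(SINGLETON_VIOLATION_STAGES)))
            ]
            gene = _background_gene(uid, rng, pool, params, off_panel=stage == STAGE_PATHWAY)
            if stage in (STAGE_FREQUENCY, STAGE_PATHOGENICITY, STAGE_CONSEQUENCE):
                consequence, scores = _violated_scores(rng, "", stage, params)
            else:
                consequence = _compliant_consequence(rng)
                scores = _sample_scores(rng, consequence, params)
            if stage == STAGE_HET_ONLY:
                # hom-ref or hom-alt: fails het-only retention but passes
                # call quality, so the planted stage is the first failure
                alleles = [(0, 0), (1, 1)][int(rng.integers(2))]
                call = SampleGenotype(
                    sample_id=patient,
                    alleles=alleles,
                    depth=int(rng.integers(params.dp_range[0], params.dp_range[1] + 1)),
                    genotype_quality=99,
                )
            else:
                call = _compliant_call(patient, het=True, rng=rng, p=params)
            v = _make_variant(uid, pos, gene, consequence, {patient: call}, scores, rng)
            if stage == STAGE_QUALITY:
                v = _apply_quality_violation(v, rng)
            entries.append(TruthEntry(f"{patient}:{v.variant_id}", False, gene, (stage,)))
            records.append(v)
        per_patient[patient] = records
    return per_patient, TruthTable(entries)
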