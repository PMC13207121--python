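"""Reading and writing annotated multi-sample VCFs and candidate tables.

Reading is delegated to :mod:`pysam`; records are decomposed to biallelic
:class:`~adfunnel.model.VariantRecord` objects on the way in. Writing
emits plain VCF v4.2 text directly so that identical inputs always
produce byte-identical files.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import pysam

from .model import SampleGenotype, TranscriptAnnotation, VariantRecord, VariantScores

__all__ = [
    "DEFAULT_CSQ_FIELDS",
    "VcfParseError",
    "parse_csq",
    "read_vcf",
    "write_vcf",
    "CandidateRow",
    "write_candidates",
    "read_candidates",
]

# Default VEP CSQ sub-field schema; override when the annotating VEP run
# used a different --fields configuration.
DEFAULT_CSQ_FIELDS: tuple[str, ...] = (
    "Consequence",
    "IMPACT",
    "SYMBOL",
    "Feature",
    "CANONICAL",
    "HGVSc",
    "HGVSp",
    "gnomAD_AF",
    "CADD_PHRED",
    "REVEL",
    "am_pathogenicity",
    "CLIN_SIG",
)

_SCORE_FIELDS = ("gnomAD_AF", "CADD_PHRED", "REVEL", "am_pathogenicity", "CLIN_SIG")


class VcfParseError(ValueError):
    """Malformed VCF content, CSQ schema mismatch, or sample mismatch."""


def _opt(value: Optional[str]) -> Optional[str]:
    return value if value not in (None, "", ".") else None


def _opt_float(value: Optional[str], context: str) -> Optional[float]:
    v = _opt(value)
    if v is None:
        return None
    try:
        return float(v)
    except ValueError:
        raise VcfParseError(f"non-numeric value {v!r} for {context}") from None


def parse_csq(
    csq_value: str,
    csq_field_names: Sequence[str] = DEFAULT_CSQ_FIELDS,
) -> tuple[list[TranscriptAnnotation], VariantScores]:
    """Parse one CSQ INFO value into annotations plus variant-level scores.

    ``csq_value`` is a comma-separated list of transcript blocks, each a
    pipe-separated tuple matching ``csq_field_names``. Variant-level
    scores are taken from the first block that defines them; empty
    sub-fields map to missing.
    """
    names = list(csq_field_names)
    annotations: list[TranscriptAnnotation] = []
    score_values: dict[str, Optional[str]] = {k: None for k in _SCORE_FIELDS}
    for i, block in enumerate(csq_value.split(",")):
        parts = block.split("|")
        if len(parts) != len(names):
            raise VcfParseError(
                f"CSQ block {i} has {len(parts)} sub-fields, "
                f"expected {len(names)} ({'|'.join(names)})"
            )
        fields = dict(zip(names, parts))
        consequence = _opt(fields.get("Consequence"))
        annotations.append(
            TranscriptAnnotation(
                gene_symbol=_opt(fields.get("SYMBOL")) or "",
                transcript_id=_opt(fields.get("Feature")) or "",
                consequence_terms=tuple((consequence or "sequence_variant").split("&")),
                impact_tier=_opt(fields.get("IMPACT")),
                hgvs_c=_opt(fields.get("HGVSc")),
                hgvs_p=_opt(fields.get("HGVSp")),
                canonical=_opt(fields.get("CANONICAL")) == "YES",
            )
        )
        for key in _SCORE_FIELDS:
            if score_values[key] is None:
                score_values[key] = _opt(fields.get(key))
    scores = VariantScores(
        population_af=_opt_float(score_values["gnomAD_AF"], "gnomAD_AF"),
        cadd_phred=_opt_float(score_values["CADD_PHRED"], "CADD_PHRED"),
        revel=_opt_float(score_values["REVEL"], "REVEL"),
        alphamissense=_opt_float(score_values["am_pathogenicity"], "am_pathogenicity"),
        clinvar_significance=score_values["CLIN_SIG"],
    )
    return annotations, scores


def _csq_fields_from_header(header: pysam.VariantHeader) -> Optional[list[str]]:
    rec = header.info.get("CSQ")
    if rec is None or not rec.description:
        return None
    marker = "Format: "
    desc = rec.description
    if marker not in desc:
        return None
    return desc.split(marker, 1)[1].strip().strip('"').split("|")


def read_vcf(
    source: Union[str, Path, IO],
    csq_field_names: Optional[Sequence[str]] = None,
) -> list[VariantRecord]:
    """Read an annotated multi-sample VCF into decomposed variant records.

    Multi-allelic sites are split into one biallelic record per alternate
    allele; genotype allele indices are re-coded per record (the record's
    alt → 1, every other allele → 0). When ``csq_field_names`` is omitted
    the schema is taken from the CSQ header Description ("Format: ...").
    """
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode()
        with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
            tmp.write(data)
            path = tmp.name
        try:
            return read_vcf(path, csq_field_names)
        finally:
            Path(path).unlink(missing_ok=True)

    try:
        vf = pysam.VariantFile(str(source))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {source}: {exc}") from exc

    names: Optional[list[str]]
    if csq_field_names is not None:
        names = list(csq_field_names)
        declared = _csq_fields_from_header(vf.header)
        if declared is not None and len(declared) != len(names):
            raise VcfParseError(
                f"CSQ schema mismatch: header declares {len(declared)} sub-fields, "
                f"caller supplied {len(names)}"
            )
    else:
        names = _csq_fields_from_header(vf.header)

    records: list[VariantRecord] = []
    sample_ids = list(vf.header.samples)
    try:
        for recno, rec in enumerate(vf, start=1):
            records.extend(_decompose(rec, recno, sample_ids, names))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"malformed VCF body in {source}: {exc}") from exc
    finally:
        vf.close()
    return records


def _decompose(
    rec: "pysam.VariantRecord",
    recno: int,
    sample_ids: list[str],
    csq_names: Optional[list[str]],
) -> list[VariantRecord]:
    alts = rec.alts or ()
    if not alts:
        return []

    def info_get(key: str):
        # pysam raises for keys absent from the header; treat as missing
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):
            return None

    csq_raw = info_get("CSQ")
    annotations: list[TranscriptAnnotation] = []
    scores = VariantScores()
    if csq_raw is not None:
        if csq_names is None:
            raise VcfParseError(
                f"record {recno}: CSQ present but no sub-field schema available"
            )
        value = ",".join(csq_raw) if isinstance(csq_raw, tuple) else str(csq_raw)
        try:
            annotations, scores = parse_csq(value, csq_names)
        except VcfParseError as exc:
            raise VcfParseError(f"record {recno} ({rec.chrom}:{rec.pos}): {exc}") from exc

    def info_float(key: str) -> Optional[float]:
        v = info_get(key)
        if v is None:
            return None
        if isinstance(v, tuple):
            v = v[0]
        return float(v)

    out: list[VariantRecord] = []
    for k, alt in enumerate(alts, start=1):
        genotypes: dict[str, SampleGenotype] = {}
        for sid in sample_ids:
            call = rec.samples[sid]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                alleles = None
            else:
                alleles = tuple(1 if a == k else 0 for a in gt)
            dp = call.get("DP")
            gq = call.get("GQ")
            genotypes[sid] = SampleGenotype(
                sample_id=sid,
                alleles=alleles,  # type: ignore[arg-type]
                depth=None if dp is None else int(dp),
                genotype_quality=None if gq is None else int(gq),
            )
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                site_qual=rec.qual,
                qd=info_float("QD"),
                mq=info_float("MQ"),
                fs=info_float("FS"),
                genotypes=genotypes,
                annotations=annotations,
                scores=scores,
            )
        )
    return out


# ---------------------------------------------------------------------------
# writing

def _fmt(x: Optional[float]) -> str:
    # repr gives the shortest digit string that round-trips the float
    if x is None:
        return ""
    return repr(float(x))


def _csq_block(a: TranscriptAnnotation, s: VariantScores, names: Sequence[str]) -> str:
    values = {
        "Consequence": "&".join(a.consequence_terms),
        "IMPACT": a.impact_tier or "",
        "SYMBOL": a.gene_symbol,
        "Feature": a.transcript_id,
        "CANONICAL": "YES" if a.canonical else "",
        "HGVSc": a.hgvs_c or "",
        "HGVSp": a.hgvs_p or "",
        "gnomAD_AF": _fmt(s.population_af),
        "CADD_PHRED": _fmt(s.cadd_phred),
        "REVEL": _fmt(s.revel),
        "am_pathogenicity": _fmt(s.alphamissense),
        "CLIN_SIG": s.clinvar_significance or "",
    }
    return "|".join(values.get(n, "") for n in names)


def write_vcf(
    records: Iterable[VariantRecord],
    destination: Union[str, Path, IO[str]],
    sample_ids: Optional[Sequence[str]] = None,
    csq_field_names: Sequence[str] = DEFAULT_CSQ_FIELDS,
) -> None:
    """Write biallelic variant records as a plain VCF v4.2 text file.

    Sample column order defaults to the genotype-key order of the first
    record. Output is deterministic: identical records yield byte-identical
    files.
    """
    records = list(records)
    if sample_ids is None:
        sample_ids = list(records[0].genotypes) if records else []
    contigs: list[str] = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)

    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
        f'from Ensembl VEP. Format: {"|".join(csq_field_names)}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for r in records:
        info_parts = []
        for key, val in (("QD", r.qd), ("MQ", r.mq), ("FS", r.fs)):
            if val is not None:
                info_parts.append(f"{key}={format(val, 'g')}")
        if r.annotations:
            blocks = ",".join(
                _csq_block(a, r.scores, csq_field_names) for a in r.annotations
            )
            info_parts.append(f"CSQ={blocks}")
        cols = [
            r.chrom,
            str(r.pos),
            ".",
            r.ref,
            r.alt,
            "." if r.site_qual is None else format(r.site_qual, "g"),
            ".",
            ";".join(info_parts) or ".",
            "GT:DP:GQ",
        ]
        for sid in sample_ids:
            g = r.genotype(sid)
            gt = "./." if g.alleles is None else f"{g.alleles[0]}/{g.alleles[1]}"
            dp = "." if g.depth is None else str(g.depth)
            gq = "." if g.genotype_quality is None else str(g.genotype_quality)
            cols.append(f"{gt}:{dp}:{gq}")
        lines.append("\t".join(cols))
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


# ---------------------------------------------------------------------------
# candidate variant tables (per-patient TSV)

_CANDIDATE_COLUMNS = (
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "pathways",
)


@dataclass(frozen=True)
class CandidateRow:
    """One row of a candidate-variant TSV (per patient, per variant)."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    hgvs_p: str
    consequence: str
    pathways: tuple[str, ...]


def write_candidates(candidates: Iterable, destination: Union[str, Path, IO[str]]) -> None:
    """Write candidate variants as a TSV with a stable column order.

    Accepts :class:`CandidateRow` objects or anything exposing
    ``to_row()``. An empty list yields a header-only file.
    """
    rows = [c if isinstance(c, CandidateRow) else c.to_row() for c in candidates]
    lines = ["\t".join(_CANDIDATE_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.patient_id,
                    r.gene,
                    r.chrom,
                    str(r.pos),
                    r.ref,
                    r.alt,
                    r.hgvs_c,
                    r.hgvs_p,
                    r.consequence,
                    ",".join(r.pathways),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def read_candidates(source: Union[str, Path, IO[str]]) -> list[CandidateRow]:
    """Read back a candidate TSV written by :func:`write_candidates`."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [l for l in text.splitlines() if l]
    header = tuple(lines[0].split("\t"))
    if header != _CANDIDATE_COLUMNS:
        raise ValueError(f"unexpected candidate table header: {header}")
    rows = []
    for line in lines[1:]:
        f = line.split("\t")
        rows.append(
            CandidateRow(
                patient_id=f[0],
                gene=f[1],
                chrom=f[2],
                pos=int(f[3]),
                ref=f[4],
                alt=f[5],
                hgvs_c=f[6],
                hgvs_p=f[7],
                consequence=f[8],
                pathways=tuple(p for p in f[9].split(",") if p),
            )
        )
    return rows
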