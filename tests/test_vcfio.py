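import io

import pytest

from adfunnel.fixtures import family_worked_example
from adfunnel.model import VariantScores
from adfunnel.simulate import SimParams, simulate_family_vcf
from adfunnel.vcfio import (
    DEFAULT_CSQ_FIELDS,
    CandidateRow,
    VcfParseError,
    parse_csq,
    read_candidates,
    read_vcf,
    write_candidates,
    write_vcf,
)

CSQ_FORMAT = "|".join(DEFAULT_CSQ_FIELDS)

HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1>\n"
    '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
    f'from Ensembl VEP. Format: {CSQ_FORMAT}">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">\n'
)


def make_vcf(body_lines, samples=("S1", "S2", "S3", "S4")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    return HEADER + cols + "\n" + "".join(line + "\n" for line in body_lines)


class TestParseCsq:
    def test_splice_donor_block(self):
        block = f"splice_donor_variant|HIGH|CD44|ENST1|YES|c.1516+1G>A||||||"
        anns, scores = parse_csq(block)
        assert anns[0].consequence_terms == ("splice_donor_variant",)
        assert anns[0].gene_symbol == "CD44"
        assert anns[0].canonical
        assert scores.population_af is None

    def test_all_score_subfields_empty_map_to_missing(self):
        anns, scores = parse_csq("missense_variant||G1|T1||||||||")
        assert scores == VariantScores()

    def test_scores_taken_from_first_defining_block(self):
        b1 = "missense_variant||G1|T1||||||||"
        b2 = "missense_variant||G1|T2||||0.001|25|0.7|0.8|"
        anns, scores = parse_csq(b1 + "," + b2)
        assert len(anns) == 2
        assert scores.revel == 0.7
        assert scores.population_af == 0.001

    def test_multiple_consequence_terms_split_on_ampersand(self):
        anns, _ = parse_csq("missense_variant&splice_region_variant||G|T||||||||")
        assert anns[0].consequence_terms == ("missense_variant", "splice_region_variant")

    def test_wrong_block_arity_is_a_parse_error(self):
        with pytest.raises(VcfParseError, match="sub-fields"):
            parse_csq("missense_variant|only|three")


class TestReadVcf:
    def test_six_sample_carrier_pattern(self, tmp_path):
        samples = ("G1-Fa", "G1-Mo", "G2-So", "G2-Da1", "G2-Da2", "G3-Da")
        csq = f"missense_variant|MODERATE|ITIH2|T1|YES|c.783C>G|p.Cys261Trp|||||"
        gts = ["0/1:45:99", "0/0:40:99", "0/0:41:99", "0/1:50:99", "0/1:39:99", "0/1:44:99"]
        body = ["chr1\t100\t.\tC\tG\t900\t.\tCSQ=" + csq + "\tGT:DP:GQ\t" + "\t".join(gts)] * 3
        body = [b.replace("\t100\t", f"\t{100 + i}\t") for i, b in enumerate(body)]
        path = tmp_path / "fam.vcf"
        path.write_text(make_vcf(body, samples))
        records = read_vcf(path)
        assert len(records) == 3
        for r in records:
            assert len(r.genotypes) == 6
            assert r.genotype("G1-Fa").is_het
            assert r.genotype("G2-So").is_hom_ref

    def test_empty_body_with_valid_header(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(make_vcf([]))
        assert read_vcf(path) == []

    def test_multiallelic_site_decomposes_to_two_biallelic_records(self, tmp_path):
        body = ["chr1\t100\t.\tA\tG,T\t50\t.\t.\tGT:DP:GQ\t0/1:30:99\t1/2:30:99\t2/2:30:99\t0/0:30:99"]
        path = tmp_path / "ma.vcf"
        path.write_text(make_vcf(body))
        records = read_vcf(path)
        assert [r.alt for r in records] == ["G", "T"]
        assert all(r.pos == 100 for r in records)
        g_rec, t_rec = records
        assert g_rec.genotype("S2").alleles == (1, 0)
        assert t_rec.genotype("S2").alleles == (0, 1)
        assert t_rec.genotype("S3").is_hom_alt

    def test_decomposition_conserves_alt_allele_observations(self, tmp_path):
        body = ["chr1\t100\t.\tA\tG,T\t50\t.\t.\tGT:DP:GQ\t0/1:30:99\t1/2:30:99\t2/2:30:99\t0/0:30:99"]
        path = tmp_path / "ma.vcf"
        path.write_text(make_vcf(body))
        records = read_vcf(path)
        # carriers per original allele: G in {S1,S2}, T in {S2,S3} -> 4 pairs
        assert sum(sum(g.n_alt > 0 for g in r.genotypes.values()) for r in records) == 4

    def test_missing_call_preserved(self, tmp_path):
        body = ["chr1\t100\t.\tA\tG\t50\t.\t.\tGT:DP:GQ\t./.:.:.\t0/1:30:99\t0/0:30:99\t0/0:30:99"]
        path = tmp_path / "m.vcf"
        path.write_text(make_vcf(body))
        (rec,) = read_vcf(path)
        assert rec.genotype("S1").is_missing
        assert rec.genotype("S1").depth is None

    def test_malformed_header_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(VcfParseError):
            read_vcf(path)

    def test_csq_schema_length_mismatch_is_a_parse_error(self, tmp_path):
        path = tmp_path / "schema.vcf"
        path.write_text(make_vcf([]))
        with pytest.raises(VcfParseError, match="schema mismatch"):
            read_vcf(path, csq_field_names=["Consequence", "SYMBOL"])


class TestRoundTrip:
    def test_worked_example_round_trips(self, tmp_path):
        records, ped = family_worked_example()
        path = tmp_path / "rt.vcf"
        write_vcf(records, path, sample_ids=ped.sample_ids)
        back = read_vcf(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            assert a.genotypes == b.genotypes
            assert a.annotations == b.annotations
            assert a.scores == b.scores

    def test_simulated_records_round_trip(self, family_ped):
        records, _ = simulate_family_vcf(family_ped, SimParams(n_background=40, n_causal=2, seed=3))
        buf = io.StringIO()
        write_vcf(records, buf, sample_ids=family_ped.sample_ids)
        back = read_vcf(io.StringIO(buf.getvalue()))
        assert [(r.variant_id, r.genotypes, r.annotations, r.scores) for r in back] == [
            (r.variant_id, r.genotypes, r.annotations, r.scores) for r in records
        ]

    def test_writing_is_deterministic(self, family_ped):
        records, _ = simulate_family_vcf(family_ped, SimParams(n_background=20, seed=9))
        a, b = io.StringIO(), io.StringIO()
        write_vcf(records, a, sample_ids=family_ped.sample_ids)
        write_vcf(records, b, sample_ids=family_ped.sample_ids)
        assert a.getvalue() == b.getvalue()


class TestCandidateTable:
    def rows(self):
        return [
            CandidateRow("family", g, "chr1", 10 + i, "A", "G", "c.1A>G", "", "missense_variant",
                         ("HA-ECM axis",))
            for i, g in enumerate(["CD44", "ITIH2", "ADAM21"])
        ]

    def test_three_candidates_give_three_row_tsv(self, tmp_path):
        path = tmp_path / "cand.tsv"
        write_candidates(self.rows(), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4
        assert [l.split("\t")[1] for l in lines[1:]] == ["CD44", "ITIH2", "ADAM21"]

    def test_empty_list_gives_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_candidates([], path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_round_trip_reproduces_rows(self, tmp_path):
        path = tmp_path / "rt.tsv"
        rows = self.rows()
        write_candidates(rows, path)
        assert read_candidates(path) == rows
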