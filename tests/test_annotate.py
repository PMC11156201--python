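"""Codon-aware classification against hand-built toy gene models, with
exhaustive substitution oracles and reverse-complement checks."""

import numpy as np
import pytest
from Bio.Seq import Seq

from purgescan.annotate import (
    AnnotationError,
    AnnotationIndex,
    classify_site,
    classify_variant,
    fourfold_site_table,
)
from purgescan.simdata import CLASS_STOPGAIN
from purgescan._codon import revcomp


def write_toy(tmp_path, seq, gff_lines, name="toy"):
    fasta = tmp_path / f"{name}.fa"
    fasta.write_text(f">chr1\n{seq}\n")
    gff = tmp_path / f"{name}.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(gff_lines) + "\n")
    return fasta, gff


def gene_gff(start, end, strand, gid="g1", phase="0"):
    return [
        f"chr1\tt\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}",
        f"chr1\tt\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}",
        f"chr1\tt\tCDS\t{start}\t{end}\t.\t{strand}\t{phase}\tID={gid}.c;Parent={gid}.t1",
    ]


@pytest.fixture()
def plus_gene(tmp_path):
    # ATG GGA AAA CAG TAA  (Met Gly Lys Gln stop), positions 11..25
    seq = "T" * 10 + "ATGGGAAAACAGTAA" + "T" * 10
    fasta, gff = write_toy(tmp_path, seq, gene_gff(11, 25, "+"))
    return AnnotationIndex(fasta, gff)


class TestDegeneracy:
    def test_third_position_of_gly_codon_is_fourfold(self, plus_gene):
        ann = classify_site(plus_gene, "chr1", 16)  # GGA third position
        assert ann.region == "CDS"
        assert ann.degeneracy == 4 and ann.fourfold

    def test_third_position_of_lys_codon_is_twofold(self, plus_gene):
        ann = classify_site(plus_gene, "chr1", 19)  # AAA third position
        assert ann.degeneracy == 2 and not ann.fourfold

    def test_first_position_is_not_fourfold(self, plus_gene):
        ann = classify_site(plus_gene, "chr1", 14)  # GGA first position
        assert ann.degeneracy == 1


class TestRegions:
    def test_flanks_and_intergenic(self, plus_gene):
        assert classify_site(plus_gene, "chr1", 5).region == "upstream"
        assert classify_site(plus_gene, "chr1", 30).region == "downstream"

    def test_position_outside_reference_fails(self, plus_gene):
        with pytest.raises(AnnotationError, match="outside"):
            classify_site(plus_gene, "chr1", 10_000)

    def test_intron_between_cds_parts(self, tmp_path):
        # two CDS exons with an intron: ATG GGA ... intron ... TAA
        seq = "A" * 10 + "ATGGGA" + "GTTTTTAG" + "CAGTAA" + "A" * 10
        lines = [
            "chr1\tt\tgene\t11\t30\t.\t+\t.\tID=g1",
            "chr1\tt\tmRNA\t11\t30\t.\t+\t.\tID=g1.t1;Parent=g1",
            "chr1\tt\tCDS\t11\t16\t.\t+\t0\tID=c1;Parent=g1.t1",
            "chr1\tt\tCDS\t25\t30\t.\t+\t0\tID=c2;Parent=g1.t1",
        ]
        fasta, gff = write_toy(tmp_path, seq, lines)
        idx = AnnotationIndex(fasta, gff)
        assert classify_site(idx, "chr1", 20).region == "intron"
        assert classify_site(idx, "chr1", 26).region == "CDS"


class TestVariantEffects:
    def test_cag_to_tag_is_stopgain(self, plus_gene):
        ann = classify_variant(plus_gene, "chr1", 20, "C", "T")  # CAG -> TAG
        assert ann.effect == "stopgain"

    def test_third_position_lys_synonymous(self, plus_gene):
        ann = classify_variant(plus_gene, "chr1", 19, "A", "G")  # AAA -> AAG
        assert ann.effect == "synonymous"

    def test_nonsynonymous(self, plus_gene):
        ann = classify_variant(plus_gene, "chr1", 14, "G", "A")  # GGA -> AGA
        assert ann.effect == "nonsynonymous"

    def test_ref_mismatch_fails(self, plus_gene):
        with pytest.raises(AnnotationError, match="REF mismatch"):
            classify_variant(plus_gene, "chr1", 14, "T", "A")

    def test_minus_strand_stopgain_via_revcomp_oracle(self, tmp_path):
        # coding ATG TGG TAA on the minus strand; genomic segment is its
        # reverse complement. TGG -> TGA truncates the protein.
        coding = "ATGTGGTAA"
        seq = "C" * 10 + revcomp(coding) + "C" * 10
        fasta, gff = write_toy(tmp_path, seq, gene_gff(11, 19, "-"))
        idx = AnnotationIndex(fasta, gff)
        # coding offset 5 (third base of TGG) maps to genomic pos 11+8-5=14
        gpos = 11 + (len(coding) - 1) - 5
        genomic_ref = seq[gpos - 1]
        assert genomic_ref == "C"  # complement of coding G
        ann = classify_variant(idx, "chr1", gpos, genomic_ref, "T")  # coding G->A
        assert ann.effect == "stopgain"

    def test_most_severe_effect_across_transcripts(self, tmp_path):
        # same CDS twice with frames shifted by one codon: a site synonymous
        # in one frame and nonsynonymous in the other reports nonsynonymous
        seq = "A" * 10 + "ATGGGAGGATAA" + "A" * 10
        lines = gene_gff(11, 22, "+", gid="g1")
        lines += [
            "chr1\tt\tmRNA\t15\t23\t.\t+\t.\tID=g1.t2;Parent=g1",
            "chr1\tt\tCDS\t15\t23\t.\t+\t0\tID=c2;Parent=g1.t2",
        ]
        fasta, gff = write_toy(tmp_path, seq, lines)
        idx = AnnotationIndex(fasta, gff)
        # pos 16: third position of GGA in t1 (synonymous A->C), second
        # position of GAG in t2 (nonsynonymous)
        ann = classify_variant(idx, "chr1", 16, "A", "C")
        assert len(ann.contexts) == 2
        assert ann.effect == "nonsynonymous"


class TestFourfoldTable:
    def brute_force_fourfold(self, idx, seq, cds_start, cds_end, strand):
        """Independent oracle: try all 9 substitutions per codon position via
        full-CDS retranslation with Biopython."""
        out = []
        for pos in range(cds_start, cds_end + 1):
            ok = True
            any_cds = False
            region = seq[cds_start - 1 : cds_end]
            offset_in_cds = pos - cds_start
            for b in "ACGT":
                if b == seq[pos - 1]:
                    continue
                mutated = list(region)
                mutated[offset_in_cds] = b
                cds_ref = region if strand == "+" else revcomp(region)
                cds_alt = "".join(mutated) if strand == "+" else revcomp("".join(mutated))
                any_cds = True
                if str(Seq(cds_ref).translate()) != str(Seq(cds_alt).translate()):
                    ok = False
            if any_cds and ok:
                out.append(("chr1", pos))
        return out

    def test_single_gene_matches_exhaustive_oracle(self, tmp_path):
        seq = "G" * 8 + "ATGGGATTACGCTAA" + "G" * 8
        fasta, gff = write_toy(tmp_path, seq, gene_gff(9, 23, "+"))
        idx = AnnotationIndex(fasta, gff)
        got = fourfold_site_table(idx)
        expected = self.brute_force_fourfold(idx, seq, 9, 23, "+")
        assert got == expected
        assert ("chr1", 14) in got  # GGA third position

    def test_atg_stop_only_gene_is_empty(self, tmp_path):
        seq = "C" * 6 + "ATGTAA" + "C" * 6
        fasta, gff = write_toy(tmp_path, seq, gene_gff(7, 12, "+"))
        idx = AnnotationIndex(fasta, gff)
        assert fourfold_site_table(idx) == []

    def test_fourfold_in_one_frame_only_is_excluded(self, tmp_path):
        # transcript 2 shifts the frame by one codon+1 nt so GGA's third
        # position is mid-codon there
        seq = "A" * 10 + "ATGGGGACTTAA" + "A" * 10
        lines = gene_gff(11, 22, "+", gid="g1")
        lines += [
            "chr1\tt\tmRNA\t12\t20\t.\t+\t.\tID=g1.t2;Parent=g1",
            "chr1\tt\tCDS\t12\t20\t.\t+\t0\tID=c2;Parent=g1.t2",
        ]
        fasta, gff = write_toy(tmp_path, seq, lines)
        idx = AnnotationIndex(fasta, gff)
        # in transcript 1, GGG (codons ATG GGG ACT TAA) third pos = 16 is 4-fold
        solo_idx = AnnotationIndex(*write_toy(tmp_path, seq, gene_gff(11, 22, "+"), name="solo"))
        assert ("chr1", 16) in fourfold_site_table(solo_idx)
        assert ("chr1", 16) not in fourfold_site_table(idx)

    def test_every_fourfold_site_has_all_synonymous_alts(self, plus_gene):
        for chrom, pos in fourfold_site_table(plus_gene):
            ref = plus_gene.ref_base(chrom, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                assert classify_variant(plus_gene, chrom, pos, ref, alt).effect == "synonymous"


def test_strand_symmetry_on_reverse_complemented_genome(tmp_path):
    """Reverse-complementing the genome and flipping strand/coordinates
    preserves classifications at mapped positions."""
    seq = "T" * 10 + "ATGGGAAAACAGTAA" + "T" * 10
    L = len(seq)
    f1, g1 = write_toy(tmp_path, seq, gene_gff(11, 25, "+"), name="fwd")
    f2, g2 = write_toy(tmp_path, revcomp(seq), gene_gff(L - 25 + 1, L - 11 + 1, "-"), name="rev")
    fwd, rev = AnnotationIndex(f1, g1), AnnotationIndex(f2, g2)
    for pos in range(11, 26):
        a = classify_site(fwd, "chr1", pos)
        b = classify_site(rev, "chr1", L - pos + 1)
        assert a.region == b.region
        assert a.degeneracy == b.degeneracy
        assert a.fourfold == b.fourfold


def test_simulated_stopgain_truth_annotates_as_stopgain(sim_pair, bundle):
    ds, truth = sim_pair
    idx = AnnotationIndex(bundle["fasta"], bundle["gff3"])
    stop = np.flatnonzero(truth.site_class == CLASS_STOPGAIN)
    assert len(stop) > 0, "scenario produced no stopgain sites"
    for i in stop:
        ann = classify_variant(idx, str(ds.chrom[i]), int(ds.pos[i]), str(ds.ref[i]), str(ds.alt[i]))
        assert ann.effect == "stopgain"
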