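"""Dual-isoform SNV/insertion annotation and frameshift scanning."""

import numpy as np
import pytest

from startloss.gene_models import (
    STOP_CODONS,
    cds_sequence,
    cds_to_genomic,
    genomic_to_cds,
    translate,
)
from startloss.variant_consequence import (
    ReferenceMismatchError,
    Variant,
    annotate_insertion,
    annotate_snv,
    downstream_inframe_atgs,
    parse_fs_notation,
)


class TestWorkedExamples:
    """The recurrent-variant arithmetic: one A>G, two isoform consequences."""

    def test_missense_on_long_isoform(self, ugp2_fixture):
        genome, long_tx, _ = ugp2_fixture
        c = annotate_snv(Variant("chr2", 64_083_454, "A", "G"), long_tx, genome)
        assert (c.effect, c.hgvs_c, c.hgvs_p) == ("missense", "c.34A>G", "p.Met12Val")
        assert c.codon_index == 12

    def test_start_loss_on_short_isoform(self, ugp2_fixture):
        genome, _, short_tx = ugp2_fixture
        c = annotate_snv(Variant("chr2", 64_083_454, "A", "G"), short_tx, genome)
        assert (c.effect, c.hgvs_c, c.hgvs_p) == ("start_lost", "c.1A>G", "p.?")

    def test_frameshift_insertion_d15rfs33(self, ugp2_fixture):
        genome, long_tx, _ = ugp2_fixture
        ref = genome.fetch("chr2", 64_083_461, 64_083_462)
        c = annotate_insertion(Variant("chr2", 64_083_462, ref, ref + "A"),
                               long_tx, genome)
        assert c.effect == "frameshift"
        assert c.hgvs_c == "c.42_43insA"
        assert c.hgvs_p == "p.D15Rfs*33"
        assert (c.fs_first_residue, c.fs_ter_offset) == (15, 33)
        assert c.fs_stop_position == 47

    def test_rescue_atg_listed_for_start_loss(self, ugp2_fixture):
        """The short isoform's ATG is codon 12 of the long CDS, so the long
        CDS lists codon 12 among its in-frame downstream ATGs."""
        genome, long_tx, _ = ugp2_fixture
        assert 12 in downstream_inframe_atgs(long_tx, genome, max_codons=20)


class TestSnvClassification:
    def _simple_fixture(self):
        from conftest import make_transcript

        # M W A K *  — TGG at codon 2 for the stop-gain case
        cds = "ATGTGGGCTAAATAA"
        return make_transcript("AA" + cds + "AA", [(0, len(cds) + 4)],
                               (2, 2 + len(cds)))

    def test_stop_gained(self):
        genome, tx = self._simple_fixture()
        # c.6 G>A: TGG -> TGA
        pos = cds_to_genomic(tx, 6)
        c = annotate_snv(Variant("chrT", pos, "G", "A"), tx, genome)
        assert c.effect == "stop_gained"

    def test_synonymous_third_position(self):
        genome, tx = self._simple_fixture()
        # codon 3 GCT -> GCC (Ala)
        pos = cds_to_genomic(tx, 9)
        c = annotate_snv(Variant("chrT", pos, "T", "C"), tx, genome)
        assert c.effect == "synonymous"

    def test_reference_mismatch_guard(self):
        genome, tx = self._simple_fixture()
        with pytest.raises(ReferenceMismatchError):
            annotate_snv(Variant("chrT", 3, "C", "G"), tx, genome)

    @pytest.mark.parametrize("strand", "+-")
    def test_agrees_with_full_cds_rebuild_oracle(self, strand):
        """Classification matches an oracle that rebuilds the whole mutant
        CDS and diffs the translations, over random variants and fixtures."""
        from conftest import random_two_exon_transcript

        rng = np.random.default_rng(41 if strand == "+" else 42)
        n_checked = 0
        while n_checked < 300:
            genome, tx = random_two_exon_transcript(rng, strand=strand)
            contig = genome.contigs[tx.contig]
            cpos = int(rng.integers(1, tx.cds_length + 1))
            gpos = cds_to_genomic(tx, cpos)
            ref = contig[gpos - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            c = annotate_snv(Variant(tx.contig, gpos, ref, alt), tx, genome)

            # oracle: mutate the genome, re-extract, retranslate, diff
            mutant = dict(genome.contigs)
            mutant[tx.contig] = contig[:gpos - 1] + alt + contig[gpos:]
            from startloss.gene_models import GenomeSequence

            mutant_cds = cds_sequence(tx, GenomeSequence(mutant))
            ref_cds = cds_sequence(tx, genome)
            assert sum(a != b for a, b in zip(ref_cds, mutant_cds)) == 1
            ci = (cpos - 1) // 3
            ref_codon = ref_cds[3 * ci:3 * ci + 3]
            alt_codon = mutant_cds[3 * ci:3 * ci + 3]
            if ci == 0 and alt_codon != "ATG":
                expect = "start_lost"
            elif ref_codon in STOP_CODONS:
                expect = "synonymous" if alt_codon in STOP_CODONS else "stop_lost"
            elif alt_codon in STOP_CODONS:
                expect = "stop_gained"
            else:
                ref_p, _ = translate(ref_cds)
                try:
                    mut_p, _ = translate(mutant_cds, require_atg=False)
                    expect = "synonymous" if str(mut_p) == str(ref_p) else "missense"
                except Exception:
                    expect = "missense"
            assert c.effect == expect, (c, expect, ref_codon, alt_codon)
            n_checked += 1


class TestInsertions:
    def test_inframe_insertion_at_codon_boundary(self, ugp2_fixture):
        genome, long_tx, _ = ugp2_fixture
        pos = 64_083_420 + 33  # after c.33, a codon boundary
        ref = genome.fetch("chr2", pos - 1, pos)
        c = annotate_insertion(Variant("chr2", pos, ref, ref + "GCTGCA"),
                               long_tx, genome)
        assert c.effect == "inframe_insertion"

    def test_inframe_insertion_preserves_downstream_protein(self):
        """After a codon-aligned 3n insertion, the downstream protein equals
        the reference shifted by n residues."""
        from conftest import random_two_exon_transcript
        from startloss.gene_models import GenomeSequence, transcript_protein

        rng = np.random.default_rng(77)
        for _ in range(20):
            genome, tx = random_two_exon_transcript(rng)
            n_codons = tx.cds_length // 3
            boundary_codon = int(rng.integers(1, n_codons - 1))
            cpos = 3 * boundary_codon  # insertion after this c. position
            gpos = cds_to_genomic(tx, cpos)
            ins = "GCT"  # +Ala
            ref = genome.contigs[tx.contig][gpos - 1]
            c = annotate_insertion(Variant(tx.contig, gpos, ref, ref + ins), tx, genome)
            assert c.effect == "inframe_insertion"
            contig = genome.contigs[tx.contig]
            mutant_contig = contig[:gpos] + ins + contig[gpos:]
            # exon holding the insertion grows by 3
            new_exons = []
            for s, e in tx.exons:
                if s <= gpos - 1 < e:
                    new_exons.append((s, e + 3))
                elif s > gpos:
                    new_exons.append((s + 3, e + 3))
                else:
                    new_exons.append((s, e))
            from startloss.gene_models import TranscriptModel

            mt = TranscriptModel(transcript_id="M", gene_id=tx.gene_id,
                                 contig=tx.contig, strand="+", exons=new_exons,
                                 cds_start=tx.cds_start, cds_end=tx.cds_end + 3)
            ref_p = str(transcript_protein(tx, genome))
            mut_p = str(transcript_protein(mt, GenomeSequence(
                {tx.contig: mutant_contig})))
            assert mut_p[:boundary_codon] == ref_p[:boundary_codon]
            assert mut_p[boundary_codon + 1:] == ref_p[boundary_codon:]

    def test_frameshift_scans_into_three_prime_utr(self):
        """A frameshift near the CDS end finds its stop beyond the old one."""
        from conftest import make_transcript

        # CDS M A K * then UTR engineered to carry the shifted-frame stop
        cds = "ATGGCTAAATAA"
        utr3 = "CCTGACC"  # shifted frame reads ...A|ACC|TGA -> stop in UTR
        seq = "AA" + cds + utr3 + "AA"
        genome, tx = make_transcript(seq, [(0, len(seq))], (2, 2 + len(cds)))
        gpos = cds_to_genomic(tx, 3)
        ref = genome.fetch("chrT", gpos - 1, gpos)
        c = annotate_insertion(Variant("chrT", gpos, ref, ref + "T"), tx, genome)
        assert c.effect == "frameshift"
        assert c.fs_ter_offset is not None

    def test_no_stop_dialect(self):
        from conftest import make_transcript

        # shifted frame reads GGC TCA TTA ACC CCC — never a stop
        cds = "ATGGCTCATTAA"
        seq = "AA" + cds + "CCCCCC"
        genome, tx = make_transcript(seq, [(0, len(seq))], (2, 2 + len(cds)))
        gpos = cds_to_genomic(tx, 3)
        ref = genome.fetch("chrT", gpos - 1, gpos)
        c = annotate_insertion(Variant("chrT", gpos, ref, ref + "G"), tx, genome)
        assert c.effect == "frameshift"
        assert c.fs_ter_offset is None
        assert c.hgvs_p.endswith("fs*?")


class TestFsNotation:
    @pytest.mark.parametrize("text,expect", [
        ("D15Rfs*33", (15, 33, 47)),
        ("p.D15Rfs*33", (15, 33, 47)),
        ("M1Vfs*2", (1, 2, 2)),
        ("K10fs*?", (10, None, None)),
    ])
    def test_examples(self, text, expect):
        assert parse_fs_notation(text) == expect

    @pytest.mark.parametrize("bad", ["fs*3", "D15R*33", "d15rfs*33", "D15Rfs*"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_fs_notation(bad)

    def test_round_trip_with_annotate_insertion(self, ugp2_fixture):
        """annotate_insertion's own hgvs_p parses back to its fields."""
        genome, long_tx, _ = ugp2_fixture
        ref = genome.fetch("chr2", 64_083_461, 64_083_462)
        c = annotate_insertion(Variant("chr2", 64_083_462, ref, ref + "A"),
                               long_tx, genome)
        first, ter, stop = parse_fs_notation(c.hgvs_p)
        assert (first, ter) == (c.fs_first_residue, c.fs_ter_offset)
        assert stop == c.fs_stop_position
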