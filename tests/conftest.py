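import numpy as np
import pytest

from startloss.gene_models import GenomeSequence, TranscriptModel
from startloss.synthetic_data import make_genome_and_annotation, make_ugp2_like_fixture


@pytest.fixture(scope="session")
def ugp2_fixture():
    """Deterministic two-isoform locus mirroring the recurrent-mutation locus."""
    return make_ugp2_like_fixture(seed=0)


@pytest.fixture(scope="session")
def bundle():
    """One synthetic genome/annotation bundle with recorded truth."""
    genome, transcripts, truth = make_genome_and_annotation(seed=1)
    return genome, transcripts, truth


def make_transcript(seq: str, exons, cds, strand="+", contig="chrT",
                    tid="T1", gene="G1"):
    """Build a (genome, transcript) pair from a raw contig sequence."""
    genome = GenomeSequence({contig: seq})
    tx = TranscriptModel(transcript_id=tid, gene_id=gene, contig=contig,
                         strand=strand, exons=list(exons),
                         cds_start=cds[0], cds_end=cds[1])
    return genome, tx


def random_two_exon_transcript(rng: np.random.Generator, strand="+"):
    """Random valid two-exon coding transcript for property tests."""
    from startloss.synthetic_data import _random_bases, _random_codons

    n_codons = int(rng.integers(10, 60))
    cds = "ATG" + "".join(_random_codons(rng, n_codons - 1)) + "TAA"
    split = 3 * int(rng.integers(1, n_codons))  # split inside the CDS
    intron = int(rng.integers(20, 200))
    utr5, utr3 = int(rng.integers(0, 30)), int(rng.integers(0, 30))
    p1, p2 = cds[:split], cds[split:]
    seq_plus = (_random_bases(rng, 50) + _random_bases(rng, utr5) + p1
                + _random_bases(rng, intron) + p2 + _random_bases(rng, utr3)
                + _random_bases(rng, 50))
    e1 = (50, 50 + utr5 + split)
    e2 = (e1[1] + intron, e1[1] + intron + len(p2) + utr3)
    cds_start, cds_end = 50 + utr5, e2[0] + len(p2)
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        L = len(seq_plus)
        seq = seq_plus.translate(comp)[::-1]
        e1f = (L - e2[1], L - e2[0])
        e2f = (L - e1[1], L - e1[0])
        cds_start, cds_end = L - cds_end, L - (50 + utr5)
        exons = [e1f, e2f]
    else:
        seq, exons = seq_plus, [e1, e2]
    return make_transcript(seq, exons, (cds_start, cds_end), strand=strand)
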