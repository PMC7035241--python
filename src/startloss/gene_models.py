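"""Genome and transcript data model.

FASTA/GTF I/O and strand-aware coordinate mapping between genomic,
CDS (HGVS ``c.``) and protein spaces, plus translation.

Coordinate conventions
----------------------
Internally everything is 0-based half-open. GTF is 1-based closed and
VCF 1-based; conversion happens only at the I/O boundary. HGVS ``c.``
positions are 1-based with c.1 = the A of the start ATG; UTR (negative)
c. numbering is deliberately unsupported — positions outside the CDS
raise :class:`NotInCDSError`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .intervals import Interval, merge, intersect

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TABLE = dict(standard_dna_table.forward_table)

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


class GtfParseError(ValueError):
    """Malformed GTF input; message carries the offending line number."""


class TranscriptValidationError(ValueError):
    """Transcript structure violates the model invariants."""


class NotInCDSError(ValueError):
    """Genomic position outside the coding exonic footprint.

    ``nearest`` holds the closest CDS boundary (1-based genomic).
    """

    def __init__(self, message: str, nearest: int | None = None):
        super().__init__(message)
        self.nearest = nearest


class NoStopCodonError(ValueError):
    """In-frame translation ran off the end without hitting a stop codon."""


@dataclass
class GenomeSequence:
    """Multi-contig nucleotide sequences, uppercase A/C/G/T/N."""

    contigs: dict[str, str]

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"contig {name!r} has invalid characters {bad}")

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs)

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """0-based half-open slice of a contig."""
        if contig not in self.contigs:
            raise KeyError(f"contig {contig!r} not in genome")
        return self.contigs[contig][start:end]


@dataclass
class ProteinSequence:
    """Amino-acid string; at most one ``*`` and only terminal."""

    residues: str

    def __post_init__(self):
        internal = self.residues[:-1] if self.residues else ""
        if "*" in internal:
            raise ValueError("internal stop in protein sequence")

    def __len__(self):
        return len(self.residues)

    def __str__(self):
        return self.residues


@dataclass
class TranscriptModel:
    """One transcript's exon/CDS structure on a genome.

    ``exons`` are 0-based half-open, sorted by genomic position and
    non-overlapping; ``cds_start``/``cds_end`` delimit the genomic
    footprint of the coding region (half-open, stop codon included).
    For minus-strand transcripts, transcript-space order is the
    reverse of genomic order.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[Interval]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise TranscriptValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        exs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
            if s2 < e1:
                raise TranscriptValidationError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})")
        self.exons = exs
        cds = self.cds_intervals()
        # the CDS footprint may span introns, but must start and end inside exons
        if not cds or cds[0][0] != self.cds_start or cds[-1][1] != self.cds_end:
            raise TranscriptValidationError(
                f"{self.transcript_id}: CDS ({self.cds_start},{self.cds_end}) "
                f"not contained in exon union")
        if self.cds_length % 3 != 0:
            raise TranscriptValidationError(
                f"{self.transcript_id}: spliced CDS length {self.cds_length} not divisible by 3")
        if self.cds_length < 6:
            raise TranscriptValidationError(
                f"{self.transcript_id}: spliced CDS length {self.cds_length} < 6")

    def cds_intervals(self) -> list[Interval]:
        """Exonic intervals clipped to the CDS footprint, genomic order."""
        return intersect(self.exons, [(self.cds_start, self.cds_end)])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    def coding_order_cds(self) -> list[Interval]:
        """CDS intervals in coding (5'→3' transcript) order."""
        ivs = self.cds_intervals()
        return ivs if self.strand == "+" else list(reversed(ivs))

    def exon_union(self) -> list[Interval]:
        return merge(self.exons)


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon/CDS features from an Ensembl-dialect GTF into transcript models.

    GTF coordinates (1-based closed) are converted to the internal 0-based
    half-open convention. Features are grouped by ``transcript_id``.
    Transcripts without CDS features are skipped with a log entry.
    """
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields, "
                                    f"got {len(fields)}")
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates "
                                    f"{start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise GtfParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            attr = _parse_attributes(attrs)
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id/transcript_id attribute")
            tid = attr["transcript_id"]
            prev = meta.setdefault(tid, (attr["gene_id"], contig, strand))
            if prev != (attr["gene_id"], contig, strand):
                raise GtfParseError(f"{path}:{lineno}: inconsistent gene/contig/strand "
                                    f"for transcript {tid}")
            iv = (start - 1, end)  # to 0-based half-open
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    models = []
    for tid, (gene_id, contig, strand) in meta.items():
        if tid not in cds:
            logger.warning("transcript %s has no CDS features; skipped", tid)
            continue
        if tid not in exons:
            raise TranscriptValidationError(f"{tid}: CDS features without exon features")
        cds_ivs = merge(cds[tid])
        model = TranscriptModel(
            transcript_id=tid, gene_id=gene_id, contig=contig, strand=strand,
            exons=merge(exons[tid]), cds_start=cds_ivs[0][0], cds_end=cds_ivs[-1][1],
        )
        # every CDS feature must lie inside the exon union
        ex_union = model.exon_union()
        if intersect(cds_ivs, ex_union) != cds_ivs:
            raise TranscriptValidationError(f"{tid}: CDS features extend outside exons")
        models.append(model)
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def write_gtf(models: list[TranscriptModel], path, source: str = "startloss") -> None:
    """Write transcripts back to Ensembl-dialect GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.gene_id, m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(f"{m.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.cds_intervals():
                fh.write(f"{m.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Sequence extraction and translation


def cds_sequence(tx: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced CDS, 5'→3' in coding orientation (reverse-complemented for '-')."""
    parts = [genome.fetch(tx.contig, s, e) for s, e in tx.cds_intervals()]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def transcript_sequence(tx: TranscriptModel, genome: GenomeSequence) -> str:
    """Full spliced exonic sequence in coding orientation (UTRs included)."""
    parts = [genome.fetch(tx.contig, s, e) for s, e in tx.exon_union()]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate(cds: str, require_atg: bool = True) -> tuple[ProteinSequence, bool]:
    """Standard-code translation up to (and excluding) the first stop codon.

    Returns ``(protein, internal_stop)`` where ``internal_stop`` is True when
    a stop codon occurred before the final codon. Raises
    :class:`NoStopCodonError` if no in-frame stop exists — frameshift scanning
    in variant annotation relies on that error.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if require_atg and not cds.startswith("ATG"):
        raise ValueError(f"CDS does not start with ATG: {cds[:3]!r}")
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in STOP_CODONS:
            return ProteinSequence("".join(residues)), i < n_codons - 1
        try:
            residues.append(CODON_TABLE[codon])
        except KeyError:
            raise ValueError(f"untranslatable codon {codon!r} at codon {i + 1}") from None
    raise NoStopCodonError("no in-frame stop codon")


def transcript_protein(tx: TranscriptModel, genome: GenomeSequence) -> ProteinSequence:
    """Protein of a transcript's annotated CDS; internal stops are rejected."""
    protein, internal = translate(cds_sequence(tx, genome))
    if internal:
        raise TranscriptValidationError(f"{tx.transcript_id}: internal stop codon in CDS")
    return protein


# ---------------------------------------------------------------------------
# Coordinate mapping


def genomic_to_cds(tx: TranscriptModel, gpos: int) -> int:
    """Map a 1-based genomic position to a 1-based HGVS ``c.`` position.

    Raises :class:`NotInCDSError` (carrying the nearest CDS boundary) for
    intronic or non-coding positions.
    """
    g = gpos - 1  # to 0-based
    offset = 0
    for s, e in tx.coding_order_cds():
        if s <= g < e:
            if tx.strand == "+":
                return offset + (g - s) + 1
            return offset + (e - 1 - g) + 1
        offset += e - s
    boundaries = [b for s, e in tx.cds_intervals() for b in (s + 1, e)]
    nearest = min(boundaries, key=lambda b: abs(b - gpos)) if boundaries else None
    raise NotInCDSError(f"{tx.transcript_id}: genomic position {gpos} is not in the CDS",
                        nearest=nearest)


def cds_to_genomic(tx: TranscriptModel, cpos: int) -> int:
    """Inverse of :func:`genomic_to_cds`; returns a 1-based genomic position."""
    if cpos < 1:
        raise ValueError(f"c. position must be >= 1, got {cpos}")
    remaining = cpos - 1
    for s, e in tx.coding_order_cds():
        width = e - s
        if remaining < width:
            if tx.strand == "+":
                return s + remaining + 1
            return e - remaining
        remaining -= width
    raise ValueError(f"{tx.transcript_id}: c.{cpos} beyond CDS length {tx.cds_length}")


def cds_to_codon(cpos: int) -> tuple[int, int]:
    """1-based codon index and 0..2 offset of a 1-based CDS position."""
    if cpos < 1:
        raise ValueError(f"c. position must be >= 1, got {cpos}")
    return (cpos - 1) // 3 + 1, (cpos - 1) % 3
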