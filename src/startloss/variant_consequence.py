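"""Dual-isoform variant consequence annotation.

Maps a genomic SNV or insertion onto each transcript isoform of a gene,
classifies the coding effect (missense, synonymous, start-loss,
stop-gain, frameshift, ...) and, for frameshifts, scans the shifted
reading frame to the new termination codon. Notation follows HGVS
conventions as used in clinical genetics: ``c.`` positions count from
the A of the start ATG, protein effects use three-letter codes for
substitutions ("p.Met12Val"), start-loss is "p.?" (downstream effect
unknown), frameshifts use the compact one-letter "p.X15Yfs*33" dialect.

The hallmark case this module formalizes: one genomic A>G can be a
benign missense on a gene's long isoform (c.34A>G, p.Met12Val) while
simultaneously destroying the start codon of the short isoform
(c.1A>G, p.?) — the start codon of a shorter isoform is the only
mutational target that ablates it specifically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .gene_models import (
    AA3,
    CODON_TABLE,
    GenomeSequence,
    NoStopCodonError,
    NotInCDSError,
    STOP_CODONS,
    TranscriptModel,
    cds_sequence,
    cds_to_codon,
    genomic_to_cds,
    transcript_sequence,
)


class ReferenceMismatchError(ValueError):
    """Variant REF allele disagrees with the genome sequence."""


@dataclass
class Variant:
    """Left-anchored SNV or insertion (VCF convention, 1-based ``pos``)."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if not (set(self.ref) | set(self.alt)) <= set("ACGT"):
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.type == "invalid":
            raise ValueError(
                f"unsupported variant {self.ref}>{self.alt}: only SNVs and "
                f"left-anchored insertions are handled")

    @property
    def type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) == 1 and len(self.alt) > 1 and self.alt[0] == self.ref:
            return "insertion"
        return "invalid"

    @property
    def inserted(self) -> str:
        if self.type != "insertion":
            raise ValueError("not an insertion")
        return self.alt[1:]


@dataclass
class VariantConsequence:
    """Per-isoform annotation of one variant."""

    transcript_id: str
    effect: str
    cds_pos: int | None
    codon_index: int | None
    hgvs_c: str
    hgvs_p: str
    fs_first_residue: int | None = None
    fs_ter_offset: int | None = None
    nmd_predicted: bool | None = None

    @property
    def fs_stop_position(self) -> int | None:
        """Protein position of the new stop: first residue + offset − 1."""
        if self.fs_first_residue is None or self.fs_ter_offset is None:
            return None
        return self.fs_first_residue + self.fs_ter_offset - 1


def _check_ref(variant: Variant, genome: GenomeSequence) -> None:
    obs = genome.fetch(variant.contig, variant.pos - 1, variant.pos - 1 + len(variant.ref))
    if obs != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.contig}:{variant.pos} REF {variant.ref!r} does not match "
            f"genome {obs!r}")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_codon(codon: str) -> str:
    return "*" if codon in STOP_CODONS else CODON_TABLE[codon]


def annotate_snv(variant: Variant, tx: TranscriptModel, genome: GenomeSequence,
                 ) -> VariantConsequence:
    """Classify a single-nucleotide substitution on one transcript.

    The variant must fall in the CDS exonic footprint and match the
    reference genome. Alleles are converted to coding orientation for
    minus-strand transcripts before the codon is rebuilt and retranslated.
    """
    if variant.type != "SNV":
        raise ValueError("annotate_snv requires an SNV")
    _check_ref(variant, genome)
    cpos = genomic_to_cds(tx, variant.pos)  # raises NotInCDSError outside CDS
    ref_c, alt_c = variant.ref, variant.alt
    if tx.strand == "-":
        ref_c, alt_c = _revcomp(ref_c), _revcomp(alt_c)
    codon_index, offset = cds_to_codon(cpos)
    cds = cds_sequence(tx, genome)
    ref_codon = cds[3 * (codon_index - 1):3 * codon_index]
    assert ref_codon[offset] == ref_c
    alt_codon = ref_codon[:offset] + alt_c + ref_codon[offset + 1:]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)

    hgvs_c = f"c.{cpos}{ref_c}>{alt_c}"
    nmd = None
    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        effect, hgvs_p = "start_lost", "p.?"
    elif alt_aa == ref_aa:
        effect = "synonymous"
        hgvs_p = f"p.{AA3[ref_aa]}{codon_index}="
    elif alt_aa == "*":
        effect = "stop_gained"
        hgvs_p = f"p.{AA3[ref_aa]}{codon_index}Ter"
        nmd = _nmd_flag(tx, codon_index)
    elif ref_aa == "*":
        effect = "stop_lost"
        hgvs_p = f"p.Ter{codon_index}{AA3[alt_aa]}ext*?"
    else:
        effect = "missense"
        hgvs_p = f"p.{AA3[ref_aa]}{codon_index}{AA3[alt_aa]}"
    return VariantConsequence(
        transcript_id=tx.transcript_id, effect=effect, cds_pos=cpos,
        codon_index=codon_index, hgvs_c=hgvs_c, hgvs_p=hgvs_p, nmd_predicted=nmd)


def annotate_insertion(variant: Variant, tx: TranscriptModel, genome: GenomeSequence,
                       ) -> VariantConsequence:
    """Classify an insertion; frameshifts are scanned to the new stop codon.

    The VCF left anchor (``pos``, one ref base) places the insertion
    between genomic ``pos`` and ``pos+1``; internally this becomes
    "between CDS positions i and i+1" in coding orientation. For a
    frameshift, the mutant coding sequence — continued through the 3'UTR,
    since the shifted frame ignores the old stop — is translated from the
    first affected codon until the first stop, giving the ``fs*N`` offset
    (N counts codons from the first changed residue, stop inclusive).
    """
    if variant.type != "insertion":
        raise ValueError("annotate_insertion requires an insertion")
    _check_ref(variant, genome)
    ins = variant.inserted
    if tx.strand == "+":
        i = genomic_to_cds(tx, variant.pos)  # insertion after c.i
        ins_c = ins
    else:
        # between genomic pos and pos+1 == after c.(of pos+1) in coding orientation
        i = genomic_to_cds(tx, variant.pos + 1)
        ins_c = _revcomp(ins)
    hgvs_c = f"c.{i}_{i + 1}ins{ins_c}"

    cds = cds_sequence(tx, genome)
    if len(ins_c) % 3 == 0 and i % 3 == 0:
        # codon-boundary, length-preserving-frame insertion
        return VariantConsequence(
            transcript_id=tx.transcript_id, effect="inframe_insertion",
            cds_pos=i, codon_index=i // 3,
            hgvs_c=hgvs_c, hgvs_p=f"p.(ins{len(ins_c) // 3}aa)")
    if len(ins_c) % 3 == 0:
        # in-frame length but straddling a codon boundary: still no frameshift
        return VariantConsequence(
            transcript_id=tx.transcript_id, effect="inframe_insertion",
            cds_pos=i, codon_index=(i - 1) // 3 + 1 if i else None,
            hgvs_c=hgvs_c, hgvs_p=f"p.(ins{len(ins_c) // 3}aa)")

    # frameshift: first affected residue is the codon containing c.(i+1)
    first = i // 3 + 1
    coding_plus_utr = _coding_and_downstream(tx, genome)
    mutant = coding_plus_utr[:i] + ins_c + coding_plus_utr[i:]
    ref_aa = _translate_codon(cds[3 * (first - 1):3 * first])
    scan = mutant[3 * (first - 1):]
    scan = scan[:len(scan) - len(scan) % 3]
    new_residues, ter = _scan_to_stop(scan)
    if ter is None:
        hgvs_p = f"p.{ref_aa}{first}{new_residues[0] if new_residues else '?'}fs*?"
        return VariantConsequence(
            transcript_id=tx.transcript_id, effect="frameshift", cds_pos=i,
            codon_index=first, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            fs_first_residue=first, fs_ter_offset=None, nmd_predicted=None)
    new_aa = new_residues[0] if new_residues else "*"
    hgvs_p = f"p.{ref_aa}{first}{new_aa}fs*{ter}"
    return VariantConsequence(
        transcript_id=tx.transcript_id, effect="frameshift", cds_pos=i,
        codon_index=first, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
        fs_first_residue=first, fs_ter_offset=ter,
        nmd_predicted=_nmd_flag(tx, first + ter - 1, frame_extended=True))


def _scan_to_stop(seq: str) -> tuple[str, int | None]:
    """Translate codons until the first stop; ter offset counts the stop (1-based)."""
    residues = []
    for j in range(len(seq) // 3):
        codon = seq[3 * j:3 * j + 3]
        if codon in STOP_CODONS:
            return "".join(residues), j + 1
        residues.append(CODON_TABLE.get(codon, "X"))
    return "".join(residues), None


def _coding_and_downstream(tx: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced sequence from the start ATG through the transcript 3' end."""
    full = transcript_sequence(tx, genome)
    cds = cds_sequence(tx, genome)
    start = full.find(cds)
    assert start >= 0
    return full[start:]


def _nmd_flag(tx: TranscriptModel, stop_codon_index: int, frame_extended: bool = False,
              ) -> bool | None:
    """50-nt rule: a premature stop > 50 nt upstream of the final exon-exon
    junction predicts nonsense-mediated decay. Annotation only; single-exon
    transcripts are immune."""
    n_exons = len(tx.exon_union())
    if n_exons < 2:
        return False
    # transcript-space position of the last junction, measured within the CDS frame
    cds_ivs = tx.coding_order_cds()
    cum = 0
    junction_from_cds_start = None
    for iv in cds_ivs[:-1]:
        cum += iv[1] - iv[0]
        junction_from_cds_start = cum
    if junction_from_cds_start is None:
        return False
    stop_nt = 3 * stop_codon_index  # end of stop codon in CDS-frame coordinates
    return stop_nt < junction_from_cds_start - 50


_FS_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z]?)fs\*(\d+|\?)$")


def parse_fs_notation(hgvs_p: str) -> tuple[int, int | None, int | None]:
    """Parse "D15Rfs*33"-style notation → (first_residue, ter_offset, stop_position).

    ``stop_position = first_residue + ter_offset − 1``; the "fs*?" dialect
    (no stop found) yields ``(first_residue, None, None)``.
    """
    m = _FS_RE.match(hgvs_p)
    if not m:
        raise ValueError(f"malformed frameshift notation: {hgvs_p!r}")
    first = int(m.group(2))
    if m.group(4) == "?":
        return first, None, None
    ter = int(m.group(4))
    return first, ter, first + ter - 1


def annotate(variant: Variant, tx: TranscriptModel, genome: GenomeSequence,
             ) -> VariantConsequence:
    """Dispatch on variant type."""
    if variant.type == "SNV":
        return annotate_snv(variant, tx, genome)
    return annotate_insertion(variant, tx, genome)


def downstream_inframe_atgs(tx: TranscriptModel, genome: GenomeSequence,
                            max_codons: int | None = None) -> list[int]:
    """Diagnostic: codon indices (> 1) holding in-frame ATGs — potential
    rescue starts after a start-loss."""
    cds = cds_sequence(tx, genome)
    out = []
    for j in range(1, len(cds) // 3):
        if max_codons is not None and j + 1 > max_codons:
            break
        if cds[3 * j:3 * j + 3] == "ATG":
            out.append(j + 1)
    return out


# ---------------------------------------------------------------------------
# VCF input / TSV output


def read_vcf_variants(path) -> list[Variant]:
    """Minimal VCF reading (CHROM, POS, REF, ALT) via cyvcf2; multi-allelic
    records are split."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.append(Variant(contig=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt))
    return out


def consequences_to_frame(rows: list[tuple[Variant, VariantConsequence]]):
    import pandas as pd

    records = [{
        "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "transcript_id": c.transcript_id, "effect": c.effect,
        "hgvs_c": c.hgvs_c, "hgvs_p": c.hgvs_p,
        "fs_first_residue": c.fs_first_residue, "fs_ter_offset": c.fs_ter_offset,
        "nmd_predicted": c.nmd_predicted,
    } for v, c in rows]
    return pd.DataFrame(records, columns=[
        "contig", "pos", "ref", "alt", "transcript_id", "effect",
        "hgvs_c", "hgvs_p", "fs_first_residue", "fs_ter_offset", "nmd_predicted"])
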