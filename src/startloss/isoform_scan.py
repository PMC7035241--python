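"""Genome-wide N-terminal truncation (isoform containment) scan.

Detects genes whose shortest coding isoform is an exact, in-frame
N-terminal truncation of the longest isoform, so that a single
start-codon mutation can ablate the short isoform while leaving the
long one intact. The containment test is exact string containment of
the short protein anchored at the in-frame ATG — equivalent to an
ungapped, mismatch-free pairwise alignment, without the external
aligner. A filter cascade then intersects the hits with an
essential-gene list, removes disease-annotated genes, and applies a
maximum truncation length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .gene_models import (
    GenomeSequence,
    NotInCDSError,
    TranscriptModel,
    TranscriptValidationError,
    cds_to_genomic,
    genomic_to_cds,
    transcript_protein,
)

logger = logging.getLogger(__name__)


@dataclass
class ContainmentResult:
    """Outcome of the short-in-long containment test for one gene.

    ``contained`` — the short protein occurs verbatim in the long protein
    as an N-terminal truncation; ``in_frame_atg`` — the short transcript's
    start ATG maps to frame offset 0 of the long CDS;
    ``n_term_truncation_aa`` — codons of the long protein preceding the
    shared ATG (0 when the test fails or the CDS are identical).
    """

    gene_id: str
    long_tx_id: str
    short_tx_id: str
    contained: bool
    in_frame_atg: bool
    n_term_truncation_aa: int
    alt_offsets: list[int] | None = None

    @property
    def is_hit(self) -> bool:
        return self.contained and self.in_frame_atg


@dataclass
class CandidateGene:
    gene_id: str
    containment: ContainmentResult
    is_essential: bool
    has_disease_annotation: bool
    passes_truncation: bool


@dataclass
class FilterCascade:
    """Nested survivor sets of the candidate-gene filter cascade."""

    stage_names: list[str]
    stage_counts: list[int]
    survivors: list[list[str]]
    max_truncation_aa: int

    def __post_init__(self):
        for prev, cur in zip(self.survivors, self.survivors[1:]):
            if not set(cur) <= set(prev):
                raise ValueError("cascade survivor sets must be nested")
        if self.stage_counts != [len(s) for s in self.survivors]:
            raise ValueError("stage_counts inconsistent with survivor lists")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "stage_names": self.stage_names,
                "stage_counts": self.stage_counts,
                "survivors": self.survivors,
                "max_truncation_aa": self.max_truncation_aa,
            }, fh, indent=2)
            fh.write("\n")


def select_isoform_pair(
    transcripts: list[TranscriptModel],
) -> tuple[TranscriptModel, TranscriptModel] | None:
    """Longest- and shortest-CDS transcript of one gene, or None.

    Length is spliced CDS length; ties break by lexicographically smallest
    transcript id. Single-transcript genes return None — only genes with
    at least two coding isoforms can lose one to a start-codon mutation.
    """
    if len(transcripts) < 2:
        return None
    long_tx = sorted(transcripts, key=lambda t: (-t.cds_length, t.transcript_id))[0]
    short_tx = sorted((t for t in transcripts if t.transcript_id != long_tx.transcript_id),
                      key=lambda t: (t.cds_length, t.transcript_id))[0]
    return long_tx, short_tx


def check_containment(
    long_tx: TranscriptModel,
    short_tx: TranscriptModel,
    genome: GenomeSequence,
    all_offsets: bool = False,
) -> ContainmentResult:
    """Test whether ``short_tx`` encodes an exact N-terminal truncation of ``long_tx``.

    The short protein must equal the long protein's suffix starting at
    residue k+1, where k is derived from mapping the short transcript's
    start ATG into the long CDS (frame offset 0 required). Transcripts on
    different contigs or strands yield a structural-mismatch result
    (``contained=False``), not an exception. With ``all_offsets=True``, a
    diagnostic list of every ungapped offset at which the short protein
    occurs in the long protein is attached.
    """

    def miss(**kw):
        return ContainmentResult(
            gene_id=long_tx.gene_id, long_tx_id=long_tx.transcript_id,
            short_tx_id=short_tx.transcript_id,
            contained=False, in_frame_atg=False, n_term_truncation_aa=0, **kw)

    if long_tx.contig != short_tx.contig or long_tx.strand != short_tx.strand:
        return miss()

    long_protein = str(transcript_protein(long_tx, genome))
    short_protein = str(transcript_protein(short_tx, genome))
    alt = None
    if all_offsets:
        alt = [k for k in range(len(long_protein) - len(short_protein) + 1)
               if long_protein[k:k + len(short_protein)] == short_protein]

    atg_gpos = cds_to_genomic(short_tx, 1)  # genomic position of short c.1
    try:
        c_in_long = genomic_to_cds(long_tx, atg_gpos)
    except NotInCDSError:
        return miss(alt_offsets=alt)
    in_frame = (c_in_long - 1) % 3 == 0
    if not in_frame:
        return miss(alt_offsets=alt)
    k = (c_in_long - 1) // 3
    contained = short_protein == long_protein[k:]
    return ContainmentResult(
        gene_id=long_tx.gene_id, long_tx_id=long_tx.transcript_id,
        short_tx_id=short_tx.transcript_id,
        contained=contained, in_frame_atg=True,
        n_term_truncation_aa=k if contained else 0,
        alt_offsets=alt)


def scan_genome(
    transcripts: list[TranscriptModel],
    genome: GenomeSequence,
) -> list[ContainmentResult]:
    """Containment test for every multi-transcript gene, ordered by gene id.

    Transcripts that fail sequence validation (internal stop, N in CDS,
    missing stop) are dropped with a log entry, mirroring a tolerant
    genome-wide scan; genes left with fewer than two valid transcripts
    are skipped.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    results = []
    for gene_id in sorted(by_gene):
        valid = []
        for tx in by_gene[gene_id]:
            try:
                transcript_protein(tx, genome)
            except (TranscriptValidationError, ValueError) as exc:
                logger.warning("skipping transcript %s: %s", tx.transcript_id, exc)
                continue
            valid.append(tx)
        pair = select_isoform_pair(valid)
        if pair is None:
            continue
        results.append(check_containment(pair[0], pair[1], genome))
    return results


def read_gene_list(path) -> set[str]:
    """One-column TSV of gene ids (comments with '#' allowed)."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    return ids


def apply_filters(
    results: list[ContainmentResult],
    essential_ids: set[str],
    disease_ids: set[str],
    max_truncation_aa: int = 50,
) -> tuple[FilterCascade, list[CandidateGene]]:
    """Four-stage cascade: containment hit → essential → non-disease → short truncation.

    The truncation threshold is strict (< ``max_truncation_aa``), so a gene
    truncated by exactly the threshold is excluded.
    """
    if not essential_ids:
        logger.warning("essential-gene list is empty; stage 2 removes every gene")

    hits = [r for r in results if r.is_hit]
    stage1 = sorted(r.gene_id for r in hits)
    by_gene = {r.gene_id: r for r in hits}
    stage2 = [g for g in stage1 if g in essential_ids]
    stage3 = [g for g in stage2 if g not in disease_ids]
    stage4 = [g for g in stage3 if by_gene[g].n_term_truncation_aa < max_truncation_aa]

    survivors = [stage1, stage2, stage3, stage4]
    cascade = FilterCascade(
        stage_names=["containment", "essential", "no_disease_annotation",
                     f"truncation_lt_{max_truncation_aa}aa"],
        stage_counts=[len(s) for s in survivors],
        survivors=survivors,
        max_truncation_aa=max_truncation_aa,
    )
    candidates = [
        CandidateGene(
            gene_id=r.gene_id, containment=r,
            is_essential=r.gene_id in essential_ids,
            has_disease_annotation=r.gene_id in disease_ids,
            passes_truncation=r.n_term_truncation_aa < max_truncation_aa,
        )
        for r in hits
    ]
    return cascade, candidates


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    rows = [{
        "gene_id": c.gene_id,
        "long_tx": c.containment.long_tx_id,
        "short_tx": c.containment.short_tx_id,
        "truncation_aa": c.containment.n_term_truncation_aa,
        "is_essential": c.is_essential,
        "has_disease_annotation": c.has_disease_annotation,
        "passes_truncation": c.passes_truncation,
    } for c in candidates]
    return pd.DataFrame(
        rows, columns=["gene_id", "long_tx", "short_tx", "truncation_aa",
                       "is_essential", "has_disease_annotation", "passes_truncation"])


def write_candidates(candidates: list[CandidateGene], path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
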