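"""Tissue-specific isoform-usage quantification from unique exon regions.

For a longest/shortest transcript pair, the exonic territory unique to
each isoform is computed by interval subtraction; reads overlapping those
regions are counted per sample (a read spanning unique regions of both
isoforms increments both, matching per-region multi-coverage counting);
counts are averaged per tissue and collapsed into the short-fraction
ratio short/(short+long). Genes whose ratio swings by more than a
threshold across tissues are flagged as showing tissue-specific isoform
usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .gene_models import TranscriptModel
from .intervals import Interval, merge, overlaps, subtract

logger = logging.getLogger(__name__)


@dataclass
class UniqueRegions:
    """Exonic intervals unique to the short / the long isoform of one gene."""

    gene_id: str
    contig: str
    short_only: list[Interval]
    long_only: list[Interval]
    indistinguishable: bool = False


@dataclass
class IsoformRatioProfile:
    """Per-tissue short-isoform usage for one gene.

    ``ratio[t]`` is short/(short+long) of tissue-mean counts, or None when
    the tissue's mean evidence is below ``min_count``. ``variability`` is
    max−min over defined tissues, or None when fewer than two are defined.
    """

    gene_id: str
    sample_counts: dict[str, tuple[float, float]]
    sample_tissue: dict[str, str]
    tissue_ratios: dict[str, float | None]
    variability: float | None

    @property
    def defined_tissues(self) -> list[str]:
        return [t for t, r in self.tissue_ratios.items() if r is not None]


def unique_regions(long_tx: TranscriptModel, short_tx: TranscriptModel) -> UniqueRegions:
    """Exonic bases belonging to exactly one of the two transcripts."""
    long_ex = merge(long_tx.exons)
    short_ex = merge(short_tx.exons)
    short_only = subtract(short_ex, long_ex)
    long_only = subtract(long_ex, short_ex)
    indist = not short_only and not long_only
    if indist:
        logger.warning("gene %s: isoforms have identical exon structure; "
                       "unique-region counting cannot distinguish them", long_tx.gene_id)
    return UniqueRegions(
        gene_id=long_tx.gene_id, contig=long_tx.contig,
        short_only=short_only, long_only=long_only, indistinguishable=indist)


def count_region_reads(
    regions: UniqueRegions,
    reads: list[tuple[str, int, int]],
    known_contigs: set[str] | None = None,
) -> tuple[int, int, int]:
    """Count reads overlapping (≥ 1 base) each isoform's unique regions.

    ``reads`` are BED-like 0-based half-open ``(contig, start, end)``
    intervals for one sample. A read overlapping unique regions of both
    isoforms increments both counts. Returns
    ``(short_count, long_count, n_unknown_contig)``.
    """
    short_count = long_count = unknown = 0
    for contig, start, end in reads:
        if known_contigs is not None and contig not in known_contigs:
            unknown += 1
            continue
        if contig != regions.contig:
            continue
        if overlaps((start, end), regions.short_only):
            short_count += 1
        if overlaps((start, end), regions.long_only):
            long_count += 1
    return short_count, long_count, unknown


def tissue_ratios(
    gene_id: str,
    sample_counts: dict[str, tuple[float, float]],
    sample_tissue: dict[str, str],
    min_count: float = 10,
) -> IsoformRatioProfile:
    """Average counts within tissue first, then form short/(short+long).

    Averaging precedes the ratio (not a mean of per-sample ratios), so a
    tissue's ratio is the usage of its pooled average sample. Tissues with
    mean total evidence below ``min_count`` stay undefined, preventing 0/1
    artifacts from single reads.
    """
    unknown = [s for s in sample_counts if s not in sample_tissue]
    if unknown:
        raise KeyError(f"samples missing from tissue map: {sorted(unknown)}")
    by_tissue: dict[str, list[tuple[float, float]]] = {}
    for sample, counts in sample_counts.items():
        by_tissue.setdefault(sample_tissue[sample], []).append(counts)

    ratios: dict[str, float | None] = {}
    for tissue in sorted(by_tissue):
        pairs = by_tissue[tissue]
        mean_short = sum(p[0] for p in pairs) / len(pairs)
        mean_long = sum(p[1] for p in pairs) / len(pairs)
        total = mean_short + mean_long
        ratios[tissue] = mean_short / total if total >= min_count and total > 0 else None

    defined = [r for r in ratios.values() if r is not None]
    variability = max(defined) - min(defined) if len(defined) >= 2 else None
    return IsoformRatioProfile(
        gene_id=gene_id, sample_counts=dict(sample_counts),
        sample_tissue=dict(sample_tissue), tissue_ratios=ratios,
        variability=variability)


def variability_filter(
    profiles: list[IsoformRatioProfile],
    threshold: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Genes whose cross-tissue ratio range strictly exceeds ``threshold``.

    Returns ``(flagged, indeterminate)``; genes with fewer than two defined
    tissue ratios cannot be assessed and are reported separately.
    """
    flagged, indeterminate = [], []
    for p in profiles:
        if p.variability is None:
            indeterminate.append(p.gene_id)
        elif p.variability > threshold:
            flagged.append(p.gene_id)
    return flagged, indeterminate


# ---------------------------------------------------------------------------
# Tabular I/O


def read_counts_tsv(path) -> dict[str, dict[str, tuple[float, float]]]:
    """Counts TSV (sample, gene, short_count, long_count) → gene → sample → counts."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "short_count", "long_count"}
    if not required <= set(df.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, {})[row.sample] = (float(row.short_count),
                                                    float(row.long_count))
    return out


def read_samples_tsv(path) -> dict[str, str]:
    """samples.tsv (sample, tissue) → sample → tissue map."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "tissue"} <= set(df.columns):
        raise ValueError("samples table must have columns ['sample', 'tissue']")
    return dict(zip(df["sample"], df["tissue"]))


def read_reads_bed(path) -> dict[str, list[tuple[str, int, int]]]:
    """BED-like reads (contig, start, end, sample) → sample → read intervals."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "sample"])
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append((row.contig, int(row.start), int(row.end)))
    return out


def profiles_to_frame(profiles: list[IsoformRatioProfile]) -> pd.DataFrame:
    """Long-format gene × tissue ratio table."""
    rows = []
    for p in profiles:
        for tissue, ratio in sorted(p.tissue_ratios.items()):
            rows.append({"gene_id": p.gene_id, "tissue": tissue,
                         "ratio": ratio, "variability": p.variability})
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "ratio", "variability"])


def write_ratios(profiles: list[IsoformRatioProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def write_flagged(flagged: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\n")
        for g in flagged:
            fh.write(g + "\n")
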