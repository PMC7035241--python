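"""Seeded generators for every input the pipeline consumes.

Three generators with recorded ground truth stand in for data that is
not desk-available (a reference annotation, fetal RNA-seq tissue
panels, and proband exomes):

* :func:`make_genome_and_annotation` — a small genome + GTF containing
  planted start-loss candidate genes (two transcripts sharing all
  downstream coding sequence, alternative first exons, an in-frame
  internal ATG at a configured truncation) amongst negative genes
  (internal protein mismatch, out-of-frame internal ATG, unrelated
  isoforms, single-transcript genes).
* :func:`make_expression_counts` — per-sample unique-region counts with
  binomial noise around planted per-tissue short-isoform usage.
* :func:`simulate_founder_probands` — proband genotypes carrying a
  founder haplotype eroded by g generations of recombination, emitted
  as a minimal multi-sample VCF (GT:DP:GQ).

Every output is byte-reproducible from (seed, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .gene_models import CODON_TABLE, GenomeSequence, STOP_CODONS, TranscriptModel
from .roh_founder import GeneticMap

_BASES = "ACGT"
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return [_NONSTOP_CODONS[i] for i in idx]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _has_stop_in_frame(seq: str) -> bool:
    return any(seq[i:i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


# ---------------------------------------------------------------------------
# Truth record


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generators, keyed for downstream assertions."""

    seed: int
    planted_candidates: dict[str, int] = field(default_factory=dict)  # gene -> truncation aa
    gene_classes: dict[str, str] = field(default_factory=dict)
    essential_genes: list[str] = field(default_factory=list)
    disease_genes: list[str] = field(default_factory=list)
    planted_usage: dict[str, dict[str, float]] = field(default_factory=dict)
    founder: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Genome + annotation generator


@dataclass
class AnnotationConfig:
    """Layout of the synthetic scan substrate.

    Counts are per class; planted genes carry a true in-frame N-terminal
    truncation drawn from ``truncation_aa_range`` (inclusive). Fractions
    of essential/disease labels apply independently to every gene.
    """

    n_planted: int = 7
    n_single: int = 6
    n_disjoint: int = 3
    n_mismatch: int = 2
    n_offframe: int = 2
    protein_aa: int = 150
    truncation_aa_range: tuple[int, int] = (5, 40)
    frac_essential: float = 0.6
    frac_disease: float = 0.3
    frac_minus_strand: float = 0.4
    contig: str = "chrS"
    tissues: tuple[str, ...] = ("brain", "liver", "heart", "kidney")
    frac_variable_usage: float = 0.6
    usage_high: float = 0.95
    usage_low: float = 0.2
    usage_flat: float = 0.5

    @property
    def n_genes(self) -> int:
        return (self.n_planted + self.n_single + self.n_disjoint
                + self.n_mismatch + self.n_offframe)

    def __post_init__(self):
        lo, hi = self.truncation_aa_range
        if not (1 <= lo <= hi):
            raise ValueError("truncation range must satisfy 1 <= lo <= hi")
        if hi > 79:
            raise ValueError("truncation must be < 80 aa (first-exon coding span)")
        if self.protein_aa < 80:
            raise ValueError("protein_aa must be >= 80")


_STRIDE = 3000  # bp reserved per gene


@dataclass
class _GeneBuild:
    """Plus-strand local-coordinate build of one gene, later offset/flipped."""

    seq: str  # local region sequence, length _STRIDE
    transcripts: list[dict]  # exons/cds in local coords


def _paint(buf: list[str], start: int, seq: str) -> None:
    buf[start:start + len(seq)] = list(seq)


def _build_planted(rng, cfg, k: int, mismatch: bool = False) -> _GeneBuild:
    """Candidate-topology gene: long tx with first-exon coding, short tx with
    its own 5'UTR exon and a start at long codon k+1.

    ``mismatch=True`` gives the short transcript a private downstream exon
    whose copied coding sequence carries one amino-acid change — an exact
    negative for the containment test that still has an in-frame ATG.
    """
    P = cfg.protein_aa
    codons = ["ATG"] + _random_codons(rng, P - 1)
    codons[k] = "ATG"  # internal in-frame start at codon k+1
    cds = "".join(codons) + "TAA"
    e1_coding, e2_coding = cds[:240], cds[240:]

    buf = list(_random_bases(rng, _STRIDE))
    # long: exons [100,400) and [1000, 1000+len(e2_coding)+60); CDS 160..
    _paint(buf, 160, e1_coding)
    _paint(buf, 1000, e2_coding)
    e2_end = 1000 + len(e2_coding) + 60
    long_tx = {"suffix": "L", "exons": [(100, 400), (1000, e2_end)],
               "cds": (160, 1000 + len(e2_coding))}

    short_start = 160 + 3 * k
    if not mismatch:
        short_tx = {"suffix": "S",
                    "exons": [(20, 80), (short_start, 400), (1000, e2_end)],
                    "cds": (short_start, 1000 + len(e2_coding))}
    else:
        # private copy of the downstream coding exon with one aa changed
        mutated = list(e2_coding)
        # change the first codon of the downstream exon to a different residue
        orig = e2_coding[:3]
        for cand in _NONSTOP_CODONS:
            if CODON_TABLE[cand] != CODON_TABLE[orig]:
                mutated[0:3] = list(cand)
                break
        e2p = "".join(mutated)
        _paint(buf, 1600, e2p)
        e2p_end = 1600 + len(e2p) + 60
        short_tx = {"suffix": "S",
                    "exons": [(20, 80), (short_start, 400), (1600, e2p_end)],
                    "cds": (short_start, 1600 + len(e2p))}
    return _GeneBuild(seq="".join(buf), transcripts=[long_tx, short_tx])


def _build_offframe(rng, cfg, k: int) -> _GeneBuild:
    """Short isoform whose ATG sits inside the long CDS at frame offset 1."""
    P = cfg.protein_aa
    g_codons = [c for c in _NONSTOP_CODONS if c.startswith("G")]
    while True:
        codons = ["ATG"] + _random_codons(rng, P - 1)
        # plant an off-frame ATG at CDS offset 3k+1: codon k+1 ends in 'AT'
        # and codon k+2 starts with 'G'
        codons[k] = ["AAT", "CAT", "GAT", "TAT"][int(rng.integers(0, 4))]
        codons[k + 1] = g_codons[int(rng.integers(0, len(g_codons)))]
        cds = "".join(codons) + "TAA"
        # the short CDS opens with 20 bases of the long CDS read in shifted
        # frame; they must be stop-free in that frame
        shared = cds[3 * k + 1:3 * k + 21]
        assert shared.startswith("ATG")
        if not _has_stop_in_frame(shared[:18]):
            break
    e1_coding, e2_coding = cds[:240], cds[240:]
    buf = list(_random_bases(rng, _STRIDE))
    _paint(buf, 160, e1_coding)
    _paint(buf, 1000, e2_coding)
    e2_end = 1000 + len(e2_coding) + 60
    long_tx = {"suffix": "L", "exons": [(100, 400), (1000, e2_end)],
               "cds": (160, 1000 + len(e2_coding))}

    short_start = 160 + 3 * k + 1
    # continuation exon: 100 bases ending in a frame-aligned stop
    # (20 + 100 ≡ 0 mod 3); reject draws that put a stop mid-frame
    while True:
        cont = _random_bases(rng, 97) + "TAA"
        if not _has_stop_in_frame((shared + cont)[:-3]):
            break
    _paint(buf, 1600, cont)
    short_tx = {"suffix": "S",
                "exons": [(short_start, short_start + 20), (1600, 1600 + 100 + 60)],
                "cds": (short_start, 1600 + 100)}
    return _GeneBuild(seq="".join(buf), transcripts=[long_tx, short_tx])


def _build_disjoint(rng, cfg) -> _GeneBuild:
    """Two coding isoforms with unrelated CDS — no containment relation."""
    buf = list(_random_bases(rng, _STRIDE))
    pa, pb = 90, 60
    cds_a = "ATG" + "".join(_random_codons(rng, pa - 1)) + "TAA"
    cds_b = "ATG" + "".join(_random_codons(rng, pb - 1)) + "TAA"
    _paint(buf, 120, cds_a)
    _paint(buf, 1020, cds_b)
    tx_a = {"suffix": "L", "exons": [(100, 120 + len(cds_a) + 40)],
            "cds": (120, 120 + len(cds_a))}
    tx_b = {"suffix": "S", "exons": [(1000, 1020 + len(cds_b) + 40)],
            "cds": (1020, 1020 + len(cds_b))}
    return _GeneBuild(seq="".join(buf), transcripts=[tx_a, tx_b])


def _build_single(rng, cfg) -> _GeneBuild:
    buf = list(_random_bases(rng, _STRIDE))
    p = 100
    cds = "ATG" + "".join(_random_codons(rng, p - 1)) + "TAA"
    _paint(buf, 120, cds)
    tx = {"suffix": "T", "exons": [(100, 120 + len(cds) + 40)],
          "cds": (120, 120 + len(cds))}
    return _GeneBuild(seq="".join(buf), transcripts=[tx])


def _flip(build: _GeneBuild) -> _GeneBuild:
    """Reverse-complement a local gene build (plus → minus strand)."""
    L = len(build.seq)
    seq = _revcomp(build.seq)
    txs = []
    for tx in build.transcripts:
        exons = sorted((L - e, L - s) for s, e in tx["exons"])
        cs, ce = tx["cds"]
        txs.append({**tx, "exons": exons, "cds": (L - ce, L - cs)})
    return _GeneBuild(seq=seq, transcripts=txs)


def make_genome_and_annotation(
    config: AnnotationConfig | None = None,
    seed: int = 0,
) -> tuple[GenomeSequence, list[TranscriptModel], SimulationTruth]:
    """Synthetic genome + annotation with planted candidate genes and truth."""
    cfg = config or AnnotationConfig()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)

    classes = (["planted"] * cfg.n_planted + ["mismatch"] * cfg.n_mismatch
               + ["offframe"] * cfg.n_offframe + ["disjoint"] * cfg.n_disjoint
               + ["single"] * cfg.n_single)
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]

    region_parts: list[str] = []
    transcripts: list[TranscriptModel] = []
    lo, hi = cfg.truncation_aa_range
    for gi, cls in enumerate(classes):
        gene_id = f"G{gi + 1:03d}"
        k = int(rng.integers(lo, hi + 1))
        if cls == "planted":
            build = _build_planted(rng, cfg, k)
            truth.planted_candidates[gene_id] = k
        elif cls == "mismatch":
            build = _build_planted(rng, cfg, k, mismatch=True)
        elif cls == "offframe":
            build = _build_offframe(rng, cfg, k)
        elif cls == "disjoint":
            build = _build_disjoint(rng, cfg)
        else:
            build = _build_single(rng, cfg)
        truth.gene_classes[gene_id] = cls

        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
        if strand == "-":
            build = _flip(build)
        g0 = gi * _STRIDE
        region_parts.append(build.seq)
        for tx in build.transcripts:
            transcripts.append(TranscriptModel(
                transcript_id=f"{gene_id}.{tx['suffix']}",
                gene_id=gene_id, contig=cfg.contig, strand=strand,
                exons=[(g0 + s, g0 + e) for s, e in tx["exons"]],
                cds_start=g0 + tx["cds"][0], cds_end=g0 + tx["cds"][1],
            ))

        if rng.random() < cfg.frac_essential:
            truth.essential_genes.append(gene_id)
        if rng.random() < cfg.frac_disease:
            truth.disease_genes.append(gene_id)

        if cls == "planted":
            usage: dict[str, float] = {}
            if rng.random() < cfg.frac_variable_usage:
                hi_tissue = cfg.tissues[int(rng.integers(0, len(cfg.tissues)))]
                for t in cfg.tissues:
                    usage[t] = cfg.usage_high if t == hi_tissue else cfg.usage_low
            else:
                usage = {t: cfg.usage_flat for t in cfg.tissues}
            truth.planted_usage[gene_id] = usage

    genome = GenomeSequence({cfg.contig: "".join(region_parts)})
    transcripts.sort(key=lambda t: (t.gene_id, t.transcript_id))
    truth.essential_genes.sort()
    truth.disease_genes.sort()
    return genome, transcripts, truth


def write_gene_list(ids, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(ids):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Expression counts generator


def make_expression_counts(
    truth: SimulationTruth,
    depth: int = 2000,
    n_samples_per_tissue: int = 3,
    seed: int = 0,
):
    """Binomial unique-region counts around the planted per-tissue usage.

    Returns ``(counts, sample_tissue)`` where ``counts`` maps
    gene → sample → (short_count, long_count) and short ~ Binomial(depth,
    usage), long = depth − short, independently per gene × sample.
    """
    rng = np.random.default_rng(seed)
    tissues = sorted({t for usage in truth.planted_usage.values() for t in usage})
    sample_tissue = {}
    for t in tissues:
        for i in range(n_samples_per_tissue):
            sample_tissue[f"{t}_{i + 1}"] = t

    counts: dict[str, dict[str, tuple[int, int]]] = {}
    for gene in sorted(truth.planted_usage):
        usage = truth.planted_usage[gene]
        per_sample = {}
        for sample in sorted(sample_tissue):
            u = usage[sample_tissue[sample]]
            short = int(rng.binomial(depth, u))
            per_sample[sample] = (short, depth - short)
        counts[gene] = per_sample
    return counts, sample_tissue


def write_counts_tsv(counts, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tshort_count\tlong_count\n")
        for gene in sorted(counts):
            for sample in sorted(counts[gene]):
                s, l = counts[gene][sample]
                fh.write(f"{sample}\t{gene}\t{s}\t{l}\n")


def write_samples_tsv(sample_tissue, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttissue\n")
        for sample in sorted(sample_tissue):
            fh.write(f"{sample}\t{sample_tissue[sample]}\n")


# ---------------------------------------------------------------------------
# Founder-proband simulator


@dataclass
class FounderConfig:
    contig: str = "chr2"
    contig_length: int = 30_000_000
    marker_spacing: int = 50_000
    focal_fraction: float = 0.5  # focal variant position along the contig
    paths_per_proband: int = 2  # consanguineous closure: both transmissions erode
    het_density: float = 0.5  # background heterozygosity outside the retained interval
    qc_fail_fraction: float = 0.0
    cm_per_mb: float = 1.0  # used when no genetic map is supplied
    retry_cap: int = 20


def simulate_founder_probands(
    g: int,
    n_probands: int = 5,
    config: FounderConfig | None = None,
    genetic_map: GeneticMap | None = None,
    seed: int = 0,
):
    """Probands homozygous across a founder haplotype eroded by g generations.

    Each proband inherits the focal allele through ``paths_per_proband``
    meiotic paths; every path retains an exponential genetic length on each
    side of the focal variant (mean 100/g cM — Poisson crossovers), and the
    proband's retained interval is the per-side minimum over its paths.
    Inside the retained interval the proband is homozygous for the
    ancestral haplotype; outside, background heterozygosity appears at the
    configured density. Returns ``(records, truth)`` where ``records`` is a
    position-sorted list of per-sample VCF-like rows.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    cfg = config or FounderConfig()
    if genetic_map is None:
        genetic_map = GeneticMap({cfg.contig: (
            np.array([0.0, float(cfg.contig_length)]),
            np.array([0.0, cfg.contig_length / 1e6 * cfg.cm_per_mb]))})
    rng = np.random.default_rng(seed)

    focal_pos = int(cfg.contig_length * cfg.focal_fraction)
    focal_cm = genetic_map.cm_at(cfg.contig, focal_pos)
    bp0, cm0 = genetic_map.anchors[cfg.contig]
    cm_max = float(cm0[-1])

    samples = [f"P{i + 1}" for i in range(n_probands)]
    retained: dict[str, tuple[int, int]] = {}
    for sample in samples:
        for _attempt in range(cfg.retry_cap):
            left = rng.exponential(100.0 / g, size=cfg.paths_per_proband).min()
            right = rng.exponential(100.0 / g, size=cfg.paths_per_proband).min()
            lo_cm = max(0.0, focal_cm - left)
            hi_cm = min(cm_max, focal_cm + right)
            lo_bp = int(genetic_map.bp_at(cfg.contig, lo_cm))
            hi_bp = int(genetic_map.bp_at(cfg.contig, hi_cm))
            if hi_bp - lo_bp >= cfg.marker_spacing:
                retained[sample] = (lo_bp, hi_bp)
                break
        else:
            raise RuntimeError(
                f"retained interval for {sample} below marker spacing after "
                f"{cfg.retry_cap} retries (g too large for this marker density?)")

    positions = sorted(set(range(cfg.marker_spacing, cfg.contig_length,
                                 cfg.marker_spacing)) | {focal_pos})
    # ancestral haplotype allele at every marker (0 = ref, 1 = alt)
    ancestral = {pos: int(rng.integers(0, 2)) for pos in positions}
    ancestral[focal_pos] = 1  # the founder mutation itself

    records = []  # (pos, sample, gt, dp, gq)
    for pos in positions:
        for sample in samples:
            lo, hi = retained[sample]
            if pos == focal_pos:
                gt = "1/1"
            elif lo <= pos <= hi:
                gt = "1/1" if ancestral[pos] else "0/0"
            elif rng.random() < cfg.het_density:
                gt = "0/1"
            else:
                gt = "0/0"
            if rng.random() < cfg.qc_fail_fraction:
                if rng.random() < 0.5:
                    dp, gq = int(rng.integers(0, 10)), 99
                else:
                    dp, gq = 30, int(rng.integers(0, 50))
            else:
                dp, gq = 30, 99
            records.append((pos, sample, gt, dp, gq))

    shared = (max(lo for lo, _ in retained.values()),
              min(hi for _, hi in retained.values()))
    truth = SimulationTruth(seed=seed, founder={
        "g": g,
        "n_probands": n_probands,
        "paths_per_proband": cfg.paths_per_proband,
        "n_paths": n_probands * cfg.paths_per_proband,
        "contig": cfg.contig,
        "focal_pos": focal_pos,
        "retained": {s: list(v) for s, v in sorted(retained.items())},
        "shared": list(shared),
    })
    return {"samples": samples, "contig": cfg.contig,
            "contig_length": cfg.contig_length, "records": records}, truth


def write_vcf(sim: dict, path) -> None:
    """Emit the simulated genotypes as a minimal biallelic VCF (GT:DP:GQ)."""
    samples = sim["samples"]
    by_pos: dict[int, dict[str, tuple[str, int, int]]] = {}
    for pos, sample, gt, dp, gq in sim["records"]:
        by_pos.setdefault(pos, {})[sample] = (gt, dp, gq)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={sim['contig']},length={sim['contig_length']}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos in sorted(by_pos):
            cells = []
            for s in samples:
                gt, dp, gq = by_pos[pos][s]
                cells.append(f"{gt}:{dp}:{gq}")
            fh.write(f"{sim['contig']}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Worked-example locus fixture


UGP2_CONTIG = "chr2"
UGP2_LONG_CDS_START = 64_083_421  # 1-based genomic position of long-isoform c.1
UGP2_TRUNCATION_AA = 11  # the isoforms differ by 11 N-terminal residues
UGP2_LONG_AA = 508  # long-isoform protein length (CDS 1527 nt incl. stop)


def make_ugp2_like_fixture(seed: int = 0):
    """Deterministic two-isoform locus mirroring the UGP2 worked examples.

    Single-exon long and short transcripts on chr2 (+) with the long CDS
    starting at 64,083,421, so that genomic position 64,083,454 is long
    c.34 (codon 12, engineered ATG — the short isoform's start codon) and
    the A-insertion between 64,083,462 and 64,083,463 is c.42_43insA. The
    shifted reading frame is engineered to terminate 33 codons after the
    first changed residue (D15Rfs*33, stop at protein position 47).

    Returns ``(genome, long_tx, short_tx)``. The contig holds filler 'A'
    up to the locus, so genomic coordinates are the real chr2 ones.
    """
    rng = np.random.default_rng(seed)
    P = UGP2_LONG_AA
    while True:
        codons = ["ATG"] + _random_codons(rng, P - 1)
        codons[11] = "ATG"  # codon 12: the short isoform's start
        codons[14] = "GAT"  # codon 15: Asp; insA makes it AGA (Arg)
        codons[45] = "GCT"  # codon 46 ends in T ...
        codons[46] = "AAA"  # ... codon 47 starts AA: shifted frame reads TAA
        cds = "".join(codons) + "TAA"
        # shifted frame after c.42_43insA reads cds[44:]; require its first
        # stop exactly at offset 137 (new codon 47 = D15Rfs*33)
        shifted = cds[44:137]
        if not _has_stop_in_frame(shifted):
            assert cds[137:140] == "TAA"
            break

    start0 = UGP2_LONG_CDS_START - 1  # 0-based
    utr5, utr3 = 20, 40
    seq = ("A" * (start0 - utr5) + _random_bases(rng, utr5) + cds
           + _random_bases(rng, utr3) + "A" * 100)
    genome = GenomeSequence({UGP2_CONTIG: seq})

    long_tx = TranscriptModel(
        transcript_id="UGP2-like.L", gene_id="UGP2-like", contig=UGP2_CONTIG,
        strand="+", exons=[(start0 - utr5, start0 + len(cds) + utr3)],
        cds_start=start0, cds_end=start0 + len(cds))
    short_start0 = start0 + 3 * UGP2_TRUNCATION_AA
    short_tx = TranscriptModel(
        transcript_id="UGP2-like.S", gene_id="UGP2-like", contig=UGP2_CONTIG,
        strand="+", exons=[(short_start0 - 10, start0 + len(cds) + utr3)],
        cds_start=short_start0, cds_end=start0 + len(cds))
    return genome, long_tx, short_tx
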