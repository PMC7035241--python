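"""Runs of homozygosity, shared founder haplotypes, and mutation dating.

Workflow: genotypes from a multi-sample VCF are quality-filtered
(depth ≥ 10, genotype quality ≥ 50 by default); per sample, maximal runs
of homozygous calls are collected with PLINK-style constraints
(min SNPs, min span in kb, max inter-SNP gap, zero tolerated
heterozygotes); the runs containing a focal variant are intersected
across carriers into the minimal shared segment; its genetic length is
obtained by piecewise-linear interpolation of a recombination map; and
the founder mutation's age in generations is estimated from haplotype
erosion.

Erosion model: on each side of the focal variant, each of the n
independent meiotic transmission paths from the founder retains an
exponentially distributed genetic length with mean 100/g cM after g
generations (crossovers arrive as a Poisson process at 1 per 100 cM
per meiosis). The shared segment takes the per-side minimum over
paths, so E[total length] = 200/(n·g) cM and the method-of-moments
estimator is ĝ = 200 / (n · length_cM). Confidence intervals come from
a parametric bootstrap of the same model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOME_SIZE_BP = 3_200_000_000  # conventional human genome size used for F_ROH


class UnsortedInputError(ValueError):
    """Genotype records must arrive position-sorted; no silent sort."""


class NoSharedSegmentError(ValueError):
    def __init__(self, message, samples):
        super().__init__(message)
        self.samples = samples


@dataclass
class GenotypeRecord:
    sample: str
    contig: str
    pos: int  # 1-based
    genotype: str  # hom_ref | het | hom_alt | missing
    depth: int
    gq: int


@dataclass
class ROHParams:
    """PLINK-style run constraints (defaults are the screen's settings)."""

    min_snp: int = 5
    min_kb: float = 100.0
    max_gap_kb: float = 10_000.0
    window_het: int = 0

    def __post_init__(self):
        if min(self.min_snp, self.min_kb, self.max_gap_kb, self.window_het) < 0:
            raise ValueError("ROH parameters must be non-negative")
        if self.window_het != 0:
            raise NotImplementedError(
                "only window_het=0 (any heterozygote breaks a run) is supported")


@dataclass
class ROHSegment:
    sample: str
    contig: str
    start_pos: int  # 1-based position of first SNP in run
    end_pos: int  # 1-based position of last SNP in run
    n_snps: int

    @property
    def span_kb(self) -> float:
        return (self.end_pos - self.start_pos) / 1000.0

    def contains(self, pos: int) -> bool:
        return self.start_pos <= pos <= self.end_pos


@dataclass
class SharedSegment:
    contig: str
    start_pos: int
    end_pos: int
    supporting_samples: list[str]

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class AgeEstimate:
    """Founder-age result: point estimate, bootstrap CI and provenance."""

    length_cM: float
    n_paths: int
    generations: float
    ci_low: float
    ci_high: float
    method: str
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            "Founder-mutation age estimate",
            "-----------------------------",
            f"method              : {self.method}",
            f"shared length (cM)  : {self.length_cM:.4g}",
            f"meiotic paths (n)   : {self.n_paths}",
            f"generations (ĝ)     : {self.generations:.3g}",
            f"95% CI              : [{self.ci_low:.3g}, {self.ci_high:.3g}]",
        ]
        if self.seed is not None:
            lines.append(f"bootstrap seed      : {self.seed}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "length_cM": self.length_cM, "n_paths": self.n_paths,
                "generations": self.generations,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "method": self.method, "seed": self.seed,
            }, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Genotype I/O and QC


def read_vcf_genotypes(path, region: str | None = None) -> list[GenotypeRecord]:
    """Read GT:DP:GQ per sample from a multi-sample VCF.

    Multiallelic sites are dropped (homozygosity is defined on biallelic
    genotypes only); ``region`` ("chr2" or "chr2:start-end") restricts the
    scan coordinate-wise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records: list[GenotypeRecord] = []
    n_multi = 0
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.gt_types  # 0=hom_ref 1=het 2=hom_alt 3=unknown (gts012)
        depths = rec.format("DP")
        quals = rec.format("GQ")
        for i, sample in enumerate(samples):
            gt = {0: "hom_ref", 1: "het", 2: "hom_alt", 3: "missing"}[int(gts[i])]
            dp = int(depths[i][0]) if depths is not None else -1
            gq = int(quals[i][0]) if quals is not None else -1
            records.append(GenotypeRecord(sample=sample, contig=rec.CHROM, pos=rec.POS,
                                          genotype=gt, depth=dp, gq=gq))
    if n_multi:
        logger.info("dropped %d multiallelic sites", n_multi)
    return records


def filter_genotypes(
    records: list[GenotypeRecord],
    min_dp: int = 10,
    min_gq: int = 50,
) -> tuple[list[GenotypeRecord], dict[str, int]]:
    """Keep calls with depth ≥ min_dp, GQ ≥ min_gq and a non-missing genotype.

    Both thresholds are inclusive ("at least"). Records without DP or GQ
    (encoded negative) are dropped and tallied. Returns (kept, qc_tally).
    """
    kept = []
    tally = {"missing_format": 0, "low_depth": 0, "low_gq": 0, "missing_genotype": 0}
    for r in records:
        if r.depth < 0 or r.gq < 0:
            tally["missing_format"] += 1
        elif r.genotype == "missing":
            tally["missing_genotype"] += 1
        elif r.depth < min_dp:
            tally["low_depth"] += 1
        elif r.gq < min_gq:
            tally["low_gq"] += 1
        else:
            kept.append(r)
    return kept, tally


# ---------------------------------------------------------------------------
# ROH calling


def call_roh(records: list[GenotypeRecord], params: ROHParams = ROHParams(),
             ) -> list[ROHSegment]:
    """Maximal homozygous runs for one sample on one contig.

    Runs break at any heterozygous call (window_het = 0), at inter-SNP gaps
    exceeding ``max_gap_kb`` and at contig ends; surviving runs must carry
    at least ``min_snp`` SNPs and span at least ``min_kb`` kb. Input must be
    position-sorted and single-sample/single-contig.
    """
    if not records:
        return []
    samples = {r.sample for r in records}
    contigs = {r.contig for r in records}
    if len(samples) != 1 or len(contigs) != 1:
        raise ValueError("call_roh expects records for one sample on one contig")
    positions = [r.pos for r in records]
    if positions != sorted(positions):
        raise UnsortedInputError("genotype records are not position-sorted")

    sample, contig = records[0].sample, records[0].contig
    max_gap_bp = params.max_gap_kb * 1000
    segments: list[ROHSegment] = []
    run: list[int] = []

    def flush():
        if len(run) >= params.min_snp and (run[-1] - run[0]) / 1000.0 >= params.min_kb:
            segments.append(ROHSegment(sample=sample, contig=contig,
                                       start_pos=run[0], end_pos=run[-1],
                                       n_snps=len(run)))
        run.clear()

    for r in records:
        if r.genotype == "het":
            flush()
            continue
        if r.genotype == "missing":
            continue
        if run and r.pos - run[-1] > max_gap_bp:
            flush()
        run.append(r.pos)
    flush()
    return segments


def shared_roh(
    segments_by_sample: dict[str, list[ROHSegment]],
    focal_contig: str,
    focal_pos: int,
) -> SharedSegment:
    """Intersect each sample's focal-variant-containing ROH across samples.

    The minimal shared segment runs from the maximum of starts to the
    minimum of ends. Samples without a focal ROH abort with
    :class:`NoSharedSegmentError` naming them.
    """
    focal_segments = {}
    missing = []
    for sample, segments in sorted(segments_by_sample.items()):
        hit = [s for s in segments if s.contig == focal_contig and s.contains(focal_pos)]
        if not hit:
            missing.append(sample)
        else:
            focal_segments[sample] = hit[0]
    if missing:
        raise NoSharedSegmentError(
            f"no ROH containing {focal_contig}:{focal_pos} in samples {missing}", missing)
    start = max(s.start_pos for s in focal_segments.values())
    end = min(s.end_pos for s in focal_segments.values())
    if start > end:
        raise NoSharedSegmentError(
            f"focal ROH segments do not mutually overlap at {focal_contig}:{focal_pos}",
            sorted(focal_segments))
    return SharedSegment(contig=focal_contig, start_pos=start, end_pos=end,
                         supporting_samples=sorted(focal_segments))


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    rows = [{"sample": s.sample, "contig": s.contig, "start_pos": s.start_pos,
             "end_pos": s.end_pos, "n_snps": s.n_snps, "span_kb": s.span_kb}
            for s in segments]
    return pd.DataFrame(rows, columns=["sample", "contig", "start_pos", "end_pos",
                                       "n_snps", "span_kb"])


# ---------------------------------------------------------------------------
# Genetic map


@dataclass
class GeneticMap:
    """Per-contig cumulative genetic positions, (bp, cM) anchors, both sorted."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        for contig, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if len(bp) != len(cm) or len(bp) < 2:
                raise ValueError(f"map for {contig} needs >= 2 (bp, cM) anchors")
            if np.any(np.diff(bp) < 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"map anchors for {contig} must be non-decreasing")
            self.anchors[contig] = (bp, cm)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        """deCODE-style TSV with columns (contig, pos, cM)."""
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:3])
        anchors = {}
        for contig, grp in df.groupby(cols[0], sort=False):
            grp = grp.sort_values(cols[1])
            anchors[str(contig)] = (grp[cols[1]].to_numpy(float),
                                    grp[cols[2]].to_numpy(float))
        return cls(anchors)

    def to_tsv(self, path) -> None:
        rows = []
        for contig, (bp, cm) in self.anchors.items():
            for b, c in zip(bp, cm):
                rows.append((contig, int(b), float(c)))
        pd.DataFrame(rows, columns=["contig", "pos", "cM"]).to_csv(
            path, sep="\t", index=False)

    def cm_at(self, contig: str, pos: float) -> float:
        if contig not in self.anchors:
            raise KeyError(f"contig {contig!r} absent from genetic map")
        bp, cm = self.anchors[contig]
        if pos < bp[0] or pos > bp[-1]:
            logger.warning("position %s:%s outside map anchors; flat extrapolation",
                           contig, pos)
        return float(np.interp(pos, bp, cm))

    def bp_at(self, contig: str, cm_pos: float) -> float:
        """Inverse interpolation (used by the haplotype-erosion simulator)."""
        bp, cm = self.anchors[contig]
        return float(np.interp(cm_pos, cm, bp))


def interval_cM(gmap: GeneticMap, contig: str, start: int, end: int) -> float:
    """Genetic length of [start, end] by linear interpolation; non-negative."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return max(0.0, gmap.cm_at(contig, end) - gmap.cm_at(contig, start))


# ---------------------------------------------------------------------------
# Founder-age estimation


def simulate_shared_lengths(g: float, n_paths: int, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Shared-segment genetic lengths (cM) under the erosion model.

    Per side, each path keeps Exp(mean 100/g) cM; the shared extent is the
    per-side minimum over the n paths; lengths of the two sides add.
    """
    left = rng.exponential(scale=100.0 / g, size=(size, n_paths)).min(axis=1)
    right = rng.exponential(scale=100.0 / g, size=(size, n_paths)).min(axis=1)
    return left + right


def estimate_generations(
    length_cM: float,
    n_paths: int,
    method: str = "erosion-mom",
    n_boot: int = 2000,
    seed: int | None = None,
) -> AgeEstimate:
    """Method-of-moments founder age ĝ = 200/(n_paths · length_cM).

    ``n_paths`` is the number of independent meiotic transmission paths
    from the founder to the observed haplotypes — it depends on pedigree
    structure, so it is a required input, never guessed. The 95% CI is a
    central parametric bootstrap: lengths are redrawn under ĝ and
    re-estimated.
    """
    if length_cM <= 0:
        raise ValueError(f"length_cM must be > 0, got {length_cM}")
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    if method != "erosion-mom":
        raise ValueError(f"unknown method {method!r}")
    g_hat = 200.0 / (n_paths * length_cM)
    rng = np.random.default_rng(seed)
    boot_lengths = simulate_shared_lengths(g_hat, n_paths, n_boot, rng)
    boot_g = 200.0 / (n_paths * boot_lengths)
    ci_low, ci_high = np.quantile(boot_g, [0.025, 0.975])
    return AgeEstimate(length_cM=length_cM, n_paths=n_paths, generations=g_hat,
                       ci_low=float(ci_low), ci_high=float(ci_high),
                       method=method, seed=seed)


def years_from_generations(g: float, years_per_generation: float = 25.0,
                           ndigits: int | None = None) -> float:
    """Calendar-age conversion; ``ndigits`` rounds the product if given."""
    if g <= 0:
        raise ValueError(f"generations must be > 0, got {g}")
    years = g * years_per_generation
    return round(years, ndigits) if ndigits is not None else years


# ---------------------------------------------------------------------------
# Worked-example arithmetic helpers


def allele_frequency(n_alt: int, n_alleles: int) -> float:
    """Minor-allele frequency from carrier and total allele counts."""
    if n_alleles <= 0 or n_alt < 0 or n_alt > n_alleles:
        raise ValueError("need 0 <= n_alt <= n_alleles, n_alleles > 0")
    return n_alt / n_alleles


def inbreeding_from_roh(total_roh_bp: float, genome_bp: float = GENOME_SIZE_BP) -> float:
    """F_ROH: fraction of the genome lying in runs of homozygosity."""
    if not 0 <= total_roh_bp <= genome_bp:
        raise ValueError("total ROH length must be within [0, genome size]")
    return total_roh_bp / genome_bp
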