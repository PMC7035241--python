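"""Pipeline orchestration: config validation, staged execution, manifest, report.

Stages run in order scan → ratio → consequence (optional) → roh → age;
each stage's outputs feed the next where applicable and are also written
to the output directory. A :class:`RunManifest` captures tool version,
config hash, input checksums, per-stage counts and the seed registry, so
re-running with identical inputs, config and seeds reproduces an
identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import isoform_ratio, isoform_scan, roh_founder, variant_consequence
from .gene_models import GenomeSequence, read_gtf

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration invalid; message names the offending field."""


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


DEFAULTS = {
    "scan": {"max_truncation_aa": 50},
    "ratio": {"threshold": 0.5, "min_count": 10},
    "roh": {"min_snp": 5, "min_kb": 100.0, "max_gap_kb": 10_000.0, "window_het": 0,
            "min_dp": 10, "min_gq": 50, "region": None},
    "age": {"n_boot": 2000, "years_per_generation": 25.0,
            "n_paths": None, "seed": None},
}

_REQUIRED_INPUTS = ("gtf", "fasta", "essential", "disease", "counts", "samples")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    stage_counts: dict
    seed_registry: dict[str, int]

    def manifest_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            d = dataclasses.asdict(self)
            d["manifest_hash"] = self.manifest_hash()
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Merge defaults and check presence/typing; raises ConfigError naming fields."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    cfg["inputs"] = {}
    for key, val in config.items():
        if key == "inputs":
            cfg["inputs"].update(val or {})
        elif key in cfg:
            unknown = set(val or {}) - set(cfg[key])
            if unknown:
                raise ConfigError(f"unknown option(s) {sorted(unknown)} in section {key!r}")
            cfg[key].update(val or {})
        elif key == "age_inputs":
            cfg["age_inputs"] = dict(val or {})
        else:
            raise ConfigError(f"unknown config section {key!r}")

    inputs = cfg["inputs"]
    for name in _REQUIRED_INPUTS:
        if name not in inputs:
            raise ConfigError(f"missing required input {name!r}")
    roh_enabled = "genotypes_vcf" in inputs
    if roh_enabled:
        if "focal" not in inputs:
            raise ConfigError("missing required input 'focal' (e.g. 'chr2:64083454') "
                              "when genotypes_vcf is given")
        if "genetic_map" not in inputs:
            raise ConfigError("missing required input 'genetic_map' "
                              "when genotypes_vcf is given (age stage needs cM lengths)")
        if cfg["age"]["n_paths"] is None:
            raise ConfigError("age.n_paths is required (meiotic paths are "
                              "pedigree-dependent and never guessed)")
        if cfg["age"]["seed"] is None:
            raise ConfigError("age.seed is required for the bootstrap CI")
    for name, path in inputs.items():
        if name in ("focal",):
            continue
        if not Path(path).exists():
            raise ConfigError(f"input file for {name!r} does not exist: {path}")
    return cfg


def _parse_focal(text: str) -> tuple[str, int]:
    try:
        contig, pos = text.split(":")
        return contig, int(pos.replace(",", ""))
    except ValueError:
        raise ConfigError(f"focal variant must look like 'chr2:64083454', got {text!r}") \
            from None


def run_all(config: dict, outdir) -> RunManifest:
    """Execute every configured stage; outputs land in ``outdir``."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    checksums = {name: _sha256_file(path) for name, path in sorted(inputs.items())
                 if name != "focal"}
    stage_counts: dict = {}
    seeds: dict[str, int] = {}

    # --- scan ---------------------------------------------------------------
    try:
        genome = GenomeSequence.from_fasta(inputs["fasta"])
        transcripts = read_gtf(inputs["gtf"])
        results = isoform_scan.scan_genome(transcripts, genome)
        essential = isoform_scan.read_gene_list(inputs["essential"])
        disease = isoform_scan.read_gene_list(inputs["disease"])
        cascade, candidates = isoform_scan.apply_filters(
            results, essential, disease,
            max_truncation_aa=cfg["scan"]["max_truncation_aa"])
        isoform_scan.write_candidates(candidates, outdir / "candidates.tsv")
        cascade.to_json(outdir / "cascade.json")
    except Exception as exc:
        raise StageError(f"scan: {exc}") from exc
    stage_counts["scan_cascade"] = dict(zip(cascade.stage_names, cascade.stage_counts))

    # --- ratio --------------------------------------------------------------
    try:
        counts = isoform_ratio.read_counts_tsv(inputs["counts"])
        sample_tissue = isoform_ratio.read_samples_tsv(inputs["samples"])
        hit_genes = {r.gene_id for r in results if r.is_hit}
        profiles = [
            isoform_ratio.tissue_ratios(gene, counts[gene], sample_tissue,
                                        min_count=cfg["ratio"]["min_count"])
            for gene in sorted(counts) if gene in hit_genes
        ]
        flagged, indeterminate = isoform_ratio.variability_filter(
            profiles, threshold=cfg["ratio"]["threshold"])
        isoform_ratio.write_ratios(profiles, outdir / "ratios.tsv")
        isoform_ratio.write_flagged(flagged, outdir / "flagged.tsv")
    except Exception as exc:
        raise StageError(f"ratio: {exc}") from exc
    stage_counts["ratio"] = {"profiled": len(profiles), "flagged": len(flagged),
                             "indeterminate": len(indeterminate)}

    # --- consequence (optional) ----------------------------------------------
    if "vcf" in inputs:
        try:
            variants = variant_consequence.read_vcf_variants(inputs["vcf"])
            rows = []
            for var in variants:
                for tx in transcripts:
                    if tx.contig != var.contig:
                        continue
                    try:
                        rows.append((var, variant_consequence.annotate(var, tx, genome)))
                    except variant_consequence.ReferenceMismatchError:
                        raise
                    except ValueError:
                        continue  # variant outside this transcript's CDS
            variant_consequence.consequences_to_frame(rows).to_csv(
                outdir / "consequences.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"consequence: {exc}") from exc
        stage_counts["consequence"] = {"annotations": len(rows)}

    # --- roh + age (optional) -------------------------------------------------
    if "genotypes_vcf" in inputs:
        try:
            focal_contig, focal_pos = _parse_focal(inputs["focal"])
            records = roh_founder.read_vcf_genotypes(
                inputs["genotypes_vcf"], region=cfg["roh"]["region"])
            kept, tally = roh_founder.filter_genotypes(
                records, min_dp=cfg["roh"]["min_dp"], min_gq=cfg["roh"]["min_gq"])
            params = roh_founder.ROHParams(
                min_snp=cfg["roh"]["min_snp"], min_kb=cfg["roh"]["min_kb"],
                max_gap_kb=cfg["roh"]["max_gap_kb"], window_het=cfg["roh"]["window_het"])
            by_sample: dict[str, list] = {}
            for r in kept:
                if r.contig == focal_contig:
                    by_sample.setdefault(r.sample, []).append(r)
            segments_by_sample = {
                s: roh_founder.call_roh(rs, params) for s, rs in sorted(by_sample.items())
            }
            all_segments = [seg for segs in segments_by_sample.values() for seg in segs]
            roh_founder.segments_to_frame(all_segments).to_csv(
                outdir / "roh.tsv", sep="\t", index=False)
            shared = roh_founder.shared_roh(segments_by_sample, focal_contig, focal_pos)
            gmap = roh_founder.GeneticMap.from_tsv(inputs["genetic_map"])
            length_cm = roh_founder.interval_cM(
                gmap, shared.contig, shared.start_pos, shared.end_pos)
            with open(outdir / "shared.json", "w") as fh:
                json.dump({"contig": shared.contig, "start_pos": shared.start_pos,
                           "end_pos": shared.end_pos, "length_mb": shared.length_mb,
                           "length_cM": length_cm,
                           "supporting_samples": shared.supporting_samples},
                          fh, indent=2)
                fh.write("\n")
            age = roh_founder.estimate_generations(
                length_cm, n_paths=cfg["age"]["n_paths"],
                n_boot=cfg["age"]["n_boot"], seed=cfg["age"]["seed"])
            age.to_json(outdir / "age.json")
            seeds["age_bootstrap"] = cfg["age"]["seed"]
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"roh/age: {exc}") from exc
        stage_counts["roh"] = {
            "genotypes_kept": len(kept), "qc_dropped": tally,
            "segments": len(all_segments),
            "shared_interval": [shared.start_pos, shared.end_pos],
            "shared_length_mb": shared.length_mb,
            "shared_length_cM": length_cm,
        }
        stage_counts["age"] = {
            "generations": age.generations,
            "ci": [age.ci_low, age.ci_high],
            "years": roh_founder.years_from_generations(
                age.generations, cfg["age"]["years_per_generation"]),
        }

    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        input_checksums=checksums,
        stage_counts=stage_counts,
        seed_registry=seeds,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def write_report(manifest: RunManifest, md_path, json_path=None) -> None:
    """Human-readable run summary (cascade table, shared ROH, age estimate)."""
    lines = ["# Start-loss screen run report", "",
             f"- tool version: {manifest.version}",
             f"- config hash: `{manifest.config_hash[:16]}…`",
             f"- manifest hash: `{manifest.manifest_hash()[:16]}…`", ""]
    sc = manifest.stage_counts
    if "scan_cascade" in sc:
        lines += ["## Candidate-gene filter cascade", "",
                  "| stage | genes |", "| --- | ---: |"]
        lines += [f"| {name} | {count} |" for name, count in sc["scan_cascade"].items()]
        lines.append("")
    if "ratio" in sc:
        r = sc["ratio"]
        lines += ["## Tissue isoform-usage variability", "",
                  f"- genes profiled: {r['profiled']}",
                  f"- flagged (variability > threshold): {r['flagged']}",
                  f"- indeterminate (< 2 tissues defined): {r['indeterminate']}", ""]
    if "consequence" in sc:
        lines += ["## Variant consequences", "",
                  f"- variant × isoform annotations: {sc['consequence']['annotations']}",
                  ""]
    if "roh" in sc:
        r = sc["roh"]
        lines += ["## Shared ROH", "",
                  f"- genotypes kept after QC: {r['genotypes_kept']}",
                  f"- ROH segments: {r['segments']}",
                  f"- shared interval: {r['shared_interval'][0]:,}–{r['shared_interval'][1]:,}"
                  f" ({r['shared_length_mb']:.2f} Mb, {r['shared_length_cM']:.3f} cM)", ""]
    if "age" in sc:
        a = sc["age"]
        seed = manifest.seed_registry.get("age_bootstrap")
        lines += ["## Founder-mutation age", "",
                  f"- generations: {a['generations']:.2f} "
                  f"(95% CI {a['ci'][0]:.2f}–{a['ci'][1]:.2f}; bootstrap seed {seed})",
                  f"- years: {a['years']:.0f}", ""]
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines))
    if json_path is not None:
        manifest.to_json(json_path)
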