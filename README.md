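# startloss

Tools for a disease-gene discovery scenario that standard loss-of-function
thinking misses: an **essential gene** can still cause a recessive disorder
when a mutation ablates only one of its protein isoforms — specifically,
when a single start-codon (ATG) variant destroys the translation start of a
shorter isoform that is an exact N-terminal truncation of the longer one,
and the affected tissue expresses mostly the short isoform. The archetype is
UGP2 (UDP-glucose pyrophosphorylase) in developmental and epileptic
encephalopathy: one genomic A>G is a benign missense (c.34A>G, p.Met12Val)
on the long isoform and a translation start loss (c.1A>G, p.?) on the short
isoform, which supplies virtually all UGP2 in fetal brain.

The package implements the four computational legs of such a screen, for
genome-annotation-scale inputs or synthetic ones:

1. **Isoform containment scan** (`isoform_scan`) — for each multi-transcript
   gene, test whether the shortest isoform's protein is an exact, ungapped,
   mismatch-free suffix of the longest isoform's protein, anchored at an
   in-frame internal ATG (the truncation length k is the number of leading
   residues missing). A filter cascade then keeps essential,
   non-disease-annotated genes with k < 50.
2. **Tissue isoform usage** (`isoform_ratio`) — count reads over exonic
   regions unique to each isoform, average counts per tissue, form the
   short-fraction ratio s/(s+l), and flag genes whose cross-tissue ratio
   range exceeds 0.5 (an isoform switch).
3. **Dual-isoform variant consequences** (`variant_consequence`) — HGVS-style
   annotation of SNVs and insertions against every isoform, including
   frameshift scanning to the new stop ("p.D15Rfs*33" means the first changed
   residue is 15 and the new stop is the 33rd codon downstream, i.e. protein
   position 15 + 33 − 1 = 47).
4. **ROH and founder-mutation dating** (`roh_founder`) — genotype QC
   (DP ≥ 10, GQ ≥ 50), PLINK-parameterized run-of-homozygosity calling
   (min 5 SNPs, min 100 kb, max gap 10 Mb, zero heterozygotes), intersection
   of the focal-variant ROH across carriers, genetic-map interpolation of the
   shared segment's length in cM, and a haplotype-erosion age estimate:
   each of n meiotic transmission paths retains Exp(100/g) cM per side after
   g generations, so E[L] = 200/(n·g) and ĝ = 200/(n·L), with a parametric
   bootstrap CI.

A seeded generator suite (`synthetic_data`) produces every input with
recorded ground truth — planted candidate genes of known truncation,
binomial counts around planted per-tissue usage, and proband genotypes
carrying an eroded founder haplotype — so the whole pipeline is testable
offline. `pipeline` + the `startloss` CLI tie the stages into a single run
with a reproducible manifest.

## Worked example

```python
from startloss.synthetic_data import make_ugp2_like_fixture
from startloss.isoform_scan import check_containment
from startloss.variant_consequence import Variant, annotate_snv, annotate_insertion
from startloss.roh_founder import estimate_generations

genome, long_tx, short_tx = make_ugp2_like_fixture()

r = check_containment(long_tx, short_tx, genome)
print(f"contained={r.contained} in_frame_atg={r.in_frame_atg} "
      f"truncation={r.n_term_truncation_aa} aa")

v = Variant("chr2", 64_083_454, "A", "G")
for tx in (long_tx, short_tx):
    c = annotate_snv(v, tx, genome)
    print(f"{tx.transcript_id}: {c.effect}  {c.hgvs_c}  {c.hgvs_p}")

ref = genome.fetch("chr2", 64_083_461, 64_083_462)
fs = annotate_insertion(Variant("chr2", 64_083_462, ref, ref + "A"), long_tx, genome)
print(f"{long_tx.transcript_id}: {fs.effect}  {fs.hgvs_c}  {fs.hgvs_p}  "
      f"stop at {fs.fs_stop_position}")

print(estimate_generations(0.75, n_paths=10, seed=1).summary())
```

prints

```text
contained=True in_frame_atg=True truncation=11 aa
UGP2-like.L: missense  c.34A>G  p.Met12Val
UGP2-like.S: start_lost  c.1A>G  p.?
UGP2-like.L: frameshift  c.42_43insA  p.D15Rfs*33  stop at 47

Founder-mutation age estimate
-----------------------------
method              : erosion-mom
shared length (cM)  : 0.75
meiotic paths (n)   : 10
generations (ĝ)     : 26.7
95% CI              : [9.41, 263]
bootstrap seed      : 1
```

Reading the output: the two isoforms differ by exactly 11 N-terminal
residues and the short CDS is an in-frame suffix of the long one, so the
locus is a start-loss candidate; the single A>G at chr2:64,083,454 is
simultaneously a Met12Val missense on the long isoform and a start loss on
the short; an A inserted after c.42 shifts the frame at residue 15 and
terminates 33 codons later; and a shared haplotype of 0.75 cM across 10
meiotic paths dates the mutation to roughly 27 generations, with the wide
CI reflecting the heavy-tailed erosion model.

## Command line

```sh
startloss simulate annotation --seed 1 --out sim/
startloss scan --gtf sim/annotation.gtf --fasta sim/genome.fa \
    --essential sim/essential.tsv --disease sim/disease.tsv --out scan/
startloss roh --vcf probands.vcf --focal chr2:64083454 --out roh/
startloss age --shared roh/shared.json --map decode_map.tsv \
    --n-paths 10 --seed 1 --out age.json
startloss run-all --config config.yaml --out out/
```

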