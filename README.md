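# splicord

Allele-specific nascent-RNA maturation analysis from spliced long reads.

Nanopore direct-RNA sequencing of chromatin-associated RNA captures
transcripts mid-maturation: partially spliced molecules whose CIGAR strings
record which introns are already gone, whose poly(A) tails were just added,
and whose sequences carry phased heterozygous SNPs identifying the parental
haplotype. splicord turns such alignments into allele-resolved measurements
of pre-mRNA processing:

* **intron excision status** per (read, intron) — excised / not excised /
  skipped / undetermined, from the CIGAR against an intron annotation;
* **haplotype assignment** per read from phased SNPs (≥ 2 informative
  observations, ≥ 75% agreement);
* **splicing-order scores** per allele for groups of 2–3 consecutive
  introns: with intermediate-isoform frequencies f_k at each splicing level
  L, the score of removal order i is the normalized path product
  p_i = Π_L f_k(i,L) / Σ_j Π_L f_k(j,L), with Σ p_i = 1;
* **allele-specific splicing-order calls** — chi-square per level +
  Benjamini-Hochberg, Euclidean distance d between the alleles' 6-slot
  score vectors, call when d > τ (default τ = 0.379, the 1.5×IQR replicate
  calibration) and some level has FDR < 0.05, plus a Fisher-exact route for
  intron pairs and a four-way classification of how the top orders differ;
* **allelic features** per gene — Wilcoxon comparisons of poly(A) tail
  lengths (optionally stratified by splice state) and of strand-resolved
  3'-end positions (APA calls need a ≥ 10 nt mean shift), and binomial
  tests of allelic abundance ratio r = n₁/(n₁+n₂) (skew: r < 0.4 or
  r > 0.6 at FDR < 0.05);
* **genotype association** of splicing orders across samples via haplotype
  blocks (genotype 0/2 per allele-sample) with a pooled chi-square test;
* **nascent-transcriptome enumeration** for polymorphic loci (all 2ⁿ
  retained-intron isoforms as FASTA) with the per-read alignment match
  percentage 100·(M+I−NM)/(M+I);
* a **ground-truth simulator** of chromatin dnRNA-seq reads (per-allele
  order mixtures, poly(A) distributions, cleavage sites, SNP errors,
  unassignable reads) writing SAM + phased VCF + BED fixtures.

See `docs/methods.md` for the full model, rules, defaults and limitations.

## Worked example

Simulate a small dataset and run the whole pipeline (the `analysis/`
scripts do the same with planted allelic effects):

```sh
splicord simulate --genes 2 --introns 3 --depth 150 --seed 1 --out fix/
splicord run-all --bam fix/reads.sam --vcf fix/variants.vcf \
    --annotation fix/introns.bed --out out/ --seed 1
```

Running the shipped study drivers:

```sh
python analysis/01_simulate_fixture.py
python analysis/02_run_pipeline.py
```

prints (abridged):

```
intron groups tested: 3
  gene0:0-1-2: d=0.143 top 2->3->1 vs 1->2->3
  gene1:0-1-2: d=1.414 top 1->2->3 vs 2->1->3 <- allele-specific reversal_of_first_or_last_two_positions
  gene2:0-1-2: d=0.087 top 3->2->1 vs 2->1->3
intron pairs tested: 5, called: ['gene1:0-1']
polya: 3 genes tested, called: ['gene1']
ends: 3 genes tested, called: ['gene1']
abundance: 3 genes tested, called: []
```

gene1 carries every planted effect: its haplotypes remove introns in
different orders (score vectors (1,0,…) vs (0,0,1,…), hence the maximal
distance √2 ≈ 1.414 and the "first two positions reversed" class), its
tails differ by ~90 nt (233 vs 143 nt means), and its 3' sites sit 100 nt
apart. The null genes gene0/gene2 show small distances and no calls — their
"top" orders are noise around the uniform mixture and never pass the
distance + FDR rule. `analysis/03_null_calibration.py` quantifies this:
across 100 null genes every caller's rate at FDR 0.05 is 0.00.
`analysis/04_genotype_association.py` shows the haplotype-block association
flagging a causal SNP (p ≈ 6e-79) while an unrelated control block stays
flat (p = 0.19).

Stage outputs are TSVs with `#` metadata headers (status, alleles, counts,
orders, comparison, pair_comparison, read_table, polya, ends, abundance)
plus a JSON manifest; reruns with the same configuration are byte-identical.

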