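# silentscan

A tested pipeline for the computational procedures of a multi-strain
transgene-silencing study in *Chlamydomonas*:

- **Transposon mobility survey** (`te_survey`) — read pairs are aligned
  against a transposon reference set; pairs with exactly one mapped mate
  ("half-mapped" pairs) anchor the element's genomic location via the
  unmapped mate.  Anchor pileups pooled over strains are merged into loci
  (≥10 distinct reads), presence is scored per strain (≥10 reads), and loci
  with a max/min count ratio ≥10 are flagged as differential.  A per-element
  pattern-class summary (shared / strain-specific / all-but-progenitor-line)
  is emitted.
- **Built-in read mapper** (`read_mapping`) — a deterministic ungapped
  seed-and-extend mapper (k-mer seeds over both strands, Hamming scoring,
  ties → unmapped) plus lossless SAM round-trip via pysam, so the survey runs
  end-to-end on synthetic data without an external aligner.
- **Variant triage and CAPS design** (`variant_triage`) — keep variants
  called reference in the progenitor strain but alternate in ≥1 mutant; find
  genes carrying distinct protein-changing variants private to each of two
  mutants; score restriction-site gain/loss (both strands, IUPAC degeneracy)
  caused by a substitution.  Reads/writes annotated VCF.
- **Differential expression** (`deg_stats`) — FPKM, median-of-ratios
  normalization, an empirical-Bayes moderated t stand-in test,
  Benjamini-Hochberg adjustment, two strict DEG criteria
  (|log2FC|>1 ∧ padj<0.01; fold-change>2 ∧ mean FPKM>1 ∧ padj<0.01), and the
  four-way directional Venn decomposition.
- **ChIP-qPCR quantification** (`chip_norm`) — percent-of-input from Cq
  differences (10% input, efficiency 2 by default), replicate-wise
  normalization to a reference region, mean ± SD/SE over replicates.
- **Mapping-screen genetics** (`mapping_screen`) — expression-phenotype
  calls (≥30%, inclusive), recombination frequencies on a phenotype-selected
  population, linkage calls (<20%, strict), YET complementation scoring
  (<30%, strict) with the four printed class bins, and summary rows.
- **Phylogenetics** (`phylo`) — Poisson-corrected protein distances
  (−ln(1−p)), Saitou–Nei neighbor joining with a deterministic tie rule,
  column-bootstrap supports, Newick output.
- **Synthetic data** (`synthetic_data`) — seeded generators for every input:
  multi-strain genomes with planted transposon insertions, FR paired-end
  reads, negative-binomial count matrices with planted fold-changes, Cq
  tables, segregant genotypes, annotated variant sets, and protein
  alignments evolved on a known tree.  Every generator returns ground truth
  for recovery testing.
- **Orchestration** (`pipeline`) — YAML configuration, per-stage seed
  expansion from one root seed, and `run_demo` exercising every stage with
  a machine-readable report of invariant checks.

## Command line

```bash
silentscan simulate genomes --length 60000 --gc 0.64 --seed 1 --out genome.fa
silentscan simulate reads --genome genome.fa --coverage 30 --seed 1 --out reads/
silentscan map --ref genome.fa --fq1 reads/reads_1.fastq --fq2 reads/reads_2.fastq --out out.sam
silentscan te-survey --te-ref te.fa --genome genome.fa \
    --strain UVM11=r1.fq,r2.fq --strain Elow47=s1.fq,s2.fq --out survey/
silentscan variants triage --vcf variants.vcf --progenitor Elow47 --mutants UVM4,UVM11
silentscan variants caps --window window.fa --pos 6 --ref G --alt A
silentscan deg --counts counts.tsv --group-a A1,A2,A3,A4 --group-b B1,B2,B3,B4 --mode ma --out deg/
silentscan chip --cq cq.tsv --reference-region CYC6 --out enrichment.tsv
silentscan screen yet --in lines.tsv
silentscan screen rf --genotypes genotypes.tsv
silentscan phylo --alignment aln.fa --bootstrap 500 --seed 1 --out phylo/
silentscan run-demo --out demo/
```

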