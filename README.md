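# editome

Detection, filtering and condition-specific analysis of RNA-editing sites
in haploid genomes from RNA-seq per-site base counts.

On a haploid genome, intermediate non-reference base frequencies in
RNA-seq cannot be explained by heterozygosity, so — after aggressive
artefact filtering — they indicate RNA editing. This package implements
that full analysis as a tested, reusable pipeline:

- **Calling** — per-site binomial error model B(n, p) with p = 0.01
  (Phred 20 worst case), upper-tail p-values, Benjamini–Hochberg
  correction over all candidate sites, significance at corrected p < 0.01,
  and a multi-allelic rule (≥ 20% overall frequency, ≥ 2 reads per
  allele).
- **Filter cascade** — edit-frequency bounds (5–95%), 201-bp window
  uniqueness against the genome (BLAST outfmt-6 ingestion or an internal
  seed-and-extend search), strand bias (> 85% of edit-supporting reads on
  one strand), intron-edge proximity (first/last 9 bp), and DNA-seq
  concordance; every site carries per-filter flags and an audit table
  reports survivors per stage.
- **Counting contract** — pileups from SAM (or REDItools-style count
  tables) with 9-bp read-end exclusion, unique-mapper-only, per-sample
  de-duplication and homopolymer masking.
- **Spatial statistics** — length-normalised positional histograms per
  gene/exon/intron, a 5′-enrichment binomial test, and a Monte-Carlo
  neighbour-distance clustering test (10,000 shuffles, χ² vs the averaged
  expected distribution).
- **Differential editing** — per-gene binomial GLM
  (`edited,unedited ~ condition * position`) on replicate × position
  cells, analysis-of-deviance LRT against the position-only model, BH per
  contrast, significance at corrected p < 0.05.
- **Effect annotation** — SnpEff-style classes (UTRs, start/stop
  gain/loss, synonymous/non-synonymous, intron), per-class Fisher + BH
  contingency analysis, 20×20 amino-acid change matrix, and delta-shift
  t-tests (non-synonymous vs synonymous).
- **Motif prep** — 201-bp transcript-sense context windows per edit type
  (genic or spliced/exonic), train/test split with multi-edit windows
  forced into the test set, background windows from unedited genes; FASTA
  export for external motif tools.
- **Synthetic data** — seeded generator for a genome with planted
  multi-exon genes on both strands, a ground-truth editome with
  per-condition frequencies, and per-sample RNA/DNA count tables
  (negative-binomial coverage, uniform miscalls, per-read strand
  allocation), so every stage is testable offline.

## Command line

```bash
# generate a synthetic dataset
editome simulate --seed 1 --n-genes 50 --n-edits 150 --out demo/

# full pipeline from a YAML config
editome run --config pipeline.yaml

# or stage by stage
editome call --genome demo/genome.fa --counts demo/counts_control_r1.tsv \
    --counts demo/counts_heat_r1.tsv --out sites.tsv
editome filter --sites sites.tsv --genome demo/genome.fa \
    --gff demo/genes.gff3 --dna-counts demo/dna_counts.tsv --out-prefix flt
editome spatial --sites flt.filtered.tsv --gff demo/genes.gff3 \
    --out-prefix sp
editome diffedit --sites flt.filtered.tsv --genome demo/genome.fa \
    --gff demo/genes.gff3 --samples demo/samples.tsv --out-prefix de
editome annotate --sites flt.filtered.tsv --genome demo/genome.fa \
    --gff demo/genes.gff3 --out-prefix ann
editome motif-prep --sites flt.filtered.tsv --genome demo/genome.fa \
    --gff demo/genes.gff3 --out-dir motifs/
```

Pipeline config schema (`editome run`):

```yaml
genome: demo/genome.fa        # FASTA
gff: demo/genes.gff3          # GFF3 gene models
samples: demo/samples.tsv     # TSV: path, condition, replicate
dna_counts: demo/dna_counts.tsv   # optional
blast_hits: hits.outfmt6.tsv      # optional; else internal uniqueness mode
outdir: results/
seed: 1
shuffles: 10000
control_condition: control
thresholds:                   # all optional; defaults shown
  error_rate: 0.01
  significance: 0.01
  min_frequency: 0.05
  max_frequency: 0.95
  strand_bias_threshold: 0.85
  intron_edge_margin: 9
  dna_mode: strict
```

## File formats

All inputs and outputs are plain text.

- **Count tables** (TSV): columns `contig`, `position` (1-based), `ref`,
  then per-strand counts `A+ A- C+ C- G+ G- T+ T-` (or plain `A C G T`,
  in which case the strand-bias filter reports not-evaluable).
- **Alignments**: SAM; reads contribute bases only at offsets
  `[end_trim, length - end_trim)`, non-unique reads (MAPQ 0 or NH > 1)
  are dropped, duplicates collapse on (contig, start, mate-start, strand).
- **BLAST hits**: tabular outfmt 6 with query ids `contig:start-end`
  (1-based window coordinates).
- **Called sites** (TSV): contig, 1-based position, ref, alt(s), n, k,
  frequency, p, q, per-strand support, per-filter flags.

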