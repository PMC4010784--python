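# srnablocks

A small RNA-seq analysis toolkit built around proximity-based "blocks":
from raw reads through hierarchical alignment triage, multi-mapper-aware
block quantification, two-proportion (difference-in-proportion) differential
expression, hairpin-criteria miRNA discovery, and functional classification
of differentially expressed blocks — together with a synthetic
genome/read simulator that plants miRNA hairpins, TE/genic siRNA clusters,
tRNA/rDNA decoys and fold-change loci with machine-readable ground truth.

## Modules

| module | what it does |
| --- | --- |
| `srnablocks.synthgen` | synthetic genome, GFF3 annotation, decoy/organellar contigs, exact-depth multinomial read libraries, truth tables |
| `srnablocks.preprocess` | read collapsing to unique tags, 17–35 nt size selection, abundance-ranked single-mismatch error correction |
| `srnablocks.aligner` | exact and bounded-mismatch (substitution-only) placement on both strands; hierarchical triage: tRNA/rDNA (≤3 mm) → genome (perfect) → genome (relaxed) → chloroplast → mitochondrion → unmapped |
| `srnablocks.blocks` | proximity-based block building (default gap 100 nt), 1/k multi-mapper weighting, size-class profiles |
| `srnablocks.diffexp` | pooled two-proportion z-test on raw counts, Bonferroni correction, >20 RPM prefilter, 2-fold cutoff, six-contrast preset |
| `srnablocks.mirna_discovery` | ≤20-locus candidate selection, 170-nt strand-specific windows, folding (built-in baseline folder or ViennaRNA), the three goodness-of-fold criteria + ΔG gate, repeat screening, known/novel calls |
| `srnablocks.annotate` | key sequences, 20–24 nt size histograms, shuffle-calibrated local-alignment search against known matures, miRNA-like / siRNA-gene / siRNA-TE classification |
| `srnablocks.pipeline` / `srnablocks.cli` | end-to-end orchestration with a YAML config and a JSON run manifest |

## CLI

Run everything on the default synthetic design:

```bash
srnablocks all --out run/
```

or stage by stage:

```bash
srnablocks simulate --config config.yaml --out sim/
srnablocks preprocess --fastq sim/reads_lib_a.fastq --fastq sim/reads_lib_b.fastq --out tags.tsv
srnablocks align --tags tags.tsv --genome sim/genome.fa --trna sim/trna.fa \
    --rdna sim/rdna.fa --chloroplast sim/chloroplast.fa \
    --mitochondrion sim/mitochondrion.fa --out aln/
srnablocks blocks --hits aln/genome_hits.tsv --tags tags.tsv --gap 100 --out blk/
srnablocks de --matrix blk/block_counts.tsv --out de/
srnablocks mirna --genome sim/genome.fa --hits aln/genome_hits.tsv \
    --tags tags.tsv --mature sim/mature.fa --gff sim/annotation.gff3 --out mir/
```

A config YAML holds the simulator design (`sim:`) and all analysis
parameters (`params:`); every parameter defaults to the published value
where one exists (17–35 nt size range, ≤3 mismatches on tRNA/rDNA, perfect
matches on the genome, 20 RPM low-expression filter, 2-fold cutoff,
Bonferroni α = 0.05, ≤20 genomic loci for miRNA candidacy, 170-nt windows,
ΔG ≤ −40 kcal/mol at 25 °C). See `tests/test_cli.py` for a complete example.

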