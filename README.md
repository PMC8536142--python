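# kmerdecomp

Alignment-free comparison of genomic regions via k-mer spectra, with
Pearson-correlation decomposition into tandem-repeat and G+C-defined word
sets, mismatch-tolerant contribution analysis, strand-pattern
classification, and deviation-pattern profiling — runnable end-to-end on
synthetic annotated genomes.

## What it does

- **Region extraction** (`kmerdecomp.regions`): load FASTA + GFF3 (or a
  minimal GenBank feature table) and derive genic, exonic, CDS, intronic
  and intergenic interval sets (0-based half-open internally), with
  composition statistics and BED/GFF3 export. Introns exclude exons of any
  gene; intergenic is the complement of all gene spans.
- **k-mer algebra** (`kmerdecomp.kmers`): spectra of all 4^k words (k ≤ 11)
  counted on one strand in overlapping windows (non-ACGT windows skipped);
  reverse complements, tandem-repeat shift sequences, STR words by minimal
  repeat-unit length b, poly/homo word families over the extended base code
  (W/S/R/Y/K/M), Hamming-1 neighborhoods and G+C word bins.
- **Null models** (`kmerdecomp.markov`): zero- and first-order Markov
  reference models (strand-symmetric, G+C-targeted, optional homopolymer
  persistence), exact expected spectra and replicate reference ensembles.
- **Correlation decomposition** (`kmerdecomp.decomposition`): Pearson r on
  frequency vectors; contribution of any word set as its share of the
  covariance numerator (exactly additive over partitions); 0-mismatch vs
  ≤1-mismatch contributions and their ratio tables; mean correlations with
  reference subtraction and quadrature errors.
- **Pattern analysis** (`kmerdecomp.patterns`): inverse-complement vs shift
  strand-pattern calls with a configurable relative tolerance;
  single-mismatch deviation profiles; ambiguity bands and strong-tendency
  flags; the three-rule expected-ranking engine and rule-coverage
  summaries; a 2-subset bipartition heuristic for genome-genome correlation
  matrices.
- **Synthetic genomes** (`kmerdecomp.synthetic`): deterministic annotated
  genomes with configurable G+C, gene/exon/intron structure, period-3 CDS
  bias, planted STR tracts (per region class, with strand-symmetry and
  mismatch-preference knobs) and full ground truth.
- **Pipeline + CLI** (`kmerdecomp.pipeline`, `kmerdecomp.cli`): one command
  producing correlation matrices, mean-correlation tables, contribution
  tables, ratio tables, strand-pattern calls, deviation profiles and rule
  coverage, all TSV + JSON with a manifest.

## CLI

```bash
# synthetic genome with planted intronic (AT)n tracts
kmerdecomp simulate --length 1000000 --gc 0.4 --plant intronic:AT:50:20 --out genome/

# region classes and composition
kmerdecomp regions genome/genome.fasta genome/genome.gff3 --out regions/

# spectra, correlation, decomposition
kmerdecomp spectrum genome/genome.fasta --k 7 --annotation genome/genome.gff3 \
    --region intronic --out intronic.tsv
kmerdecomp correlate intronic.tsv intergenic.tsv
kmerdecomp decompose intronic.tsv intergenic.tsv --grouping b

# single-mismatch deviation profiles of the 16 b<=2 STR words
kmerdecomp deviations intronic.tsv

# full pipeline on two synthetic genomes
kmerdecomp run-all --synthetic 2 --k 7 --seed 1 --out results/
```

`run-all` also accepts a YAML config (`--config run.yaml`) mirroring the
`RunConfig` fields.

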