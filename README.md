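# methcut

Methylation profiling from cut-site read counts: a tested, reusable pipeline
for reduced-representation methylation data in which a methylation-sensitive
restriction enzyme (paired with an insensitive companion) generates per-locus
read counts that report the unmethylated fraction of each site.

The package covers the full analysis chain plus a synthetic-data generator so
every stage can be exercised and scored against planted ground truth:

| module | what it does |
| --- | --- |
| `methcut.synth` | seeded synthetic genomes with planted recognition sites, per-locus methylation truth (clustered differential effects), negative-binomial count matrices |
| `methcut.digest` | IUPAC-aware in-silico double digestion, fragment size / mixed-end selection, candidate-enzyme ranking |
| `methcut.counts` | count-matrix assembly, library standardization, minimum-coverage filter, relative methylation levels, PCA QC |
| `methcut.dmp` | per-locus binomial logistic-regression differential test (closed-form LRT), Benjamini–Hochberg FDR, direction calls |
| `methcut.dmr` | adjacent-window DMR calling (≥ 2 concordant significant positions) with window-width optimization over a 100–2000 bp grid |
| `methcut.genemap` | GFF3/BED gene models, strand-aware 2.5 kb regulatory extensions, DMR–gene intersection with body/regulatory classification |
| `methcut.downstream` | early/mid/continuous response classification (configurable set algebra), hypergeometric term enrichment with BH+Bonferroni consensus, 2^−ΔΔCt relative expression, methylation/expression agreement calls |

## Command-line usage

All stages are exposed through one entry point:

```sh
# synthetic dataset (genome FASTA, counts TSV, design TSV, planted truth BED)
methcut simulate --seed 1 --outdir sim/

# in-silico digestion and enzyme choice
methcut digest --fasta sim/genome.fasta --out fragments.bed
methcut rank-enzymes --fasta sim/genome.fasta --out ranking.tsv

# counts -> methylation levels, QC
methcut counts --counts sim/counts.tsv --design sim/design.tsv --out-prefix run
methcut qc-pca --counts sim/counts.tsv --design sim/design.tsv --out pca.tsv

# differential positions and regions
methcut dmp --counts sim/counts.tsv --design sim/design.tsv \
    --comparison T30_vs_T0 --out t30.dmp.tsv
methcut dmr --dmp t30.dmp.tsv --chrom-lengths sim/chrom_lengths.tsv --out-prefix t30

# gene assignment and downstream analyses
methcut annotate --dmr-bed t30.dmr.bed --annotation genes.gff3 --out-prefix t30
methcut classify --genes gene_directions.tsv --out classes.tsv
methcut enrich --selected sel.txt --background bg.txt --term-map terms.tsv --out enrich.tsv
methcut qpcr --ct-table ct.tsv --out-prefix qpcr
methcut agree --outcomes outcomes.tsv --out agreement.tsv

# whole pipeline from one YAML config
methcut run-all --config pipeline.yaml --outdir run/
```

Coordinates are 0-based half-open everywhere; GFF3 input is converted on
load. Counts TSV is `chrom  pos  <sample>...`; the design table is
`sample  bulk  timepoint  library_size`.

## Statistical notes

- Counts are modeled as arising from successful digestion at unmethylated
  sites: expected count = library scale × locus propensity × (1 −
  methylation). The relative-methylation transform anchors each locus at its
  most-cut sample (`level = 1 − count / rowmax`), so every locus has at
  least one zero-methylation sample; a `--meth-transform`-style hook
  (`relative_methylation(transform=...)`) accepts alternatives.
- The binomial trials used by the differential test default to
  `rowmax − rowmean` per locus ("noise-matched"), which makes the binomial
  proportion variance match the counting-noise variance of the level
  estimate and keeps the null test calibrated; `trials_mode="rowmax"` gives
  the naive (anti-conservative) alternative.
- The two-group binomial logistic regression is fitted in closed form (the
  group-wise pooled proportions are the MLE), so the likelihood-ratio test
  equals the G-test on the pooled 2×2 table and genome-scale scans stay
  vectorized. No overdispersion correction is applied — a documented
  limitation.
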