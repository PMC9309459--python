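# sweepscan

Cross-population selective-sweep scanning for diploid SNP data, as used in
crop-breeding selection studies: a composite likelihood ratio (XP-CLR-style)
sliding-window scan between subpopulations, percentile-based region calling
with cross-comparison consensus, Weir–Cockerham F_ST and nucleotide-diversity
cross-validation, and region annotation (genes, QTL overlaps, high-impact
alleles, GO-term enrichment). A synthetic-data module with known drift and
sweep structure makes every stage testable without external downloads.

## Method overview

1. **Filtering** (`variantio`) — biallelic SNPs only; minor-allele-frequency
   (default 5%), per-SNP heterozygous-call fraction (default 0.591) and
   missingness filters.
2. **Scan** (`xpclr`) — per ordered (test, reference) subpopulation pair, a
   genome-wide drift coefficient ω is estimated, then each 100 kb window
   (10 kb step, ≤200 SNPs, LD down-weighting) is scored with
   `2 · max_σ Σ_j w_j (log L_sweep − log L_neutral)` where the sweep model
   uses escape probability `c = 1 − exp(−d/σ)` at genetic distance `d` and a
   truncated-Normal drift kernel integrated against the binomial sampling
   likelihood by Gauss–Legendre quadrature.
3. **Region calling** (`regions`) — centromere masking; per-subpopulation
   cutoff = mean of its comparisons' 99th-percentile scores; windows above
   the cutoff merged (gap ≤ 100 kb), regions < 80 kb dropped; consensus =
   bases supported by ≥ N comparisons (3 for the larger group, 2 for the
   smaller), re-merged and length-filtered.
4. **Cross-validation** (`popstats`) — per-SNP Weir–Cockerham (1984) F_ST
   (pooled-monomorphic sites removed, negative values clamped to 0),
   ratio-of-sums windowed F_ST, windowed per-bp nucleotide diversity, and
   per-gene/per-region mean F_ST.
5. **Annotation** (`annotate`) — genes and QTLs overlapping regions,
   candidate genes by three criteria (F_ST > 0.5, HIGH-impact SnpEff
   effects, QTL candidate genes), per-subpopulation allele-count tables,
   per-region GO enrichment (hypergeometric test, Benjamini–Hochberg FDR).
6. **Pipeline** (`pipeline`) — YAML-configured orchestration of all ordered
   pairwise scans within each subpopulation group, with checksummed,
   resumable TSV outputs.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (summary-table
arithmetic, estimator-vs-oracle equivalences, neutral-limit and
sweep-recovery simulations, end-to-end truth recovery); the full suite takes
a few minutes, dominated by the simulation-backed tests.

## CLI

```sh
sweepscan simulate --out-dir sim/ --n-pops 2 --seq-len 1000000 --seed 1
sweepscan filter --vcf in.vcf --out filtered.vcf --maf 0.05 --max-het 0.591
sweepscan scan --vcf filtered.vcf --pops popmap.tsv --test I5 --ref I2 \
    --window 100000 --step 10000 --out track.tsv
sweepscan cutoff track1.tsv track2.tsv track3.tsv
sweepscan call --track track.tsv --cutoff 440 --out regions.tsv
sweepscan consensus r1.tsv r2.tsv r3.tsv --min-support 3 --out final.tsv
sweepscan summary --regions final.tsv --genome-bp 373245519
sweepscan fst --vcf filtered.vcf --pops popmap.tsv --pop-a I5 --pop-b I2,I3,I4 \
    --out fst.tsv
sweepscan pi --vcf filtered.vcf --pops popmap.tsv --pop I5 --out pi.tsv
sweepscan run --config config.yaml
```

A complete worked example (9 subpopulations, 2 chromosomes, 3 planted
sweeps, ready-made `config.yaml`) is produced by
`sweepscan.sim.make_bundled_dataset(outdir, seed)`.

## Notes

- Internal intervals are 0-based half-open; VCF positions 1-based. GFF3 is
  converted on read/write.
- Genetic distance defaults to physical distance × 1 cM/Mb (configurable;
  a genetic-map TSV `chrom, bp, cM` is linearly interpolated when given).
- The windowed F_ST estimator is the ratio of variance-component sums;
  per-gene and per-region values are means of per-SNP clamped θ. Published
  tracks do not state the windowed variant; this choice is documented here.
- GO enrichment uses the classical per-term hypergeometric test with BH-FDR
  (no GO-graph decorrelation).
- One known source-table discrepancy: a figure caption reports 5.4% coverage
  for one subpopulation where the summary table's arithmetic yields 5.3%;
  `region_summary` follows the table.
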